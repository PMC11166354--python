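"""End-to-end drivers tying the simulator to the pipelines.

These functions run whole analyses (generate/ingest reads, preprocess,
filter, map, call, test) and return the summary objects the CLI and the
reproduction script report.  They contain no science of their own — each
step is a call into the corresponding module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import fourc, methylation, qpcr, simulate, srna
from .mapper import SequenceIndex
from .simulate import SimulatedHaplotype, SrnaLibrarySpec


def haplotype_indexes(sim: SimulatedHaplotype):
    genome_index = SequenceIndex({"genome": sim.genome})
    collapsed_index = SequenceIndex({"collapsed": sim.collapsed.sequence})
    structural_index = SequenceIndex({"structural": sim.structural_ref})
    return genome_index, collapsed_index, structural_index


@dataclass
class ProcessedLibrary:
    name: str
    genotype: str
    tissue: str
    clean_total: int
    alignments: list
    clean_lengths: list[int] = field(default_factory=list)


def process_srna_library(
    raw_reads,
    name: str,
    genotype: str,
    tissue: str,
    genome_index: SequenceIndex,
    collapsed_index: SequenceIndex,
    structural_index: SequenceIndex,
    protocol: str = "umi4n",
    adapter: str = "TGGAATTCTCGGGTGCCAAGG",
) -> ProcessedLibrary:
    lib = srna.preprocess_reads(raw_reads, protocol=protocol, adapter=adapter,
                                name=name, genotype=genotype, tissue=tissue)
    clean = srna.filter_structural(lib, structural_index)
    alignments = srna.map_library(clean, genome_index, collapsed_index)
    return ProcessedLibrary(name, genotype, tissue, clean.clean_total,
                            alignments, [len(r) for r in clean.reads])


@dataclass
class SrnaContrastResult:
    clusters: srna.SrnaClusterSet
    differential: pd.DataFrame  # quantify_and_test output + significance
    libraries: list[ProcessedLibrary]
    alpha: float

    @property
    def significant(self) -> pd.DataFrame:
        return self.differential[self.differential["significant"]]


def run_srna_contrast(
    specs: list[SrnaLibrarySpec],
    sim: SimulatedHaplotype,
    rng: np.random.Generator,
    group_labels: tuple[str, str],
    alpha: float = 0.05,
    family_wise: bool = True,
    test: str = "welch",
) -> SrnaContrastResult:
    """Simulate the listed libraries, run the full sRNA pipeline, call
    clusters on all of them and test group B against group A.

    A cluster is reported as differential when its p-value clears ``alpha``;
    with ``family_wise`` (default) the threshold is Bonferroni-shared across
    the called clusters, the defensible rule when a whole cluster set is
    screened.
    """
    genome_index, collapsed_index, structural_index = haplotype_indexes(sim)
    libs = []
    for spec in specs:
        raw, _ = simulate.simulate_srna_library(spec, sim, rng)
        libs.append(process_srna_library(
            raw, spec.name, spec.genotype, spec.tissue,
            genome_index, collapsed_index, structural_index))
    group_a = [(l.alignments, l.clean_total) for l in libs
               if l.genotype == group_labels[0]]
    group_b = [(l.alignments, l.clean_total) for l in libs
               if l.genotype == group_labels[1]]
    clusters = srna.call_clusters(
        [l.alignments for l in libs],
        [l.clean_total for l in libs],
    )
    diff = srna.quantify_and_test(clusters, group_a, group_b, test=test)
    threshold = alpha / max(len(diff), 1) if family_wise else alpha
    diff["significant"] = diff["p"] < threshold
    return SrnaContrastResult(clusters, diff, libs, alpha)


def usr_cluster_row(result: SrnaContrastResult, sim: SimulatedHaplotype) -> pd.Series:
    """The differential-test row of the cluster overlapping the USR."""
    usr = sim.usr_collapsed
    d = result.differential
    hit = d[(d["start"] < usr[1]) & (d["end"] > usr[0])]
    if len(hit) == 0:
        raise ValueError("no cluster overlaps the USR")
    return hit.iloc[0]


def region_size_profile(
    libs: list[ProcessedLibrary], region: tuple[int, int]
) -> srna.SizeClassProfile:
    pooled = [a for l in libs for a in l.alignments]
    return srna.size_class_profile(pooled, region)


def region_rpm(lib: ProcessedLibrary, region: tuple[int, int]) -> float:
    n = sum(1 for a in lib.alignments if a.start < region[1] and a.end > region[0])
    return 1e6 * n / lib.clean_total


def genomewide_residual_24(
    het: ProcessedLibrary, mut: ProcessedLibrary
) -> float:
    """21-mer-normalised residual fraction of 24-mers in a mutant library,
    computed on all clean reads (before genome filtering)."""
    het_profile = srna.size_class_profile(het.clean_lengths)
    mut_profile = srna.size_class_profile(mut.clean_lengths)
    _, residual = srna.normalize_by_21mer(mut_profile, het_profile)
    return residual[24]


@dataclass
class FourCResult:
    tag_table: fourc.FourCTagTable
    binned: pd.DataFrame
    parse_report: dict
    truth_weights: dict


def run_fourc(
    sim: SimulatedHaplotype,
    rng: np.random.Generator,
    sim_cfg: simulate.FourCSimConfig | None = None,
) -> FourCResult:
    """Simulate one 4C library and run parsing, mapping, exclusion,
    ranking and binning against the collapsed haplotype."""
    sim_cfg = sim_cfg or simulate.FourCSimConfig()
    reads, _, weights = simulate.simulate_4c_reads(sim_cfg, sim, rng)
    cfg = fourc.FourCConfig(bait_position=sim.bait_collapsed,
                            read_length=sim_cfg.read_length)
    fragments, report = fourc.parse_4c_library(reads, cfg)
    genome_index, collapsed_index, _ = haplotype_indexes(sim)
    table = fourc.quantify_tags(fragments, genome_index, collapsed_index, cfg)
    binned = fourc.bin_tags(table, cfg.bin_size,
                            region_length=sim.collapsed.length)
    return FourCResult(table, binned, report, weights)


def run_methylation(
    sim: SimulatedHaplotype,
    rng: np.random.Generator,
    cfg: simulate.MethylSimConfig | None = None,
) -> dict:
    """Simulate converted amplicon clones for every genotype and call
    per-context methylation plus the control conversion efficiency."""
    cfg = cfg or simulate.MethylSimConfig()
    usr = sim.usr_collapsed
    ref = sim.collapsed.sequence[usr[0] : usr[0] + cfg.amplicon_length]
    data = simulate.simulate_methyl_clones(cfg, ref, rng)
    profiles = {
        geno: methylation.profile_clones(clones, ref)
        for geno, clones in data["clones"].items()
    }
    efficiency, ok = methylation.conversion_efficiency(
        data["lambda_clones"], data["lambda_reference"])
    return {
        "profiles": profiles,
        "percent": {g: p.percent_methylated() for g, p in profiles.items()},
        "conversion_efficiency": efficiency,
        "conversion_ok": ok,
        "truth_rates": data["truth_rates"],
    }


def run_qpcr(
    rng: np.random.Generator,
    cfg: simulate.QpcrSimConfig | None = None,
) -> dict[str, qpcr.FoldChangeResult]:
    cfg = cfg or simulate.QpcrSimConfig()
    table = simulate.simulate_ct_table(cfg, rng)
    return {
        amp: qpcr.delta_delta_ct(table, amp, cfg.reference_amplicon,
                                 cfg.calibrator_group)
        for amp in cfg.true_folds
    }
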