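"""Synthetic data generator for every pipeline input, with recorded truth.

The generator emulates the geometry and genotype signatures of a
repeat-associated paramutation locus:

* a desk-sized haplotype (default 50 kb) carrying a perfect tandem array
  (default 2092 bp unit x 5 copies) with an embedded 390 bp unique
  subregion (USR), a highly repetitive DNA-TE fragment (copies of which
  also sit in a decoy genome background, making its reads multi-map
  genome-wide) and a relatively unique PIF-Harbinger-type TE next to the
  USR;
* genotype-dependent small-RNA emission: 24-mer-dominant USR production in
  the repressed (Pl') state, strongly reduced in the active (Pl-Rh) state,
  with scenario builders for the published genotype contrasts (cob and
  seedling Pl-Rh vs Pl', chd3a redistribution, rpd1/rmr1 genome-wide
  size-class depletion);
* 4C amplicon reads with the designed P5-primer-DpnII-fragment-NlaIII-
  primer-P7 anatomy plus anchor-less decoy reads;
* conversion-treated methylation amplicon clones with per-context truth
  rates and an unmethylated lambda-style control;
* raw Ct tables with known fold changes and Gaussian noise.

All randomness flows from one ``numpy`` integer-seeded generator; a fixed
seed reproduces every output byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .haplotype import (
    CollapsedReference,
    Feature,
    HaplotypeModel,
    TandemArray,
    collapse_repeats,
    reverse_complement,
)

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

SRNA_LENGTHS = list(range(18, 31))


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(BASES, size=length).tobytes().decode("ascii")


# ---------------------------------------------------------------------------
# haplotype


@dataclass
class HaplotypeSimConfig:
    length: int = 50_000
    unit_length: int = 2092
    copy_number: int = 5
    array_position: int = 24_000
    usr_offset: int = 850       # within the repeat unit
    usr_length: int = 390
    te1_offset: int = 200       # highly repetitive DNA TE (multimaps genome-wide)
    te1_length: int = 300
    te2_offset: int = 1290      # relatively unique DNA TE flanking the USR
    te2_length: int = 350
    bait_position: int = 6000   # exclusion-window centre, full coordinates
    decoy_length: int = 20_000  # genome background
    decoy_te1_copies: int = 3
    structural_length: int = 2000  # synthetic rRNA/tRNA reference


@dataclass
class SimulatedHaplotype:
    """A generated haplotype plus everything downstream stages need."""

    model: HaplotypeModel
    collapsed: CollapsedReference
    genome: str          # decoy background standing in for the whole genome
    structural_ref: str  # synthetic rRNA/tRNA reference
    config: HaplotypeSimConfig

    @property
    def array(self) -> TandemArray:
        return self.model.arrays[0]

    def unit_interval_full(self, copy: int, offset: int, length: int) -> tuple[int, int]:
        s = self.array.start + copy * self.array.unit_length + offset
        return s, s + length

    def unit_interval_collapsed(self, offset: int, length: int) -> tuple[int, int]:
        s = self.collapsed.collapse_position(self.array.start) + offset
        return s, s + length

    @property
    def usr_collapsed(self) -> tuple[int, int]:
        return self.unit_interval_collapsed(self.config.usr_offset, self.config.usr_length)

    @property
    def te1_collapsed(self) -> tuple[int, int]:
        return self.unit_interval_collapsed(self.config.te1_offset, self.config.te1_length)

    @property
    def te2_collapsed(self) -> tuple[int, int]:
        return self.unit_interval_collapsed(self.config.te2_offset, self.config.te2_length)

    @property
    def bait_collapsed(self) -> int:
        return self.collapsed.collapse_position(self.config.bait_position)


def generate_haplotype(
    cfg: HaplotypeSimConfig | None = None, rng: np.random.Generator | int = 0
) -> SimulatedHaplotype:
    cfg = cfg or HaplotypeSimConfig()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    span = cfg.unit_length * cfg.copy_number
    if cfg.array_position + span >= cfg.length:
        raise ValueError("array does not fit in the haplotype")
    unit_chars = list(_random_seq(rng, cfg.unit_length))
    # the 4C scenario needs a cuttable (DpnII) fragment inside the USR
    site = cfg.usr_offset + cfg.usr_length // 3
    unit_chars[site : site + 4] = "GATC"
    unit = "".join(unit_chars)
    hap = list(_random_seq(rng, cfg.length))
    hap[cfg.bait_position : cfg.bait_position + 4] = "GATC"
    hap[cfg.array_position : cfg.array_position + span] = list(unit * cfg.copy_number)
    sequence = "".join(hap)
    array = TandemArray(cfg.array_position, cfg.unit_length, cfg.copy_number, unit)
    features = [
        Feature("bait", cfg.bait_position, cfg.bait_position + 4, "+", "bait"),
    ]
    for copy in range(cfg.copy_number):
        base = cfg.array_position + copy * cfg.unit_length
        features.append(Feature(f"USR_{copy}", base + cfg.usr_offset,
                                base + cfg.usr_offset + cfg.usr_length, "+", "USR"))
        features.append(Feature(f"TE_DNA7_{copy}", base + cfg.te1_offset,
                                base + cfg.te1_offset + cfg.te1_length, "+", "transposon"))
        features.append(Feature(f"TE_PIF_{copy}", base + cfg.te2_offset,
                                base + cfg.te2_offset + cfg.te2_length, "+", "transposon"))
    model = HaplotypeModel("synthetic_haplotype", sequence, features, [array])
    collapsed = collapse_repeats(model)
    # decoy genome: random background with extra copies of the repetitive TE
    te1 = unit[cfg.te1_offset : cfg.te1_offset + cfg.te1_length]
    decoy = list(_random_seq(rng, cfg.decoy_length))
    step = cfg.decoy_length // (cfg.decoy_te1_copies + 1)
    for k in range(cfg.decoy_te1_copies):
        pos = (k + 1) * step
        decoy[pos : pos + cfg.te1_length] = list(te1)
    structural = _random_seq(rng, cfg.structural_length)
    return SimulatedHaplotype(model, collapsed, "".join(decoy), structural, cfg)


# ---------------------------------------------------------------------------
# small RNA libraries


def srna_length_probs(pct24: float = 0.80, pct21: float = 0.05) -> dict[int, float]:
    """Length distribution with specified 24-mer and 21-mer shares; the
    remaining mass is spread uniformly over the other 18-30 nt lengths."""
    rest = (1.0 - pct24 - pct21) / (len(SRNA_LENGTHS) - 2)
    probs = {L: rest for L in SRNA_LENGTHS}
    probs[24] = pct24
    probs[21] = pct21
    return probs


@dataclass
class LocusEmission:
    """One source of sRNA reads.

    ``kind``: 'unit' loci live at an offset within the repeat unit and each
    read picks a random copy; 'interval' loci are fixed full-haplotype
    intervals; 'structural' reads come from the rRNA/tRNA reference.
    """

    name: str
    weight: float
    length_probs: dict[int, float]
    kind: str = "interval"
    interval: tuple[int, int] | None = None  # full coordinates (interval kind)
    unit_offset: int = 0
    unit_length: int = 0
    minus_prob: float = 0.5
    minus_prob_23: float | None = None  # antisense bias for 23-mers if set


@dataclass
class SrnaLibrarySpec:
    name: str
    genotype: str
    tissue: str
    emissions: list[LocusEmission]
    depth: int = 100_000


@dataclass
class SrnaProtocolConfig:
    adapter: str = "TGGAATTCTCGGGTGCCAAGG"
    protocol: str = "umi4n"  # 4 random nt flanking the insert on each side


def simulate_srna_library(
    spec: SrnaLibrarySpec,
    sim: SimulatedHaplotype,
    rng: np.random.Generator,
    protocol: SrnaProtocolConfig | None = None,
) -> tuple[list[str], pd.DataFrame]:
    """Raw reads (adapter/UMI-wrapped inserts) plus a truth table with one
    row per read: origin locus, copy, full/collapsed position, length,
    strand."""
    protocol = protocol or SrnaProtocolConfig()
    weights = np.array([e.weight for e in spec.emissions], dtype=float)
    n_per_locus = rng.multinomial(spec.depth, weights / weights.sum())
    reads: list[str] = []
    rows = []
    read_no = 0
    for em, n in zip(spec.emissions, n_per_locus):
        if n == 0:
            continue
        lengths = np.array(list(em.length_probs))
        probs = np.array([em.length_probs[L] for L in lengths], dtype=float)
        length_draw = rng.choice(lengths, size=n, p=probs / probs.sum())
        minus_p = np.full(n, em.minus_prob)
        if em.minus_prob_23 is not None:
            minus_p[length_draw == 23] = em.minus_prob_23
        minus = rng.random(n) < minus_p
        if em.kind == "unit":
            copies = rng.integers(0, sim.array.copy_number, size=n)
        else:
            copies = np.full(n, -1)
        umis = _random_seq(rng, 8 * n) if protocol.protocol == "umi4n" else ""
        for j in range(n):
            length = int(length_draw[j])
            copy = int(copies[j])
            if em.kind == "structural":
                start = int(rng.integers(0, len(sim.structural_ref) - length + 1))
                insert = sim.structural_ref[start : start + length]
                cpos = -1
            else:
                if em.kind == "unit":
                    lo, hi = sim.unit_interval_full(copy, em.unit_offset,
                                                    em.unit_length)
                else:
                    lo, hi = em.interval
                start = int(rng.integers(lo, hi - length + 1))
                insert = sim.model.sequence[start : start + length]
                cpos = sim.collapsed.collapse_position(start)
            strand = "-" if minus[j] else "+"
            if strand == "-":
                insert = reverse_complement(insert)
            if protocol.protocol == "umi4n":
                raw = (umis[8 * j : 8 * j + 4] + insert
                       + umis[8 * j + 4 : 8 * j + 8] + protocol.adapter)
            else:
                raw = insert + protocol.adapter
            reads.append(raw)
            rows.append((f"{spec.name}:{read_no}", em.name, copy,
                         start if em.kind != "structural" else -1,
                         cpos, length, strand))
            read_no += 1
    truth = pd.DataFrame(
        rows, columns=["read_id", "locus", "copy", "full_start",
                       "collapsed_start", "length", "strand"],
    )
    return reads, truth


def _background_loci(
    sim: SimulatedHaplotype, rng: np.random.Generator,
    n_loci: int = 28, locus_length: int = 300,
) -> list[tuple[int, int]]:
    """Fixed non-array background sRNA loci, well separated and clear of
    the array and the haplotype edges."""
    cfg = sim.config
    forbidden = (cfg.array_position - 2 * locus_length,
                 cfg.array_position + cfg.unit_length * cfg.copy_number + locus_length)
    loci: list[tuple[int, int]] = []
    attempts = 0
    while len(loci) < n_loci and attempts < 100_000:
        attempts += 1
        s = int(rng.integers(500, cfg.length - locus_length - 500))
        if forbidden[0] <= s < forbidden[1]:
            continue
        if any(abs(s - t) < locus_length + 200 for t, _ in loci):
            continue
        loci.append((s, s + locus_length))
    loci.sort()
    return loci


@dataclass
class SrnaScenarioConfig:
    """Emission rates defining the genotype contrasts.

    Weights are per-read origin probabilities.  The repressed-state USR
    weight and the fold between states are the dials the published
    contrasts fix; everything else is shared background.
    """

    depth: int = 100_000
    n_background_loci: int = 28
    background_locus_length: int = 300
    background_weight: float = 0.75   # split equally across background loci
    te1_weight: float = 0.08          # multimapper, removed by genome filter
    te2_weight: float = 0.004
    structural_weight: float = 0.05
    usr_weight_repressed: float = 0.015
    cob_fold: float = 9.9
    seedling_fold: float = 4.4
    usr_pct24: float = 0.79
    background_pct24: float = 0.80
    cob_minus_prob_23: float = 0.8    # antisense bias for cob 23-mers
    # chd3a scenario
    chd3a_usr_residual: float = 0.52  # 48% USR reduction in the mutant
    chd3a_te2_fold: float = 15.8
    chd3a_usr_pct24_mutant: float = 0.73
    chd3a_te2_pct24: float = 0.678
    chd3a_te2_pct24_mutant: float = 0.777
    # genome-wide size-class scenarios
    genomewide_pct24: float = 0.60
    genomewide_pct21: float = 0.15
    rpd1_residual_24: float = 0.08
    rmr1_residual_24: float = 0.48


def _base_emissions(
    sim: SimulatedHaplotype, scn: SrnaScenarioConfig, loci: list[tuple[int, int]],
    usr_weight: float, usr_pct24: float, te2_weight: float | None = None,
    te2_pct24: float | None = None, minus_prob_23: float | None = None,
) -> list[LocusEmission]:
    cfg = sim.config
    ems = [
        LocusEmission("structural", scn.structural_weight,
                      srna_length_probs(0.5), kind="structural"),
        LocusEmission("TE_DNA7", scn.te1_weight, srna_length_probs(0.8),
                      kind="unit", unit_offset=cfg.te1_offset,
                      unit_length=cfg.te1_length),
        LocusEmission("TE_PIF", te2_weight if te2_weight is not None else scn.te2_weight,
                      srna_length_probs(te2_pct24 if te2_pct24 is not None else 0.7),
                      kind="unit", unit_offset=cfg.te2_offset,
                      unit_length=cfg.te2_length),
        LocusEmission("USR", usr_weight, srna_length_probs(usr_pct24),
                      kind="unit", unit_offset=cfg.usr_offset,
                      unit_length=cfg.usr_length, minus_prob_23=minus_prob_23),
    ]
    per_bg = scn.background_weight / len(loci)
    for j, iv in enumerate(loci):
        ems.append(LocusEmission(f"bg{j:02d}", per_bg,
                                 srna_length_probs(scn.background_pct24),
                                 interval=iv, minus_prob_23=minus_prob_23))
    return ems


def contrast_specs(
    sim: SimulatedHaplotype,
    rng: np.random.Generator,
    scn: SrnaScenarioConfig | None = None,
    tissue: str = "cob",
    n_per_group: int = 3,
) -> list[SrnaLibrarySpec]:
    """Pl-Rh vs Pl' libraries for one tissue: USR emission high in the
    repressed state, ``fold`` lower in the active state; all other loci
    shared."""
    scn = scn or SrnaScenarioConfig()
    loci = _background_loci(sim, rng, scn.n_background_loci,
                            scn.background_locus_length)
    fold = scn.cob_fold if tissue == "cob" else scn.seedling_fold
    minus23 = scn.cob_minus_prob_23 if tissue == "cob" else None
    specs = []
    for g, usr_w in (("Pl-Rh", scn.usr_weight_repressed / fold),
                     ("Pl'", scn.usr_weight_repressed)):
        for r in range(n_per_group):
            ems = _base_emissions(sim, scn, loci, usr_w, scn.usr_pct24,
                                  minus_prob_23=minus23)
            specs.append(SrnaLibrarySpec(f"{tissue}_{g}_{r + 1}", g, tissue,
                                         ems, scn.depth))
    return specs


def chd3a_specs(
    sim: SimulatedHaplotype,
    rng: np.random.Generator,
    scn: SrnaScenarioConfig | None = None,
    n_nonmutant: int = 2,
    n_mutant: int = 3,
) -> list[SrnaLibrarySpec]:
    """chd3a redistribution in Pl' seedlings: mutant USR output drops to
    ``chd3a_usr_residual`` of the non-mutant level while the flanking PIF
    TE gains a ``chd3a_te2_fold`` peak."""
    scn = scn or SrnaScenarioConfig()
    loci = _background_loci(sim, rng, scn.n_background_loci,
                            scn.background_locus_length)
    specs = []
    for r in range(n_nonmutant):
        ems = _base_emissions(sim, scn, loci, scn.usr_weight_repressed,
                              scn.usr_pct24, te2_pct24=scn.chd3a_te2_pct24)
        specs.append(SrnaLibrarySpec(f"seedling_Chd3a_{r + 1}", "Chd3a",
                                     "seedling", ems, scn.depth))
    for r in range(n_mutant):
        ems = _base_emissions(
            sim, scn, loci,
            scn.usr_weight_repressed * scn.chd3a_usr_residual,
            scn.chd3a_usr_pct24_mutant,
            te2_weight=scn.te2_weight * scn.chd3a_te2_fold,
            te2_pct24=scn.chd3a_te2_pct24_mutant,
        )
        specs.append(SrnaLibrarySpec(f"seedling_chd3a-3_{r + 1}", "chd3a-3",
                                     "seedling", ems, scn.depth))
    return specs


def sizeclass_mutant_specs(
    sim: SimulatedHaplotype,
    rng: np.random.Generator,
    residual_24: float,
    label: str,
    scn: SrnaScenarioConfig | None = None,
) -> list[SrnaLibrarySpec]:
    """Heterozygote + mutant pair for genome-wide size-class depletion:
    the mutant loses (1 - residual_24) of its 24-mers while 21-mer output
    is unchanged, and the library is resampled to depth (so percentages
    renormalise, which the 21-mer normalisation must undo).  The mutant
    also loses USR emission entirely."""
    scn = scn or SrnaScenarioConfig()
    loci = _background_loci(sim, rng, scn.n_background_loci,
                            scn.background_locus_length)
    het_probs = srna_length_probs(scn.genomewide_pct24, scn.genomewide_pct21)
    mut_probs = dict(het_probs)
    mut_probs[24] = het_probs[24] * residual_24
    specs = []
    for geno, probs, usr_w in ((f"{label}-het", het_probs, scn.usr_weight_repressed),
                               (f"{label}-mut", mut_probs, 1e-9)):
        ems = _base_emissions(sim, scn, loci, usr_w, scn.usr_pct24)
        for em in ems:
            if em.kind != "structural":
                em.length_probs = dict(probs)
        specs.append(SrnaLibrarySpec(f"cob_{geno}", geno, "cob", ems, scn.depth))
    return specs


# ---------------------------------------------------------------------------
# 4C reads


@dataclass
class FourCSimConfig:
    depth: int = 100_000
    proper_fraction: float = 0.8
    read_length: int = 49
    quality: int = 35
    forward_primer_pad: str = "GTCAG"       # + left-trim adapter = 21 nt primer
    reverse_primer: str = "AGCTATGACGGTTACAGGTC"  # begins after the NlaIII site
    capture_lengths: tuple[int, ...] = (12, 16, 28)  # incl. leading DpnII site
    capture_probs: tuple[float, ...] = (0.25, 0.25, 0.5)
    n_sites: int = 40
    modal_site_weight: float = 0.30   # modal site inside the USR
    array_site_weight: float = 0.05   # other sites inside the repeat unit
    bait_proximal_weight: float = 0.10  # within the exclusion window


def _dpnii_sites(sim: SimulatedHaplotype, margin: int = 40) -> list[int]:
    seq = sim.collapsed.sequence
    sites = []
    i = seq.find("GATC")
    while i != -1:
        if margin <= i < len(seq) - margin:
            sites.append(i)
        i = seq.find("GATC", i + 1)
    return sites


def simulate_4c_reads(
    cfg: FourCSimConfig,
    sim: SimulatedHaplotype,
    rng: np.random.Generator,
) -> tuple[list[tuple[str, str, list[int]]], pd.DataFrame, dict[int, float]]:
    """4C reads plus per-read truth and the true site-weight map
    (collapsed coordinates).

    Proper amplicons are primer + captured fragment (starting at a DpnII
    site of the collapsed haplotype) + NlaIII site + reverse primer,
    truncated to the read length; decoys lack the anchor.
    """
    from .fourc import FourCConfig

    parse_cfg = FourCConfig()
    sites = _dpnii_sites(sim)
    if not sites:
        raise ValueError("no DpnII sites available")
    usr = sim.usr_collapsed
    te1 = sim.te1_collapsed
    bait = sim.bait_collapsed
    unit_lo = sim.collapsed.collapse_position(sim.array.start)
    unit_hi = unit_lo + sim.array.unit_length
    # exclude sites in the repetitive TE (shared with the decoy genome)
    sites = [p for p in sites if not (te1[0] - 30 <= p < te1[1])]
    usr_sites = [p for p in sites if usr[0] <= p < usr[1] - max(cfg.capture_lengths)]
    array_sites = [p for p in sites if unit_lo <= p < unit_hi]
    bait_sites = [p for p in sites if abs(p - bait) <= parse_cfg.exclusion_radius]
    if not usr_sites:
        raise ValueError("no DpnII site inside the USR; adjust the haplotype seed")
    modal = usr_sites[0]
    weights: dict[int, float] = {}
    others = [p for p in sites if p != modal]
    rng.shuffle(others)
    chosen = others[: cfg.n_sites - 1]
    rest_w = 1.0 - cfg.modal_site_weight
    n_array = sum(1 for p in chosen if p in set(array_sites))
    n_bait = sum(1 for p in chosen if p in set(bait_sites))
    n_plain = len(chosen) - n_array - n_bait
    plain_w = max(rest_w - cfg.array_site_weight * n_array
                  - cfg.bait_proximal_weight * n_bait, 0.05)
    for p in chosen:
        if p in set(array_sites):
            weights[p] = cfg.array_site_weight
        elif p in set(bait_sites):
            weights[p] = cfg.bait_proximal_weight
        else:
            weights[p] = plain_w / max(n_plain, 1)
    weights[modal] = cfg.modal_site_weight
    site_list = sorted(weights)
    w = np.array([weights[p] for p in site_list])
    w = w / w.sum()
    true_weights = dict(zip(site_list, w))

    primer = cfg.forward_primer_pad + parse_cfg.left_trim_adapter
    reads = []
    rows = []
    quals = [cfg.quality] * cfg.read_length
    cap_probs = np.array(cfg.capture_probs) / np.sum(cfg.capture_probs)
    seq = sim.collapsed.sequence
    for i in range(cfg.depth):
        rid = f"4c:{i}"
        if rng.random() < cfg.proper_fraction:
            p = int(rng.choice(site_list, p=w))
            cap = int(rng.choice(cfg.capture_lengths, p=cap_probs))
            amplicon = (primer + seq[p : p + cap] + "CATG" + cfg.reverse_primer)
            read = amplicon[: cfg.read_length]
            rows.append((rid, True, p, cap))
        else:
            while True:
                read = _random_seq(rng, cfg.read_length)
                from .trimming import contains_anchor
                if not contains_anchor(read, parse_cfg.forward_anchor,
                                       parse_cfg.anchor_k, parse_cfg.anchor_min_k,
                                       parse_cfg.anchor_max_hamming):
                    break
            rows.append((rid, False, -1, -1))
        reads.append((rid, read, quals))
    truth = pd.DataFrame(rows, columns=["read_id", "proper", "site", "capture_len"])
    return reads, truth, true_weights


# ---------------------------------------------------------------------------
# methylation clones


@dataclass
class MethylSimConfig:
    amplicon_length: int = 123
    clones_per_genotype: int = 20
    conversion_failure: float = 0.0
    lambda_length: int = 300
    lambda_clones: int = 8
    rates: dict = field(default_factory=lambda: {
        "Pl-Rh": {"CG": 0.02, "CHG": 0.02, "CHH": 0.01},
        "Pl'": {"CG": 0.88, "CHG": 0.60, "CHH": 0.07},
        "Pl-Rh/Pl'": {"CG": 0.88, "CHG": 0.60, "CHH": 0.07},
    })


def _convert_clone(
    reference: str, rates: dict[str, float], failure: float,
    rng: np.random.Generator,
) -> str:
    from .methylation import classify_contexts

    contexts = {c.position: c.context for c in classify_contexts(reference, "+")}
    out = list(reference)
    for pos, ctx in contexts.items():
        rate = rates.get(ctx, 0.0) if ctx is not None else 0.0
        if rng.random() < rate:
            continue  # methylated: protected from conversion
        if rng.random() >= failure:
            out[pos] = "T"
    return "".join(out)


def simulate_methyl_clones(
    cfg: MethylSimConfig,
    reference: str,
    rng: np.random.Generator,
) -> dict:
    """Per-genotype converted clones of ``reference`` plus an unmethylated
    lambda-style control with its own reference."""
    clones = {
        geno: {f"{geno}_clone{i}": _convert_clone(reference, rates,
                                                  cfg.conversion_failure, rng)
               for i in range(cfg.clones_per_genotype)}
        for geno, rates in cfg.rates.items()
    }
    lambda_ref = _random_seq(rng, cfg.lambda_length)[: cfg.amplicon_length]
    lambda_clones = {
        f"lambda_clone{i}": _convert_clone(lambda_ref, {}, cfg.conversion_failure, rng)
        for i in range(cfg.lambda_clones)
    }
    return {
        "clones": clones,
        "lambda_reference": lambda_ref,
        "lambda_clones": lambda_clones,
        "truth_rates": cfg.rates,
    }


# ---------------------------------------------------------------------------
# Ct tables


@dataclass
class QpcrSimConfig:
    groups: tuple[str, str] = ("Pl-Rh", "Pl'")
    calibrator_group: str = "Pl'"
    n_biological: int = 3
    n_technical: int = 3
    reference_amplicon: str = "gapdh"
    ct_reference: float = 18.0
    ct_target_base: float = 24.0
    noise_sd_technical: float = 0.1
    noise_sd_biological: float = 0.2   # s.d. of log2 expression per sample
    sample_load_sd: float = 0.3        # common shift of all Cts of a sample
    true_folds: dict = field(default_factory=lambda: {"P3": 15.0})


def simulate_ct_table(
    cfg: QpcrSimConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Raw Ct table with known fold changes.

    Ct = baseline - log2(expression) + noise; the reference amplicon is
    unaffected by group.  Folds are expressed relative to the calibrator
    group."""
    rows = []
    for group in cfg.groups:
        for b in range(cfg.n_biological):
            sample = f"{group}_{b + 1}"
            load = rng.normal(0.0, cfg.sample_load_sd)
            for amp, fold in cfg.true_folds.items():
                expr = fold if group != cfg.calibrator_group else 1.0
                log2e = np.log2(expr) + rng.normal(0.0, cfg.noise_sd_biological)
                base = cfg.ct_target_base - log2e + load
                for t in range(cfg.n_technical):
                    rows.append((sample, group, amp, t + 1,
                                 base + rng.normal(0.0, cfg.noise_sd_technical)))
            for t in range(cfg.n_technical):
                rows.append((sample, group, cfg.reference_amplicon, t + 1,
                             cfg.ct_reference + load
                             + rng.normal(0.0, cfg.noise_sd_technical)))
    return pd.DataFrame(rows, columns=["sample", "group", "amplicon",
                                       "replicate", "ct"])


@dataclass
class SimulationConfig:
    """Master configuration bundling every generator."""

    seed: int = 0
    haplotype: HaplotypeSimConfig = field(default_factory=HaplotypeSimConfig)
    srna: SrnaScenarioConfig = field(default_factory=SrnaScenarioConfig)
    fourc: FourCSimConfig = field(default_factory=FourCSimConfig)
    methyl: MethylSimConfig = field(default_factory=MethylSimConfig)
    qpcr: QpcrSimConfig = field(default_factory=QpcrSimConfig)

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def with_depth(scn: SrnaScenarioConfig, depth: int) -> SrnaScenarioConfig:
    return replace(scn, depth=depth)
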