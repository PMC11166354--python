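"""Small-RNA pipeline: preprocessing, structural-RNA filtering, cluster
calling on a collapsed reference, differential abundance, 5'-collapsed
size/strand profiles and mutant size-class normalisation.

Read counts are normalised to reads per million (rpm) against each
library's *clean* total: the number of reads surviving rRNA/tRNA removal,
before any genome filtering.  Cluster calling merges uniquely-mapped read
intervals separated by less than ``pad`` bases and keeps merged intervals
whose summed read count reaches a minimum coverage expressed in rpm of the
combined defining libraries.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import trimming
from .mapper import ReadAlignment, SequenceIndex, two_pass_filter

LENGTH_RANGE = (18, 30)


@dataclass
class SrnaLibrary:
    """A preprocessed small-RNA library (reads 18-30 nt)."""

    name: str
    reads: list[str]
    genotype: str = ""
    tissue: str = ""
    clean_total: int | None = None  # set by filter_structural; rpm denominator

    def __post_init__(self):
        if self.clean_total is not None and self.clean_total < len(self.reads):
            raise ValueError("clean_total smaller than retained read count")


def preprocess_reads(
    raw_reads,
    protocol: str = "umi4n",
    length_range: tuple[int, int] = LENGTH_RANGE,
    adapter: str = "TGGAATTCTCGGGTGCCAAGG",
    dedup: bool = True,
    adapter_k: int = 18,
    adapter_min_k: int = 11,
    adapter_max_hamming: int = 1,
    trimmed_length_range: tuple[int, int] = (26, 38),
    name: str = "library",
    genotype: str = "",
    tissue: str = "",
) -> SrnaLibrary:
    """Adapter-trim, deduplicate and length-filter raw reads.

    ``protocol='umi4n'`` models kits whose adapters carry 4 random nt on
    each side of the insert: after 3' adapter removal, reads are filtered to
    ``trimmed_length_range`` (insert + 8), deduplicated on the full trimmed
    sequence, and 4 nt are removed from each end.  ``protocol='plain'``
    trims and (optionally) deduplicates only.  The 18-30 nt length filter is
    applied last.
    """
    if protocol not in {"umi4n", "plain"}:
        raise ValueError(f"unknown protocol {protocol!r}")
    if not adapter:
        raise ValueError("adapter required")
    trimmed = [
        trimming.trim_right(r, adapter, adapter_k, adapter_min_k, adapter_max_hamming)
        for r in raw_reads
    ]
    if protocol == "umi4n":
        lo, hi = trimmed_length_range
        trimmed = [r for r in trimmed if lo <= len(r) <= hi]
        if dedup:
            trimmed = list(dict.fromkeys(trimmed))  # order-preserving
        trimmed = [r[4:-4] for r in trimmed]
    elif dedup:
        trimmed = list(dict.fromkeys(trimmed))
    lo, hi = length_range
    reads = [r for r in trimmed if lo <= len(r) <= hi]
    if not reads:
        warnings.warn(f"library {name}: empty after preprocessing")
    return SrnaLibrary(name, reads, genotype, tissue)


def filter_structural(lib: SrnaLibrary, structural_index: SequenceIndex) -> SrnaLibrary:
    """Remove reads with any exact placement (either strand) on the
    rRNA/tRNA reference; the survivors are the 'clean' set and define the
    library's rpm denominator."""
    clean = [r for r in lib.reads if not structural_index.locate(r, limit=1)]
    return SrnaLibrary(lib.name, clean, lib.genotype, lib.tissue, clean_total=len(clean))


@dataclass
class SrnaCluster:
    cluster_id: int
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class SrnaClusterSet:
    clusters: list[SrnaCluster]
    mincov_reads: int
    pad: int

    def __iter__(self):
        return iter(self.clusters)

    def __len__(self):
        return len(self.clusters)


def call_clusters(
    defining_alignments: list[list[ReadAlignment]],
    clean_totals: list[int],
    mincov_rpm: float = 0.5,
    pad: int = 50,
    mincov_reads: int | None = None,
) -> SrnaClusterSet:
    """Call sRNA clusters from uniquely-mapped read intervals.

    Steps: (1) pool read intervals across the defining libraries; (2) merge
    intervals separated by < ``pad`` bp; (3) retain merged intervals whose
    summed read count >= ``mincov_reads``, computed by default as
    ceil(mincov_rpm x sum(clean totals) / 1e6).  Clusters get dense ids in
    coordinate order.
    """
    if pad < 0:
        raise ValueError("pad must be >= 0")
    if mincov_reads is None:
        mincov_reads = math.ceil(mincov_rpm * sum(clean_totals) / 1e6)
        mincov_reads = max(mincov_reads, 1)
    intervals = sorted(
        (aln.start, aln.end) for alns in defining_alignments for aln in alns
    )
    clusters: list[SrnaCluster] = []
    cur_start = cur_end = None
    cur_count = 0
    for s, e in intervals + [(None, None)]:
        if cur_start is not None and (s is None or s - cur_end >= pad):
            if cur_count >= mincov_reads:
                clusters.append(SrnaCluster(len(clusters), cur_start, cur_end))
            cur_start = None
        if s is None:
            break
        if cur_start is None:
            cur_start, cur_end, cur_count = s, e, 1
        else:
            cur_end = max(cur_end, e)
            cur_count += 1
    return SrnaClusterSet(clusters, mincov_reads, pad)


def _overlaps(aln: ReadAlignment, start: int, end: int) -> bool:
    return aln.start < end and aln.end > start  # >= 1 bp intersection


def cluster_counts(
    clusters: SrnaClusterSet, alignments: list[ReadAlignment]
) -> np.ndarray:
    starts = np.array([a.start for a in alignments], dtype=int)
    ends = np.array([a.end for a in alignments], dtype=int)
    return np.array([
        int(((starts < c.end) & (ends > c.start)).sum()) for c in clusters
    ])


@dataclass
class DifferentialResult:
    cluster_id: int
    start: int
    end: int
    mean_a: float  # rpm
    mean_b: float
    fold: float  # mean_b / mean_a
    t: float
    p: float
    test: str


def quantify_and_test(
    clusters: SrnaClusterSet,
    group_a: list[tuple[list[ReadAlignment], int]],
    group_b: list[tuple[list[ReadAlignment], int]],
    test: str = "welch",
    bonferroni: bool = False,
) -> pd.DataFrame:
    """Per-cluster rpm quantification and two-sided two-sample t-tests.

    Each group entry is (alignments, clean_total).  Returns a DataFrame with
    one row per cluster: interval, per-group mean rpm, fold (B over A), t, p.
    Zero variance in both groups with equal means gives p = 1 by convention.
    """
    if test not in {"welch", "pooled"}:
        raise ValueError(f"unknown test variant {test!r}")
    rpm_a = np.array([
        cluster_counts(clusters, alns) * 1e6 / total for alns, total in group_a
    ])  # shape (n_libs, n_clusters)
    rpm_b = np.array([
        cluster_counts(clusters, alns) * 1e6 / total for alns, total in group_b
    ])
    rows = []
    for j, c in enumerate(clusters):
        a, b = rpm_a[:, j], rpm_b[:, j]
        mean_a, mean_b = a.mean(), b.mean()
        fold = mean_b / mean_a if mean_a > 0 else math.inf if mean_b > 0 else math.nan
        if a.std() == 0 and b.std() == 0:
            t, p = (0.0, 1.0) if mean_a == mean_b else (math.inf, 0.0)
        else:
            t, p = stats.ttest_ind(b, a, equal_var=(test == "pooled"))
        rows.append(DifferentialResult(c.cluster_id, c.start, c.end,
                                       mean_a, mean_b, fold, float(t), float(p), test))
    df = pd.DataFrame([r.__dict__ for r in rows])
    if bonferroni and len(df):
        df["p_adjusted"] = np.minimum(df["p"] * len(df), 1.0)
    return df


def collapse_5prime_profile(
    alignments: list[ReadAlignment],
    region: tuple[int, int],
    clean_total: int,
    bin_size: int = 10,
) -> pd.DataFrame:
    """5'-collapsed, strand- and length-separated rpm in bins across a region.

    The 5' coordinate is strand-aware: interval start on the plus strand,
    interval end - 1 on the minus strand.  Bins are half-open, tiled from
    the region start.  Returns columns bin_start, strand, length, rpm.
    """
    start, end = region
    rows = []
    for aln in alignments:
        p5 = aln.start if aln.strand == "+" else aln.end - 1
        if not (start <= p5 < end):
            continue
        rows.append(((p5 - start) // bin_size * bin_size + start, aln.strand, aln.length))
    if not rows:
        return pd.DataFrame(columns=["bin_start", "strand", "length", "rpm"])
    df = pd.DataFrame(rows, columns=["bin_start", "strand", "length"])
    out = df.value_counts().rename("count").reset_index()
    out["rpm"] = out["count"] * 1e6 / clean_total
    return out.drop(columns="count").sort_values(
        ["bin_start", "strand", "length"]).reset_index(drop=True)


@dataclass
class SizeClassProfile:
    """Per-length read percentages over 18-30 nt."""

    percentages: dict[int, float]
    total_reads: int
    defined: bool = True

    def pct(self, length: int) -> float:
        return self.percentages.get(length, 0.0)


def size_class_profile(
    lengths_or_alignments, region: tuple[int, int] | None = None
) -> SizeClassProfile:
    """Length composition of reads, optionally restricted to reads
    overlapping ``region`` by >= 1 bp.  Accepts either read lengths or
    alignments (required when a region is given)."""
    if region is not None:
        start, end = region
        lengths = [a.length for a in lengths_or_alignments if _overlaps(a, start, end)]
    else:
        lengths = [
            a.length if isinstance(a, ReadAlignment) else
            (len(a) if isinstance(a, str) else int(a))
            for a in lengths_or_alignments
        ]
    total = len(lengths)
    if total == 0:
        warnings.warn("empty region: size-class profile undefined")
        return SizeClassProfile({}, 0, defined=False)
    counts = pd.Series(lengths).value_counts()
    pcts = {int(k): 100.0 * v / total for k, v in counts.items()}
    return SizeClassProfile(pcts, total)


def normalize_by_21mer(
    mutant: SizeClassProfile, control: SizeClassProfile
) -> tuple[dict[int, float], dict[int, float]]:
    """Rescale a mutant size-class profile so its 21-mer share matches the
    control's (21-mers are unaffected by loss of the polymerase under
    study), and report per-length residual fractions relative to control.

    normalized(L) = pct_mut(L) * pct21_control / pct21_mut
    residual(L)   = normalized(L) / pct_control(L)
    """
    p21_m, p21_c = mutant.pct(21), control.pct(21)
    if p21_m <= 0 or p21_c <= 0:
        raise ValueError("21-mer percentage is zero: normalization undefined")
    factor = p21_c / p21_m
    normalized = {L: v * factor for L, v in mutant.percentages.items()}
    residual = {
        L: normalized[L] / control.pct(L)
        for L in normalized
        if control.pct(L) > 0
    }
    return normalized, residual


def map_library(
    lib: SrnaLibrary, genome_index: SequenceIndex, target_index: SequenceIndex
) -> list[ReadAlignment]:
    """Two-pass filter a clean library: drop genome multimappers, keep
    unique placements on the collapsed haplotype."""
    return two_pass_filter(lib.reads, genome_index, target_index)
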