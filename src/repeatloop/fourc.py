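"""4C bait-interaction pipeline.

Proper 4C amplicons have the anatomy

    P5 - forward primer (bait) - DpnII site - interacting fragment
       - NlaIII site - reverse primer - P7

sequenced as fixed-length single-end reads.  Parsing proceeds through four
stages, each with its own rejection reason:

1. *anchor*: the read must contain the last 3 nt of the forward primer
   followed by the first-cutter site (default ``CTCGATC``), placing the
   DpnII site in its designed context;
2. *left trim*: everything up through the forward-primer match is removed,
   leaving the captured fragment starting at the first-cutter site; reads
   whose primer could not be recognised stay longer than
   ``post_left_max_len`` and are rejected;
3. *right trim*: the second-cutter site plus reverse-primer start is
   removed if present (fragments long enough to fill the read need not
   contain it); fragments shorter than ``min_fragment_len`` are rejected;
4. *quality*: 3' bases below the quality floor are trimmed, then the read
   is rejected if its mean quality or length is too low.

Retained fragments are mapped (two-pass genome filter then unique placement
on the collapsed haplotype), collapsed to their strand-aware 5'-most
coordinate, windowed away from the bait, rpm-normalised and ranked.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import trimming
from .mapper import SequenceIndex, two_pass_filter

REJECT_ANCHOR = "anchor"
REJECT_LEFT_TRIM = "left_trim"
REJECT_SHORT = "min_fragment_len"
REJECT_QUALITY = "low_quality"
RETAINED = "retained"


@dataclass
class FourCConfig:
    bait_position: int = 0  # exclusion-window centre on the collapsed haplotype
    forward_anchor: str = "CTCGATC"  # 3' 3 nt of forward primer + DpnII site
    left_trim_adapter: str = "TACGCCGGCGGAGCTC"
    right_trim_adapter: str = "CATGAGCTATGA"  # NlaIII site + reverse-primer start
    first_cutter: str = "GATC"
    second_cutter: str = "CATG"
    anchor_k: int = 7
    anchor_min_k: int = 7
    anchor_max_hamming: int = 1
    left_trim_k: int = 16
    left_trim_min_k: int = 12
    left_trim_max_hamming: int = 2
    post_left_max_len: int = 28
    right_trim_k: int = 12
    right_trim_min_k: int = 7
    right_trim_max_hamming: int = 1
    min_fragment_len: int = 8
    quality_floor: float = 20.0
    exclusion_radius: int = 2000
    bin_size: int = 2000
    read_length: int = 49

    def __post_init__(self):
        for a in (self.forward_anchor, self.left_trim_adapter, self.right_trim_adapter):
            if not a or set(a) - set("ACGT"):
                raise ValueError(f"adapter must be non-empty uppercase ACGT: {a!r}")


def parse_4c_read(
    seq: str, quals: list[int] | np.ndarray, cfg: FourCConfig
) -> tuple[str | None, str]:
    """Parse one read; returns ``(fragment, 'retained')`` or ``(None, reason)``."""
    if len(seq) != len(quals):
        raise ValueError("sequence/quality length mismatch")
    # stage 1: DpnII site in primer context
    if not trimming.contains_anchor(
        seq, cfg.forward_anchor, cfg.anchor_k, cfg.anchor_min_k, cfg.anchor_max_hamming
    ):
        return None, REJECT_ANCHOR
    # stage 2: remove primer up to the first-cutter site
    end = trimming.match_left(
        seq, cfg.left_trim_adapter, cfg.left_trim_k, cfg.left_trim_min_k,
        cfg.left_trim_max_hamming,
    )
    if end is not None:
        seq, quals = seq[end:], quals[end:]
    if len(seq) > cfg.post_left_max_len:
        return None, REJECT_LEFT_TRIM
    # stage 3: remove second cutter + reverse primer if present
    start = trimming.match_right(
        seq, cfg.right_trim_adapter, cfg.right_trim_k, cfg.right_trim_min_k,
        cfg.right_trim_max_hamming,
    )
    if start is not None:
        seq, quals = seq[:start], quals[:start]
    if len(seq) < cfg.min_fragment_len:
        return None, REJECT_SHORT
    # stage 4: 3' quality trim then mean-quality floor
    q = np.asarray(quals, dtype=float)
    keep = len(q)
    while keep > 0 and q[keep - 1] < cfg.quality_floor:
        keep -= 1
    seq, q = seq[:keep], q[:keep]
    if len(seq) < cfg.min_fragment_len or q.mean() < cfg.quality_floor:
        return None, REJECT_QUALITY
    return seq, RETAINED


def parse_4c_library(records, cfg: FourCConfig):
    """Parse an iterable of (read_id, sequence, qualities) records.

    Returns (fragments, report) where fragments is a list of
    (read_id, fragment) and report counts each outcome; every input read is
    accounted for exactly once.
    """
    fragments: list[tuple[str, str]] = []
    report = {RETAINED: 0, REJECT_ANCHOR: 0, REJECT_LEFT_TRIM: 0,
              REJECT_SHORT: 0, REJECT_QUALITY: 0}
    for read_id, seq, quals in records:
        frag, outcome = parse_4c_read(seq, quals, cfg)
        report[outcome] += 1
        if frag is not None:
            fragments.append((read_id, frag))
    return fragments, report


@dataclass
class FourCTagTable:
    """Per-position ligation-tag counts on the collapsed haplotype.

    ``table`` columns: position (5'-most base of the captured fragment),
    count, rpm, rank (competition ranking, ties share the better rank).
    rpm is normalised over retained (post-exclusion) tags.
    """

    table: pd.DataFrame
    library_size: int  # retained tag total (rpm denominator)
    n_excluded: int = 0
    report: dict = field(default_factory=dict)

    def top(self, n: int = 5) -> pd.DataFrame:
        return self.table.nsmallest(n, "rank")


def quantify_tags(
    fragments,
    genome_index: SequenceIndex,
    collapsed_index: SequenceIndex,
    cfg: FourCConfig,
) -> FourCTagTable:
    """Map parsed fragments and build the ranked per-position tag table.

    Fragments multi-mapping on the genome are discarded; survivors must map
    uniquely to the collapsed haplotype.  Unique placements are collapsed to
    their strand-aware 5' coordinate (plus strand: interval start; minus
    strand: interval end - 1); positions within ``exclusion_radius`` of the
    bait are removed before rpm normalisation and ranking.
    """
    alignments = two_pass_filter(fragments, genome_index, collapsed_index)
    positions = [
        aln.start if aln.strand == "+" else aln.end - 1 for aln in alignments
    ]
    counts = pd.Series(positions, dtype=int).value_counts().sort_index()
    near_bait = abs(counts.index.to_numpy() - cfg.bait_position) <= cfg.exclusion_radius
    n_excluded = int(counts[near_bait].sum())
    counts = counts[~near_bait]
    total = int(counts.sum())
    if total == 0:
        warnings.warn("no 4C tags retained after mapping and bait exclusion")
        empty = pd.DataFrame(columns=["position", "count", "rpm", "rank"])
        return FourCTagTable(empty, 0, n_excluded)
    df = pd.DataFrame({"position": counts.index, "count": counts.to_numpy()})
    df["rpm"] = 1e6 * df["count"] / total
    df["rank"] = df["rpm"].rank(method="min", ascending=False).astype(int)
    return FourCTagTable(df.reset_index(drop=True), total, n_excluded)


def bin_tags(tag_table: FourCTagTable, bin_size: int | None = None,
             region_length: int | None = None) -> pd.DataFrame:
    """Sum rpm into half-open bins tiled from position 0.

    Returns a DataFrame with columns bin_start, bin_end, rpm.  If
    ``region_length`` is given, empty bins up to it are included with rpm 0.
    """
    if bin_size is None:
        bin_size = 2000
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    df = tag_table.table
    if len(df):
        binned = df.groupby(df["position"] // bin_size)["rpm"].sum()
    else:
        binned = pd.Series(dtype=float)
    if region_length is not None:
        n_bins = (region_length + bin_size - 1) // bin_size
        binned = binned.reindex(range(n_bins), fill_value=0.0)
    out = pd.DataFrame({
        "bin_start": binned.index.to_numpy() * bin_size,
        "rpm": binned.to_numpy(),
    })
    out["bin_end"] = out["bin_start"] + bin_size
    return out[["bin_start", "bin_end", "rpm"]]
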