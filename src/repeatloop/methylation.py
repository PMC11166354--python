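"""Amplicon cytosine-methylation calling from conversion-treated clones.

Unmethylated cytosines are deaminated (APOBEC / bisulfite) and read as T
after PCR; methylated cytosines stay C.  Clones of a short amplicon are
compared ungapped to the reference interval: reference C read as C ->
methylated, read as T -> unmethylated, anything else -> ambiguous.
Cytosines are stratified by sequence context (CG, CHG, CHH with H = A/C/T,
determined by the two bases 3' of the cytosine on its strand), and a fully
unmethylated control (e.g. lambda spike-in) validates conversion
efficiency.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .haplotype import reverse_complement

CONTEXTS = ("CG", "CHG", "CHH")


@dataclass
class CytosineContext:
    position: int  # 0-based on the reference interval, forward coordinates
    strand: str
    context: str | None  # None when the 3' flank is unavailable


def _context_from_flank(nxt: str, nxt2: str | None) -> str | None:
    if nxt == "G":
        return "CG"
    if nxt in "ACT":
        if nxt2 is None:
            return None
        return "CHG" if nxt2 == "G" else "CHH"
    return None  # flank contains N


def classify_contexts(reference: str, strand: str = "+") -> list[CytosineContext]:
    """Context of every cytosine on the chosen strand of ``reference``.

    Positions are always reported in forward-strand coordinates.  Terminal
    cytosines lacking the needed 3' flank get context None (ambiguous).
    """
    if strand not in {"+", "-"}:
        raise ValueError("strand must be '+' or '-'")
    seq = reference if strand == "+" else reverse_complement(reference)
    n = len(seq)
    out = []
    for i, base in enumerate(seq):
        if base != "C":
            continue
        nxt = seq[i + 1] if i + 1 < n else None
        nxt2 = seq[i + 2] if i + 2 < n else None
        if nxt is None:
            ctx = None
        elif nxt == "G":
            ctx = "CG"
        else:
            ctx = _context_from_flank(nxt, nxt2)
        pos = i if strand == "+" else n - 1 - i
        out.append(CytosineContext(pos, strand, ctx))
    return sorted(out, key=lambda c: c.position)


METHYLATED = "methylated"
UNMETHYLATED = "unmethylated"
AMBIGUOUS = "ambiguous"


def call_clone(
    clone: str, reference: str, strand: str = "+", max_mismatches: int = 3
) -> dict[int, str]:
    """Per-cytosine calls for one clone against the reference interval.

    The clone must align without indels (equal length).  On the top strand,
    conversion reads an unmethylated C as T; on the bottom strand (when the
    amplified strand is the reverse complement) the reference C appears as G
    in forward coordinates and converts to A.  Mismatches at non-cytosine
    positions beyond ``max_mismatches`` reject the clone.
    """
    if len(clone) != len(reference):
        raise ValueError("clone/reference length mismatch (indel-containing clone rejected)")
    contexts = classify_contexts(reference, strand)
    cyt_positions = {c.position for c in contexts}
    conv_from, conv_to = ("C", "T") if strand == "+" else ("G", "A")
    mismatches = sum(
        1 for i, (a, b) in enumerate(zip(reference, clone))
        if i not in cyt_positions and a != b
    )
    if mismatches > max_mismatches:
        raise ValueError(
            f"{mismatches} non-cytosine mismatches exceed threshold {max_mismatches}"
        )
    calls: dict[int, str] = {}
    for pos in sorted(cyt_positions):
        base = clone[pos]
        if base == conv_from:
            calls[pos] = METHYLATED
        elif base == conv_to:
            calls[pos] = UNMETHYLATED
        else:
            calls[pos] = AMBIGUOUS
    return calls


@dataclass
class MethylationProfile:
    """Context-stratified methylation summary across clones."""

    calls: pd.DataFrame  # columns: clone, position, context, call
    interval: tuple[int, int]
    conversion_efficiency: float | None = None
    rejected_clones: list[str] = field(default_factory=list)

    def percent_methylated(self) -> dict[str, float]:
        """Per-context percent methylated over unambiguous calls."""
        out = {}
        for ctx in CONTEXTS:
            sub = self.calls[(self.calls["context"] == ctx)
                             & (self.calls["call"] != AMBIGUOUS)]
            out[ctx] = 100.0 * (sub["call"] == METHYLATED).mean() if len(sub) else float("nan")
        return out

    def ambiguous_fraction(self) -> float:
        if not len(self.calls):
            return float("nan")
        return float((self.calls["call"] == AMBIGUOUS).mean())


def profile_clones(
    clones: dict[str, str] | list[str],
    reference: str,
    strand: str = "+",
    interval: tuple[int, int] | None = None,
    max_mismatches: int = 3,
) -> MethylationProfile:
    """Call every clone against the reference; indel/divergent clones are
    recorded as rejected rather than realigned."""
    if not isinstance(clones, dict):
        clones = {f"clone{i}": s for i, s in enumerate(clones)}
    contexts = {c.position: c.context for c in classify_contexts(reference, strand)}
    rows = []
    rejected = []
    for name, seq in clones.items():
        try:
            calls = call_clone(seq, reference, strand, max_mismatches)
        except ValueError:
            rejected.append(name)
            continue
        for pos, call in calls.items():
            ctx = contexts[pos]
            rows.append((name, pos, ctx, call if ctx is not None else AMBIGUOUS))
    df = pd.DataFrame(rows, columns=["clone", "position", "context", "call"])
    return MethylationProfile(df, interval or (0, len(reference)), rejected_clones=rejected)


def conversion_efficiency(
    control_clones: dict[str, str] | list[str],
    control_reference: str,
    strand: str = "+",
    flag_threshold: float = 0.98,
) -> tuple[float, bool]:
    """Fraction of control-reference cytosines read as converted across all
    control clones, and whether it clears ``flag_threshold``.

    The control is fully unmethylated, so every unconverted C marks a
    conversion failure.
    """
    profile = profile_clones(control_clones, control_reference, strand)
    unambig = profile.calls[profile.calls["call"] != AMBIGUOUS]
    if not len(unambig):
        raise ValueError("no callable control cytosines")
    eff = float((unambig["call"] == UNMETHYLATED).mean())
    return eff, eff >= flag_threshold
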