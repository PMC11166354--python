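"""Reference-haplotype modelling: perfect tandem arrays, collapsed references,
coordinate lift-over, and repetitive-index tracks.

The central object is a haplotype carrying one or more perfect tandem arrays
(e.g. a penta-repeat downstream of a regulated gene).  Short reads derived
from any unit of such an array cannot map uniquely to the full sequence, so
analyses run against a *collapsed* reference in which each array is reduced
to a single unit; coordinate maps connect the two spaces.

Coordinates are 0-based, half-open throughout this package.  GFF3 I/O
(see :mod:`repeatloop.io`) converts to/from the 1-based closed convention.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

VALID_BASES = set("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class Feature:
    """An annotated interval on a haplotype (0-based, half-open)."""

    name: str
    start: int
    end: int
    strand: str = "."
    kind: str = "region"
    attributes: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid feature interval [{self.start}, {self.end})")
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class TandemArray:
    """A maximal perfect tandem array: ``unit_sequence`` repeated
    ``copy_number`` times starting at ``start``."""

    start: int
    unit_length: int
    copy_number: int
    unit_sequence: str

    def __post_init__(self):
        if self.copy_number < 2:
            raise ValueError("a tandem array has at least 2 copies")
        if len(self.unit_sequence) != self.unit_length:
            raise ValueError("unit_sequence length disagrees with unit_length")

    @property
    def end(self) -> int:
        return self.start + self.unit_length * self.copy_number

    @property
    def span(self) -> int:
        return self.end - self.start


@dataclass
class HaplotypeModel:
    """A named reference sequence with feature annotations and tandem arrays."""

    name: str
    sequence: str
    features: list[Feature] = field(default_factory=list)
    arrays: list[TandemArray] = field(default_factory=list)

    def __post_init__(self):
        if not self.sequence:
            raise ValueError("empty haplotype sequence")
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise ValueError(f"invalid bases in sequence: {sorted(bad)}")
        for f in self.features:
            if f.end > len(self.sequence):
                raise ValueError(f"feature {f.name} outside sequence")
        for a in self.arrays:
            expected = a.unit_sequence * a.copy_number
            if self.sequence[a.start : a.end] != expected:
                raise ValueError("array does not match its declared unit sequence")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def feature(self, name: str) -> Feature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)


def _primitive_period(unit: str) -> int:
    """Smallest d dividing len(unit) with unit == unit[:d] * (len(unit)//d)."""
    n = len(unit)
    for d in range(1, n // 2 + 1):
        if n % d == 0 and unit == unit[:d] * (n // d):
            return d
    return n


def detect_tandem_arrays(
    sequence: str, min_unit: int, min_copies: int
) -> list[TandemArray]:
    """Find all maximal perfect tandem arrays with primitive unit length
    >= ``min_unit`` and copy number >= ``min_copies``.

    Arrays are reported with the shortest (primitive) unit explaining them
    and the leftmost phase.  Overlap conflicts are resolved in favour of the
    larger span, then the smaller unit.
    """
    if min_unit < 1:
        raise ValueError("min_unit must be >= 1")
    if min_copies < 2:
        raise ValueError("min_copies must be >= 2")
    L = len(sequence)
    if L == 0:
        return []
    arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    candidates: list[TandemArray] = []
    max_period = L // min_copies
    stride = 64
    for p in range(min_unit, max_period + 1):
        eq = arr[:-p] == arr[p:]
        need = (min_copies - 1) * p
        k = need // stride
        if k >= 3:
            # cheap pretest: a match run of length >= need must cover
            # >= k - 1 consecutive strided samples
            s = eq[::stride]
            w = k - 1
            if len(s) < w:
                continue
            cs = np.concatenate(([0], np.cumsum(s, dtype=np.int32)))
            if not (cs[w:] - cs[:-w] == w).any():
                continue
        elif not eq.any():
            continue
        mism = np.flatnonzero(~eq)
        bounds = np.concatenate(([-1], mism, [len(eq)]))
        gaps = np.diff(bounds) - 1
        for idx in np.flatnonzero(gaps >= need):
            s = int(bounds[idx]) + 1
            run_len = int(gaps[idx])
            copies = run_len // p + 1
            unit = sequence[s : s + p]
            if "N" in unit:
                continue
            if _primitive_period(unit) != p:
                # reported at its primitive period instead (or skipped if
                # that period is below min_unit)
                continue
            candidates.append(TandemArray(s, p, copies, unit))
    # resolve overlaps: prefer larger span, then smaller unit, then leftmost
    candidates.sort(key=lambda a: (-a.span, a.unit_length, a.start))
    chosen: list[TandemArray] = []
    for c in candidates:
        if all(c.end <= k.start or c.start >= k.end for k in chosen):
            chosen.append(c)
    chosen.sort(key=lambda a: a.start)
    return chosen


@dataclass
class _Segment:
    """Map between one collapsed-space interval and full space."""

    c_start: int
    c_end: int
    f_start: int
    copy_number: int  # 1 outside arrays
    unit_length: int  # == c_end - c_start inside arrays


class CollapsedReference:
    """Haplotype with each tandem array reduced to a single unit.

    Provides position/interval lift-over in both directions.  A collapsed
    position inside an array lifts to exactly ``copy_number`` full positions;
    any other position lifts to exactly one.
    """

    def __init__(self, sequence: str, segments: list[_Segment], full_length: int):
        self.sequence = sequence
        self.segments = segments
        self.full_length = full_length

    @property
    def length(self) -> int:
        return len(self.sequence)

    def _segment_at(self, cpos: int) -> _Segment:
        if not (0 <= cpos < self.length):
            raise IndexError(f"collapsed position {cpos} out of range")
        for seg in self.segments:
            if seg.c_start <= cpos < seg.c_end:
                return seg
        raise IndexError(cpos)  # pragma: no cover

    def lift_position(self, cpos: int) -> list[int]:
        seg = self._segment_at(cpos)
        off = cpos - seg.c_start
        return [seg.f_start + k * seg.unit_length + off for k in range(seg.copy_number)]

    def collapse_position(self, fpos: int) -> int:
        if not (0 <= fpos < self.full_length):
            raise IndexError(f"full position {fpos} out of range")
        for seg in self.segments:
            span = seg.unit_length * seg.copy_number if seg.copy_number > 1 else seg.c_end - seg.c_start
            if seg.f_start <= fpos < seg.f_start + span:
                off = (fpos - seg.f_start) % seg.unit_length if seg.copy_number > 1 else fpos - seg.f_start
                return seg.c_start + off
        raise IndexError(fpos)  # pragma: no cover


def collapse_repeats(model: HaplotypeModel) -> CollapsedReference:
    """Reduce each tandem array of ``model`` to a single unit.

    Raises ``ValueError`` if the annotated arrays overlap.
    """
    arrays = sorted(model.arrays, key=lambda a: a.start)
    for a, b in zip(arrays, arrays[1:]):
        if a.end > b.start:
            raise ValueError("overlapping tandem arrays: annotation conflict")
    segments: list[_Segment] = []
    parts: list[str] = []
    fpos = 0
    cpos = 0
    for a in arrays:
        if a.start > fpos:
            seg_len = a.start - fpos
            segments.append(_Segment(cpos, cpos + seg_len, fpos, 1, seg_len))
            parts.append(model.sequence[fpos : a.start])
            cpos += seg_len
            fpos = a.start
        segments.append(_Segment(cpos, cpos + a.unit_length, fpos, a.copy_number, a.unit_length))
        parts.append(a.unit_sequence)
        cpos += a.unit_length
        fpos = a.end
    if fpos < model.length:
        seg_len = model.length - fpos
        segments.append(_Segment(cpos, cpos + seg_len, fpos, 1, seg_len))
        parts.append(model.sequence[fpos:])
    return CollapsedReference("".join(parts), segments, model.length)


def lift_to_full(ref: CollapsedReference, interval: tuple[int, int]) -> list[tuple[int, int]]:
    """Lift a collapsed-space interval to all full-space intervals it
    represents.  Intervals straddling an array boundary are rejected."""
    start, end = interval
    if not (0 <= start < end <= ref.length):
        raise IndexError(f"interval [{start}, {end}) outside collapsed space")
    seg = ref._segment_at(start)
    if end > seg.c_end:
        raise ValueError(
            f"interval [{start}, {end}) straddles a segment boundary at {seg.c_end}"
        )
    off = start - seg.c_start
    length = end - start
    return [
        (seg.f_start + k * seg.unit_length + off, seg.f_start + k * seg.unit_length + off + length)
        for k in range(seg.copy_number)
    ]


@dataclass
class RepetitiveIndexTrack:
    """Per-window occurrence counts of a query sequence in a background set.

    ``values[i]`` counts exact occurrences (either strand) of the window
    starting at query position ``i``.  Windows containing N get value 0 and
    a flag.
    """

    window_size: int
    values: np.ndarray
    n_flags: np.ndarray  # bool; True where window contained N


def repetitive_index(
    query: str, background: list[str], window: int = 24
) -> RepetitiveIndexTrack:
    if window > len(query):
        raise ValueError("window longer than query")
    counts: Counter[str] = Counter()
    for bg in background:
        for i in range(len(bg) - window + 1):
            counts[bg[i : i + window]] += 1
    n_pos = len(query) - window + 1
    values = np.zeros(n_pos, dtype=np.int64)
    flags = np.zeros(n_pos, dtype=bool)
    for i in range(n_pos):
        w = query[i : i + window]
        if "N" in w:
            flags[i] = True
            continue
        rc = reverse_complement(w)
        v = counts.get(w, 0)
        if rc != w:
            v += counts.get(rc, 0)
        values[i] = v
    return RepetitiveIndexTrack(window, values, flags)
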