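"""Shared k/mink/hdist adapter-matching contract.

An adapter *matches* a read at a position if a window of length ``k``
aligns with at most ``hdist`` mismatches; at the relevant read end a
partial alignment of length ``mink``..``k-1`` also counts.  Trimming takes
the leftmost match for right-side (3') trimming and the rightmost match for
left-side (5') trimming.  This operational definition is the published
semantics of those parameters and is implemented directly.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def _to_arr(s: str) -> np.ndarray:
    return np.frombuffer(s.encode("ascii"), dtype=np.uint8)


def _full_window_matches(seq: str, pattern: str, hdist: int) -> np.ndarray:
    """Start offsets of all length-len(pattern) windows of ``seq`` matching
    ``pattern`` with <= hdist mismatches."""
    k = len(pattern)
    if len(seq) < k:
        return np.empty(0, dtype=np.int64)
    w = sliding_window_view(_to_arr(seq), k)
    mm = (w != _to_arr(pattern)).sum(axis=1)
    return np.flatnonzero(mm <= hdist)

def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def contains_anchor(seq: str, anchor: str, k: int, mink: int, hdist: int) -> bool:
    """Filter-mode containment check (no trimming)."""
    if len(_full_window_matches(seq, anchor[:k], hdist)):
        return True
    # end partials
    for m in range(k - 1, mink - 1, -1):
        if m > len(seq):
            continue
        if _hamming(seq[-m:], anchor[:m]) <= hdist:  # adapter runs off 3' end
            return True
        if _hamming(seq[:m], anchor[-m:]) <= hdist:  # adapter runs off 5' end
            return True
    return False


def match_right(seq: str, adapter: str, k: int, mink: int, hdist: int) -> int | None:
    """Leftmost start of an adapter match for 3' (right-side) trimming, or
    None.  Partial matches (adapter prefix, length >= mink) are only
    recognised at the read's 3' end."""
    hits = _full_window_matches(seq, adapter[:k], hdist)
    best = int(hits[0]) if len(hits) else None
    for m in range(k - 1, mink - 1, -1):
        if m > len(seq):
            continue
        i = len(seq) - m
        if (best is None or i < best) and _hamming(seq[i:], adapter[:m]) <= hdist:
            best = i
    return best


def match_left(seq: str, adapter: str, k: int, mink: int, hdist: int) -> int | None:
    """End (exclusive) of the rightmost adapter match for 5' (left-side)
    trimming, or None.  Partial matches (adapter suffix, length >= mink) are
    only recognised at the read's 5' end."""
    hits = _full_window_matches(seq, adapter[-k:], hdist)
    best = int(hits[-1]) + k if len(hits) else None
    for m in range(k - 1, mink - 1, -1):
        if m > len(seq):
            continue
        if (best is None or m > best) and _hamming(seq[:m], adapter[-m:]) <= hdist:
            best = m
    return best


def trim_right(seq: str, adapter: str, k: int, mink: int, hdist: int) -> str:
    i = match_right(seq, adapter, k, mink, hdist)
    return seq if i is None else seq[:i]


def trim_left(seq: str, adapter: str, k: int, mink: int, hdist: int) -> str:
    i = match_left(seq, adapter, k, mink, hdist)
    return seq if i is None else seq[i:]
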