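"""Tandem-array detection, collapsed references, lift-over, repetitive index."""

import numpy as np
import pytest

from repeatloop.haplotype import (
    HaplotypeModel,
    TandemArray,
    collapse_repeats,
    detect_tandem_arrays,
    lift_to_full,
    repetitive_index,
    reverse_complement,
)


def brute_force_arrays(seq, min_unit, min_copies):
    """Exhaustive period scan: every (start, period) pair, maximal runs,
    primitive-period reduction."""
    L = len(seq)
    found = []
    for p in range(min_unit, L // min_copies + 1):
        i = 0
        while i + 2 * p <= L:
            # maximal run of s[j] == s[j+p] starting at i
            if seq[i] != seq[i + p]:
                i += 1
                continue
            j = i
            while j + p < L and seq[j] == seq[j + p]:
                j += 1
            run = j - i
            copies = run // p + 1
            if copies >= min_copies:
                unit = seq[i : i + p]
                primitive = next(
                    d for d in range(1, p + 1)
                    if p % d == 0 and unit == unit[:d] * (p // d)
                )
                if primitive == p:
                    found.append((i, p, copies))
            i = j + 1
    # drop contained/overlapping duplicates the same way: larger span first
    found.sort(key=lambda a: (-(a[1] * a[2]), a[1], a[0]))
    kept = []
    for s, p, c in found:
        e = s + p * c
        if all(e <= ks or s >= ks + kp * kc for ks, kp, kc in kept):
            kept.append((s, p, c))
    return sorted(kept)


def test_simple_periodic_string():
    arrays = detect_tandem_arrays("ACGTACGTACGT", min_unit=4, min_copies=2)
    assert [(a.start, a.unit_length, a.copy_number) for a in arrays] == [(0, 4, 3)]
    assert arrays[0].unit_sequence == "ACGT"


def test_random_sequence_has_no_arrays():
    rng = np.random.default_rng(7)
    seq = "".join(rng.choice(list("ACGT"), size=10_000))
    assert detect_tandem_arrays(seq, min_unit=20, min_copies=2) == []
    assert brute_force_arrays(seq[:2000], 20, 2) == []


def test_empty_sequence_gives_empty_list():
    assert detect_tandem_arrays("", 4, 2) == []


@pytest.mark.parametrize("seed,unit_len,copies", [(0, 17, 3), (1, 40, 2), (2, 9, 5)])
def test_detection_matches_brute_force_on_planted_arrays(seed, unit_len, copies):
    rng = np.random.default_rng(seed)
    bases = list("ACGT")
    unit = "".join(rng.choice(bases, size=unit_len))
    left = "".join(rng.choice(bases, size=400))
    right = "".join(rng.choice(bases, size=400))
    seq = left + unit * copies + right
    got = [(a.start, a.unit_length, a.copy_number)
           for a in detect_tandem_arrays(seq, min_unit=5, min_copies=2)]
    assert got == brute_force_arrays(seq, 5, 2)


def test_primitive_period_reported():
    # "ABAB" repeated: unit AB is the primitive explanation
    seq = "GGGG" + "ACAC" * 4 + "TTTT"
    arrays = detect_tandem_arrays(seq, min_unit=2, min_copies=2)
    assert [(a.start, a.unit_length, a.copy_number) for a in arrays] == [(4, 2, 8)]


def _model_with_array(seed=3, left=10, unit_len=20, copies=3, right=30):
    rng = np.random.default_rng(seed)
    bases = list("ACGT")
    unit = "".join(rng.choice(bases, size=unit_len))
    seq = ("".join(rng.choice(bases, size=left)) + unit * copies
           + "".join(rng.choice(bases, size=right)))
    arr = TandemArray(left, unit_len, copies, unit)
    return HaplotypeModel("m", seq, arrays=[arr])


def test_collapse_lengths_and_maps():
    model = _model_with_array(left=10, unit_len=20, copies=3, right=30)
    ref = collapse_repeats(model)
    assert ref.length == model.length - 2 * 20
    # collapsed position inside the array lifts to one position per copy
    assert ref.lift_position(15) == [15, 35, 55]
    # outside: identity before the array, shifted after
    assert ref.lift_position(5) == [5]
    assert ref.lift_position(35) == [35 + 2 * 20]


def test_collapse_with_no_arrays_is_identity():
    model = HaplotypeModel("m", "ACGTACGTAA")
    ref = collapse_repeats(model)
    assert ref.sequence == model.sequence
    assert all(ref.lift_position(i) == [i] for i in range(model.length))


def test_overlapping_arrays_rejected():
    seq = "ACAC" * 10
    model = HaplotypeModel.__new__(HaplotypeModel)  # bypass unit validation
    model.name, model.sequence, model.features = "m", seq, []
    model.arrays = [TandemArray(0, 2, 10, "AC"), TandemArray(2, 2, 8, "AC")]
    with pytest.raises(ValueError, match="overlap"):
        collapse_repeats(model)


def test_lift_round_trip_and_position_conservation():
    model = _model_with_array(left=13, unit_len=11, copies=4, right=17)
    ref = collapse_repeats(model)
    lifted_total = 0
    for c in range(ref.length):
        fulls = ref.lift_position(c)
        lifted_total += len(fulls)
        for f in fulls:
            assert ref.collapse_position(f) == c
    assert lifted_total == model.length


def test_lift_to_full_interval_semantics():
    model = _model_with_array(left=10, unit_len=20, copies=3, right=30)
    ref = collapse_repeats(model)
    assert lift_to_full(ref, (2, 8)) == [(2, 8)]
    assert lift_to_full(ref, (12, 28)) == [(12, 28), (32, 48), (52, 68)]
    with pytest.raises(ValueError, match="straddles"):
        lift_to_full(ref, (8, 14))
    with pytest.raises(IndexError):
        lift_to_full(ref, (0, ref.length + 1))


def naive_window_counts(query, backgrounds, k):
    vals = []
    for i in range(len(query) - k + 1):
        w = query[i : i + k]
        if "N" in w:
            vals.append(0)
            continue
        rc = reverse_complement(w)
        hits = set()
        for b, bg in enumerate(backgrounds):
            for j in range(len(bg) - k + 1):
                if bg[j : j + k] == w or bg[j : j + k] == rc:
                    hits.add((b, j))
        vals.append(len(hits))
    return vals


def test_repetitive_index_self_background_unique():
    rng = np.random.default_rng(11)
    seq = "".join(rng.choice(list("ACGT"), size=500))
    track = repetitive_index(seq, [seq], window=24)
    assert (track.values >= 1).all()
    assert (track.values == 1).mean() > 0.99  # random 24-mers ~unique


def test_repetitive_index_counts_array_copies(sim_hap):
    unit = sim_hap.array
    win_start = unit.start + 50
    window_seq = sim_hap.model.sequence[win_start : win_start + 24]
    track = repetitive_index(window_seq, [sim_hap.model.sequence], window=24)
    assert track.values[0] == unit.copy_number


def test_repetitive_index_matches_naive_scan():
    rng = np.random.default_rng(5)
    q = "".join(rng.choice(list("ACGT"), size=120))
    bgs = ["".join(rng.choice(list("ACGT"), size=300)), q[30:90]]
    track = repetitive_index(q, bgs, window=8)
    assert list(track.values) == naive_window_counts(q, bgs, 8)


def test_repetitive_index_flags_n_windows():
    track = repetitive_index("ACGTNACGTACG", ["ACGTACGTACGT"], window=4)
    assert track.n_flags[1]  # window containing the N
    assert track.values[1] == 0
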