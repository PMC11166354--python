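"""sRNA preprocessing, filtering, cluster calling, differential testing,
5'-collapsed profiles and 21-mer size-class normalisation."""

import math

import numpy as np
import pytest
from scipy import stats

from repeatloop import simulate
from repeatloop.mapper import ReadAlignment, SequenceIndex
from repeatloop.srna import (
    SizeClassProfile,
    SrnaLibrary,
    call_clusters,
    collapse_5prime_profile,
    filter_structural,
    normalize_by_21mer,
    preprocess_reads,
    quantify_and_test,
    size_class_profile,
)

ADAPTER = "TGGAATTCTCGGGTGCCAAGG"


def _raw(insert, umi5="ACGT", umi3="TGCA"):
    return umi5 + insert + umi3 + ADAPTER


class TestPreprocess:
    def test_umi_read_recovers_insert(self, rng):
        insert = "".join(rng.choice(list("ACGT"), size=24))
        lib = preprocess_reads([_raw(insert)], protocol="umi4n", adapter=ADAPTER)
        assert lib.reads == [insert]

    def test_duplicates_collapse_to_one(self):
        insert = "ACGTACGTACGTACGTACGTACGT"
        lib = preprocess_reads([_raw(insert)] * 3, protocol="umi4n")
        assert lib.reads == [insert]
        # distinct UMIs are distinct molecules: both survive
        lib2 = preprocess_reads([_raw(insert, "AAAA"), _raw(insert, "CCCC")])
        assert lib2.reads == [insert, insert]

    @pytest.mark.parametrize("n,kept", [(17, False), (18, True), (30, True), (31, False)])
    def test_length_window_boundaries(self, n, kept, rng):
        insert = "".join(rng.choice(list("ACGT"), size=n))
        lib = preprocess_reads([_raw(insert)], protocol="umi4n")
        assert (lib.reads == [insert]) == kept

    def test_plain_protocol_skips_umi_strip(self):
        insert = "ACGTACGTACGTACGTACGTACG"
        lib = preprocess_reads([insert + ADAPTER], protocol="plain", dedup=False)
        assert lib.reads == [insert]

    def test_empty_library_warns(self):
        with pytest.warns(UserWarning, match="empty"):
            lib = preprocess_reads(["ACGT" + ADAPTER], protocol="plain")
        assert lib.reads == []


def test_structural_filter_sets_clean_total(rng):
    structural = "".join(rng.choice(list("ACGT"), size=500))
    idx = SequenceIndex({"s": structural})
    struct_reads = [structural[i : i + 21] for i in range(0, 40, 10)]
    other = ["".join(rng.choice(list("ACGT"), size=24)) for _ in range(10)]
    lib = SrnaLibrary("x", struct_reads + other)
    clean = filter_structural(lib, idx)
    assert clean.reads == other
    assert clean.clean_total == len(other)


def _aln(start, length=24, strand="+", name="r"):
    return ReadAlignment(name, "unique", length, "t", start, strand)


class TestClusterCalling:
    def test_pad_boundary(self):
        near = [_aln(0), _aln(24 + 49)]   # gap 49 < pad 50: one cluster
        far = [_aln(0), _aln(24 + 51)]    # gap 51: two candidates
        one = call_clusters([near], [100], mincov_reads=1)
        two = call_clusters([far], [100], mincov_reads=1)
        assert len(one) == 1 and (one.clusters[0].start, one.clusters[0].end) == (0, 97)
        assert len(two) == 2

    def test_mincov_boundary(self):
        alns = [_aln(i) for i in [0, 5, 10]]
        assert len(call_clusters([alns], [100], mincov_reads=3)) == 1
        assert len(call_clusters([alns], [100], mincov_reads=4)) == 0

    def test_mincov_recomputed_from_clean_totals(self):
        # 0.5 rpm of 8M combined clean reads -> 4 reads
        alns = [_aln(i) for i in [0, 3, 6]]
        cs = call_clusters([alns], [8_000_000], mincov_rpm=0.5)
        assert cs.mincov_reads == 4 and len(cs) == 0

    def test_matches_interval_merge_oracle(self, rng):
        """Union-find component oracle over random placements: link every
        interval pair with gap < pad, then threshold component sizes."""
        n = 800
        starts = rng.integers(0, 60_000, size=n)
        lengths = rng.integers(18, 31, size=n)
        alns = [_aln(int(s), int(l)) for s, l in zip(starts, lengths)]
        pad, mincov = 50, 3
        got = call_clusters([alns], [n], pad=pad, mincov_reads=mincov)
        ivs = [(a.start, a.end) for a in alns]
        parent = list(range(n))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(n):
            for j in range(i):
                gap = max(ivs[i][0] - ivs[j][1], ivs[j][0] - ivs[i][1])
                if gap < pad:
                    parent[find(i)] = find(j)
        comps = {}
        for i, iv in enumerate(ivs):
            comps.setdefault(find(i), []).append(iv)
        expect = sorted(
            (min(s for s, _ in c), max(e for _, e in c))
            for c in comps.values() if len(c) >= mincov
        )
        assert [(c.start, c.end) for c in got] == expect


class TestDifferential:
    def _clusters(self):
        return call_clusters([[_aln(10)]], [100], mincov_reads=1)

    def _group(self, counts, total=1_000_000):
        return [([_aln(10)] * c, total) for c in counts]

    def test_identical_groups_fold_one_p_one(self):
        cs = self._clusters()
        df = quantify_and_test(cs, self._group([2, 2]), self._group([2, 2]))
        assert df["fold"].iloc[0] == 1.0 and df["p"].iloc[0] == 1.0

    def test_textbook_two_sample_computation(self):
        """rpm A={1,2,3}, B={2,4,6}: fold 2; Welch t and p from the closed
        form."""
        cs = self._clusters()
        df = quantify_and_test(cs, self._group([1, 2, 3]), self._group([2, 4, 6]))
        assert df["fold"].iloc[0] == pytest.approx(2.0)
        s2a, s2b, n = 1.0, 4.0, 3
        se = math.sqrt(s2a / n + s2b / n)
        t_expect = (4.0 - 2.0) / se
        df_w = (s2a / n + s2b / n) ** 2 / (
            (s2a / n) ** 2 / (n - 1) + (s2b / n) ** 2 / (n - 1))
        p_expect = 2 * stats.t.sf(t_expect, df_w)
        assert df["t"].iloc[0] == pytest.approx(t_expect)
        assert df["p"].iloc[0] == pytest.approx(p_expect)
        pooled = quantify_and_test(cs, self._group([1, 2, 3]),
                                   self._group([2, 4, 6]), test="pooled")
        sp2 = (2 * s2a + 2 * s2b) / 4
        t_pool = 2.0 / math.sqrt(sp2 * 2 / 3)
        assert pooled["t"].iloc[0] == pytest.approx(t_pool)

    def test_bonferroni_option(self):
        cs = self._clusters()
        df = quantify_and_test(cs, self._group([1, 2, 3]), self._group([2, 4, 6]),
                               bonferroni=True)
        assert df["p_adjusted"].iloc[0] == pytest.approx(min(df["p"].iloc[0] * 1, 1))

    def test_true_fold_cluster_is_the_unique_significant_one(self, sim_hap):
        """With one truly differential locus among several null loci, only
        that cluster reaches alpha=0.01, in >=90% of seeds."""
        scn = simulate.SrnaScenarioConfig(depth=10_000, n_background_loci=4,
                                          te2_weight=0.01)
        from repeatloop import workflows

        usr = sim_hap.usr_collapsed
        hits, false_pos = 0, 0
        n_seeds = 10
        for seed in range(n_seeds):
            rng = np.random.default_rng(1000 + seed)
            specs = simulate.contrast_specs(sim_hap, rng, scn, tissue="cob")
            res = workflows.run_srna_contrast(specs, sim_hap, rng,
                                              ("Pl-Rh", "Pl'"),
                                              alpha=0.01, family_wise=False)
            sig = res.differential[res.differential["p"] < 0.01]
            is_usr = (sig["start"] < usr[1]) & (sig["end"] > usr[0])
            hits += int(is_usr.any())
            false_pos += int((~is_usr).sum())
        assert hits >= 0.9 * n_seeds
        assert false_pos <= 2  # null clusters stay at the alpha level


class TestProfiles:
    def test_five_prime_collapse_strand_aware(self):
        plus = _aln(100, 24, "+")
        minus = _aln(100, 24, "-")
        prof = collapse_5prime_profile([plus, minus], (0, 200), clean_total=1000)
        plus_row = prof[prof["strand"] == "+"].iloc[0]
        minus_row = prof[prof["strand"] == "-"].iloc[0]
        assert plus_row["bin_start"] == 100
        assert minus_row["bin_start"] == 120  # 5' of a minus read = end - 1
        assert plus_row["rpm"] == pytest.approx(1000.0)

    def test_five_prime_profile_matches_loop_oracle(self, rng):
        alns = [_aln(int(s), int(l), "+-"[int(m)])
                for s, l, m in zip(rng.integers(0, 300, 400),
                                   rng.integers(18, 31, 400),
                                   rng.integers(0, 2, 400))]
        prof = collapse_5prime_profile(alns, (0, 400), clean_total=400, bin_size=10)
        naive = {}
        for a in alns:
            p5 = a.start if a.strand == "+" else a.end - 1
            if not 0 <= p5 < 400:
                continue
            key = (p5 // 10 * 10, a.strand, a.length)
            naive[key] = naive.get(key, 0) + 1e6 / 400
        got = {(r.bin_start, r.strand, r.length): r.rpm
               for r in prof.itertuples()}
        assert got == pytest.approx(naive)
        assert prof["rpm"].sum() == pytest.approx(sum(naive.values()))

    def test_size_class_profile_pure_24(self):
        prof = size_class_profile([24] * 50)
        assert prof.pct(24) == 100.0 and prof.defined

    def test_size_class_profile_empty_region_flagged(self):
        with pytest.warns(UserWarning, match="undefined"):
            prof = size_class_profile([_aln(500)], region=(0, 100))
        assert not prof.defined

    def test_size_class_percentages_sum_to_100(self, rng):
        lengths = rng.integers(18, 31, size=500)
        prof = size_class_profile(list(lengths))
        assert sum(prof.percentages.values()) == pytest.approx(100.0)


class TestNormalize21:
    def test_equal_pct21_leaves_profile_unchanged(self):
        m = SizeClassProfile({21: 30.0, 24: 5.0}, 100)
        c = SizeClassProfile({21: 30.0, 24: 50.0}, 100)
        norm, resid = normalize_by_21mer(m, c)
        assert norm == pytest.approx(m.percentages)
        assert resid[24] == pytest.approx(0.1)

    def test_stated_arithmetic(self):
        m = SizeClassProfile({21: 30.0, 24: 5.0}, 100)
        c = SizeClassProfile({21: 15.0, 24: 40.0}, 100)
        norm, resid = normalize_by_21mer(m, c)
        assert norm[24] == pytest.approx(2.5)
        assert resid[24] == pytest.approx(2.5 / 40.0)

    def test_zero_pct21_is_an_error(self):
        m = SizeClassProfile({24: 100.0}, 10)
        c = SizeClassProfile({21: 10.0, 24: 90.0}, 10)
        with pytest.raises(ValueError, match="21-mer"):
            normalize_by_21mer(m, c)

    def test_invariant_under_uniform_subsampling(self, rng):
        lengths = list(rng.choice(SRNA_LENGTHS_ALL, size=20_000,
                                  p=LENGTH_P))
        sub = [lengths[i] for i in sorted(
            rng.choice(len(lengths), size=5000, replace=False))]
        control = SizeClassProfile({21: 15.0, 24: 55.0}, 100)
        full_prof = size_class_profile(lengths)
        sub_prof = size_class_profile(sub)
        n_full, _ = normalize_by_21mer(full_prof, control)
        n_sub, _ = normalize_by_21mer(sub_prof, control)
        # expected percentages unchanged by subsampling: agreement within
        # a few points of sampling noise
        assert n_full[24] == pytest.approx(n_sub[24], rel=0.1)


SRNA_LENGTHS_ALL = list(range(18, 31))
_base = simulate.srna_length_probs(0.55, 0.15)
LENGTH_P = [_base[L] for L in SRNA_LENGTHS_ALL]
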