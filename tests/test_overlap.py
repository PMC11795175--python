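import math

import numpy as np
import pytest
from scipy import stats

from sigoverlap.overlap import (
    PAIRS,
    compare,
    directional_partition,
    hypergeom_upper_tail,
    log_hypergeom_upper_tail,
    running_scan,
)
from sigoverlap.signatures import GeneEntry, Universe

from conftest import make_signature, random_signature
from oracles import compare_oracle, hypergeom_tail_oracle


class TestHypergeomUpperTail:
    def test_enumerated_example(self):
        # N=10, K=5, n=4, x=4: only C(5,4)C(5,0) = 5 of C(10,4) = 210 draws
        assert hypergeom_upper_tail(10, 5, 4, 4) == pytest.approx(5 / 210, rel=1e-12)

    def test_zero_overlap_is_certain(self):
        assert hypergeom_upper_tail(100, 30, 10, 0) == 1.0

    def test_forced_overlap_is_certain(self):
        assert hypergeom_upper_tail(7, 7, 7, 7) == 1.0

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_upper_tail(10, 11, 4, 2)
        with pytest.raises(ValueError):
            hypergeom_upper_tail(10, 5, 4, 5)  # x > min(K, n)
        with pytest.raises(ValueError):
            hypergeom_upper_tail(10, 8, 7, 2)  # x below forced minimum

    def test_matches_exact_enumeration_on_random_arguments(self, rng):
        for _ in range(300):
            N = int(rng.integers(2, 61))
            K = int(rng.integers(0, N + 1))
            n = int(rng.integers(0, N + 1))
            lo, hi = max(0, K + n - N), min(K, n)
            x = int(rng.integers(lo, hi + 1))
            assert hypergeom_upper_tail(N, K, n, x) == pytest.approx(
                hypergeom_tail_oracle(N, K, n, x), rel=1e-10
            )

    def test_agrees_with_scipy_at_moderate_scale(self):
        for N, K, n, x in [(5000, 800, 300, 80), (2000, 50, 400, 25), (300, 150, 150, 90)]:
            assert hypergeom_upper_tail(N, K, n, x) == pytest.approx(
                float(stats.hypergeom.sf(x - 1, N, K, n)), rel=1e-9
            )

    def test_log_space_survives_extreme_overlap(self):
        # self-overlap of an 800-gene set in a 5000-gene universe: the linear
        # probability is far below float range but the log must stay finite
        lp = log_hypergeom_upper_tail(5000, 800, 800, 800)
        assert math.isfinite(lp)
        assert lp / math.log(10) < -700


class TestRunningScan:
    def entries(self, scores):
        return tuple(GeneEntry(s, v) for s, v in scores.items())

    def test_perfect_prefix_example(self):
        # 3 query genes all inside a 3-gene reference, universe of 20:
        # the best cutoff is k=3 with p = 1/C(20,3); three cutoffs evaluated
        ranked = self.entries({"A": 3.0, "B": 2.0, "C": 1.0})
        res = running_scan(ranked, {"A", "B", "C"}, 20)
        assert res.p_raw == pytest.approx(1 / 1140, rel=1e-12)
        assert res.p_corrected == pytest.approx(3 / 1140, rel=1e-12)
        assert res.k_best == 3
        assert res.n_cutoffs == 3

    def test_empty_reference_is_degenerate(self):
        ranked = self.entries({"A": 1.0})
        res = running_scan(ranked, set(), 100)
        assert (res.p_raw, res.p_corrected, res.k_best, res.n_cutoffs) == (1.0, 1.0, 0, 0)

    def test_all_tied_scores_single_cutoff(self):
        ranked = self.entries({"A": 1.0, "B": -1.0, "C": 1.0})
        res = running_scan(ranked, {"A", "B"}, 50)
        assert res.n_cutoffs == 1
        assert res.p_corrected == res.p_raw
        assert res.k_best == 3

    def test_correction_multiplies_by_cutoff_count(self, rng):
        sig = random_signature(rng, "q", [f"G{i:03d}" for i in range(200)], 30)
        ref = random_signature(rng, "r", [f"G{i:03d}" for i in range(200)], 40)
        res = running_scan(sig.entries, ref.symbols, 200)
        expected = min(1.0, res.p_raw * res.n_cutoffs)
        assert res.p_corrected == pytest.approx(expected, rel=1e-12)
        assert res.p_corrected >= res.p_raw


class TestDirectionalPartition:
    def test_hand_enumerable_example(self):
        q = make_signature("q", {"A": 1.0, "B": 2.0, "C": -1.0})
        r = make_signature("r", {"B": 0.5, "C": 0.5, "A": -0.5})
        parts = directional_partition(q, r)
        assert parts["up-up"][2] == {"B"}
        assert parts["down-down"][2] == set()
        assert parts["up-down"][2] == {"A"}
        assert parts["down-up"][2] == {"C"}

    def test_disjoint_signatures_all_empty(self):
        q = make_signature("q", {"A": 1.0})
        r = make_signature("r", {"B": -1.0})
        assert all(not p[2] for p in directional_partition(q, r).values())

    def test_partition_is_disjoint_and_covers_intersection(self, rng):
        pool = [f"G{i:03d}" for i in range(120)]
        for seed in range(10):
            local = np.random.default_rng(seed)
            q = random_signature(local, "q", pool, 40)
            r = random_signature(local, "r", pool, 50)
            parts = directional_partition(q, r)
            sets = [p[2] for p in parts.values()]
            union = set().union(*sets)
            assert sum(len(s) for s in sets) == len(union)
            assert union == q.symbols & r.symbols


class TestCompare:
    def universe(self, n=1000):
        return Universe(frozenset(f"G{i:04d}" for i in range(n)))

    def test_self_comparison_is_maximally_concordant(self, rng):
        uni = self.universe()
        sig = random_signature(rng, "s", sorted(uni.symbols), 50)
        res = compare(sig, sig, uni)
        assert res.dominant == "positive"
        assert res.overall_log10_p < -30
        assert res.total_shared == 50

    def test_negating_reference_flips_dominance_not_overall_p(self, rng):
        uni = self.universe()
        q = random_signature(rng, "q", sorted(uni.symbols), 60)
        r = random_signature(rng, "r", sorted(uni.symbols), 60)
        res = compare(q, q.negated(), uni)  # fully discordant self-comparison
        assert res.dominant == "negative"
        ref = compare(q, q, uni)
        assert res.overall_log10_p == ref.overall_log10_p

    def test_antisymmetry_swaps_directional_results_exactly(self, rng):
        uni = self.universe(300)
        pool = sorted(uni.symbols)
        q = random_signature(rng, "q", pool, 80)
        r = random_signature(rng, "r", pool, 70)
        res = compare(q, r, uni)
        res_neg = compare(q, r.negated(), uni)
        swap = {"up-up": "up-down", "up-down": "up-up",
                "down-down": "down-up", "down-up": "down-down"}
        for pair in PAIRS:
            a, b = res.directional[pair], res_neg.directional[swap[pair]]
            assert a.overlap_genes == b.overlap_genes
            assert a.log10_p_corrected == b.log10_p_corrected
            assert a.k_best == b.k_best
        assert res.overall_log10_p == res_neg.overall_log10_p
        assert res.concordant_score == res_neg.discordant_score

    def test_partition_counts_sum_to_total_shared(self, rng):
        uni = self.universe(200)
        pool = sorted(uni.symbols)
        for _ in range(10):
            q = random_signature(rng, "q", pool, 60)
            r = random_signature(rng, "r", pool, 50)
            res = compare(q, r, uni)
            assert (
                sum(res.directional[p].count for p in PAIRS) == res.total_shared
            )

    def test_symbol_outside_universe_errors(self):
        uni = Universe(frozenset({"A", "B"}))
        q = make_signature("q", {"A": 1.0, "Z": -1.0})
        r = make_signature("r", {"B": 1.0})
        with pytest.raises(ValueError, match="outside the universe"):
            compare(q, r, uni)

    def test_matches_bruteforce_oracle_on_small_instances(self):
        pool = [f"g{i:02d}" for i in range(40)]
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            uni = Universe(frozenset(pool))
            q = random_signature(rng, "q", pool, int(rng.integers(5, 20)))
            r = random_signature(rng, "r", pool, int(rng.integers(5, 20)))
            res = compare(q, r, uni)
            ora = compare_oracle(
                {e.key: e.score for e in q.entries},
                {e.key: e.score for e in r.entries},
                40,
            )
            for pair in PAIRS:
                p_raw, p_corr, k_best, n_cut = ora[pair]
                d = res.directional[pair]
                assert d.p_raw == pytest.approx(p_raw, rel=1e-10)
                assert d.p_corrected == pytest.approx(p_corr, rel=1e-10)
                assert (d.k_best, d.n_cutoffs) == (k_best, n_cut)
            assert res.overall_p == pytest.approx(ora["overall"][1], rel=1e-10)
            assert res.dominant == ora["dominant"]
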