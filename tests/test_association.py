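from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from codonvar import simulate
from codonvar.association import (
    compare_all,
    dunn_posthoc,
    filter_small_genomes,
    four_group_gc,
    holm_adjust,
    kruskal_wallis,
    rank_sum_test,
    split_by_presence,
)


def exact_rank_sum_p(x, y) -> float:
    """Independent oracle: enumerate every assignment of the pooled values.

    Two-sided p = 2 * min-tail probability of the observed U over all
    C(n, n_x) ways the pooled sample could have been split.
    """
    pooled = sorted(list(x) + list(y))
    n_x = len(x)

    def u_of(subset):
        ranks = stats.rankdata(pooled)
        return sum(ranks[i] for i in subset) - n_x * (n_x + 1) / 2

    obs = u_of([pooled.index(v) for v in sorted(x)])
    us = [u_of(c) for c in combinations(range(len(pooled)), n_x)]
    lo = sum(u <= obs for u in us) / len(us)
    hi = sum(u >= obs for u in us) / len(us)
    return min(1.0, 2 * min(lo, hi))


class TestSplitByPresence:
    @staticmethod
    def _presence(flags):
        return pd.DataFrame({"m": flags},
                            index=[f"g{i}" for i in range(len(flags))])

    def test_partition(self):
        vals = pd.Series([1.0, 2.0, 3.0, 4.0], index=[f"g{i}" for i in range(4)])
        present, absent = split_by_presence(
            vals, self._presence([True, True, False, False]), "m")
        assert list(present) == [1.0, 2.0] and list(absent) == [3.0, 4.0]

    def test_all_present_gives_empty_absent(self):
        vals = pd.Series([1.0, 2.0], index=["g0", "g1"])
        present, absent = split_by_presence(vals, self._presence([True, True]), "m")
        assert len(absent) == 0 and len(present) == 2

    def test_unknown_genome_named_in_error(self):
        vals = pd.Series([1.0], index=["missing"])
        with pytest.raises(KeyError, match="missing"):
            split_by_presence(vals, self._presence([True]), "m")


class TestRankSum:
    def test_small_sample_exact_p(self):
        u, p = rank_sum_test([1, 2], [3, 4])
        assert u == 0.0
        assert p == pytest.approx(1 / 3)

    def test_identical_samples(self):
        _, p = rank_sum_test([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_test([], [1.0])

    def test_exact_matches_enumeration_spot_checks(self, rng):
        for _ in range(20):
            n_x = int(rng.integers(2, 5))
            n_y = int(rng.integers(2, 5))
            pooled = rng.permutation(np.arange(1.0, n_x + n_y + 1))
            x, y = pooled[:n_x], pooled[n_x:]
            _, p = rank_sum_test(x, y)
            assert p == pytest.approx(exact_rank_sum_p(x, y), abs=1e-12)

    def test_type_i_error_calibrated(self, rng):
        # 30 vs 30 from one distribution: alpha=0.05 rejections in [0.042, 0.058]
        rejections = 0
        n_sims = 10_000
        for _ in range(n_sims):
            x = rng.normal(size=30)
            y = rng.normal(size=30)
            _, p = rank_sum_test(x, y)
            rejections += p < 0.05
        assert 0.042 <= rejections / n_sims <= 0.058


class TestKruskalWallis:
    def test_hand_formula_value(self):
        h, _ = kruskal_wallis([[1, 2], [3, 4], [5, 6]])
        assert h == pytest.approx(4.5714, abs=1e-4)

    def test_all_equal_degenerate(self):
        h, p = kruskal_wallis([[2, 2], [2, 2], [2, 2]])
        assert h == 0.0 and p == 1.0

    def test_too_few_groups(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2, 3]])
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2], []])

    def test_null_rejection_rate(self, rng):
        rejections = 0
        n_sims = 10_000
        for _ in range(n_sims):
            groups = [rng.normal(size=15) for _ in range(3)]
            _, p = kruskal_wallis(groups)
            rejections += p < 0.05
        assert 0.04 <= rejections / n_sims <= 0.06

    def test_two_groups_monotone_in_rank_sum_statistic(self, rng):
        # With k=2 and no ties, H is a monotone function of |U - n1 n2 / 2|
        records = []
        for _ in range(50):
            pooled = rng.permutation(np.arange(1.0, 21))
            x, y = pooled[:10], pooled[10:]
            u, _ = rank_sum_test(x, y)
            h, _ = kruskal_wallis([x, y])
            records.append((abs(u - 50.0), h))
        records.sort()
        hs = [h for _, h in records]
        assert all(h2 >= h1 - 1e-12 for h1, h2 in zip(hs, hs[1:]))


class TestDunnPosthoc:
    def test_identical_groups_z_zero(self):
        res = dunn_posthoc([[1.0, 2.0], [1.0, 2.0]])
        row = res.iloc[0]
        assert row["z"] == pytest.approx(0.0)
        assert row["p_raw"] == pytest.approx(1.0)

    def test_hand_formula_oracle(self):
        # groups [1,2],[3,4],[5,6]: pooled ranks 1..6, no ties (T=0)
        # z_13 = (1.5 - 5.5) / sqrt((6*7/12) * (1/2 + 1/2)) = -4/sqrt(3.5)
        res = dunn_posthoc([[1, 2], [3, 4], [5, 6]])
        row = res[(res["i"] == 0) & (res["j"] == 2)].iloc[0]
        expected_z = -4.0 / np.sqrt(3.5)
        assert row["z"] == pytest.approx(expected_z)
        assert row["p_raw"] == pytest.approx(2 * stats.norm.sf(abs(expected_z)))

    def test_antisymmetry_under_group_swap(self, rng):
        a, b = rng.normal(size=8), rng.normal(1.0, 1.0, size=6)
        z_ab = dunn_posthoc([a, b]).iloc[0]["z"]
        z_ba = dunn_posthoc([b, a]).iloc[0]["z"]
        assert z_ab == pytest.approx(-z_ba)


class TestHolm:
    def test_worked_example(self):
        np.testing.assert_allclose(
            holm_adjust([0.01, 0.02, 0.04]), [0.03, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert holm_adjust([0.2])[0] == pytest.approx(0.2)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            holm_adjust([0.5, 1.5])

    def test_dominance_and_step_down_oracle(self, rng):
        p = rng.random(12)
        adj = holm_adjust(p)
        assert (adj >= p - 1e-15).all() and (adj <= 1.0).all()
        # independent step-down evaluation
        order = np.argsort(p)
        running = 0.0
        expected = np.empty_like(p)
        for rank, idx in enumerate(order):
            running = max(running, (len(p) - rank) * p[idx])
            expected[idx] = min(1.0, running)
        np.testing.assert_allclose(adj, expected)

    def test_never_more_discoveries_than_unadjusted(self, rng):
        p = rng.random(20) * 0.2
        alpha = 0.05
        assert (holm_adjust(p) < alpha).sum() <= (p < alpha).sum()


class TestCompareAll:
    def test_marker_effect_detected_single_seed(self):
        col = simulate.simulate_collection(simulate.marker_power_config(seed=11))
        res = compare_all(col.usage[["AAA"]], col.presence, ["tusE_motif3"])
        row = res.iloc[0]
        assert row["tested"] and row["significant"]
        assert row["median_present"] > row["median_absent"]

    def test_small_group_reported_untested(self):
        vals = pd.DataFrame({"AAA": np.arange(10.0)},
                            index=[f"g{i}" for i in range(10)])
        presence = pd.DataFrame({"m": [True] + [False] * 9}, index=vals.index)
        res = compare_all(vals, presence, ["m"])
        row = res.iloc[0]
        assert row["small_group"] and not row["tested"]
        assert np.isnan(row["p_two_sided"])


class TestFourGroupGc:
    @staticmethod
    def _synthetic(rng, n=400):
        # GC ~ N(0.35, 0.03^2) for neither, N(0.50, 0.05^2) for one marker,
        # N(0.55, 0.05^2) for both
        a = rng.random(n) < 0.5
        b = rng.random(n) < 0.5
        mu = np.where(a & b, 0.55, np.where(a | b, 0.50, 0.35))
        sd = np.where(a & b, 0.05, np.where(a | b, 0.05, 0.03))
        gc = rng.normal(mu, sd)
        ids = [f"g{i}" for i in range(n)]
        return (pd.Series(gc, index=ids),
                pd.DataFrame({"ma": a, "mb": b}, index=ids))

    def test_separated_design_flags_neither_vs_both(self, rng):
        gc, presence = self._synthetic(rng)
        res = four_group_gc(gc, presence, "ma", "mb")
        pair = res.pairs.set_index(["group_a", "group_b"])
        assert pair.loc[("both_present", "neither"), "significant"]
        assert res.group_medians["neither"] < res.group_medians["a_only"]
        assert res.group_medians["neither"] < res.group_medians["both_present"]

    def test_single_group_degenerate(self):
        gc = pd.Series([0.4, 0.5], index=["g0", "g1"])
        presence = pd.DataFrame({"ma": [True, True], "mb": [True, True]},
                                index=gc.index)
        res = four_group_gc(gc, presence, "ma", "mb")
        assert np.isnan(res.kw_h) and len(res.pairs) == 0
        assert set(res.untested_groups) == {"a_only", "b_only", "neither"}

    def test_holm_dominates_raw(self, rng):
        gc, presence = self._synthetic(rng, n=100)
        res = four_group_gc(gc, presence, "ma", "mb")
        assert (res.pairs["p_holm"] >= res.pairs["p_raw"] - 1e-15).all()


class TestFilterSmallGenomes:
    def test_400_or_fewer_removed(self):
        prof = pd.DataFrame({"n_cds": [120, 400, 401, 5000]},
                            index=["a", "b", "c", "d"])
        kept, removed = filter_small_genomes(prof)
        assert list(removed.index) == ["a", "b"]
        assert list(kept.index) == ["c", "d"]

    def test_all_large_kept(self):
        prof = pd.DataFrame({"n_cds": [500, 600]}, index=["a", "b"])
        kept, removed = filter_small_genomes(prof)
        assert len(removed) == 0 and len(kept) == 2
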