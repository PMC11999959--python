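"""Rank tests against brute-force oracles and scipy, SPM behaviour."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from mrcpspeller.stats import (
    _f_curve,
    _friedman_chi_square,
    bonferroni,
    estimate_fwer,
    friedman_test,
    grand_average,
    paired_t_curves,
    spm_oneway_anova,
    wilcoxon_signed_rank,
)


def brute_force_friedman_p(table):
    """Enumerate every within-row ordering; p = P(chi2 >= observed)."""
    table = np.asarray(table, float)
    n, k = table.shape
    chi_obs = _friedman_chi_square(table)
    perms = list(itertools.permutations(range(k)))
    count = total = 0
    for combo in itertools.product(perms, repeat=n):
        perm_table = np.stack([table[i, list(p)] for i, p in enumerate(combo)])
        total += 1
        if _friedman_chi_square(perm_table) >= chi_obs - 1e-12:
            count += 1
    return count / total


def brute_force_wilcoxon_p(diffs):
    """Enumerate every sign assignment conditional on the observed ranks."""
    d = np.asarray(diffs, float)
    d = d[d != 0]
    ranks = sps.rankdata(np.abs(d))
    w_obs = min(ranks[d > 0].sum(), ranks[d < 0].sum())
    total = ranks.sum()
    count = 0
    n = ranks.size
    for signs in itertools.product([0, 1], repeat=n):
        w_pos = sum(r for r, s in zip(ranks, signs) if s)
        w = min(w_pos, total - w_pos)
        if w <= w_obs + 1e-12:
            count += 1
    return count / 2**n


class TestFriedman:
    @pytest.mark.parametrize(
        "table",
        [
            [[1.0, 2.0, 3.0], [1.0, 3.0, 2.0], [2.0, 1.0, 3.0], [1.0, 2.0, 3.0]],
            [[67, 62, 54], [70, 65, 50], [60, 66, 58], [72, 60, 63]],
            [[1.0, 1.0, 2.0], [3.0, 3.0, 3.0], [2.0, 1.0, 1.0]],  # heavy ties
        ],
    )
    def test_exact_p_matches_brute_force(self, table):
        res = friedman_test(np.asarray(table, float))
        assert res.exact
        assert res.p_value == pytest.approx(brute_force_friedman_p(table), abs=1e-12)

    def test_chi_square_matches_scipy_without_ties(self, rng):
        table = rng.normal(size=(12, 3))
        chi, p = sps.friedmanchisquare(*table.T)
        res = friedman_test(table)
        assert res.chi_square == pytest.approx(chi, abs=1e-9)

    def test_large_n_uses_chi_square_tail(self, rng):
        table = rng.normal(size=(13, 3))  # 6^13 arrangements: asymptotic path
        res = friedman_test(table)
        assert not res.exact
        assert res.p_value == pytest.approx(sps.chi2.sf(res.chi_square, 2), abs=1e-12)

    def test_perfectly_ordered_small_table(self):
        table = np.tile([1.0, 2.0, 3.0], (5, 1))
        res = friedman_test(table)
        assert res.chi_square == pytest.approx(10.0)
        # the maximal statistic needs all 5 rows in the same ordering and any
        # of the 6 orderings qualifies: p = 6 / 6^5
        assert res.p_value == pytest.approx(6 / 6**5, rel=1e-9)

    def test_all_tied_table_is_null(self):
        res = friedman_test(np.ones((5, 3)))
        assert res.chi_square == 0.0
        assert res.p_value == 1.0

    def test_missing_cells_rejected(self):
        table = np.ones((3, 3))
        table[1, 2] = np.nan
        with pytest.raises(ValueError, match="missing"):
            friedman_test(table)


class TestWilcoxon:
    @pytest.mark.parametrize(
        "diffs",
        [
            [1.2, -0.4, 2.2, 0.3, -1.8, 0.9],
            [0.5, 0.5, -0.5, 1.5, 2.0],  # tied magnitudes -> mid-ranks
            [3.0, 1.0, 2.0, 4.0],  # all positive
        ],
    )
    def test_exact_p_matches_brute_force(self, diffs):
        res = wilcoxon_signed_rank(np.asarray(diffs))
        assert res.exact
        assert res.p_value == pytest.approx(brute_force_wilcoxon_p(diffs), abs=1e-12)

    def test_matches_scipy_exact_without_ties(self, rng):
        d = rng.normal(0.5, 1.0, size=13)
        d = d[d != 0]
        res = wilcoxon_signed_rank(d)
        w, p = sps.wilcoxon(d, mode="exact")
        assert res.w_statistic == pytest.approx(w)
        assert res.p_value == pytest.approx(p, abs=1e-12)

    def test_all_positive_n13(self):
        res = wilcoxon_signed_rank(np.arange(1.0, 14.0))
        assert res.w_statistic == 0.0
        assert res.p_value == pytest.approx(2.0 / 2**13, abs=1e-15)

    def test_large_n_matches_scipy_normal_approximation(self, rng):
        d = rng.normal(0.3, 1.0, size=40)
        res = wilcoxon_signed_rank(d)
        assert not res.exact
        _, p = sps.wilcoxon(d, mode="approx", correction=False)
        assert res.p_value == pytest.approx(p, abs=1e-9)

    def test_zeros_dropped_and_all_zero_rejected(self):
        res = wilcoxon_signed_rank([0.0, 1.0, -2.0, 0.0, 3.0])
        assert res.n == 3
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([0.0, 0.0])


class TestBonferroni:
    def test_three_comparisons(self):
        assert round(bonferroni(0.05, 3), 4) == 0.0167

    def test_identity_for_one(self):
        assert bonferroni(0.05, 1) == 0.05

    def test_zero_comparisons_rejected(self):
        with pytest.raises(ValueError):
            bonferroni(0.05, 0)


class TestGrandAverage:
    def test_mean_and_sd(self):
        data = np.array([[1.0, 2.0], [3.0, 4.0]])
        mean, sd = grand_average(data)
        assert np.allclose(mean, [2.0, 3.0])
        assert np.allclose(sd, [1.0, 1.0])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            grand_average(np.empty((0, 5)))


class TestSPM:
    def test_f_curve_matches_scipy_pooled_anova(self, rng):
        data = rng.normal(size=(8, 3, 20))
        f = _f_curve(data, repeated=False)
        for t in (0, 7, 19):
            f_ref, _ = sps.f_oneway(*[data[:, j, t] for j in range(3)])
            assert f[t] == pytest.approx(f_ref, abs=1e-9)

    def test_null_data_has_no_significant_cluster(self, rng):
        data = rng.standard_normal((10, 3, 60))
        res = spm_oneway_anova(data, n_permutations=199, seed=3)
        assert not res.significant

    def test_planted_effect_is_localised(self, rng):
        n, k, n_t = 12, 3, 100
        data = rng.standard_normal((n, k, n_t))
        times = np.arange(n_t, dtype=float)
        data[:, 2, 40:60] += 2.5  # one condition deviates on [40, 60)
        res = spm_oneway_anova(data, times=times, n_permutations=199, seed=3)
        assert res.significant
        sig = [c for c in res.clusters if c.p_value < 0.05]
        assert any(abs(c.start_s - 40) <= 3 and abs(c.end_s - 59) <= 3 for c in sig)

    def test_permutation_p_is_anchored(self, rng):
        """p >= 1/(B+1) by construction and deterministic under a fixed seed."""
        data = rng.standard_normal((8, 3, 50))
        data[:, 0, 10:20] += 3.0
        a = spm_oneway_anova(data, n_permutations=99, seed=5)
        b = spm_oneway_anova(data, n_permutations=99, seed=5)
        assert [c.p_value for c in a.clusters] == [c.p_value for c in b.clusters]
        assert all(c.p_value >= 1 / 100 for c in a.clusters)

    def test_wrong_shape_rejected(self, rng):
        with pytest.raises(ValueError):
            spm_oneway_anova(rng.normal(size=(5, 10)))

    def test_paired_t_posthoc_flags_planted_pair(self, rng):
        data = rng.standard_normal((12, 3, 80))
        data[:, 2, 30:50] += 2.5
        out = paired_t_curves(data, ["a", "b", "c"], times=np.arange(80.0))
        # the planted pairs must show a run covering most of [30, 50)
        for label in ("a vs c", "b vs c"):
            runs = out[label]["significant_runs"]
            assert any(a <= 33 and b >= 46 for a, b in runs), runs
        # pointwise t curves carry no cluster correction, so the null pair
        # may show isolated spurious points but no sustained run
        assert all(b - a < 5 for a, b in out["a vs b"]["significant_runs"])

    def test_fwer_near_nominal_small_budget(self):
        """Quick FWER sanity (200 sims); tight bound tested in acceptance."""
        rate = estimate_fwer(n_simulations=200, n_permutations=99, seed=1)
        se = np.sqrt(0.05 * 0.95 / 200)
        assert abs(rate - 0.05) <= 4 * se
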