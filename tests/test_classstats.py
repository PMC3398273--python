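"""Wilcoxon tests, residual corrections, Holm, bootstrap null, correlations."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cardevol.classstats import (
    bootstrap_class_null,
    class_vs_rest,
    fisher_exact_2x2,
    holm_bonferroni,
    residuals_on_length,
    spearman,
    variance_f_test,
    wilcoxon_rank_sum,
)


from conftest import wilcoxon_enumeration_oracle


class TestWilcoxon:
    def test_small_sample_worked_example(self):
        r = wilcoxon_rank_sum([1, 2], [3, 4])
        assert r.pvalue == pytest.approx(1 / 3)
        assert r.method == "wilcoxon-exact"

    def test_identical_samples_p_one(self):
        r = wilcoxon_rank_sum([5, 5, 5], [5, 5])
        assert r.pvalue == 1.0

    def test_exact_branch_equals_enumeration_oracle(self, rng):
        for na in range(1, 7):
            for nb in range(1, 7):
                pooled = rng.permutation(np.arange(1.0, na + nb + 1))
                a, b = pooled[:na], pooled[na:]
                r = wilcoxon_rank_sum(a, b)
                assert r.method == "wilcoxon-exact"
                assert r.pvalue == pytest.approx(wilcoxon_enumeration_oracle(a, b), abs=1e-9)

    def test_exact_and_asymptotic_agree_at_n8(self, rng):
        gaps = []
        for _ in range(20):
            a = rng.normal(0, 1, 8)
            b = rng.normal(0.3, 1, 8)
            exact = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact").pvalue
            approx = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue
            gaps.append(abs(exact - approx))
        # the continuity-corrected normal approximation tracks the exact null
        # closely at n=8; mid-range P values can deviate by just over 0.01
        assert np.mean(gaps) < 0.01
        assert max(gaps) < 0.02

    def test_ties_use_asymptotic_branch(self):
        r = wilcoxon_rank_sum([1, 2, 2], [2, 3])
        assert r.method == "wilcoxon-asymptotic"

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


class TestResiduals:
    def test_uncorrelated_metric_centred(self, rng):
        y = np.array([1.0, 3.0, 2.0, 4.0, 2.0])
        x = np.array([1.0, 1.0, 2.0, 1.0, 2.0])
        # slope-zero construction: shuffle so cov(x, y) == 0
        y = np.array([1.0, 2.0, 1.5, 2.0, 1.0])
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = y - np.polyval(np.polyfit(x, y, 1), x) + y.mean()  # force slope 0
        res = residuals_on_length(y, x)
        assert np.allclose(res, y - y.mean(), atol=1e-10)

    def test_perfectly_linear_metric_zero_residuals(self):
        x = np.array([100.0, 200.0, 300.0, 400.0])
        assert np.allclose(residuals_on_length(2 * x, x), 0.0, atol=1e-9)

    def test_matches_normal_equations_on_fixture(self, rng):
        x = rng.uniform(100, 2000, 10)
        y = 0.002 * x + rng.normal(0, 0.5, 10)
        sxx = ((x - x.mean()) ** 2).sum()
        slope = ((x - x.mean()) * (y - y.mean())).sum() / sxx
        manual = y - (y.mean() + slope * (x - x.mean()))
        assert np.allclose(residuals_on_length(y, x), manual, atol=1e-10)
        assert residuals_on_length(y, x).mean() == pytest.approx(0.0, abs=1e-10)

    def test_constant_length_centres(self):
        y = np.array([1.0, 2.0, 3.0])
        assert np.allclose(residuals_on_length(y, np.ones(3)), y - 2.0)


class TestClassVsRest:
    def _table(self, rng, n=400, k=40, shift=0.0):
        omega = rng.gamma(2.0, 0.1, n)
        flags = np.zeros(n, dtype=bool)
        flags[rng.choice(n, k, replace=False)] = True
        omega[flags] *= 1.0 + shift
        return pd.DataFrame(
            {"omega_Cr": omega, "CRG": flags, "length": rng.uniform(150, 2000, n)}
        )

    def test_planted_shift_detected(self, rng):
        table = self._table(rng, shift=0.8)
        r = class_vs_rest(table, "CRG", "omega_Cr", correct_for="length")
        assert r.pvalue < 0.05
        assert r.mean_a > r.mean_b

    def test_null_class_rejection_near_alpha(self, rng):
        hits = 0
        for _ in range(200):
            table = self._table(rng, shift=0.0)
            if class_vs_rest(table, "CRG", "omega_Cr").pvalue < 0.05 :
                hits += 1
        assert hits / 200 < 0.10  # ~alpha with Monte-Carlo slack

    def test_absent_class_errors(self, rng):
        with pytest.raises(ValueError):
            class_vs_rest(self._table(rng), "PGO", "omega_Cr")

    def test_degenerate_split_errors(self, rng):
        table = self._table(rng, n=10, k=9)
        with pytest.raises(ValueError):
            class_vs_rest(table, "CRG", "omega_Cr")


class TestHolm:
    def test_worked_example(self):
        assert np.allclose(holm_bonferroni([0.01, 0.04]), [0.02, 0.04])

    def test_single_p_unchanged(self):
        assert holm_bonferroni([0.3])[0] == pytest.approx(0.3)

    def test_all_equal_ties(self):
        p = holm_bonferroni([0.02] * 5)
        assert np.allclose(p, 0.10)

    def test_monotone_and_bounded(self, rng):
        p = rng.random(20)
        adj = holm_bonferroni(p)
        assert np.all(adj <= 1.0) and np.all(adj >= p - 1e-12)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)


class TestBootstrap:
    def _table(self, rng, shift):
        n, k = 200, 25
        omega = rng.gamma(2.0, 0.1, n)
        flags = np.zeros(n, dtype=bool)
        flags[rng.choice(n, k, replace=False)] = True
        omega[flags] *= 1.0 + shift
        return pd.DataFrame({"omega_Cr": omega, "CRG": flags})

    def test_determinism(self, rng):
        table = self._table(rng, 0.8)
        r1 = bootstrap_class_null(table, "CRG", "omega_Cr", B=300, seed=7)
        r2 = bootstrap_class_null(table, "CRG", "omega_Cr", B=300, seed=7)
        assert r1.fraction_leq == r2.fraction_leq

    def test_planted_effect_rarely_beaten(self, rng):
        table = self._table(rng, 1.5)
        r = bootstrap_class_null(table, "CRG", "omega_Cr", B=500, seed=3)
        assert r.fraction_leq < 0.05

    def test_null_class_fraction_moderate(self, rng):
        table = self._table(rng, 0.0)
        r = bootstrap_class_null(table, "CRG", "omega_Cr", B=500, seed=4)
        # under exchangeability the fraction estimates the observed P itself
        assert abs(r.fraction_leq - r.observed_pvalue) < 0.15

    def test_b_floor(self, rng):
        with pytest.raises(ValueError):
            bootstrap_class_null(self._table(rng, 0.0), "CRG", "omega_Cr", B=50)


class TestSpearman:
    def test_perfect_monotone(self, rng):
        x = rng.uniform(0, 1, 30)
        assert spearman(x, 2 * x + 1).rho == pytest.approx(1.0)
        assert spearman(x, -x).rho == pytest.approx(-1.0)

    def test_conditional_independence_partial_near_zero(self, rng):
        n = 500
        z = rng.normal(0, 1, n)
        x = z + rng.normal(0, 1, n)
        y = z + rng.normal(0, 1, n)
        plain = spearman(x, y)
        partial = spearman(x, y, partial_given=[z])
        assert plain.rho > 0.2  # induced by the confounder
        assert abs(partial.rho) < 3.0 / np.sqrt(n)

    def test_partial_matches_pingouin(self, rng):
        import pingouin as pg

        n = 120
        z = rng.normal(0, 1, n)
        x = 0.6 * z + rng.normal(0, 1, n)
        y = -0.4 * z + 0.3 * x + rng.normal(0, 1, n)
        ours = spearman(x, y, partial_given=[z])
        df = pd.DataFrame({"x": x, "y": y, "z": z})
        ref = pg.partial_corr(df, x="x", y="y", covar="z", method="spearman")
        assert ours.rho == pytest.approx(float(ref["r"].iloc[0]), abs=1e-6)

    def test_constant_vector_flagged(self, rng):
        with pytest.warns(UserWarning):
            r = spearman(np.ones(10), rng.normal(0, 1, 10))
        assert np.isnan(r.rho)


class TestVarianceF:
    def test_identical_samples_p_one(self, rng):
        a = rng.normal(0, 1, 50)
        assert variance_f_test(a, a.copy()).pvalue == pytest.approx(1.0)

    def test_unit_ratio_large_n(self, rng):
        a = rng.normal(0, 1, 5000)
        b = rng.normal(5, 1, 5000)
        assert variance_f_test(a, b).pvalue > 0.2

    def test_power_matches_f_distribution(self, rng):
        """sigma^2 ratio 2 at n = 200: Monte-Carlo rejection rate matches the
        closed-form power computation."""
        n, ratio, alpha = 200, 2.0, 0.05
        lo = stats.f.ppf(alpha / 2, n - 1, n - 1)
        hi = stats.f.ppf(1 - alpha / 2, n - 1, n - 1)
        power = stats.f.sf(hi / ratio, n - 1, n - 1) + stats.f.cdf(lo / ratio, n - 1, n - 1)
        rejections = 0
        sims = 300
        for _ in range(sims):
            a = rng.normal(0, np.sqrt(ratio), n)
            b = rng.normal(0, 1.0, n)
            if variance_f_test(a, b).pvalue < alpha:
                rejections += 1
        se = np.sqrt(power * (1 - power) / sims)
        assert abs(rejections / sims - power) < 4 * se

    def test_zero_variance_flagged(self):
        r = variance_f_test([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert r.flag == "zero variance"


class TestFisher:
    def test_worked_example(self):
        r = fisher_exact_2x2([[1, 9], [11, 3]])
        assert r.pvalue == pytest.approx(0.0028, abs=2e-4)

    def test_identical_row_proportions(self):
        assert fisher_exact_2x2([[5, 10], [10, 20]]).pvalue == pytest.approx(1.0)

    def test_row_swap_symmetric(self):
        p1 = fisher_exact_2x2([[2, 8], [7, 3]]).pvalue
        p2 = fisher_exact_2x2([[7, 3], [2, 8]]).pvalue
        assert p1 == pytest.approx(p2)

    def test_zero_margin_p_one(self):
        assert fisher_exact_2x2([[0, 0], [5, 7]]).pvalue == pytest.approx(1.0)

    def test_non_integer_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[1.5, 2], [3, 4]])
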