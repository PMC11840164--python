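"""Normality gate, ANCOVA/Quade group comparison, chi-square, partial
correlation, ROC/AUC and Benjamini-Hochberg correction."""

from itertools import permutations

import numpy as np
import pytest
from scipy import stats

from alpsflow import (ancova_group_compare, bh_adjust, binormal_auc,
                      chi2_independence, partial_correlation, quade_rank_ancova,
                      roc_auc, shapiro_gate)


class TestShapiroGate:
    def test_normal_sample_passes(self):
        rng = np.random.default_rng(0)
        normal, p, flag = shapiro_gate(rng.normal(0, 1, 100))
        assert normal and flag is None

    def test_exponential_sample_fails(self):
        rng = np.random.default_rng(0)
        normal, _, _ = shapiro_gate(rng.exponential(1, 100))
        assert not normal

    def test_constant_vector_non_normal_and_flagged(self):
        normal, p, flag = shapiro_gate(np.ones(10))
        assert not normal
        assert flag == "constant vector"

    def test_type_i_rate_near_alpha(self):
        """Rejection rate of truly normal samples approximates alpha."""
        rng = np.random.default_rng(21)
        rejections = sum(not shapiro_gate(rng.normal(0, 1, 100))[0]
                         for _ in range(400))
        assert 0.02 <= rejections / 400 <= 0.09


class TestGroupComparison:
    GROUP = np.array(["A"] * 51 + ["B"] * 30)

    def test_ancova_type_i_error_nominal(self):
        rng = np.random.default_rng(42)
        rej = sum(ancova_group_compare(rng.normal(0, 1, 81), self.GROUP,
                                       rng.normal(0, 1, (81, 2))).p_value < 0.05
                  for _ in range(600))
        assert 0.03 <= rej / 600 <= 0.07

    def test_ancova_group_effect_not_absorbed_by_covariate(self):
        rng = np.random.default_rng(1)
        cov = rng.normal(0, 1, 81)
        y = 5.0 * cov + rng.normal(0, 1, 81)  # covariate effect only
        res = ancova_group_compare(y, self.GROUP, cov)
        assert res.p_value > 0.01
        assert res.statistic < 8

    def test_ancova_detects_adjusted_shift(self):
        rng = np.random.default_rng(2)
        cov = rng.normal(0, 1, 81)
        y = 2.0 * cov + (self.GROUP == "B") * 1.0 + rng.normal(0, 0.5, 81)
        res = ancova_group_compare(y, self.GROUP, cov)
        assert res.p_value < 1e-6
        diff = res.adjusted_means["B"] - res.adjusted_means["A"]
        assert diff == pytest.approx(1.0, abs=0.4)

    def test_ancova_equals_statsmodels_type_iii(self):
        import pandas as pd
        import statsmodels.api as sm
        from statsmodels.formula.api import ols
        rng = np.random.default_rng(3)
        df = pd.DataFrame({"y": rng.normal(0, 1, 81), "g": self.GROUP,
                           "c1": rng.normal(0, 1, 81), "c2": rng.normal(0, 1, 81)})
        res = ancova_group_compare(df["y"], df["g"], df[["c1", "c2"]].to_numpy())
        fit = ols("y ~ C(g) + c1 + c2", df).fit()
        table = sm.stats.anova_lm(fit, typ=3)
        assert res.statistic == pytest.approx(table.loc["C(g)", "F"], rel=1e-8)
        assert res.p_value == pytest.approx(table.loc["C(g)", "PR(>F)"], rel=1e-8)

    def test_ancova_rank_deficient_covariates_rejected(self):
        rng = np.random.default_rng(4)
        c = rng.normal(0, 1, 81)
        with pytest.raises(ValueError, match="rank-deficient"):
            ancova_group_compare(rng.normal(0, 1, 81), self.GROUP,
                                 np.column_stack([c, 2 * c]))

    def test_quade_type_i_error_nominal_under_heavy_tails(self):
        rng = np.random.default_rng(5)
        rej = sum(quade_rank_ancova(rng.standard_cauchy(81), self.GROUP,
                                    rng.normal(0, 1, (81, 2))).p_value < 0.05
                  for _ in range(600))
        assert 0.03 <= rej / 600 <= 0.07

    def test_quade_rank_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(6)
        y = rng.exponential(1, 81)
        cov = rng.normal(0, 1, (81, 2))
        r1 = quade_rank_ancova(y, self.GROUP, cov)
        r2 = quade_rank_ancova(np.log(y), self.GROUP, cov)
        assert r1.statistic == pytest.approx(r2.statistic, rel=1e-12)

    def test_quade_power_against_shift_on_exponential_noise(self):
        rng = np.random.default_rng(7)
        hits = 0
        for _ in range(100):
            y = rng.exponential(1, 81) + (self.GROUP == "B") * 1.0
            hits += quade_rank_ancova(y, self.GROUP,
                                      rng.normal(0, 1, 81)).p_value < 0.05
        assert hits > 90

    def test_quade_all_tied_outcome_rejected(self):
        with pytest.raises(ValueError, match="tied"):
            quade_rank_ancova(np.ones(81), self.GROUP, None)


class TestChiSquare:
    def test_perfect_independence(self):
        chi2, p = chi2_independence([[10, 10], [10, 10]])
        assert chi2 == 0.0
        assert p == pytest.approx(1.0)

    def test_printed_sex_table_matches_hand_oracle(self):
        """chi2 = N(ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d)) on the 28/23 vs 11/19
        table, computed by hand beforehand."""
        chi2, p = chi2_independence([[28, 23], [11, 19]])
        assert chi2 == pytest.approx(2.515869424692954, rel=1e-12)
        assert p == pytest.approx(0.112705458, abs=1e-6)

    def test_doubling_counts_doubles_statistic(self):
        t = np.array([[20, 10], [8, 16]])
        c1, _ = chi2_independence(t)
        c2, _ = chi2_independence(2 * t)
        assert c2 == pytest.approx(2 * c1, rel=1e-12)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError, match="marginal"):
            chi2_independence([[0, 0], [5, 7]])

    def test_yates_correction_shrinks_statistic(self):
        plain, _ = chi2_independence([[28, 23], [11, 19]], yates=False)
        corrected, _ = chi2_independence([[28, 23], [11, 19]], yates=True)
        assert corrected < plain


class TestPartialCorrelation:
    def test_no_covariates_reduces_to_pearson(self, rng):
        x = rng.normal(0, 1, 50)
        y = 0.5 * x + rng.normal(0, 1, 50)
        res = partial_correlation(x, y)
        r_ref, p_ref = stats.pearsonr(x, y)
        assert res.r == pytest.approx(r_ref, abs=1e-12)
        assert res.p_value == pytest.approx(p_ref, rel=1e-9)

    def test_toy_data_matches_recursive_formula(self, rng):
        """Residual-regression partial r equals
        (r_xy - r_xz r_yz) / sqrt((1-r_xz^2)(1-r_yz^2)) on a 6-point set."""
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.5])
        y = np.array([2.1, 2.9, 4.2, 3.8, 5.5, 6.0])
        z = np.array([0.5, 1.0, 2.0, 2.5, 3.5, 4.0])
        r_xy = stats.pearsonr(x, y)[0]
        r_xz = stats.pearsonr(x, z)[0]
        r_yz = stats.pearsonr(y, z)[0]
        expected = (r_xy - r_xz * r_yz) / np.sqrt((1 - r_xz**2) * (1 - r_yz**2))
        res = partial_correlation(x, y, z)
        assert res.r == pytest.approx(expected, abs=1e-12)
        assert res.df == 6 - 2 - 1

    def test_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd
        n = 40
        z = rng.normal(0, 1, (n, 2))
        x = z @ [1.0, -0.5] + rng.normal(0, 1, n)
        y = z @ [0.3, 0.8] + 0.4 * x + rng.normal(0, 1, n)
        df = pd.DataFrame({"x": x, "y": y, "z1": z[:, 0], "z2": z[:, 1]})
        ref = pingouin.partial_corr(df, x="x", y="y", covar=["z1", "z2"])
        res = partial_correlation(x, y, z)
        assert res.r == pytest.approx(ref["r"].item(), abs=1e-10)
        assert res.p_value == pytest.approx(ref["p_val"].item(), rel=1e-6)

    def test_shared_confounder_partialled_out(self):
        rng = np.random.default_rng(8)
        n = 100000
        z = rng.normal(0, 1, n)
        x = z + rng.normal(0, 1, n)
        y = z + rng.normal(0, 1, n)
        assert abs(partial_correlation(x, y, z).r) < 0.01

    def test_zero_residual_variance_flagged(self):
        z = np.arange(10.0)
        res = partial_correlation(2 * z + 1, np.random.default_rng(0).normal(0, 1, 10), z)
        assert res.flag is not None
        assert np.isnan(res.r)


class TestROC:
    def test_perfect_separation(self):
        res = roc_auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert res.auc == 1.0

    def test_null_scores_give_half(self):
        rng = np.random.default_rng(9)
        labels = rng.integers(0, 2, 20000)
        res = roc_auc(rng.normal(0, 1, 20000), labels)
        assert res.auc == pytest.approx(0.5, abs=0.02)

    def test_auc_equals_mann_whitney(self, rng):
        pos = rng.normal(1, 1, 80)
        neg = rng.normal(0, 1.5, 50)
        res = roc_auc(np.r_[pos, neg], np.r_[np.ones(80), np.zeros(80 * 0 + 50)])
        u = stats.mannwhitneyu(pos, neg).statistic
        assert res.auc == pytest.approx(u / (80 * 50), abs=1e-12)

    def test_binormal_closed_form_within_monte_carlo_band(self):
        """Empirical AUC matches Phi(dmu/sqrt(s1^2+s2^2)) for unequal variances."""
        rng = np.random.default_rng(10)
        n = 20000
        pos = rng.normal(1.64, 0.17, n)
        neg = rng.normal(1.45, 0.21, n)
        res = roc_auc(np.r_[pos, neg], np.r_[np.ones(n), np.zeros(n)])
        expected = binormal_auc(1.64, 0.17, 1.45, 0.21)
        se = np.sqrt(expected * (1 - expected) / n)  # conservative MC band
        assert abs(res.auc - expected) < 3 * se

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_auc([1.0, 2.0], [1, 1])

    def test_curve_is_monotone(self, rng):
        res = roc_auc(rng.normal(0, 1, 200), rng.integers(0, 2, 200))
        assert np.all(np.diff(res.sensitivities) >= 0)
        assert np.all(np.diff(res.specificities) <= 0)


def bh_oracle(p):
    """Hand step-up: p_(i) * m / i, cumulative min from the largest down."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03]) == pytest.approx([0.03])

    def test_hand_stepup_example(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_equal_ps_unchanged(self):
        assert bh_adjust([0.2, 0.2, 0.2]) == pytest.approx([0.2] * 3)

    def test_all_permutations_of_four_match_oracle(self):
        base = [0.005, 0.04, 0.2, 0.9]
        for perm in permutations(base):
            assert bh_adjust(list(perm)) == pytest.approx(bh_oracle(perm), abs=1e-12)

    def test_never_below_raw_and_monotone_when_sorted(self, rng):
        p = np.sort(rng.random(20))
        adj = bh_adjust(p)
        assert np.all(adj >= p)
        assert np.all(np.diff(adj) >= -1e-15)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            bh_adjust([0.1, 1.2])
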