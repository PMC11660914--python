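"""Cohort statistics against independent oracles.

The chi-square is checked against the hand Sum((O-E)^2/E) formula, the
partial correlation against residual correlation (and pingouin), the
Wilks-lambda repeated-measures ANOVA against a brute-force
det(E)/det(E+H) implementation and the paired-t reduction at k=2.
"""

import numpy as np
import pytest
from scipy import stats as sps

from glioloc.stats import (
    bonferroni,
    chi_square_2x2,
    classify_methylation,
    classify_methylation_series,
    involvement_percentages,
    median_split,
    partial_r,
    pearson_r,
    rm_anova_wilks,
    two_sample_t,
)


class TestClassifyMethylation:
    @pytest.mark.parametrize(
        "pct,expected",
        [(8.0, "methylated"), (7.9, "unmethylated"), (37.0, "methylated"), (0.0, "unmethylated")],
    )
    def test_cutoff_is_inclusive(self, pct, expected):
        assert classify_methylation(pct) == expected

    def test_monotone_in_pct(self):
        grid = np.linspace(0, 100, 200)
        labels = [classify_methylation(p) for p in grid]
        flips = sum(a != b for a, b in zip(labels, labels[1:]))
        assert flips == 1  # single transition, at the cutoff

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify_methylation(101.0)

    def test_series_handles_missing(self):
        assert classify_methylation_series([5.0, np.nan, 50.0]) == [
            "unmethylated",
            None,
            "methylated",
        ]


class TestMedianSplit:
    def test_even_split(self):
        high, low, cutoff = median_split([10, 20, 30, 40])
        assert cutoff == 25
        assert sorted(high) == [30, 40] and sorted(low) == [10, 20]

    def test_tie_goes_to_low_group(self):
        high, low, cutoff = median_split([10, 37, 60])
        assert cutoff == 37
        assert list(high) == [60] and sorted(low) == [10, 37]

    def test_degenerate_warns_not_raises(self):
        with pytest.warns(UserWarning):
            high, low, _ = median_split([5, 5, 5])
        assert high.size == 0 and low.size == 3


class TestChiSquare:
    def test_reconstructed_cohort_table(self):
        """42 methylated (64.3% right) vs 51 unmethylated (43.1% right)."""
        res = chi_square_2x2([[27, 15], [22, 29]])
        assert res.statistic == pytest.approx(4.1, abs=0.05)
        assert res.p_value == pytest.approx(0.042, abs=5e-4)

    def test_independence_gives_zero(self):
        res = chi_square_2x2([[10, 10], [10, 10]])
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_hand_formula(self, seed):
        """Oracle: explicit Sum((O-E)^2/E) over expected counts."""
        rng = np.random.default_rng(seed)
        t = rng.integers(1, 60, size=(2, 2)).astype(float)
        res = chi_square_2x2(t)
        row, col, n = t.sum(1), t.sum(0), t.sum()
        expected = np.outer(row, col) / n
        hand = ((t - expected) ** 2 / expected).sum()
        assert res.statistic == pytest.approx(hand, rel=1e-12)
        assert res.p_value == pytest.approx(sps.chi2.sf(hand, 1), rel=1e-12)

    def test_invariant_under_row_and_column_swap(self):
        a = chi_square_2x2([[27, 15], [22, 29]])
        b = chi_square_2x2([[29, 22], [15, 27]])
        assert a.statistic == pytest.approx(b.statistic, rel=1e-12)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError):
            chi_square_2x2([[0, 0], [5, 5]])


class TestTwoSampleT:
    def test_textbook_pooled_t(self):
        res = two_sample_t([1, 2, 3], [4, 5, 6])
        assert abs(res.statistic) == pytest.approx(3.674, abs=5e-4)
        assert res.df == 4

    def test_identical_groups(self):
        res = two_sample_t([1.0, 2.0], [1.0, 2.0])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_antisymmetric_in_group_order(self):
        a = two_sample_t([1, 2, 3, 7], [4, 5, 6])
        b = two_sample_t([4, 5, 6], [1, 2, 3, 7])
        assert a.statistic == pytest.approx(-b.statistic)
        assert a.p_value == pytest.approx(b.p_value)

    def test_zero_variance_cases(self):
        res = two_sample_t([2.0, 2.0], [2.0, 2.0])
        assert res.statistic == 0.0 and res.p_value == 1.0
        with pytest.raises(ValueError):
            two_sample_t([2.0, 2.0], [3.0, 3.0])


class TestCorrelations:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        assert pearson_r(x, 2 * x + 1).statistic == pytest.approx(1.0)
        assert pearson_r(x, -x).statistic == pytest.approx(-1.0)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_sum_formula(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.random(30), rng.random(30)
        r = pearson_r(x, y).statistic
        # oracle: covariance / sigma computed in an independent pass
        hand = np.mean((x - x.mean()) * (y - y.mean())) / (x.std() * y.std())
        assert r == pytest.approx(hand, abs=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            pearson_r([1, 1, 1], [1, 2, 3])


class TestPartialR:
    @pytest.mark.parametrize("seed", range(8))
    def test_equals_residual_correlation(self, seed):
        """Oracle: correlate residuals of x|z and y|z."""
        rng = np.random.default_rng(seed)
        n = 25
        z = rng.random(n)
        x = 0.5 * z + rng.random(n)
        y = -0.3 * z + rng.random(n)
        res = partial_r(x, y, z)
        rx = x - np.polyval(np.polyfit(z, x, 1), z)
        ry = y - np.polyval(np.polyfit(z, y, 1), z)
        assert res.statistic == pytest.approx(np.corrcoef(rx, ry)[0, 1], abs=1e-10)

    def test_reduces_to_plain_r_when_z_orthogonal(self):
        # construct x, y exactly uncorrelated with z
        n = 16
        z = np.tile([1.0, -1.0], n // 2)
        rng = np.random.default_rng(0)
        x, y = rng.random(n), rng.random(n)
        x -= z * (x @ z) / (z @ z)
        y -= z * (y @ z) / (z @ z)
        assert partial_r(x, y, z).statistic == pytest.approx(
            np.corrcoef(x, y)[0, 1], abs=1e-10
        )

    def test_degenerate_control_rejected(self):
        x = np.arange(10.0)
        with pytest.raises(ValueError):
            partial_r(x, np.random.default_rng(0).random(10), x)

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(42)
        df = pd.DataFrame(rng.random((30, 3)), columns=list("xyz"))
        ours = partial_r(df.x, df.y, df.z)
        ref = pingouin.partial_corr(df, x="x", y="y", covar="z")
        assert ours.statistic == pytest.approx(float(ref["r"].iloc[0]), abs=1e-9)
        assert ours.p_value == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-9)


def _brute_force_wilks(d):
    """Independent Lambda = det(E)/det(E+H) for the flatness hypothesis."""
    n, m = d.shape
    dbar = d.mean(0)
    e = (d - dbar).T @ (d - dbar)
    h = n * np.outer(dbar, dbar)
    lam = np.linalg.det(e) / np.linalg.det(e + h)
    f = (1 - lam) / lam * (n - m) / m
    return lam, f


class TestRmAnovaWilks:
    def test_k2_reduces_to_paired_t_squared(self):
        rng = np.random.default_rng(1)
        y = rng.random((12, 2))
        res = rm_anova_wilks(y)
        t = sps.ttest_rel(y[:, 0], y[:, 1])
        assert res.condition.statistic == pytest.approx(t.statistic**2, rel=1e-10)
        assert res.condition.p_value == pytest.approx(t.pvalue, rel=1e-10)

    @pytest.mark.parametrize("k", [3, 5])
    def test_matches_determinant_ratio_oracle(self, k):
        rng = np.random.default_rng(k)
        y = rng.random((20, k)) + np.linspace(0, 1, k)
        res = rm_anova_wilks(y)
        from glioloc.stats import _difference_contrasts

        _, f = _brute_force_wilks(y @ _difference_contrasts(k))
        assert res.condition.statistic == pytest.approx(f, rel=1e-10)
        assert res.condition.df == (k - 1, 20 - k + 1)

    def test_matches_statsmodels_manova(self):
        """Independent cross-check of the covariate interaction test."""
        statsmodels = pytest.importorskip("statsmodels.multivariate.manova")
        from glioloc.stats import _difference_contrasts

        rng = np.random.default_rng(9)
        n, k = 24, 4
        y = rng.random((n, k))
        x = rng.random(n)
        d = y @ _difference_contrasts(k)
        res = rm_anova_wilks(y, between=x)
        exog = np.column_stack([np.ones(n), x])
        mv = statsmodels.MANOVA(d, exog)
        tbl = mv.mv_test(hypotheses=[("x", np.array([[0.0, 1.0]]))])
        frame = tbl.results["x"]["stat"]
        assert res.interaction.statistic == pytest.approx(
            float(frame.loc["Wilks' lambda", "F Value"]), rel=1e-8
        )
        assert res.interaction.p_value == pytest.approx(
            float(frame.loc["Wilks' lambda", "Pr > F"]), rel=1e-6
        )

    def test_degenerate_zero_variance_rejected(self):
        y = np.ones((10, 3))
        with pytest.raises((ValueError, np.linalg.LinAlgError)):
            rm_anova_wilks(y)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            rm_anova_wilks(np.random.default_rng(0).random((3, 5)))


class TestBonferroni:
    def test_six_way_family_threshold(self):
        """Four status-x-side categories -> six pairwise tests, alpha 0.008."""
        corrected, alpha = bonferroni([0.016], family_size=6)
        assert round(alpha, 3) == 0.008
        assert corrected[0] == pytest.approx(0.096)
        assert corrected[0] > 0.05  # loses significance after correction

    def test_identity_for_family_of_one(self):
        corrected, alpha = bonferroni([0.03])
        assert corrected[0] == 0.03 and alpha == 0.05

    @pytest.mark.parametrize("seed", range(3))
    def test_never_below_raw_p(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.random(10)
        corrected, _ = bonferroni(p, family_size=12)
        assert (corrected >= p).all()
        assert (corrected <= 1.0).all()


def test_involvement_percentages_bookkeeping():
    """Printed counts over n=93 reproduce the printed percentages."""
    pct = involvement_percentages({"frontal": 60, "occipital": 22}, 93)
    assert round(pct["frontal"], 1) == 64.5
    assert round(pct["occipital"], 1) == 23.7
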