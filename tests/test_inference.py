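"""One-tailed t-tests and Deming errors-in-variables regression."""

import dataclasses
import math

import numpy as np
import pytest
from scipy import optimize, stats as sps

from riskallele import (
    DegenerateDataError,
    DemingFit,
    compare_populations,
    deming_fit,
    deming_regression,
    deming_slope_se,
    one_tailed_t_test,
)
from riskallele import test_slope as slope_vs_reference
from riskallele.stats import InferenceError

from riskallele import aggregate_catalog
from conftest import make_catalog, make_record


def perpendicular_ls_slope(x, y, lam=1.0):
    """Independent oracle: 1-D numeric search over the slope minimising the
    lambda-scaled perpendicular sum of squares, intercept through centroid."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)

    def ss(b):
        a = y.mean() - b * x.mean()
        return float(np.sum((y - a - b * x) ** 2 / (1.0 + lam * b**2)))

    best = None
    for lo, hi in ((-100.0, -1e-9), (1e-9, 100.0)):
        r = optimize.minimize_scalar(ss, bounds=(lo, hi), method="bounded",
                                     options={"xatol": 1e-13})
        if best is None or r.fun < best.fun:
            best = r
    return float(best.x)


class TestOneTailedTTest:
    def test_constant_paired_differences_are_degenerate(self):
        # a constant shift leaves the paired statistic undefined (zero sd)
        with pytest.raises(DegenerateDataError):
            one_tailed_t_test([4.0, 5.0, 6.0], [1.0, 2.0, 3.0], variant="paired")

    def test_equal_samples_give_p_half_in_unpaired_variants(self):
        a = [0.4, 0.5, 0.6]
        for variant in ("student", "welch"):
            res = one_tailed_t_test(a, a, variant=variant)
            assert res.statistic == pytest.approx(0.0)
            assert res.p_one_tailed == pytest.approx(0.5)

    def test_paired_closed_form_example(self):
        # frozen from the closed-form paired-t tail probability with df = 2
        res = one_tailed_t_test([0.4, 0.5, 0.7], [0.1, 0.3, 0.3],
                                direction="greater", variant="paired")
        assert res.statistic == pytest.approx(5.196152422706633, abs=1e-12)
        assert res.df == 2
        assert res.p_one_tailed == pytest.approx(0.017549359322992317, abs=1e-12)

    def test_direction_mirroring(self):
        a, b = [0.5, 0.6, 0.8], [0.1, 0.2, 0.4]
        g = one_tailed_t_test(a, b, direction="greater", variant="welch")
        l = one_tailed_t_test(a, b, direction="less", variant="welch")
        assert g.p_one_tailed + l.p_one_tailed == pytest.approx(1.0)

    def test_paired_length_mismatch_is_usage_error(self):
        with pytest.raises(InferenceError, match="equal-length"):
            one_tailed_t_test([1, 2, 3], [1, 2], variant="paired")

    @pytest.mark.parametrize("variant", ["paired", "student", "welch"])
    def test_matches_scipy_oracle_on_random_inputs(self, variant):
        rng = np.random.default_rng(20260101)
        for _ in range(100):
            n = int(rng.integers(3, 40))
            m = n if variant == "paired" else int(rng.integers(3, 40))
            a = rng.normal(0.45, 0.1, n)
            b = rng.normal(0.42, 0.12, m)
            direction = "greater" if rng.random() < 0.5 else "less"
            res = one_tailed_t_test(a, b, direction=direction, variant=variant)
            if variant == "paired":
                t, p = sps.ttest_rel(a, b, alternative=direction)
            else:
                t, p = sps.ttest_ind(a, b, equal_var=(variant == "student"),
                                     alternative=direction)
            assert res.statistic == pytest.approx(t, abs=1e-10)
            assert res.p_one_tailed == pytest.approx(p, abs=1e-10)


class TestDemingFit:
    def test_exact_collinear_fit(self):
        fit = deming_fit([0, 1, 2], [0, 1, 2])
        assert fit.slope == pytest.approx(1.0)
        assert fit.intercept == pytest.approx(0.0)

    def test_brute_force_oracle_example(self):
        # frozen from the perpendicular-least-squares search oracle
        fit = deming_fit([0.0, 0.3, 0.5, 0.8], [0.1, 0.25, 0.6, 0.75])
        assert fit.slope == pytest.approx(0.8921164008562547, abs=1e-6)
        assert fit.intercept == pytest.approx(0.0681534396574981, abs=1e-6)

    def test_axis_swap_reciprocal_identity(self):
        rng = np.random.default_rng(7)
        x = rng.uniform(0.1, 0.9, 20)
        y = x + rng.normal(0, 0.05, 20)
        fxy = deming_fit(x, y).slope
        fyx = deming_fit(y, x).slope
        assert fxy * fyx == pytest.approx(1.0, abs=1e-10)

    def test_lambda_zero_limit_is_ols(self):
        rng = np.random.default_rng(11)
        x = rng.uniform(0, 1, 30)
        y = 0.8 * x + rng.normal(0, 0.05, 30)
        ols = np.polyfit(x, y, 1)[0]
        assert deming_fit(x, y, lam=1e-8).slope == pytest.approx(ols, abs=1e-4)

    def test_sandwich_between_ols_and_inverse_ols(self):
        rng = np.random.default_rng(13)
        x = rng.uniform(0, 1, 50)
        y = x + rng.normal(0, 0.1, 50)
        b_yx = np.polyfit(x, y, 1)[0]
        b_inv = 1.0 / np.polyfit(y, x, 1)[0]
        slope = deming_fit(x, y).slope
        assert min(b_yx, b_inv) - 1e-12 <= slope <= max(b_yx, b_inv) + 1e-12

    def test_common_rescaling_equivariance(self):
        rng = np.random.default_rng(17)
        x = rng.uniform(0, 1, 15)
        y = 0.7 * x + rng.normal(0, 0.03, 15)
        base = deming_fit(x, y)
        scaled = deming_fit(10 * x, 10 * y)
        assert scaled.slope == pytest.approx(base.slope, abs=1e-12)
        assert scaled.intercept == pytest.approx(10 * base.intercept, abs=1e-10)

    def test_centroid_invariant(self):
        rng = np.random.default_rng(19)
        x = rng.uniform(0, 1, 12)
        y = rng.uniform(0, 1, 12)
        fit = deming_fit(x, y)
        assert fit.intercept == pytest.approx(y.mean() - fit.slope * x.mean(), abs=1e-12)

    def test_zero_covariance_convention(self):
        # symmetric cross: s_xy = 0, slope falls back to sqrt(lam*syy/sxx) > 0
        fit = deming_fit([0, 0, 1, 1], [0, 1, 0, 1])
        assert fit.slope == pytest.approx(1.0)

    def test_insufficient_or_degenerate_input(self):
        with pytest.raises(InferenceError, match="at least 3"):
            deming_fit([0, 1], [0, 1])
        with pytest.raises(DegenerateDataError):
            deming_fit([0.5, 0.5, 0.5], [0.1, 0.2, 0.3])


class TestSlopeSE:
    def test_collinear_points_have_zero_se(self):
        x = np.linspace(0, 1, 8)
        assert deming_slope_se(x, 2 * x + 1) == pytest.approx(0.0)

    def test_duplicated_dataset_shrinks_se(self):
        rng = np.random.default_rng(23)
        x = rng.uniform(0, 1, 10)
        y = x + rng.normal(0, 0.08, 10)
        se1 = deming_slope_se(x, y)
        se2 = deming_slope_se(np.tile(x, 2), np.tile(y, 2))
        assert se2 < se1

    def test_jackknife_tracks_parametric_bootstrap(self):
        """Jackknife SE within 25% of the SD of slopes over 2,000 parametric
        bootstrap replicates of a 10-point scatter (the independent oracle)."""
        rng = np.random.default_rng(29)
        x_true = np.linspace(0.1, 0.9, 10)
        sigma = 0.05
        x = x_true + rng.normal(0, sigma, 10)
        y = x_true + rng.normal(0, sigma, 10)
        se_jack = deming_slope_se(x, y)
        boot = np.empty(2000)
        for i in range(2000):
            xb = x_true + rng.normal(0, sigma, 10)
            yb = x_true + rng.normal(0, sigma, 10)
            boot[i] = deming_fit(xb, yb).slope
        assert se_jack == pytest.approx(boot.std(ddof=1), rel=0.25)


class TestSlopeTest:
    def fit(self, slope, se, n=20):
        return DemingFit(slope=slope, intercept=0.0, n=n, lam=1.0, slope_se=se)

    def test_slope_at_reference_gives_maximal_p(self):
        assert slope_vs_reference(self.fit(1.0, 0.05), 1.0) == pytest.approx(1.0)

    def test_degenerate_se_cases(self):
        assert slope_vs_reference(self.fit(1.0, 0.0), 1.0) == 1.0
        with pytest.warns(UserWarning, match="zero slope SE"):
            assert slope_vs_reference(self.fit(1.2, 0.0), 1.0) == 0.0

    def test_two_sided_t_reference(self):
        fit = self.fit(1.3, 0.1, n=30)
        expected = 2 * sps.t.sf(3.0, 28)
        assert slope_vs_reference(fit, 1.0) == pytest.approx(expected, abs=1e-12)

    def test_full_regression_fills_everything(self):
        rng = np.random.default_rng(31)
        x = rng.uniform(0.1, 0.9, 25)
        y = 1.2 * x + rng.normal(0, 0.04, 25)
        fit = deming_regression(x, y)
        assert fit.slope_se > 0
        assert 0 < fit.p_slope_vs_one < 1
        assert fit.p_slope_vs_zero < 1e-6


def test_compare_populations_identical_groups():
    cat = make_catalog(
        [make_record(f"rs{i}", odds_ratio=1 + 0.1 * i, f_afr=0.3 + 0.05 * i,
                     f_eur=0.3 + 0.05 * i) for i in range(5)]
    )
    _, units = aggregate_catalog(cat)
    res = compare_populations(units, "afr", "eur", variant="student")
    assert res.mean_a == pytest.approx(res.mean_b)
    assert res.ttest.p_one_tailed == pytest.approx(0.5)


def test_deming_matches_oracle_on_random_datasets():
    """Closed-form slope equals the brute-force perpendicular search on
    random small datasets, including anticorrelated ones."""
    rng = np.random.default_rng(20260102)
    for _ in range(50):
        n = int(rng.integers(4, 15))
        x = rng.uniform(0, 1, n)
        sign = 1.0 if rng.random() < 0.8 else -1.0
        y = sign * rng.uniform(0.5, 1.5) * x + rng.normal(0, 0.1, n)
        lam = float(rng.uniform(0.3, 3.0))
        got = deming_fit(x, y, lam).slope
        assert got == pytest.approx(perpendicular_ls_slope(x, y, lam), abs=1e-6)
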