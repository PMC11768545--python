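"""Errors-in-both-variables line fit: oracle equivalence, symmetry,
jackknife inference and between-model comparisons."""

import warnings

import numpy as np
import pytest
from conftest import (CONTROL_PHI, CONTROL_STRESSES, CONTROL_Y, grid_oracle,
                      random_instance)

from wallcreep.mlfr import (MLFRFit, StressRatePoints, compare_models,
                            fit_with_inference, jackknife_aggregate,
                            jackknife_se, mlfr_fit, mlfr_symmetry_check,
                            simulate_line_ensemble, slope_significance)


def exact_line_points(x_se=(0.75, 0.95, 1.15, 1.3), y_se=(0.5,) * 4):
    x = CONTROL_STRESSES
    return StressRatePoints(x=x, y=CONTROL_PHI * (x - CONTROL_Y),
                            x_se=np.asarray(x_se), y_se=np.asarray(y_se))


class TestFit:
    @pytest.mark.parametrize("x_se,y_se", [
        ((0.75, 0.95, 1.15, 1.3), (0.5,) * 4),
        ((1.0,) * 4, (1.0,) * 4),
        ((0.0,) * 4, (0.0,) * 4),   # exact data -> unweighted fallback
    ])
    def test_exact_line_recovered(self, x_se, y_se):
        fit = mlfr_fit(exact_line_points(x_se, y_se))
        assert fit.converged
        assert fit.slope_phi == pytest.approx(CONTROL_PHI, rel=1e-9)
        assert fit.x_intercept_y == pytest.approx(CONTROL_Y, rel=1e-9)

    def test_unweighted_fallback_flagged(self):
        fit = mlfr_fit(exact_line_points((0.0,) * 4, (0.0,) * 4))
        assert "unweighted" in fit.lambda_weighting

    def test_degenerate_abscissa_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            mlfr_fit(StressRatePoints(x=[5.0, 5.0, 5.0], y=[1, 2, 3],
                                      x_se=[1, 1, 1], y_se=[1, 1, 1]))

    def test_matches_grid_oracle_on_random_instances(self, rng):
        """Profiled 1-D solver vs an independent 2-D (alpha, beta) grid
        minimiser of the ML objective, 30 random 4-point instances."""
        for _ in range(30):
            pts = random_instance(rng)
            fit = mlfr_fit(pts)
            a, b = grid_oracle(pts.x, pts.y, pts.x_se**2, pts.y_se**2)
            assert fit.slope_phi == pytest.approx(b, abs=1e-6 * max(1, abs(b)))
            assert fit.intercept == pytest.approx(a, abs=1e-5 * max(1, abs(a)))

    def test_pooled_lambda_matches_closed_form_deming(self, rng):
        """With a single pooled variance ratio lambda, the slope equals the
        classical Deming closed form
        [Syy - lam*Sxx + sqrt((Syy - lam*Sxx)^2 + 4*lam*Sxy^2)] / (2*Sxy)."""
        for _ in range(20):
            pts = random_instance(rng)
            lam = np.mean(pts.y_se**2) / np.mean(pts.x_se**2)
            xc = pts.x - pts.x.mean()
            yc = pts.y - pts.y.mean()
            sxx, syy, sxy = xc @ xc, yc @ yc, xc @ yc
            closed = (syy - lam * sxx + np.sqrt(
                (syy - lam * sxx) ** 2 + 4 * lam * sxy**2)) / (2 * sxy)
            fit = mlfr_fit(pts, lambda_mode="pooled")
            assert fit.slope_phi == pytest.approx(closed, rel=1e-8)

    def test_inverse_regression_limit(self):
        """As y-errors vanish relative to x-errors the fit approaches the
        inverse (x-on-y) OLS line."""
        rng = np.random.default_rng(4)
        x = CONTROL_STRESSES + rng.normal(0, 1.0, 4)
        y = CONTROL_PHI * (CONTROL_STRESSES - CONTROL_Y) + rng.normal(0, 0.6, 4)
        xc, yc = x - x.mean(), y - y.mean()
        b_inv = (yc @ yc) / (xc @ yc)
        fit = mlfr_fit(StressRatePoints(x=x, y=y, x_se=np.full(4, 2.0),
                                        y_se=np.full(4, 1e-6)))
        assert fit.slope_phi == pytest.approx(b_inv, rel=1e-4)

    def test_ols_limit_along_decreasing_x_errors(self):
        rng = np.random.default_rng(6)
        x = CONTROL_STRESSES + rng.normal(0, 1.0, 4)
        y = CONTROL_PHI * (CONTROL_STRESSES - CONTROL_Y) + rng.normal(0, 0.6, 4)
        xc, yc = x - x.mean(), y - y.mean()
        b_ols = (xc @ yc) / (xc @ xc)
        prev_gap = np.inf
        for x_se in (1.0, 0.1, 0.01, 1e-4):
            fit = mlfr_fit(StressRatePoints(x=x, y=y, x_se=np.full(4, x_se),
                                            y_se=np.full(4, 0.5)))
            gap = abs(fit.slope_phi - b_ols)
            assert gap <= prev_gap + 1e-12
            prev_gap = gap
        assert prev_gap < 1e-6

    def test_slope_bracketing(self, rng):
        """With a pooled variance ratio the MLFR slope lies between OLS(y|x)
        and 1/OLS(x|y) for positively correlated instances (exact property
        of the Deming estimator; per-point weights track it only loosely)."""
        for _ in range(20):
            pts = random_instance(rng)
            xc = pts.x - pts.x.mean()
            yc = pts.y - pts.y.mean()
            if xc @ yc <= 0:
                continue
            b_ols = (xc @ yc) / (xc @ xc)
            b_inv = (yc @ yc) / (xc @ yc)
            fit = mlfr_fit(pts, lambda_mode="pooled")
            lo, hi = sorted((b_ols, b_inv))
            assert lo - 1e-9 <= fit.slope_phi <= hi + 1e-9


class TestSymmetry:
    def test_exact_line_symmetric(self):
        assert mlfr_symmetry_check(exact_line_points())

    def test_noisy_instances_symmetric(self, rng):
        assert all(mlfr_symmetry_check(random_instance(rng))
                   for _ in range(25))

    def test_ols_is_not_symmetric(self, rng):
        """Negative control: OLS slopes in the two orientations are not
        mutual reciprocals on noisy data."""
        pts = random_instance(rng)
        xc = pts.x - pts.x.mean()
        yc = pts.y - pts.y.mean()
        b_yx = (xc @ yc) / (xc @ xc)
        b_xy = (xc @ yc) / (yc @ yc)
        assert abs(b_yx - 1.0 / b_xy) > 1e-3 * abs(b_yx)


class TestJackknife:
    def test_aggregate_formula(self):
        """Leave-one-out estimates {1,2,3,4}: SE = sqrt((3/4)*5)."""
        assert jackknife_aggregate([1, 2, 3, 4]) == pytest.approx(
            np.sqrt(0.75 * 5.0))

    def test_exact_line_zero_se(self):
        se_phi, se_y = jackknife_se(exact_line_points())
        assert se_phi == pytest.approx(0.0, abs=1e-9)
        assert se_y == pytest.approx(0.0, abs=1e-7)

    def test_too_few_points_rejected(self):
        pts = StressRatePoints(x=[10, 20, 30], y=[1, 2, 3],
                               x_se=[1, 1, 1], y_se=[1, 1, 1])
        with pytest.raises(ValueError):
            jackknife_se(pts)

    def test_jackknife_tracks_ensemble_sd(self):
        """Mean jackknife slope SE within 50% of the empirical SD of slopes
        across replicate ensembles (loose: N = 4)."""
        x_se = np.array([1.5, 1.9, 2.3, 2.6]) / 2
        slopes, _ = simulate_line_ensemble(CONTROL_PHI, CONTROL_Y,
                                           CONTROL_STRESSES, x_se, 0.5,
                                           n_replicates=400, seed=21)
        rng = np.random.default_rng(22)
        ses = []
        for _ in range(400):
            y = CONTROL_PHI * (CONTROL_STRESSES - CONTROL_Y) + rng.normal(
                0, 0.5, 4)
            x = CONTROL_STRESSES + rng.normal(0, x_se)
            pts = StressRatePoints(x=x, y=y, x_se=x_se, y_se=np.full(4, 0.5))
            ses.append(jackknife_se(pts)[0])
        ratio = np.mean(ses) / slopes.std(ddof=1)
        assert 0.5 <= ratio <= 1.5

    def test_interval_coverage(self):
        """95% jackknife-t intervals for the slope cover the generating value
        in >= 80% of 200 replicates."""
        from scipy import stats
        x_se = np.array([1.5, 1.9, 2.3, 2.6]) / 2
        rng = np.random.default_rng(31)
        tcrit = stats.t.ppf(0.975, 2)
        covered = 0
        for _ in range(200):
            y = CONTROL_PHI * (CONTROL_STRESSES - CONTROL_Y) + rng.normal(
                0, 0.5, 4)
            x = CONTROL_STRESSES + rng.normal(0, x_se)
            pts = StressRatePoints(x=x, y=y, x_se=x_se, y_se=np.full(4, 0.5))
            fit = fit_with_inference(pts)
            covered += abs(fit.slope_phi - CONTROL_PHI) <= tcrit * fit.se_phi
        assert covered / 200 >= 0.80


class TestInference:
    def _fit(self, slope, se, n=4):
        return MLFRFit(slope_phi=slope, intercept=0.0, x_intercept_y=0.0,
                       n_points=n, df_regression=n - 2, lambda_weighting="",
                       converged=True, se_phi=se, se_y=se)

    def test_zero_slope_p_one(self):
        assert slope_significance(self._fit(0.0, 0.3)) == 1.0

    def test_critical_t_at_df2(self):
        """|t| = 4.30265 on 2 df is the two-tailed 5% point."""
        assert slope_significance(self._fit(4.30265, 1.0)) == pytest.approx(
            0.05, abs=1e-4)

    def test_exact_line_degenerate_certainty(self):
        with pytest.warns(UserWarning, match="zero slope SE"):
            p = slope_significance(self._fit(0.8, 0.0))
        assert p == 0.0

    def test_compare_identical_fits(self):
        c = compare_models(self._fit(0.8, 0.02), self._fit(0.8, 0.02), "phi")
        assert c.t_ratio == 0.0
        assert c.p_value == 1.0

    def test_compare_separated_groups(self):
        """phi 0.80 vs 0.31, both SE 0.02: t = 0.49/sqrt(0.5*2*0.0004) = 24.5
        on 4 df, p < 1e-4."""
        c = compare_models(self._fit(0.80, 0.02), self._fit(0.31, 0.02), "phi")
        assert c.t_ratio == pytest.approx(24.5, rel=1e-6)
        assert c.df == 4
        assert c.p_value < 1e-4

    def test_compare_order_antisymmetric(self):
        f1, f2 = self._fit(0.80, 0.03), self._fit(0.31, 0.05)
        a = compare_models(f1, f2, "phi")
        b = compare_models(f2, f1, "phi")
        assert a.t_ratio == pytest.approx(-b.t_ratio)
        assert a.p_value == b.p_value

    def test_undefined_se_rejected(self):
        bad = self._fit(0.8, float("nan"))
        with pytest.raises(ValueError, match="undefined SE"):
            compare_models(bad, self._fit(0.3, 0.02), "phi")
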