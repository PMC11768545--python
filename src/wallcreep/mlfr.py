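"""Errors-in-both-variables line fit for creep rate versus wall stress.

Both coordinates of each (stress, creep rate) point are sample means with
their own standard errors, so an ordinary least-squares fit — which assumes
an error-free abscissa — attenuates the slope.  The maximum-likelihood
functional-relationship (MLFR) estimator, a weighted generalisation of
Deming regression, minimises

    sum_i [ (y_i - a - b*xi_i)^2 / s_yi^2  +  (x_i - xi_i)^2 / s_xi^2 ]

over the line (a, b) and the latent true abscissae xi_i, with per-point
error variances proportional to the supplied standard errors.  Each xi_i has
a closed-form optimum given (a, b), which reduces the problem to

    R(a, b) = sum_i (y_i - a - b*x_i)^2 / (s_yi^2 + b^2 s_xi^2),

profiled further to a one-dimensional search over the slope b.  The
estimator is symmetric: regressing x on y gives the reciprocal slope and the
matching intercept, so the x-intercept of the rate-vs-stress line (the yield
threshold) equals the intercept obtained by regressing stress on rate.

Scientific outputs: the slope is the in vitro wall extensibility phi
(% h^-1 MPa^-1); the x-intercept is the in vitro yield threshold y (MPa).
Standard errors come from a leave-one-out jackknife over the load points;
slope significance is a t-test on N - 2 degrees of freedom (N loads, one
predictor), and parameters of non-significant fits are reported as not
determined (ND) downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize, stats


@dataclass(frozen=True)
class StressRatePoints:
    """Per-load (stress, creep rate) means with their standard errors."""

    x: np.ndarray        # stress means, MPa
    y: np.ndarray        # creep-rate means, % h^-1
    x_se: np.ndarray     # MPa
    y_se: np.ndarray     # % h^-1
    group: str = ""
    ph: float = float("nan")
    inactivated: bool = False

    def __post_init__(self):
        for name in ("x", "y", "x_se", "y_se"):
            object.__setattr__(self, name,
                               np.asarray(getattr(self, name), dtype=float))
        n = self.x.size
        if any(getattr(self, a).size != n for a in ("y", "x_se", "y_se")):
            raise ValueError("coordinate and SE vectors must share a length")
        if n < 3:
            raise ValueError("need at least 3 load points")
        if np.any(self.x <= 0):
            raise ValueError("stresses must be > 0")
        if np.any(self.x_se < 0) or np.any(self.y_se < 0):
            raise ValueError("standard errors must be >= 0")

    @property
    def n_points(self) -> int:
        return int(self.x.size)

    def swapped(self) -> "StressRatePoints":
        """The same points with the two coordinate axes exchanged.

        Only used for the symmetry diagnostic; the positivity check on the
        abscissa is deliberately bypassed (rates may be ~0).
        """
        obj = object.__new__(StressRatePoints)
        for name, val in (("x", self.y), ("y", self.x),
                          ("x_se", self.y_se), ("y_se", self.x_se)):
            object.__setattr__(obj, name, np.asarray(val, dtype=float))
        object.__setattr__(obj, "group", self.group)
        object.__setattr__(obj, "ph", self.ph)
        object.__setattr__(obj, "inactivated", self.inactivated)
        return obj


@dataclass(frozen=True)
class MLFRFit:
    """Fitted functional-relationship line and its inference summary."""

    slope_phi: float             # % h^-1 MPa^-1
    intercept: float             # % h^-1
    x_intercept_y: float         # MPa
    n_points: int
    df_regression: int           # N - p - 1, p = 1 predictor
    lambda_weighting: str
    converged: bool
    se_phi: float = float("nan")
    se_y: float = float("nan")
    slope_p: float = float("nan")

    @property
    def significant(self) -> bool:
        return bool(np.isfinite(self.slope_p) and self.slope_p < 0.05)


@dataclass(frozen=True)
class CoefComparison:
    """t-ratio comparison of one parameter between two fitted lines."""

    parameter: str               # "phi" or "y"
    t_ratio: float
    df: int
    p_value: float

    def __post_init__(self):
        if not 0 <= self.p_value <= 1:
            raise ValueError("p_value must lie in [0, 1]")


def _error_variances(points: StressRatePoints, lambda_mode: str):
    """Per-point (var_x, var_y) used in the profiled objective."""
    vx = points.x_se**2
    vy = points.y_se**2
    if not np.any(vx > 0) and not np.any(vy > 0):
        # exact data: unweighted Deming (lambda = 1)
        return np.ones_like(vx), np.ones_like(vy), "unweighted (lambda=1)"
    if lambda_mode == "pooled":
        vx = np.full_like(vx, vx.mean())
        vy = np.full_like(vy, vy.mean())
        tag = "pooled lambda = mean(y_se^2)/mean(x_se^2)"
    elif lambda_mode == "per_point":
        tag = "per-point lambda_i = (y_se_i/x_se_i)^2"
    else:
        raise ValueError(f"unknown lambda_mode {lambda_mode!r}")
    # floor zero variances so single error-free coordinates stay finite
    floor = 1e-14 * max(float(np.var(points.x) + np.var(points.y)), 1.0)
    return np.maximum(vx, floor), np.maximum(vy, floor), tag


def _profile_objective(beta, x, y, vx, vy):
    """R(beta) with the intercept profiled out; beta may be an array."""
    beta = np.atleast_1d(np.asarray(beta, dtype=float))[:, None]
    w = 1.0 / (vy[None, :] + beta**2 * vx[None, :])
    alpha = (w * (y[None, :] - beta * x[None, :])).sum(axis=1) / w.sum(axis=1)
    r = y[None, :] - alpha[:, None] - beta * x[None, :]
    return (w * r * r).sum(axis=1), alpha


def _profile_grad(beta, x, y, vx, vy):
    """dR/dbeta at profiled alpha (the sum(w*r)*alpha' term vanishes)."""
    w = 1.0 / (vy + beta**2 * vx)
    alpha = (w * (y - beta * x)).sum() / w.sum()
    r = y - alpha - beta * x
    return float(-2.0 * beta * (vx * w**2 * r**2).sum()
                 - 2.0 * (w * r * x).sum())


def _slope_bracket(x, y):
    xc, yc = x - x.mean(), y - y.mean()
    sxx = float(xc @ xc)
    sxy = float(xc @ yc)
    syy = float(yc @ yc)
    if sxx == 0:
        raise ValueError("degenerate abscissa: all x identical")
    if sxy == 0:
        half = np.sqrt(syy / sxx) + 1.0
        return -half, half
    b_ols = sxy / sxx
    b_inv = syy / sxy
    lo, hi = sorted((b_ols, b_inv))
    pad = (hi - lo) + 0.1 * (abs(lo) + abs(hi)) + 1e-8
    return lo - pad, hi + pad


def mlfr_fit(points: StressRatePoints, lambda_mode="per_point") -> MLFRFit:
    """Fit the MLFR/Deming line of creep rate (y) on wall stress (x).

    ``lambda_mode`` chooses the error-variance weighting: ``"per_point"``
    (default) uses each point's own SE pair; ``"pooled"`` uses a single
    variance ratio pooled across points.  With all SEs zero the fit falls
    back to unweighted Deming (lambda = 1).

    Returns the slope (extensibility phi), intercept, and x-intercept
    (yield threshold y = -intercept/slope).  Jackknife SEs and the slope
    p-value are filled in by :func:`jackknife_se` /
    :func:`slope_significance` (see :func:`fit_with_inference`).
    """
    x, y = points.x, points.y
    vx, vy, tag = _error_variances(points, lambda_mode)
    lo, hi = _slope_bracket(x, y)
    grid = np.linspace(lo, hi, 512)
    vals, _ = _profile_objective(grid, x, y, vx, vy)
    i = int(np.argmin(vals))
    b_lo = grid[max(i - 1, 0)]
    b_hi = grid[min(i + 1, grid.size - 1)]
    # refine to machine precision on the stationarity condition dR/dbeta = 0;
    # fall back to bounded minimisation if the bracket lacks a sign change
    g_lo = _profile_grad(b_lo, x, y, vx, vy)
    g_hi = _profile_grad(b_hi, x, y, vx, vy)
    converged = True
    if g_lo == 0.0:
        beta = float(b_lo)
    elif g_hi == 0.0:
        beta = float(b_hi)
    elif g_lo * g_hi < 0:
        beta = float(optimize.brentq(_profile_grad, b_lo, b_hi,
                                     args=(x, y, vx, vy), xtol=1e-15,
                                     rtol=8.9e-16, maxiter=200))
    else:
        res = optimize.minimize_scalar(
            lambda b: _profile_objective(b, x, y, vx, vy)[0][0],
            bounds=(b_lo, b_hi), method="bounded", options={"xatol": 1e-13})
        beta = float(res.x)
        converged = bool(res.success)
    obj, alpha = _profile_objective(beta, x, y, vx, vy)
    alpha = float(alpha[0])
    if beta != 0:
        x_int = -alpha / beta
    else:
        warnings.warn("zero slope: x-intercept undefined", stacklevel=2)
        x_int = float("nan")
    n = points.n_points
    return MLFRFit(
        slope_phi=beta,
        intercept=alpha,
        x_intercept_y=x_int,
        n_points=n,
        df_regression=n - 2,
        lambda_weighting=tag,
        converged=bool(converged and np.isfinite(obj[0])),
    )


def mlfr_symmetry_check(points: StressRatePoints, lambda_mode="per_point",
                        rtol=1e-8) -> bool:
    """True iff the fit is orientation-symmetric on these points.

    Fits rate-on-stress and stress-on-rate; checks that the slopes are
    mutual reciprocals and that the x-intercept of the first equals the
    intercept of the second, to relative tolerance ``rtol``.
    """
    f1 = mlfr_fit(points, lambda_mode)
    f2 = mlfr_fit(points.swapped(), lambda_mode)
    if f2.slope_phi == 0 or f1.slope_phi == 0:
        return False
    scale_b = max(abs(f1.slope_phi), 1e-12)
    ok_slope = abs(f1.slope_phi - 1.0 / f2.slope_phi) <= rtol * scale_b
    scale_i = max(abs(f1.x_intercept_y), abs(f2.intercept), 1e-9)
    ok_int = abs(f1.x_intercept_y - f2.intercept) <= rtol * scale_i
    return bool(ok_slope and ok_int)


def jackknife_aggregate(leave_one_out_estimates) -> float:
    """Jackknife SE from the N leave-one-out estimates:
    sqrt(((N-1)/N) * sum_i (theta_(i) - theta_bar)^2)."""
    vals = np.asarray(leave_one_out_estimates, dtype=float)
    n = vals.size
    if n < 2:
        raise ValueError("need >= 2 leave-one-out estimates")
    return float(np.sqrt((n - 1) / n * ((vals - vals.mean()) ** 2).sum()))


def jackknife_se(points: StressRatePoints, lambda_mode="per_point"):
    """Leave-one-out jackknife SEs of the slope and the x-intercept.

    SE = sqrt(((N-1)/N) * sum_i (theta_(i) - theta_bar)^2) over the N
    leave-one-load-out refits.  Returns (se_phi, se_y); (nan, nan) with a
    warning if any reduced fit is degenerate.
    """
    n = points.n_points
    if n < 4:
        raise ValueError("jackknife needs >= 4 points (refits keep >= 3)")
    slopes, xints = [], []
    for i in range(n):
        keep = np.arange(n) != i
        sub = StressRatePoints(
            x=points.x[keep], y=points.y[keep],
            x_se=points.x_se[keep], y_se=points.y_se[keep],
            group=points.group, ph=points.ph, inactivated=points.inactivated,
        )
        try:
            fit = mlfr_fit(sub, lambda_mode)
        except ValueError:
            warnings.warn("degenerate leave-one-out refit; jackknife SE "
                          "undefined", stacklevel=2)
            return float("nan"), float("nan")
        if not np.isfinite(fit.x_intercept_y):
            warnings.warn("undefined x-intercept in leave-one-out refit",
                          stacklevel=2)
            return float("nan"), float("nan")
        slopes.append(fit.slope_phi)
        xints.append(fit.x_intercept_y)
    return jackknife_aggregate(slopes), jackknife_aggregate(xints)


def slope_significance(fit: MLFRFit, n_points=None) -> float:
    """Two-tailed p-value of the slope on N - p - 1 = N - 2 df.

    A zero jackknife SE with a non-zero slope (exact-line data) yields p = 0
    with a warning: the line is degenerate-certain, not untestable.
    """
    n = fit.n_points if n_points is None else int(n_points)
    df = n - 2
    if not np.isfinite(fit.se_phi):
        raise ValueError("slope SE undefined; run jackknife_se first")
    if fit.se_phi == 0:
        if fit.slope_phi == 0:
            return 1.0
        warnings.warn("zero slope SE with non-zero slope: p = 0", stacklevel=2)
        return 0.0
    t = fit.slope_phi / fit.se_phi
    return min(1.0, 2.0 * float(stats.t.sf(abs(t), df)))


def fit_with_inference(points: StressRatePoints,
                       lambda_mode="per_point") -> MLFRFit:
    """Convenience: MLFR fit + jackknife SEs + slope p-value in one call."""
    fit = mlfr_fit(points, lambda_mode)
    se_phi, se_y = jackknife_se(points, lambda_mode)
    fit = replace(fit, se_phi=se_phi, se_y=se_y)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p = slope_significance(fit) if np.isfinite(se_phi) else float("nan")
    return replace(fit, slope_p=p)


def compare_models(fit1: MLFRFit, fit2: MLFRFit,
                   parameter: str) -> CoefComparison:
    """t-ratio for a parameter difference between two fitted lines.

    t = (coef1 - coef2) / sqrt(0.5 * (se1^2 + se2^2)), two-tailed on
    df1 + df2 degrees of freedom (df = N - 2 per fit; 4 for two 4-load
    fits).
    """
    if parameter == "phi":
        c1, s1 = fit1.slope_phi, fit1.se_phi
        c2, s2 = fit2.slope_phi, fit2.se_phi
    elif parameter == "y":
        c1, s1 = fit1.x_intercept_y, fit1.se_y
        c2, s2 = fit2.x_intercept_y, fit2.se_y
    else:
        raise ValueError("parameter must be 'phi' or 'y'")
    if not (np.isfinite(s1) and np.isfinite(s2)):
        raise ValueError(f"undefined SE for parameter {parameter!r}")
    df = fit1.df_regression + fit2.df_regression
    denom = np.sqrt(0.5 * (s1**2 + s2**2))
    if denom == 0:
        t = 0.0 if c1 == c2 else np.inf * np.sign(c1 - c2)
        p = 1.0 if c1 == c2 else 0.0
    else:
        t = (c1 - c2) / denom
        p = min(1.0, 2.0 * float(stats.t.sf(abs(t), df)))
    return CoefComparison(parameter=parameter, t_ratio=float(t), df=int(df),
                          p_value=float(p))


def simulate_line_ensemble(phi, y_threshold, stress_means, stress_ses,
                           rate_se, n_replicates=200, seed=0,
                           lambda_mode="per_point"):
    """Recovery ensemble: refit the line on noisy replicates of known truth.

    For each replicate, creep-rate means are generated from the line
    ``phi * (stress - y_threshold)`` at the true stress means plus Gaussian
    noise of SD ``rate_se``, and the observed stress means are the true
    values jittered by their per-load SEs.  Each replicate is refit with
    :func:`mlfr_fit`; returns arrays of recovered slopes and x-intercepts.
    """
    x_true = np.asarray(stress_means, dtype=float)
    x_se = np.asarray(stress_ses, dtype=float)
    rng = np.random.default_rng(seed)
    slopes = np.empty(n_replicates)
    xints = np.empty(n_replicates)
    for r in range(n_replicates):
        y_obs = phi * (x_true - y_threshold) + rng.normal(0, rate_se, x_true.size)
        x_obs = x_true + rng.normal(0, x_se)
        pts = StressRatePoints(x=x_obs, y=y_obs, x_se=x_se,
                               y_se=np.full(x_true.size, float(rate_se)))
        fit = mlfr_fit(pts, lambda_mode)
        slopes[r] = fit.slope_phi
        xints[r] = fit.x_intercept_y
    return slopes, xints
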