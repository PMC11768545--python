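"""Shared fixtures and independent oracles for the test suite."""

import numpy as np
import pytest

from wallcreep.mlfr import StressRatePoints

# printed group summaries used as fixed study conditions throughout the tests
CONTROL_STRESSES = np.array([19.5, 24.4, 29.2, 34.1])     # MPa
CONTROL_STRESS_SDS = np.array([1.5, 1.9, 2.3, 2.6])       # MPa, n = 4
EBL_STRESSES = np.array([12.8, 16.0, 19.2, 22.4])
EBL_STRESS_SDS = np.array([0.7, 0.9, 1.1, 1.3])
CONTROL_PHI, CONTROL_Y = 0.80, 15.23                      # % h^-1 MPa^-1, MPa
EBL_PHI, EBL_Y = 0.31, 5.42
LOADS_MG = (400.0, 500.0, 600.0, 700.0)


def grid_oracle(x, y, vx, vy, alpha_range=(-80.0, 40.0), beta_range=(-3.0, 4.0),
                npts=201):
    """Independent numeric minimiser of the errors-in-both-variables ML
    objective R(a, b) = sum_i (y_i - a - b x_i)^2 / (vy_i + b^2 vx_i) (the
    latent true abscissae profiled out analytically): a coarse 2-D (a, b)
    grid scan to localise the valley, then a derivative-free Nelder-Mead
    polish of the full 2-D objective.  Shares no code path with the
    package's profiled 1-D solver."""
    from scipy.optimize import minimize

    x, y = np.asarray(x, float), np.asarray(y, float)
    vx, vy = np.asarray(vx, float), np.asarray(vy, float)

    def objective(ab):
        a, b = ab
        return float((((y - a - b * x) ** 2) / (vy + b**2 * vx)).sum())

    A = np.linspace(*alpha_range, npts)[:, None, None]
    B = np.linspace(*beta_range, npts)[None, :, None]
    R = (((y - A - B * x) ** 2) / (vy + B**2 * vx)).sum(axis=2)
    i, j = np.unravel_index(np.argmin(R), R.shape)
    start = np.array([A[i, 0, 0], B[0, j, 0]])
    res = minimize(objective, start, method="Nelder-Mead",
                   options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 5000})
    return float(res.x[0]), float(res.x[1])


def random_instance(rng, n=4):
    """A noisy 4-point stress/rate instance with plausible physiology."""
    slope = rng.uniform(0.15, 1.2)
    y0 = rng.uniform(2.0, 18.0)
    x_true = np.sort(rng.uniform(10.0, 35.0, n))
    while np.ptp(x_true) < 6.0:  # ensure usable abscissa spread
        x_true = np.sort(rng.uniform(10.0, 35.0, n))
    x_se = rng.uniform(0.3, 1.4, n)
    y_se = rng.uniform(0.2, 0.8, n)
    y_obs = slope * (x_true - y0) + rng.normal(0, y_se)
    x_obs = np.clip(x_true + rng.normal(0, x_se), 1.0, None)
    return StressRatePoints(x=x_obs, y=y_obs, x_se=x_se, y_se=y_se)


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)
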