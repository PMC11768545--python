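"""Diagnostic plot of creep rate versus wall stress with the fitted line."""

from __future__ import annotations

import numpy as np

from .mlfr import MLFRFit, StressRatePoints


def plot_stress_rate_fit(points: StressRatePoints, fit: MLFRFit, ax=None,
                         label=None):
    """Points with two-axis error bars and the fitted line.

    The line is solid when the regression is significant (slope p < 0.05),
    dashed otherwise — the convention used for yield-threshold plots.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.errorbar(points.x, points.y, xerr=points.x_se, yerr=points.y_se,
                fmt="o", capsize=3, label=label or points.group)
    xs = np.linspace(points.x.min() - 1, points.x.max() + 1, 50)
    style = "-" if fit.significant else "--"
    ax.plot(xs, fit.intercept + fit.slope_phi * xs, style)
    ax.set_xlabel("wall stress (MPa)")
    ax.set_ylabel("creep rate (% h$^{-1}$)")
    return ax
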