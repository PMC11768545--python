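"""Bootstrap creep-rate x stress^-1 estimation and group comparisons.

Creep rate (n ~ 10 specimens) and wall stress (n = 4 dry-mass replicates) are
measured on different material, so their ratio has no paired form.  It is
estimated by a bootstrap: each replicate draws ``resample_size`` values with
replacement from the rate pool and from the stress pool independently and
forms the ratio of the resample means (or, optionally, the mean of pointwise
ratios); the estimate is the mean of the ratios over ``n_boot`` replicates
and its spread is their SD.  Between-group contrasts use a t-statistic on the
bootstrap summaries with Benjamini-Hochberg FDR control across the batch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class RatioEstimate:
    """Bootstrap summary of creep rate x stress^-1 for one condition cell."""

    mean_ratio: float            # % h^-1 MPa^-1
    sd_ratio: float
    n_boot: int
    resample_size_rates: int
    resample_size_stress: int
    seed: int
    group: str = ""
    load_mg: float = float("nan")
    ph: float = float("nan")
    inactivated: bool = False

    def __post_init__(self):
        if self.n_boot < 1 or self.sd_ratio < 0:
            raise ValueError("invalid bootstrap summary")
        if not np.isfinite(self.mean_ratio):
            raise ValueError("mean_ratio must be finite")


@dataclass(frozen=True)
class ComparisonResult:
    """One between-group contrast of bootstrap ratio estimates."""

    contrast: tuple              # (group_a, group_b, load, ph, inactivated)
    t_stat: float
    df: float
    p_raw: float
    p_adjusted: float
    significant: bool

    def __post_init__(self):
        if not (0 <= self.p_raw <= 1 and 0 <= self.p_adjusted <= 1):
            raise ValueError("p-values must lie in [0, 1]")


def bootstrap_ratio(creep_rates, stresses, n_boot=10000,
                    resample_size_rates=4, resample_size_stress=4,
                    statistic="ratio_of_means", seed=0, **labels) -> RatioEstimate:
    """Bootstrap the creep-rate x stress^-1 ratio for one condition.

    Parameters
    ----------
    creep_rates, stresses
        Observed pools (stresses must be strictly positive).
    statistic
        ``"ratio_of_means"`` (default): mean(resampled rates) /
        mean(resampled stresses) per replicate.  ``"mean_of_ratios"``:
        mean of pointwise rate/stress ratios (requires equal resample sizes).
    labels
        Optional ``group``, ``load_mg``, ``ph``, ``inactivated`` carried
        through to the estimate.
    """
    rates = np.asarray(creep_rates, dtype=float)
    sig = np.asarray(stresses, dtype=float)
    if rates.size == 0 or sig.size == 0:
        raise ValueError("rate and stress pools must be non-empty")
    if np.any(sig <= 0):
        raise ValueError("stresses must all be > 0")
    if statistic not in ("ratio_of_means", "mean_of_ratios"):
        raise ValueError(f"unknown statistic {statistic!r}")
    if statistic == "mean_of_ratios" and resample_size_rates != resample_size_stress:
        raise ValueError("mean_of_ratios requires equal resample sizes")
    rng = np.random.default_rng(seed)
    ir = rng.integers(0, rates.size, size=(n_boot, resample_size_rates))
    isg = rng.integers(0, sig.size, size=(n_boot, resample_size_stress))
    if statistic == "ratio_of_means":
        ratios = rates[ir].mean(axis=1) / sig[isg].mean(axis=1)
    else:
        ratios = (rates[ir] / sig[isg]).mean(axis=1)
    sd = float(ratios.std(ddof=1)) if n_boot > 1 else 0.0
    return RatioEstimate(
        mean_ratio=float(ratios.mean()),
        sd_ratio=sd,
        n_boot=int(n_boot),
        resample_size_rates=int(resample_size_rates),
        resample_size_stress=int(resample_size_stress),
        seed=int(seed),
        **labels,
    )


def bh_adjust(p_values):
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    _, p_adj, _, _ = multipletests(p, method="fdr_bh")
    return p_adj


def _welch_t(a: RatioEstimate, b: RatioEstimate):
    """t on bootstrap summaries; the bootstrap SD plays the role of each
    estimate's standard error, with Welch-Satterthwaite df from the
    bootstrap replicate counts."""
    va, vb = a.sd_ratio**2, b.sd_ratio**2
    diff = a.mean_ratio - b.mean_ratio
    denom = np.sqrt(va + vb)
    if denom == 0:
        return (0.0, float(a.n_boot + b.n_boot - 2), 1.0) if diff == 0 else \
               (np.inf if diff > 0 else -np.inf, float(a.n_boot + b.n_boot - 2), 0.0)
    t = diff / denom
    df = (va + vb) ** 2 / (va**2 / (a.n_boot - 1) + vb**2 / (b.n_boot - 1))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return float(t), float(df), min(1.0, p)


def compare_ratio_groups(estimates, pairs=None, alpha=0.05):
    """Contrast bootstrap ratio estimates between groups with BH-FDR control.

    ``pairs`` is a list of contrast keys ``(group_a, group_b, load_mg, ph,
    inactivated)``; if omitted, every pair of groups sharing a (load, pH,
    inactivation) cell is contrasted.  Adjustment is Benjamini-Hochberg
    step-up across all contrasts in the batch; ``significant`` flags
    adjusted p < alpha.
    """
    index = {(e.group, e.load_mg, e.ph, e.inactivated): e for e in estimates}
    if pairs is None:
        cells = sorted({(e.load_mg, e.ph, e.inactivated) for e in estimates})
        groups = sorted({e.group for e in estimates})
        pairs = [(ga, gb, *cell)
                 for cell in cells
                 for i, ga in enumerate(groups) for gb in groups[i + 1:]
                 if (ga, *cell) in index and (gb, *cell) in index]
    results = []
    for ga, gb, load, ph, inact in pairs:
        try:
            a = index[(ga, load, ph, inact)]
            b = index[(gb, load, ph, inact)]
        except KeyError as exc:
            raise KeyError(f"no estimate for contrast key {exc}") from None
        t, df, p = _welch_t(a, b)
        results.append(((ga, gb, load, ph, inact), t, df, p))
    if not results:
        return []
    p_raw = np.array([r[3] for r in results])
    reject, p_adj, _, _ = multipletests(p_raw, alpha=alpha, method="fdr_bh")
    return [
        ComparisonResult(contrast=c, t_stat=t, df=df, p_raw=float(p),
                         p_adjusted=float(pa), significant=bool(rej))
        for (c, t, df, p), pa, rej in zip(results, p_adj, reject)
    ]
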