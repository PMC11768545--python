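"""Relative creep rates from constant-load extensometer traces.

A creep trace records the time-dependent extension of a wall specimen under a
constant tensile load, expressed as percent of the initial segment length.
The relative creep rate (% h^-1) is the least-squares slope of relative
extension versus time over a fit window, by default the final 10 minutes of a
15-minute test so the initial viscoelastic transient after load application is
excluded.  The window is configurable and recorded on every sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

#: default fit window (s): final 10 min of a 15-min creep test
DEFAULT_WINDOW = (300.0, 900.0)

TRACES_COLUMNS = ["specimen_id", "group", "load_mg", "ph", "inactivated",
                  "time_s", "rel_extension_pct"]


@dataclass(frozen=True)
class CreepTrace:
    """One specimen's constant-load creep record."""

    specimen_id: str
    group: str
    load_mg: float
    ph: float
    inactivated: bool
    times: np.ndarray            # seconds, strictly increasing
    rel_extension: np.ndarray    # percent of initial length
    initial_length_mm: float = 5.0

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        e = np.asarray(self.rel_extension, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "rel_extension", e)
        if t.size < 10:
            raise ValueError("trace needs >= 10 samples")
        if t.size != e.size:
            raise ValueError("times and rel_extension differ in length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(e)):
            raise ValueError("rel_extension contains non-finite values")
        if self.initial_length_mm <= 0:
            raise ValueError("initial_length_mm must be > 0")


@dataclass(frozen=True)
class CreepRateSample:
    """Fitted relative creep rate for one specimen."""

    specimen_id: str
    group: str
    load_mg: float
    ph: float
    inactivated: bool
    creep_rate: float            # % h^-1
    fit_window: tuple
    fit_r2: float

    def __post_init__(self):
        if not np.isfinite(self.creep_rate):
            raise ValueError("creep_rate must be finite")


def creep_rate(trace: CreepTrace, window=DEFAULT_WINDOW) -> CreepRateSample:
    """Relative creep rate (% h^-1): OLS slope of extension vs time in window.

    The window must lie within the trace support and contain >= 5 samples.
    ``fit_r2`` is the coefficient of determination of the linear fit; for a
    perfectly flat (zero-residual) trace it is reported as 1.
    """
    t0, t1 = float(window[0]), float(window[1])
    if t1 <= t0:
        raise ValueError("window end must exceed window start")
    if t0 < trace.times[0] or t1 > trace.times[-1]:
        raise ValueError("fit window outside trace support")
    mask = (trace.times >= t0) & (trace.times <= t1)
    if mask.sum() < 5:
        raise ValueError("fewer than 5 samples in fit window")
    t = trace.times[mask]
    e = trace.rel_extension[mask]
    tc = t - t.mean()
    slope_per_s = float(tc @ (e - e.mean()) / (tc @ tc))
    intercept = float(e.mean() - slope_per_s * t.mean())
    resid = e - (intercept + slope_per_s * t)
    ss_res = float(resid @ resid)
    ss_tot = float(((e - e.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0.0 and ss_res <= 1e-30 else (
        0.0 if ss_tot == 0.0 else max(0.0, 1.0 - ss_res / ss_tot))
    return CreepRateSample(
        specimen_id=trace.specimen_id,
        group=trace.group,
        load_mg=trace.load_mg,
        ph=trace.ph,
        inactivated=trace.inactivated,
        creep_rate=slope_per_s * 3600.0,
        fit_window=(t0, t1),
        fit_r2=min(1.0, r2),
    )


def rates_from_traces(traces_df: pd.DataFrame, window=DEFAULT_WINDOW,
                      r2_floor=0.0) -> pd.DataFrame:
    """Fit creep rates for every specimen in a long-format traces table.

    Expects columns ``specimen_id, group, load_mg, ph, inactivated, time_s,
    rel_extension_pct``.  Specimens whose fit R^2 falls below ``r2_floor`` are
    flagged (column ``low_r2``), never dropped.
    """
    missing = [c for c in TRACES_COLUMNS if c not in traces_df.columns]
    if missing:
        raise ValueError(f"traces table missing columns: {missing}")
    rows = []
    for sid, sub in traces_df.groupby("specimen_id", sort=True):
        sub = sub.sort_values("time_s")
        trace = CreepTrace(
            specimen_id=str(sid),
            group=str(sub["group"].iloc[0]),
            load_mg=float(sub["load_mg"].iloc[0]),
            ph=float(sub["ph"].iloc[0]),
            inactivated=bool(sub["inactivated"].iloc[0]),
            times=sub["time_s"].to_numpy(dtype=float),
            rel_extension=sub["rel_extension_pct"].to_numpy(dtype=float),
        )
        s = creep_rate(trace, window)
        rows.append(
            {
                "specimen_id": s.specimen_id,
                "group": s.group,
                "load_mg": s.load_mg,
                "ph": s.ph,
                "inactivated": s.inactivated,
                "creep_rate_pct_h": s.creep_rate,
                "fit_t_start_s": s.fit_window[0],
                "fit_t_end_s": s.fit_window[1],
                "fit_r2": s.fit_r2,
                "low_r2": s.fit_r2 < r2_floor,
            }
        )
    return pd.DataFrame(rows)


GROUP_KEYS = ["group", "load_mg", "ph", "inactivated"]


def group_rates(samples) -> pd.DataFrame:
    """Mean, SE (= SD/sqrt(n)) and n of creep rate per condition cell.

    ``samples`` is a list of :class:`CreepRateSample` or the DataFrame
    returned by :func:`rates_from_traces`.  Every (group, load, pH,
    inactivation) cell needs >= 2 specimens.
    """
    if isinstance(samples, pd.DataFrame):
        df = samples
    else:
        df = pd.DataFrame(
            {
                "group": [s.group for s in samples],
                "load_mg": [s.load_mg for s in samples],
                "ph": [s.ph for s in samples],
                "inactivated": [s.inactivated for s in samples],
                "creep_rate_pct_h": [s.creep_rate for s in samples],
            }
        )
    if df.empty:
        raise ValueError("no creep-rate samples supplied")
    rows = []
    for keys, sub in df.groupby(GROUP_KEYS, sort=True):
        n = len(sub)
        if n < 2:
            raise ValueError(f"condition cell {keys} has < 2 specimens")
        rates = sub["creep_rate_pct_h"].to_numpy(dtype=float)
        rows.append(dict(zip(GROUP_KEYS, keys)) | {
            "mean_rate_pct_h": float(rates.mean()),
            "se_rate_pct_h": float(rates.std(ddof=1) / np.sqrt(n)),
            "n": n,
        })
    return pd.DataFrame(rows)
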