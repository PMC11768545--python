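"""End-to-end analysis pipeline: traces -> rates -> stress -> ratios -> fits.

One :class:`AnalysisConfig` drives the whole chain.  Inputs are either a pair
of CSV files (creep traces and dry masses) or a pair of simulation scenarios;
outputs are tidy CSV tables per stage plus a machine-readable summary JSON
embedding the resolved configuration, its hash, and all seeds, so a run is
reproducible and byte-identical under a fixed config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import kinematics, mechanics, mlfr, ratio, synthetic

log = logging.getLogger("wallcreep")

SCHEMA_VERSION = 1

MASSES_REQUIRED = ["group", "replicate", "dry_mass_ug", "segment_length_mm"]


@dataclass
class AnalysisConfig:
    """Resolved parameters for one pipeline run."""

    traces_csv: str | None = None
    masses_csv: str | None = None
    scenario_control: synthetic.SimulationScenario | None = None
    scenario_treated: synthetic.SimulationScenario | None = None
    window_s: tuple = kinematics.DEFAULT_WINDOW
    density_g_cm3: float = mechanics.WALL_DENSITY
    g_constant: float = mechanics.G_STANDARD
    stress_mode: str = "per_replicate"
    n_boot: int = 10000
    resample_size_rates: int = 4
    resample_size_stress: int = 4
    ratio_statistic: str = "ratio_of_means"
    lambda_mode: str = "per_point"
    alpha: float = 0.05
    seed: int = 0
    outdir: str | None = None

    def __post_init__(self):
        has_files = self.traces_csv is not None and self.masses_csv is not None
        has_scen = (self.scenario_control is not None
                    and self.scenario_treated is not None)
        if not (has_files or has_scen):
            raise ValueError("config needs input CSVs or a scenario pair")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")

    @classmethod
    def from_file(cls, path) -> "AnalysisConfig":
        text = Path(path).read_text()
        raw = yaml.safe_load(text)
        for key in ("scenario_control", "scenario_treated"):
            if raw.get(key) is not None:
                raw[key] = synthetic.scenario_from_dict(raw[key])
        if "window_s" in raw:
            raw["window_s"] = tuple(raw["window_s"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["window_s"] = list(self.window_s)
        d.pop("outdir", None)  # output location does not affect results
        return d

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def validate_inputs(traces_csv=None, masses_csv=None) -> list[dict]:
    """Schema diagnostics for input CSVs; always returns a report.

    Each entry: ``{"file", "passed", "issues": [...]}``.
    """
    report = []
    if traces_csv is not None:
        issues = []
        try:
            df = pd.read_csv(traces_csv)
            missing = [c for c in kinematics.TRACES_COLUMNS
                       if c not in df.columns]
            if missing:
                issues.append(f"missing columns: {missing}")
            else:
                for sid, sub in df.groupby("specimen_id"):
                    t = sub["time_s"].to_numpy(dtype=float)
                    if np.any(np.diff(t) <= 0):
                        issues.append(f"specimen {sid}: times not increasing")
                    if not np.all(np.isfinite(
                            sub["rel_extension_pct"].to_numpy(dtype=float))):
                        issues.append(f"specimen {sid}: non-finite extension")
        except Exception as exc:  # unreadable file is a diagnostic, not a crash
            issues.append(f"unreadable: {exc}")
        report.append({"file": str(traces_csv), "passed": not issues,
                       "issues": issues})
    if masses_csv is not None:
        issues = []
        try:
            df = pd.read_csv(masses_csv)
            missing = [c for c in MASSES_REQUIRED if c not in df.columns]
            if missing:
                issues.append(f"missing columns: {missing}")
            elif (df["dry_mass_ug"] <= 0).any():
                issues.append("non-positive dry mass")
        except Exception as exc:
            issues.append(f"unreadable: {exc}")
        report.append({"file": str(masses_csv), "passed": not issues,
                       "issues": issues})
    return report


@dataclass
class PipelineResult:
    """All stage outputs of one run, in memory."""

    rates: pd.DataFrame
    rate_summary: pd.DataFrame
    stress_table: pd.DataFrame
    ratios: pd.DataFrame
    ratio_comparisons: pd.DataFrame
    fits: pd.DataFrame
    fit_comparisons: pd.DataFrame
    summary: dict

    def write(self, outdir):
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        fmt = "%.10g"
        self.rates.to_csv(outdir / "rates.csv", index=False, float_format=fmt)
        self.rate_summary.to_csv(outdir / "rate_summary.csv", index=False,
                                 float_format=fmt)
        self.stress_table.to_csv(outdir / "stress_table.csv", index=False,
                                 float_format=fmt)
        self.ratios.to_csv(outdir / "ratios.csv", index=False, float_format=fmt)
        self.ratio_comparisons.to_csv(outdir / "ratio_comparisons.csv",
                                      index=False, float_format=fmt)
        self.fits.to_csv(outdir / "fits.csv", index=False, float_format=fmt)
        self.fit_comparisons.to_csv(outdir / "fit_comparisons.csv",
                                    index=False, float_format=fmt)
        (outdir / "summary.json").write_text(
            json.dumps(self.summary, indent=2, sort_keys=True) + "\n")
        return outdir


def _load_inputs(config: AnalysisConfig):
    if config.traces_csv is not None:
        traces = pd.read_csv(config.traces_csv)
        masses = pd.read_csv(config.masses_csv)
        return traces, masses
    ds = synthetic.simulate_experiment(config.scenario_control,
                                       config.scenario_treated)
    return ds.traces, ds.masses


def run_pipeline(config: AnalysisConfig) -> PipelineResult:
    """Run the full analysis described by ``config``.

    Stages: creep-rate extraction (OLS slope per specimen over the config
    window), stress table from dry masses, bootstrap creep-rate x stress^-1
    ratios with BH-FDR contrasts, and the MLFR line fit per condition with
    jackknife SEs, significance, ND propagation and between-group parameter
    comparisons.  Deterministic for a fixed config.
    """
    traces, masses = _load_inputs(config)
    log.info("loaded %d trace rows, %d mass replicates",
             len(traces), len(masses))

    rates = kinematics.rates_from_traces(traces, config.window_s)
    rate_summary = kinematics.group_rates(rates)
    log.info("rates: %d specimens, %d condition cells",
             len(rates), len(rate_summary))

    loads = sorted(traces["load_mg"].unique())
    stress_table = mechanics.group_stress_table(
        masses, loads, config.density_g_cm3, config.g_constant,
        config.stress_mode)

    # per-group replicate stress pools for the bootstrap
    stress_pools = {}
    for group, sub in masses.groupby("group"):
        mvals = sub["dry_mass_ug"].to_numpy(dtype=float)
        lens = sub["segment_length_mm"].to_numpy(dtype=float)
        for load in loads:
            stress_pools[(group, float(load))] = mechanics.wall_stress(
                mechanics.load_to_force(load, config.g_constant),
                mechanics.cross_section_area(mvals, float(lens.mean()),
                                             config.density_g_cm3))

    # bootstrap ratios per condition cell; child seeds keyed by the
    # condition (not the group), so paired groups share resampling streams
    cells = [tuple(k) for k, _ in rates.groupby(kinematics.GROUP_KEYS,
                                                sort=True)]
    conditions = sorted({(load, ph, inact) for _, load, ph, inact in cells})
    cond_seeds = dict(zip(conditions, np.random.SeedSequence(
        config.seed, spawn_key=(2,)).generate_state(len(conditions))))
    estimates = []
    for group, load, ph, inact in cells:
        cseed = cond_seeds[(load, ph, inact)]
        pool = rates[(rates["group"] == group) & (rates["load_mg"] == load)
                     & (rates["ph"] == ph) & (rates["inactivated"] == inact)]
        est = ratio.bootstrap_ratio(
            pool["creep_rate_pct_h"].to_numpy(),
            stress_pools[(group, float(load))],
            n_boot=config.n_boot,
            resample_size_rates=config.resample_size_rates,
            resample_size_stress=config.resample_size_stress,
            statistic=config.ratio_statistic,
            seed=int(cseed),
            group=group, load_mg=float(load), ph=float(ph),
            inactivated=bool(inact))
        estimates.append(est)
    ratios_df = pd.DataFrame([dataclasses.asdict(e) for e in estimates])
    comparisons = ratio.compare_ratio_groups(estimates, alpha=config.alpha)
    ratio_cmp_df = pd.DataFrame([
        {
            "group_a": c.contrast[0], "group_b": c.contrast[1],
            "load_mg": c.contrast[2], "ph": c.contrast[3],
            "inactivated": c.contrast[4], "t_stat": c.t_stat, "df": c.df,
            "p_raw": c.p_raw, "p_adjusted": c.p_adjusted,
            "significant": c.significant,
        }
        for c in comparisons
    ])

    # MLFR fit per (group, ph, inactivated) across loads
    fits = {}
    fit_rows = []
    for (group, ph, inact), sub in rate_summary.groupby(
            ["group", "ph", "inactivated"], sort=True):
        sub = sub.sort_values("load_mg")
        st = stress_table[stress_table["group"] == group].set_index("load_mg")
        st = st.loc[sub["load_mg"].to_numpy()]
        n_rep = st["n_replicates"].to_numpy()
        points = mlfr.StressRatePoints(
            x=st["stress_mean_mpa"].to_numpy(),
            x_se=st["stress_sd_mpa"].to_numpy() / np.sqrt(n_rep),
            y=sub["mean_rate_pct_h"].to_numpy(),
            y_se=sub["se_rate_pct_h"].to_numpy(),
            group=group, ph=float(ph), inactivated=bool(inact))
        fit = mlfr.fit_with_inference(points, config.lambda_mode)
        fits[(group, float(ph), bool(inact))] = fit
        nd = not (np.isfinite(fit.slope_p) and fit.slope_p < config.alpha)
        fit_rows.append({
            "group": group, "ph": float(ph), "inactivated": bool(inact),
            "phi_pct_h_mpa": fit.slope_phi, "phi_se": fit.se_phi,
            "y_mpa": fit.x_intercept_y, "y_se": fit.se_y,
            "intercept_pct_h": fit.intercept, "slope_p": fit.slope_p,
            "df": fit.df_regression, "nd": nd,
            "phi_report": "ND" if nd else f"{fit.slope_phi:.2f}",
            "y_report": "ND" if nd else f"{fit.x_intercept_y:.2f}",
            "lambda_weighting": fit.lambda_weighting,
        })
    fits_df = pd.DataFrame(fit_rows)

    # parameter comparisons between groups within the same condition
    cmp_rows = []
    keys = sorted(fits)
    for i, k1 in enumerate(keys):
        for k2 in keys[i + 1:]:
            if k1[1:] != k2[1:]:
                continue  # only contrast like conditions across groups
            f1, f2 = fits[k1], fits[k2]
            if not (np.isfinite(f1.se_phi) and np.isfinite(f2.se_phi)):
                continue
            for param in ("phi", "y"):
                c = mlfr.compare_models(f1, f2, param)
                cmp_rows.append({
                    "group_a": k1[0], "group_b": k2[0], "ph": k1[1],
                    "inactivated": k1[2], "parameter": param,
                    "t_ratio": c.t_ratio, "df": c.df, "p_value": c.p_value,
                    "significant": c.p_value < config.alpha,
                    # comparisons of ND parameters are reported but flagged
                    "nd_either": not (f1.significant and f2.significant),
                })
    fit_cmp_df = pd.DataFrame(cmp_rows)

    summary = {
        "schema_version": SCHEMA_VERSION,
        "config": config.to_dict(),
        "config_hash": config.hash(),
        "n_specimens": int(len(rates)),
        "n_condition_cells": int(len(rate_summary)),
        "fits": {
            f"{r['group']}|ph{r['ph']:g}|"
            f"{'inactivated' if r['inactivated'] else 'native'}": {
                "phi": r["phi_report"], "y": r["y_report"],
                "phi_value": r["phi_pct_h_mpa"], "phi_se": r["phi_se"],
                "y_value": r["y_mpa"], "y_se": r["y_se"],
                "slope_p": r["slope_p"],
            }
            for r in fit_rows
        },
        "n_ratio_contrasts": int(len(ratio_cmp_df)),
        "n_significant_ratio_contrasts":
            int(ratio_cmp_df["significant"].sum()) if len(ratio_cmp_df) else 0,
    }
    result = PipelineResult(
        rates=rates, rate_summary=rate_summary, stress_table=stress_table,
        ratios=ratios_df, ratio_comparisons=ratio_cmp_df, fits=fits_df,
        fit_comparisons=fit_cmp_df, summary=summary)
    if config.outdir is not None:
        result.write(config.outdir)
        log.info("wrote outputs to %s", config.outdir)
    return result
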