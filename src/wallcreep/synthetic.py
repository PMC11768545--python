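"""Synthetic creep-extensometry experiments.

Emulates the measurement structure of a two-group, four-load constant-load
creep study on isolated hypocotyl cell walls: per-specimen extension traces
whose relative creep rate follows a Lockhart-type law

    rate = phi * max(0, sigma - y)        (% h^-1)

with extensibility ``phi`` (% h^-1 MPa^-1) and yield threshold ``y`` (MPa),
plus between-specimen Gaussian rate noise; and segment dry-mass replicates
drawn from a zero-truncated Gaussian, from which the analysis derives wall
cross-section area and tensile stress.

Defaults reproduce the study design: loads 400-700 mg, 10 creep specimens per
load, 4 dry-mass replicates, 15-min traces sampled at 1 s, 1 % instantaneous
elastic extension at load application.  Everything is seeded and reproducible;
two identical scenarios (including seed) generate byte-identical group tables.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .kinematics import CreepTrace
from .mechanics import (G_STANDARD, WALL_DENSITY, cross_section_area,
                        load_to_force, wall_stress)

MASSES_COLUMNS = ["group", "replicate", "dry_mass_ug", "segment_length_mm"]


@dataclass(frozen=True)
class SimulationScenario:
    """Generating parameters for one treatment group.

    ``phi`` and ``y_threshold`` define the creep-rate-vs-stress line;
    ``creep_rate_noise_sd`` is the between-specimen SD of the rate
    (one draw per specimen); ``point_noise_sd`` optionally adds small
    per-sample jitter to the trace itself.
    """

    group: str = "control"
    phi: float = 0.80                   # % h^-1 MPa^-1
    y_threshold: float = 15.23          # MPa
    loads_mg: tuple = (400.0, 500.0, 600.0, 700.0)
    n_specimens_per_load: int = 10
    dry_mass_mean: float = 1.52         # ug per segment
    dry_mass_sd: float = 0.11           # ug
    n_mass_replicates: int = 4
    creep_rate_noise_sd: float = 1.5    # % h^-1, between specimens
    point_noise_sd: float = 0.0         # %, per time point
    trace_duration_s: float = 900.0
    trace_sampling_interval_s: float = 1.0
    elastic_jump_pct: float = 1.0
    segment_length_mm: float = 5.0
    ph: float = 5.0
    inactivated: bool = False
    density_g_cm3: float = WALL_DENSITY
    seed: int = 0

    def __post_init__(self):
        if self.phi < 0 or self.y_threshold < 0:
            raise ValueError("phi and y_threshold must be >= 0")
        if not self.loads_mg or any(l <= 0 for l in self.loads_mg):
            raise ValueError("loads_mg must be non-empty and positive")
        if self.n_specimens_per_load < 2 or self.n_mass_replicates < 2:
            raise ValueError("need >= 2 specimens per load and >= 2 mass replicates")
        if self.dry_mass_mean <= 0:
            raise ValueError("dry_mass_mean must be > 0")
        if min(self.dry_mass_sd, self.creep_rate_noise_sd,
               self.point_noise_sd) < 0:
            raise ValueError("noise SDs must be >= 0")
        if self.trace_duration_s <= 0 or self.trace_sampling_interval_s <= 0:
            raise ValueError("trace duration and sampling interval must be > 0")

    def to_dict(self):
        return dataclasses.asdict(self)


def control_scenario(**overrides) -> SimulationScenario:
    """Untreated-control group at pH 5 (defaults of SimulationScenario)."""
    return SimulationScenario(**overrides)


def ebl_scenario(**overrides) -> SimulationScenario:
    """Epibrassinolide-grown group at pH 5: softer line, heavier walls."""
    params = dict(group="ebl", phi=0.31, y_threshold=5.42,
                  dry_mass_mean=2.30, dry_mass_sd=0.13,
                  creep_rate_noise_sd=0.75)
    params.update(overrides)
    return SimulationScenario(**params)


def simulate_dry_masses(scenario: SimulationScenario, rng=None) -> np.ndarray:
    """Draw ``n_mass_replicates`` dry masses (ug), Gaussian truncated at 0."""
    if rng is None:
        rng = np.random.default_rng(
            np.random.SeedSequence(scenario.seed, spawn_key=(0,)))
    n = scenario.n_mass_replicates
    if scenario.dry_mass_sd == 0:
        return np.full(n, scenario.dry_mass_mean)
    out = rng.normal(scenario.dry_mass_mean, scenario.dry_mass_sd, size=n)
    # rejection step: redraw non-positive values (negligible at realistic CV)
    while np.any(out <= 0):
        bad = out <= 0
        out[bad] = rng.normal(scenario.dry_mass_mean, scenario.dry_mass_sd,
                              size=int(bad.sum()))
    return out


def simulate_creep_trace(scenario: SimulationScenario, load_mg: float,
                         true_stress_mpa: float, seed: int,
                         specimen_id: str = "sim-0") -> CreepTrace:
    """One specimen's creep trace at a given true wall stress.

    The specimen's rate is ``phi * max(0, stress - y)`` plus one Gaussian
    draw of SD ``creep_rate_noise_sd``; the trace is the 1 % elastic jump
    plus linear creep at that rate, sampled on the scenario's time grid.
    """
    if true_stress_mpa <= 0:
        raise ValueError("true_stress_mpa must be > 0")
    rng = np.random.default_rng(seed)
    base = scenario.phi * max(0.0, true_stress_mpa - scenario.y_threshold)
    rate = base
    if scenario.creep_rate_noise_sd > 0:
        rate += rng.normal(0.0, scenario.creep_rate_noise_sd)
    dt = scenario.trace_sampling_interval_s
    times = np.arange(0.0, scenario.trace_duration_s + dt / 2, dt)
    rel = scenario.elastic_jump_pct + rate * times / 3600.0
    if scenario.point_noise_sd > 0:
        rel = rel + rng.normal(0.0, scenario.point_noise_sd, size=times.size)
    return CreepTrace(
        specimen_id=specimen_id,
        group=scenario.group,
        load_mg=float(load_mg),
        ph=scenario.ph,
        inactivated=scenario.inactivated,
        times=times,
        rel_extension=rel,
        initial_length_mm=scenario.segment_length_mm,
    )


@dataclass
class ExperimentDataset:
    """Simulated two-group dataset with full generation provenance."""

    traces: pd.DataFrame
    masses: pd.DataFrame
    metadata: dict

    def to_csv(self, outdir):
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.traces.to_csv(outdir / "traces.csv", index=False,
                           float_format="%.10g")
        self.masses.to_csv(outdir / "masses.csv", index=False,
                           float_format="%.10g")
        (outdir / "metadata.json").write_text(
            json.dumps(self.metadata, indent=2, sort_keys=True) + "\n")
        return outdir


def _simulate_group(scenario: SimulationScenario):
    """Traces + masses for one scenario, seeded from the scenario itself."""
    masses = simulate_dry_masses(scenario)
    true_area = cross_section_area(scenario.dry_mass_mean,
                                   scenario.segment_length_mm,
                                   scenario.density_g_cm3)
    n_traces = len(scenario.loads_mg) * scenario.n_specimens_per_load
    trace_seeds = np.random.SeedSequence(
        scenario.seed, spawn_key=(1,)).generate_state(n_traces)
    frames = []
    k = 0
    for load in scenario.loads_mg:
        stress = wall_stress(load_to_force(load), true_area)
        for j in range(scenario.n_specimens_per_load):
            sid = f"{scenario.group}-L{int(load)}-{j:02d}"
            tr = simulate_creep_trace(scenario, load, stress,
                                      int(trace_seeds[k]), specimen_id=sid)
            k += 1
            frames.append(pd.DataFrame({
                "specimen_id": sid,
                "group": tr.group,
                "load_mg": tr.load_mg,
                "ph": tr.ph,
                "inactivated": tr.inactivated,
                "time_s": tr.times,
                "rel_extension_pct": tr.rel_extension,
            }))
    traces = pd.concat(frames, ignore_index=True)
    masses_df = pd.DataFrame({
        "group": scenario.group,
        "replicate": np.arange(len(masses)),
        "dry_mass_ug": masses,
        "segment_length_mm": scenario.segment_length_mm,
    })
    return traces, masses_df


def simulate_experiment(scenario_control: SimulationScenario,
                        scenario_treated: SimulationScenario) -> ExperimentDataset:
    """Complete two-group dataset (traces + dry masses + provenance).

    Group labels must differ.  Each group's random stream derives from its
    own scenario seed, so identical scenarios yield identical group tables.
    """
    if scenario_control.group == scenario_treated.group:
        raise ValueError("the two scenarios must use distinct group labels")
    parts = [_simulate_group(s) for s in (scenario_control, scenario_treated)]
    traces = pd.concat([p[0] for p in parts], ignore_index=True)
    masses = pd.concat([p[1] for p in parts], ignore_index=True)
    metadata = {
        "scenarios": {
            scenario_control.group: scenario_control.to_dict(),
            scenario_treated.group: scenario_treated.to_dict(),
        },
        "n_traces": int(traces["specimen_id"].nunique()),
    }
    return ExperimentDataset(traces=traces, masses=masses, metadata=metadata)


def scenario_from_dict(d: dict) -> SimulationScenario:
    d = dict(d)
    if "loads_mg" in d:
        d["loads_mg"] = tuple(d["loads_mg"])
    return SimulationScenario(**d)
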