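"""Cell-wall cross-section area and tensile stress under constant load.

The wall cross-section area of a cylindrical organ segment is estimated from
its dry mass: with wall density rho, ``A = m / (rho * l)``.  A hanging load of
``m_load`` milligrams exerts a tensile force ``F = m_load * g`` and the wall
stress is ``sigma = F / A``.

Units are fixed at the bench scale used throughout the package: dry mass in
micrograms, segment length in millimetres, density in g cm^-3, area in square
micrometres, force in newtons, stress in MPa.  Conversions are exact; rounding
happens only in report tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: standard gravitational acceleration, m s^-2
G_STANDARD = 9.80665

#: assumed cell wall density, g cm^-3
WALL_DENSITY = 1.5

#: default segment length, mm
SEGMENT_LENGTH_MM = 5.0


def cross_section_area(mass_ug, length_mm=SEGMENT_LENGTH_MM, density_g_cm3=WALL_DENSITY):
    """Wall cross-section area (um^2) from segment dry mass.

    A = m / (rho * l).  With mass in ug, length in mm and density in g cm^-3
    the area in um^2 is ``mass_ug * 1000 / (density * length_mm)``.

    Accepts scalars or arrays; all inputs must be strictly positive.
    """
    mass_ug = np.asarray(mass_ug, dtype=float)
    if np.any(mass_ug <= 0):
        raise ValueError("dry mass must be > 0")
    if length_mm <= 0 or density_g_cm3 <= 0:
        raise ValueError("segment length and density must be > 0")
    area = mass_ug * 1e3 / (density_g_cm3 * length_mm)
    return float(area) if area.ndim == 0 else area


def load_to_force(load_mg, g_constant=G_STANDARD):
    """Tensile force (N) exerted by a hanging load of ``load_mg`` milligrams."""
    load_mg = np.asarray(load_mg, dtype=float)
    if np.any(load_mg <= 0):
        raise ValueError("load must be > 0")
    force = load_mg * 1e-6 * g_constant
    return float(force) if force.ndim == 0 else force


def wall_stress(force_n, area_um2):
    """Tensile stress (MPa) from force (N) over wall area (um^2).

    1 um^2 = 1e-12 m^2, so sigma[MPa] = F/A * 1e-12^-1 Pa * 1e-6 = F * 1e6 / A.
    """
    force_n = np.asarray(force_n, dtype=float)
    area_um2 = np.asarray(area_um2, dtype=float)
    if np.any(force_n <= 0) or np.any(area_um2 <= 0):
        raise ValueError("force and area must be > 0")
    sigma = force_n * 1e6 / area_um2
    return float(sigma) if sigma.ndim == 0 else sigma


@dataclass(frozen=True)
class SegmentDryMass:
    """One dry-mass replicate for a treatment group."""

    group: str
    dry_mass_ug: float
    segment_length_mm: float = SEGMENT_LENGTH_MM
    replicate: int = 0

    def __post_init__(self):
        if self.dry_mass_ug <= 0:
            raise ValueError("dry_mass_ug must be > 0")
        if self.segment_length_mm <= 0:
            raise ValueError("segment_length_mm must be > 0")


@dataclass(frozen=True)
class WallGeometry:
    """Group-level wall geometry derived from dry-mass replicates."""

    group: str
    area_um2: float
    density_used: float
    per_replicate_areas: tuple = field(default_factory=tuple)

    def __post_init__(self):
        if self.area_um2 <= 0 or self.density_used <= 0:
            raise ValueError("area and density must be > 0")


def replicate_stresses(mass_values_ug, load_mg, length_mm=SEGMENT_LENGTH_MM,
                       density_g_cm3=WALL_DENSITY, g_constant=G_STANDARD):
    """Per-replicate stresses (MPa) for one load from dry-mass replicates."""
    masses = np.asarray(mass_values_ug, dtype=float)
    areas = cross_section_area(masses, length_mm, density_g_cm3)
    force = load_to_force(load_mg, g_constant)
    return wall_stress(force, areas)


def group_stress_table(masses, loads_mg, density_g_cm3=WALL_DENSITY,
                       g_constant=G_STANDARD, mode="per_replicate"):
    """Stress summary table per (group, load).

    Parameters
    ----------
    masses
        Sequence of :class:`SegmentDryMass` or a DataFrame with columns
        ``group, replicate, dry_mass_ug, segment_length_mm``.
    loads_mg
        Applied loads in milligrams.
    mode
        ``"per_replicate"`` (default): stress computed for each mass
        replicate, the table reports mean +/- SD across replicates.
        ``"mean_mass"``: stress computed once from the mean mass (SD 0).

    Returns
    -------
    DataFrame with columns ``group, load_mg, force_n, stress_mean_mpa,
    stress_sd_mpa, n_replicates, area_um2``.
    """
    if mode not in ("per_replicate", "mean_mass"):
        raise ValueError(f"unknown stress mode {mode!r}")
    loads_mg = list(loads_mg)
    if not loads_mg:
        raise ValueError("loads_mg must be non-empty")
    if isinstance(masses, pd.DataFrame):
        df = masses
    else:
        df = pd.DataFrame(
            {
                "group": [m.group for m in masses],
                "replicate": [m.replicate for m in masses],
                "dry_mass_ug": [m.dry_mass_ug for m in masses],
                "segment_length_mm": [m.segment_length_mm for m in masses],
            }
        )
    if df.empty:
        raise ValueError("no dry-mass replicates supplied")

    rows = []
    for group, sub in df.groupby("group", sort=True):
        if len(sub) < 2:
            raise ValueError(f"group {group!r} has < 2 dry-mass replicates")
        lengths = sub["segment_length_mm"].to_numpy(dtype=float)
        masses_ug = sub["dry_mass_ug"].to_numpy(dtype=float)
        mean_area = cross_section_area(masses_ug.mean(), float(lengths.mean()),
                                       density_g_cm3)
        for load in loads_mg:
            force = load_to_force(load, g_constant)
            if mode == "per_replicate":
                sigmas = np.array([
                    wall_stress(force, cross_section_area(m, l, density_g_cm3))
                    for m, l in zip(masses_ug, lengths)
                ])
                mean, sd = float(sigmas.mean()), float(sigmas.std(ddof=1))
            else:
                mean, sd = float(wall_stress(force, mean_area)), 0.0
            rows.append(
                {
                    "group": group,
                    "load_mg": float(load),
                    "force_n": float(force),
                    "stress_mean_mpa": mean,
                    "stress_sd_mpa": sd,
                    "n_replicates": int(len(sub)),
                    "area_um2": float(mean_area),
                }
            )
    out = pd.DataFrame(rows)
    # sanity: stress must increase with load within each group
    for group, sub in out.groupby("group"):
        s = sub.sort_values("load_mg")["stress_mean_mpa"].to_numpy()
        if np.any(np.diff(s) <= 0):
            raise AssertionError("stress not increasing with load")
    return out
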