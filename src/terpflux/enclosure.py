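"""Emission rates from dynamic (flow-through) enclosure measurements.

A dynamic enclosure is purged at flow rate Q (L h⁻¹); the emission of the
enclosed vegetation raises the outlet analyte concentration C_out above
the inlet (purge air) concentration C_in.  At steady state the flux is

    ER_surface = (C_out − C_in) · Q / S        [μgC m⁻² h⁻¹]
    ER_branch  = (C_out − C_in) · Q / m_dry    [μgC g⁻¹ h⁻¹]

with S the enclosed footprint area (m²) and m_dry the dry mass (g) of the
enclosed foliage.  Negative differences (deposition or analytical noise)
are retained but flagged so that downstream log-space fits can exclude
them explicitly.

Cartridge-level QC covers internal-standard recovery and two-stage
breakthrough checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "EnclosureRecord",
    "EmissionRateRecord",
    "GeometryError",
    "surface_emission_rate",
    "branch_emission_rate",
    "emission_rates",
    "internal_standard_recovery",
    "breakthrough_check",
    "drop_acclimation",
]

FLAG_DEPOSITION = "deposition_or_noise"
FLAG_RECOVERY = "recovery_out_of_range"
FLAG_BREAKTHROUGH = "breakthrough"

#: Default acceptance window for internal-standard recoveries, percent.
RECOVERY_WINDOW = (70.0, 130.0)

#: Default back/total fraction above which a cartridge pair is flagged.
BREAKTHROUGH_THRESHOLD = 0.05


class GeometryError(ValueError):
    """Missing or invalid chamber geometry (area or dry mass)."""


@dataclass(frozen=True)
class EnclosureRecord:
    """One timed chamber observation for one compound.

    Concentrations are carbon-mass based (μgC L⁻¹); ``s`` applies to
    surface chambers and ``m_dry`` to branch chambers (exactly one set).
    The timestamp marks the end of the integrated sampling period.
    """

    timestamp: pd.Timestamp
    enclosure_id: str
    kind: str                      # "surface" | "branch"
    compound: str
    c_in: float                    # μgC L⁻¹
    c_out: float                   # μgC L⁻¹
    q: float                       # L h⁻¹
    t_enclosure: float             # °C
    par: float                     # μmol m⁻² s⁻¹
    s: float | None = None         # m²
    m_dry: float | None = None     # g
    vegetation_class: str = "miscellaneous"
    rh: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("surface", "branch"):
            raise ValueError(f"unknown enclosure kind {self.kind!r}")
        if self.q <= 0:
            raise ValueError("purge flow q must be positive")
        if self.c_in < 0 or self.c_out < 0:
            raise ValueError("concentrations must be non-negative")


@dataclass(frozen=True)
class EmissionRateRecord:
    """A computed emission rate with its measurement conditions."""

    timestamp: pd.Timestamp
    enclosure_id: str
    compound: str
    value: float                   # μgC m⁻² h⁻¹ or μgC g⁻¹ h⁻¹
    basis: str                     # "per_area" | "per_dry_mass"
    t_enclosure: float             # °C
    par: float
    vegetation_class: str = "miscellaneous"
    qc_flags: frozenset = field(default_factory=frozenset)


def surface_emission_rate(record: EnclosureRecord) -> EmissionRateRecord:
    """Areal emission rate (C_out − C_in)·Q/S for a surface chamber."""
    if record.kind != "surface":
        raise GeometryError("surface_emission_rate requires kind='surface'")
    if record.s is None or record.s <= 0:
        raise GeometryError("surface record needs a positive footprint area s")
    value = (record.c_out - record.c_in) * record.q / record.s
    flags = frozenset({FLAG_DEPOSITION}) if value < 0 else frozenset()
    return EmissionRateRecord(
        timestamp=record.timestamp,
        enclosure_id=record.enclosure_id,
        compound=record.compound,
        value=value,
        basis="per_area",
        t_enclosure=record.t_enclosure,
        par=record.par,
        vegetation_class=record.vegetation_class,
        qc_flags=flags,
    )


def branch_emission_rate(record: EnclosureRecord) -> EmissionRateRecord:
    """Per-dry-mass emission rate (C_out − C_in)·Q/m_dry for a branch chamber."""
    if record.kind != "branch":
        raise GeometryError("branch_emission_rate requires kind='branch'")
    if record.m_dry is None or record.m_dry <= 0:
        raise GeometryError("branch record needs a positive dry mass m_dry")
    value = (record.c_out - record.c_in) * record.q / record.m_dry
    flags = frozenset({FLAG_DEPOSITION}) if value < 0 else frozenset()
    return EmissionRateRecord(
        timestamp=record.timestamp,
        enclosure_id=record.enclosure_id,
        compound=record.compound,
        value=value,
        basis="per_dry_mass",
        t_enclosure=record.t_enclosure,
        par=record.par,
        vegetation_class=record.vegetation_class,
        qc_flags=flags,
    )


def emission_rates(df: pd.DataFrame) -> pd.DataFrame:
    """Vectorized emission-rate computation over an enclosure table.

    Expects columns ``timestamp, enclosure_id, kind, compound, c_in, c_out,
    q, t_enclosure, par`` plus ``s`` (surface rows) and/or ``m_dry``
    (branch rows).  Returns one row per input with ``value``, ``basis`` and
    semicolon-joined ``qc_flags``.
    """
    required = {"timestamp", "enclosure_id", "kind", "compound",
                "c_in", "c_out", "q", "t_enclosure", "par"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"enclosure table missing columns: {sorted(missing)}")
    if (df["q"] <= 0).any():
        raise ValueError("purge flow q must be positive")

    delta = (df["c_out"] - df["c_in"]) * df["q"]
    is_surface = df["kind"] == "surface"
    is_branch = df["kind"] == "branch"
    if not (is_surface | is_branch).all():
        bad = df.loc[~(is_surface | is_branch), "kind"].unique()
        raise ValueError(f"unknown enclosure kind(s): {list(bad)}")

    value = pd.Series(np.nan, index=df.index, dtype=float)
    if is_surface.any():
        s = df.loc[is_surface, "s"] if "s" in df.columns else None
        if s is None or s.isna().any() or (s <= 0).any():
            raise GeometryError("surface rows need a positive footprint area s")
        value[is_surface] = delta[is_surface] / s
    if is_branch.any():
        m = df.loc[is_branch, "m_dry"] if "m_dry" in df.columns else None
        if m is None or m.isna().any() or (m <= 0).any():
            raise GeometryError("branch rows need a positive dry mass m_dry")
        value[is_branch] = delta[is_branch] / m

    out = df[["timestamp", "enclosure_id", "compound",
              "t_enclosure", "par"]].copy()
    if "vegetation_class" in df.columns:
        out["vegetation_class"] = df["vegetation_class"]
    out["value"] = value
    out["basis"] = np.where(is_surface, "per_area", "per_dry_mass")
    out["qc_flags"] = np.where(value < 0, FLAG_DEPOSITION, "")
    # keep planted truth columns if the table came from the simulator
    for col in ("er_true",):
        if col in df.columns:
            out[col] = df[col]
    return out


@dataclass(frozen=True)
class RecoveryResult:
    percent: float
    flagged: bool


def internal_standard_recovery(
    measured: float,
    loaded: float,
    window: tuple[float, float] = RECOVERY_WINDOW,
) -> RecoveryResult:
    """Recovery of a preloaded internal standard, percent of loaded mass.

    Cartridges outside the acceptance window (default 70–130 %) are
    flagged, indicating analyte loss or contamination during transport,
    storage or analysis.
    """
    if loaded <= 0:
        raise ValueError("loaded mass must be positive")
    pct = 100.0 * measured / loaded
    return RecoveryResult(percent=pct, flagged=not (window[0] <= pct <= window[1]))


@dataclass(frozen=True)
class BreakthroughResult:
    fraction: float
    flagged: bool


def breakthrough_check(
    front: float,
    back: float,
    threshold: float = BREAKTHROUGH_THRESHOLD,
) -> BreakthroughResult:
    """Analyte breakthrough fraction back/(front+back) for cartridges in series.

    The pair is flagged when the fraction strictly exceeds *threshold*
    (the boundary value itself passes).
    """
    if front < 0 or back < 0:
        raise ValueError("masses must be non-negative")
    total = front + back
    if total == 0:
        raise ZeroDivisionError("front and back both zero; ratio undefined")
    frac = back / total
    return BreakthroughResult(fraction=frac, flagged=frac > threshold)


def drop_acclimation(df: pd.DataFrame, hours: float = 24.0) -> pd.DataFrame:
    """Drop each enclosure's records within *hours* of its first timestamp.

    Vegetation is allowed to acclimate after chamber installation before
    sampling is considered representative.
    """
    if hours <= 0:
        return df.copy()

    def _keep(group: pd.DataFrame) -> pd.DataFrame:
        start = group["timestamp"].min()
        return group[group["timestamp"] >= start + pd.Timedelta(hours=hours)]

    out = (df.groupby("enclosure_id", group_keys=False, sort=False)
             [df.columns].apply(_keep))
    return out.reset_index(drop=True)
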