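"""Compound metadata, carbon-basis unit conversions, and censored summaries.

Terpenoid amounts are reported on a carbon-mass basis (μgC) throughout this
package, because isoprene (C5H8), monoterpenes (C10H16) and sesquiterpenes
(C15H24) are all (C5H8)n oligomers and therefore share the same carbon mass
fraction to three decimals.  Converting a mixing ratio (pptv, pmol mol⁻¹) to
a carbon mass concentration requires the air molar density from the ideal
gas law plus the compound molar mass and carbon fraction.

Ambient chromatographic data are censored at a limit of quantification
(LOQ); summary statistics follow the half-LOQ substitution convention used
for trace-gas climatologies.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "ATOMIC_MASSES",
    "R_GAS",
    "CompoundSpec",
    "CensoredSummary",
    "compound_from_formula",
    "load_registry",
    "get_compound",
    "carbon_fraction",
    "mixing_ratio_to_carbon_conc",
    "carbon_conc_to_mixing_ratio",
    "censored_stats",
]

#: Standard atomic masses (g mol⁻¹).
ATOMIC_MASSES: Mapping[str, float] = {
    "C": 12.011,
    "H": 1.008,
    "O": 15.999,
    "N": 14.007,
    "F": 18.998,
    "Cl": 35.45,
}

#: Molar gas constant, J mol⁻¹ K⁻¹.
R_GAS = 8.314

#: Default limit of quantification for the GC system, pptv.
DEFAULT_LOQ_PPTV = 2.0

#: Default station pressure (kPa) for mixing-ratio ↔ mass conversions;
#: appropriate for a field site at roughly 720 m elevation.
DEFAULT_PRESSURE_KPA = 96.0

#: Fallback air temperature (K) when no measurement accompanies a sample.
DEFAULT_TEMPERATURE_K = 298.15

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class InvalidCompoundError(ValueError):
    """Raised for physically impossible compound definitions."""


@dataclass(frozen=True)
class CompoundSpec:
    """Chemical identity of an analyte.

    Parameters
    ----------
    name
        Canonical lower-case compound name.
    formula
        Hill-style elemental formula, e.g. ``"C5H8"``.
    molar_mass
        Molar mass in g mol⁻¹.
    n_carbon
        Number of carbon atoms per molecule.
    category
        Compound class label (``"isoprene"``, ``"monoterpene"``, ...).
    """

    name: str
    formula: str
    molar_mass: float
    n_carbon: int
    category: str = "other"

    def __post_init__(self) -> None:
        if self.molar_mass <= 0:
            raise InvalidCompoundError(
                f"{self.name}: molar mass must be positive, got {self.molar_mass}"
            )
        if self.n_carbon < 0:
            raise InvalidCompoundError(f"{self.name}: negative carbon count")

    @property
    def carbon_fraction(self) -> float:
        """Mass fraction of carbon, 12.011·n_C / M."""
        return ATOMIC_MASSES["C"] * self.n_carbon / self.molar_mass


def _parse_formula(formula: str) -> dict[str, int]:
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_TOKEN.finditer(formula):
        if m.start() != pos:
            raise InvalidCompoundError(f"cannot parse formula {formula!r}")
        pos = m.end()
        counts[m.group(1)] = counts.get(m.group(1), 0) + int(m.group(2) or 1)
    if pos != len(formula) or not counts:
        raise InvalidCompoundError(f"cannot parse formula {formula!r}")
    return counts


def compound_from_formula(name: str, formula: str, category: str = "other") -> CompoundSpec:
    """Build a :class:`CompoundSpec` from an elemental formula.

    Molar mass is computed from standard atomic masses; elements outside
    the small built-in table raise :class:`InvalidCompoundError`.
    """
    counts = _parse_formula(formula)
    try:
        molar_mass = sum(ATOMIC_MASSES[el] * n for el, n in counts.items())
    except KeyError as exc:  # pragma: no cover - registry is curated
        raise InvalidCompoundError(f"no atomic mass for element {exc}") from exc
    return CompoundSpec(
        name=name,
        formula=formula,
        molar_mass=molar_mass,
        n_carbon=counts.get("C", 0),
        category=category,
    )


def load_registry() -> dict[str, CompoundSpec]:
    """Load the packaged compound registry (user code may add entries)."""
    text = resources.files("terpflux.data").joinpath("compounds.json").read_text()
    table = json.loads(text)
    return {
        name: compound_from_formula(name, entry["formula"], entry.get("category", "other"))
        for name, entry in table.items()
    }


_REGISTRY: dict[str, CompoundSpec] | None = None


def get_compound(name: str) -> CompoundSpec:
    """Look up a compound by name in the packaged registry."""
    global _REGISTRY
    if _REGISTRY is None:
        _REGISTRY = load_registry()
    try:
        return _REGISTRY[name.lower()]
    except KeyError:
        raise KeyError(f"unknown compound {name!r}; extend the registry or "
                       f"use compound_from_formula") from None


def carbon_fraction(compound: CompoundSpec) -> float:
    """Carbon mass fraction of *compound* (dimensionless, (0, 1])."""
    if compound.n_carbon < 1:
        raise InvalidCompoundError(f"{compound.name}: carbon-free compound has no carbon fraction")
    return compound.carbon_fraction


def mixing_ratio_to_carbon_conc(
    x_pptv,
    compound: CompoundSpec,
    temperature_k: float = DEFAULT_TEMPERATURE_K,
    pressure_kpa: float = DEFAULT_PRESSURE_KPA,
):
    """Convert a mixing ratio (pptv) to carbon mass concentration (μgC m⁻³).

    Uses the ideal-gas molar density n/V = P/(RT); the result is linear in
    the mixing ratio, pressure, and 1/T.  Accepts scalars or arrays.

    Raises
    ------
    ValueError
        For non-positive temperature/pressure or negative mixing ratios.
    """
    x = np.asarray(x_pptv, dtype=float)
    if temperature_k <= 0 or pressure_kpa <= 0:
        raise ValueError("temperature and pressure must be positive")
    if np.any(x < 0):
        raise ValueError("mixing ratio must be non-negative")
    molar_density = pressure_kpa * 1e3 / (R_GAS * temperature_k)  # mol m⁻³
    out = x * 1e-12 * molar_density * compound.molar_mass * compound.carbon_fraction * 1e6
    return float(out) if np.isscalar(x_pptv) else out


def carbon_conc_to_mixing_ratio(
    conc_ugc_m3,
    compound: CompoundSpec,
    temperature_k: float = DEFAULT_TEMPERATURE_K,
    pressure_kpa: float = DEFAULT_PRESSURE_KPA,
):
    """Inverse of :func:`mixing_ratio_to_carbon_conc` (μgC m⁻³ → pptv)."""
    c = np.asarray(conc_ugc_m3, dtype=float)
    if temperature_k <= 0 or pressure_kpa <= 0:
        raise ValueError("temperature and pressure must be positive")
    molar_density = pressure_kpa * 1e3 / (R_GAS * temperature_k)
    out = c / (1e-12 * molar_density * compound.molar_mass * compound.carbon_fraction * 1e6)
    return float(out) if np.isscalar(conc_ugc_m3) else out


@dataclass(frozen=True)
class CensoredSummary:
    """Summary statistics of a left-censored (below-LOQ) sample.

    Censored entries are replaced by LOQ/2 before computing mean, sd, min
    and max; ``quantification_frequency`` is the percentage of entries at
    or above the LOQ.
    """

    mean: float
    sd: float
    min: float
    max: float
    quantification_frequency: float
    loq: float
    n: int


def censored_stats(
    values: Sequence[float],
    loq: float = DEFAULT_LOQ_PPTV,
    censored: Sequence[bool] | None = None,
) -> CensoredSummary:
    """Summarize a sample with below-LOQ censoring.

    Parameters
    ----------
    values
        Measured mixing ratios (pptv).  Censored entries may hold any
        placeholder value; they are replaced by ``loq / 2``.
    loq
        Limit of quantification (pptv), must be positive.
    censored
        Boolean mask marking censored entries.  When omitted, entries with
        ``value < loq`` are treated as censored.

    Notes
    -----
    The standard deviation is computed after the half-LOQ substitution
    (ddof=1), matching how campaign tables report mean ± sd over partially
    censored series.
    """
    if loq <= 0:
        raise ValueError("loq must be positive")
    vals = np.asarray(values, dtype=float)
    if vals.size == 0:
        raise ValueError("cannot summarize empty data")
    mask = vals < loq if censored is None else np.asarray(censored, dtype=bool)
    if mask.shape != vals.shape:
        raise ValueError("censored mask length must match values")
    filled = np.where(mask, loq / 2.0, vals)
    qf = 100.0 * (vals.size - int(mask.sum())) / vals.size
    sd = float(np.std(filled, ddof=1)) if vals.size > 1 else math.nan
    return CensoredSummary(
        mean=float(filled.mean()),
        sd=sd,
        min=float(filled.min()),
        max=float(filled.max()),
        quantification_frequency=qf,
        loq=loq,
        n=int(vals.size),
    )
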