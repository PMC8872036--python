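"""Synthetic enclosure, ambient, and balloon-profile data with planted truth.

Every downstream stage of the package (flux computation, standardization,
temperature-response fitting, ambient QC) is exercised against data
generated here, where the governing quantities are known exactly:

* Enclosure series obey the chamber mass balance
  ``C_out = C_in + ER_true·S/Q`` with the true emission following an
  exponential temperature response ``E(T) = E20·exp[a·(T − 20)]`` (times a
  light activity ratio when light dependence is enabled) and multiplicative
  lognormal measurement noise of a chosen coefficient of variation.
* Ambient series combine a background, a temperature-driven enhancement, a
  slow multiplicative detector-sensitivity drift mirrored in the CFC
  reference peak areas, below-LOQ censoring, and an optional
  wildfire-style event window with known enhancement factors.
* Vertical profiles decay with altitude from a surface maximum and carry
  per-flight blank values.

The diurnal forcing emulates a high-latitude midsummer: temperature peaks
mid-afternoon, and PAR follows the solar cycle but never reaches zero
(midnight sun), only a low nocturnal floor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .compounds import get_compound, mixing_ratio_to_carbon_conc
from .standardization import DEFAULT_CONSTANTS, cl_light

__all__ = [
    "GeneratorParams",
    "EnclosureScenario",
    "AmbientParams",
    "diurnal_temperature",
    "diurnal_par",
    "true_emission",
    "gen_enclosure_timeseries",
    "response_scenario",
    "gen_ambient_timeseries",
    "gen_profile_flights",
]

#: Campaign start for synthetic timestamps (local Alaska standard time,
#: UTC−9, during the midnight-sun period).
CAMPAIGN_START = "2019-06-15 00:00"
AST = "-09:00"

#: Fraction of peak PAR persisting through the midnight-sun night.
PAR_NIGHT_FLOOR = 0.02


@dataclass(frozen=True)
class GeneratorParams:
    """Physical truth and noise model for synthetic enclosure data.

    Defaults describe a willow-dominated tussock-tundra surface chamber:
    a basal isoprene emission ``e20`` at the 20 °C reference, exponential
    temperature coefficient ``a_true`` (per °C), a weak near-constant
    monoterpene source, lognormal multiplicative noise with coefficient of
    variation ``noise_cv``, a 25 L min⁻¹ purge flow through a 25 cm
    diameter chamber base, and a diurnal temperature cycle typical of an
    Arctic midsummer heat spell.
    """

    e20: float = 100.0             # μgC m⁻² h⁻¹ at 20 °C
    a_true: float = 0.1935         # °C⁻¹ exponential coefficient
    mt_e20: float = 0.5            # μgC m⁻² h⁻¹ monoterpene level at 20 °C
    beta_mt: float = 0.09          # °C⁻¹ monoterpene coefficient
    noise_cv: float = 0.15         # lognormal CV of the measured flux
    t_mean: float = 12.0           # °C diurnal mean temperature
    t_amplitude: float = 8.0       # °C diurnal half-range
    t_day_sd: float = 3.0          # °C day-to-day offset spread
    par_max: float = 1000.0        # μmol m⁻² s⁻¹ midday PAR
    q: float = 1500.0              # L h⁻¹ purge flow (25 L min⁻¹)
    s: float = 0.04909             # m² chamber footprint (25 cm diameter)
    c_in_background_pptv: float = 5.0
    enclosure_scale_sd: float = 0.5  # lognormal sigma of per-enclosure biomass scale
    light_dependence: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.e20 <= 0:
            raise ValueError("e20 must be positive")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")
        if self.q <= 0 or self.s <= 0:
            raise ValueError("q and s must be positive")


@dataclass(frozen=True)
class EnclosureScenario:
    """A simulated deployment of ``n_enclosures`` surface or branch chambers."""

    n_enclosures: int = 10
    vegetation_class: str = "salix"
    kind: str = "surface"
    duration_days: float = 5.0
    sampling_interval_h: float = 2.0
    params: GeneratorParams = field(default_factory=GeneratorParams)
    t_mode: str = "diurnal"        # "diurnal" | "uniform"
    t_range: tuple[float, float] = (2.0, 32.0)
    daytime_only: bool = False

    def __post_init__(self) -> None:
        if self.sampling_interval_h <= 0:
            raise ValueError("sampling_interval_h must be positive")
        if self.duration_days * 24 < self.sampling_interval_h:
            raise ValueError("duration must cover at least one sampling interval")
        if self.t_mode not in ("diurnal", "uniform"):
            raise ValueError("t_mode must be 'diurnal' or 'uniform'")
        if self.vegetation_class not in ("salix", "betula", "miscellaneous"):
            raise ValueError("vegetation_class must be salix, betula or miscellaneous")


def diurnal_temperature(hour_of_day, params: GeneratorParams):
    """Diurnal enclosure temperature (°C) peaking at 14:00 local time.

    Chamber air tracks solar radiation (greenhouse heating), so the peak
    sits at local solar noon (~14:00 AST) rather than the later free-air
    maximum.
    """
    h = np.asarray(hour_of_day, dtype=float)
    return params.t_mean + params.t_amplitude * np.sin(2 * np.pi * (h - 8.0) / 24.0)


def diurnal_par(hour_of_day, params: GeneratorParams):
    """PAR (μmol m⁻² s⁻¹) peaking at 14:00, with a midnight-sun floor.

    The solar cycle is a clipped sinusoid; the nocturnal floor reflects
    that the sun never sets, although low solar elevation keeps nighttime
    PAR very small.
    """
    h = np.asarray(hour_of_day, dtype=float)
    solar = np.sin(2 * np.pi * (h - 8.0) / 24.0)
    return params.par_max * np.maximum(solar, PAR_NIGHT_FLOOR)


def true_emission(t_c, par, params: GeneratorParams):
    """Planted isoprene emission (μgC m⁻² h⁻¹) at temperature/light.

    ``E20·exp[a·(T − 20)]`` modulated by the light activity ratio
    ``C_L(PAR)/C_L(1000)`` when light dependence is enabled (so PAR = 0
    yields zero emission), or purely temperature-driven otherwise.
    """
    t = np.asarray(t_c, dtype=float)
    e = params.e20 * np.exp(params.a_true * (t - 20.0))
    if params.light_dependence:
        p = np.asarray(par, dtype=float)
        if np.any(p < 0):
            raise ValueError("PAR must be non-negative")
        e = e * cl_light(p, DEFAULT_CONSTANTS) / cl_light(1000.0, DEFAULT_CONSTANTS)
    return e if e.shape else float(e)


def _lognormal_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative lognormal noise with unit mean and the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma2 = math.log(1.0 + cv * cv)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=math.sqrt(sigma2), size=size)


def _sample_times(scenario: EnclosureScenario) -> pd.DatetimeIndex:
    dt = scenario.sampling_interval_h
    n_days = int(math.ceil(scenario.duration_days))
    start = pd.Timestamp(f"{CAMPAIGN_START}{AST}")
    if scenario.daytime_only:
        # end-of-period stamps inside the 10:00–20:00 daytime window
        hours = np.arange(10.0 + dt / 2.0, 20.0, dt)
        stamps = [start + pd.Timedelta(days=d) + pd.Timedelta(hours=h)
                  for d in range(n_days) for h in hours]
    else:
        n = int(round(scenario.duration_days * 24.0 / dt))
        stamps = [start + pd.Timedelta(hours=dt * (i + 1)) for i in range(n)]
    return pd.DatetimeIndex(stamps)


def gen_enclosure_timeseries(scenario: EnclosureScenario) -> pd.DataFrame:
    """Simulate chamber records for every enclosure in *scenario*.

    Returns a long-format table with one row per (enclosure, time,
    compound) holding inlet/outlet concentrations (μgC L⁻¹) consistent
    with the mass balance ``C_out = C_in + ER·S/Q``, the driving
    temperature and PAR, and the planted truth in ``er_true`` for use as a
    test oracle.  Noise multiplies the emission term only, so with
    ``noise_cv = 0`` the flux equation recovers ``er_true`` exactly.
    """
    p = scenario.params
    rng = np.random.default_rng(p.seed)
    times = _sample_times(scenario)
    n_t = len(times)
    hours = times.hour.values + times.minute.values / 60.0
    day_index = ((times - times[0]).days).values

    iso = get_compound("isoprene")
    # inlet concentration: background mixing ratio → μgC L⁻¹
    c_in_base = mixing_ratio_to_carbon_conc(p.c_in_background_pptv, iso) / 1000.0

    # per-enclosure biomass/species scaling (what normalization removes)
    scales = np.exp(rng.normal(0.0, p.enclosure_scale_sd, scenario.n_enclosures)) \
        if p.enclosure_scale_sd > 0 else np.ones(scenario.n_enclosures)

    frames = []
    for i in range(scenario.n_enclosures):
        if scenario.t_mode == "uniform":
            # stratified (Latin-hypercube style) draw: marginally uniform on
            # t_range while guaranteeing every enclosure covers the 20 ± 1 °C
            # reference bin needed for normalization
            lo, hi = scenario.t_range
            strata = (rng.permutation(n_t) + rng.uniform(0.0, 1.0, n_t)) / n_t
            t_c = lo + (hi - lo) * strata
            par = np.full(n_t, 1000.0)  # near-saturating daytime light
        else:
            day_off = rng.normal(0.0, p.t_day_sd, int(day_index.max()) + 1)
            t_c = diurnal_temperature(hours, p) + day_off[day_index]
            par = diurnal_par(hours, p)

        er_iso = scales[i] * true_emission(t_c, par, p)
        er_mt = scales[i] * p.mt_e20 * np.exp(p.beta_mt * (t_c - 20.0))

        # branch chambers balance per dry mass (g) instead of footprint area
        m_dry = 5.0
        geom = p.s if scenario.kind == "surface" else m_dry
        for compound, er in (("isoprene", er_iso), ("alpha-pinene", er_mt)):
            eps = _lognormal_factor(rng, p.noise_cv, n_t)
            c_out = c_in_base + er * geom / p.q * eps
            frames.append(pd.DataFrame({
                "timestamp": times,
                "enclosure_id": f"enc{i + 1:02d}",
                "kind": scenario.kind,
                "vegetation_class": scenario.vegetation_class,
                "compound": compound,
                "c_in": c_in_base,
                "c_out": c_out,
                "q": p.q,
                "s": p.s if scenario.kind == "surface" else np.nan,
                "m_dry": m_dry if scenario.kind == "branch" else np.nan,
                "t_enclosure": t_c,
                "par": par,
                "er_true": er,
            }))
    return pd.concat(frames, ignore_index=True)


def response_scenario(
    n_enclosures: int = 10,
    samples_per_enclosure: int = 60,
    t_range: tuple[float, float] = (2.0, 32.0),
    noise_cv: float = 0.15,
    a_true: float = 0.1935,
    seed: int = 0,
) -> EnclosureScenario:
    """Scenario for the emission–temperature study.

    Daytime sampling with enclosure temperatures uniform over *t_range*
    and near-saturating light, so the planted response is the pure
    exponential ``exp[a_true·(T − 20)]``.
    """
    dt = 2.0
    per_day = len(np.arange(10.0 + dt / 2.0, 20.0, dt))
    days = math.ceil(samples_per_enclosure / per_day)
    params = GeneratorParams(a_true=a_true, noise_cv=noise_cv, seed=seed)
    return EnclosureScenario(
        n_enclosures=n_enclosures,
        duration_days=days,
        sampling_interval_h=dt,
        params=params,
        t_mode="uniform",
        t_range=t_range,
        daytime_only=True,
    )


@dataclass(frozen=True)
class AmbientParams:
    """Truth model for the synthetic ambient mixing-ratio series."""

    iso_background: float = 10.0   # pptv
    iso_amp: float = 25.0          # pptv scale of the temperature-driven term
    acn_level: float = 100.0       # pptv acetonitrile
    macr_level: float = 12.0       # pptv methacrolein
    mvk_macr_ratio: float = 2.7
    mt_level: float = 3.0          # pptv α-pinene (partially censored)
    noise_cv: float = 0.15
    loq: float = 2.0               # pptv
    drift_total: float = 0.2       # fractional sensitivity loss over campaign
    event_factors: dict | None = None   # default {"isoprene": 21, "acetonitrile": 4}
    cfc_base_area: float = 1e6     # detector response units
    seed: int = 0


def gen_ambient_timeseries(
    days: float = 30.0,
    interval_h: float = 2.0,
    params: AmbientParams | None = None,
    event: bool = False,
    event_day: int = 20,
) -> pd.DataFrame:
    """Simulate an ambient GC time series with drift, censoring and events.

    Returns a long table (timestamp, compound, value_pptv, censored,
    cfc11_area, cfc113_area, instrument) plus truth columns
    ``true_value_pptv`` and ``sens_factor``.  The detector sensitivity
    decays linearly by ``drift_total`` over the campaign and multiplies
    both the analyte responses and the CFC reference areas.  When *event*
    is set, one day is scaled by the planted enhancement factors
    (defaults: isoprene ×21, acetonitrile ×4).  ``df.attrs`` records the
    event and background windows.
    """
    p = params or AmbientParams()
    rng = np.random.default_rng(p.seed)
    n = int(round(days * 24.0 / interval_h))
    start = pd.Timestamp(f"{CAMPAIGN_START}{AST}")
    times = pd.DatetimeIndex([start + pd.Timedelta(hours=interval_h * i) for i in range(n)])
    hours = times.hour.values + times.minute.values / 60.0
    frac = np.arange(n) / max(n - 1, 1)
    sens = 1.0 - p.drift_total * frac

    gp = GeneratorParams(seed=p.seed)
    t_c = diurnal_temperature(hours, gp) + rng.normal(0, 2.0, n)

    truth = {
        "isoprene": p.iso_background + p.iso_amp * np.exp(0.1 * (t_c - 20.0)),
        "acetonitrile": np.full(n, p.acn_level),
        "methacrolein": np.full(n, p.macr_level),
        "mvk": np.full(n, p.macr_level * p.mvk_macr_ratio),
        "alpha-pinene": np.full(n, p.mt_level),
    }

    factors = p.event_factors or {"isoprene": 21.0, "acetonitrile": 4.0}
    event_mask = np.zeros(n, dtype=bool)
    if event:
        d0 = start + pd.Timedelta(days=event_day)
        d1 = d0 + pd.Timedelta(days=1)
        event_mask = (times >= d0) & (times < d1)
        for comp, f in factors.items():
            truth[comp] = np.where(event_mask, truth[comp] * f, truth[comp])

    cfc11 = p.cfc_base_area * sens * _lognormal_factor(rng, 0.01, n)
    cfc113 = 0.8 * p.cfc_base_area * sens * _lognormal_factor(rng, 0.01, n)

    frames = []
    for comp, tv in truth.items():
        measured = tv * sens * _lognormal_factor(rng, p.noise_cv, n)
        censored = measured < p.loq
        frames.append(pd.DataFrame({
            "timestamp": times,
            "compound": comp,
            "value_pptv": measured,
            "censored": censored,
            "cfc11_area": cfc11,
            "cfc113_area": cfc113,
            "instrument": "gc_ms_fid",
            "true_value_pptv": tv,
            "sens_factor": sens,
        }))
    df = pd.concat(frames, ignore_index=True)
    if event:
        df.attrs["event_window"] = (str(start + pd.Timedelta(days=event_day)),
                                    str(start + pd.Timedelta(days=event_day + 1)))
        df.attrs["background_window"] = (str(start),
                                         str(start + pd.Timedelta(days=event_day)))
    return df


def gen_profile_flights(
    n_flights: int = 8,
    altitudes: tuple[float, ...] = (0.0, 30.0, 100.0, 170.0, 240.0),
    surface_pptv: float = 50.0,
    scale_height_m: float = 150.0,
    blank_pptv: float = 5.0,
    noise_cv: float = 0.2,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate tethered-balloon vertical profiles of isoprene.

    Mixing ratios decay exponentially with altitude from a surface
    maximum (a surface-source profile); each flight carries a field-blank
    value.  Some high-altitude samples fall below the blank so that blank
    filtering has work to do.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for f in range(n_flights):
        surf = surface_pptv * _lognormal_factor(rng, 0.3, 1)[0]
        blank = blank_pptv * _lognormal_factor(rng, 0.2, 1)[0]
        for z in altitudes:
            tv = surf * math.exp(-z / scale_height_m)
            meas = tv * _lognormal_factor(rng, noise_cv, 1)[0]
            rows.append({
                "flight_id": f"flight{f + 1:02d}",
                "altitude_m": float(z),
                "value_pptv": meas,
                "blank_pptv": blank,
                "true_value_pptv": tv,
            })
    return pd.DataFrame(rows)
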