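"""Standardization of emission rates to reference temperature and light.

Isoprene emission depends on both leaf temperature and photosynthetically
active radiation (PAR).  Field emission rates are conventionally reported
at 30 °C and PAR = 1000 μmol m⁻² s⁻¹ using the classical leaf-level
activity factors

    C_L(PAR) = α·c_L1·PAR / sqrt(1 + α²·PAR²)
    C_T(T)   = exp[c_T1(T − T_s)/(R·T_s·T)] / (1 + exp[c_T2(T − T_M)/(R·T_s·T)])

with the canonical published constants (α = 0.0027, c_L1 = 1.066,
c_T1 = 95 000 J mol⁻¹, c_T2 = 230 000 J mol⁻¹, T_M = 314 K).  C_L rises
from 0 at darkness to an asymptote of c_L1; C_T is unimodal with an
optimum slightly above T_s.

Standardization here uses the *ratio* form

    ER_std = ER_obs · [C_T(T_std)·C_L(PAR_std)] / [C_T(T_obs)·C_L(PAR_obs)]

so that an observation already at standard conditions is returned
unchanged regardless of whether C_T(T_std) equals exactly one.
Monoterpene emission is treated as purely temperature-driven with an
exponential factor exp[β(T_std − T_obs)], β = 0.09 K⁻¹.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "StandardizationConstants",
    "cl_light",
    "ct_temperature",
    "isoprene_activity",
    "standardize_isoprene",
    "destandardize_isoprene",
    "standardize_monoterpene",
    "destandardize_monoterpene",
]

T_STANDARD_K = 303.15      # 30 °C reference temperature
PAR_STANDARD = 1000.0      # μmol m⁻² s⁻¹ reference light level


@dataclass(frozen=True)
class StandardizationConstants:
    """Constants of the leaf-level light/temperature activity algorithms."""

    alpha: float = 0.0027        # (μmol m⁻² s⁻¹)⁻¹
    c_l1: float = 1.066          # dimensionless
    c_t1: float = 95_000.0       # J mol⁻¹
    c_t2: float = 230_000.0      # J mol⁻¹
    t_m: float = 314.0           # K
    t_s: float = 303.15          # K
    r: float = 8.314             # J mol⁻¹ K⁻¹
    beta_mt: float = 0.09        # K⁻¹, monoterpene temperature coefficient

    def __post_init__(self) -> None:
        for field in ("alpha", "c_l1", "c_t1", "c_t2", "t_m", "t_s", "r"):
            if getattr(self, field) <= 0:
                raise ValueError(f"{field} must be positive")
        if self.t_m <= self.t_s:
            raise ValueError("t_m must exceed t_s")


DEFAULT_CONSTANTS = StandardizationConstants()


def cl_light(par, k: StandardizationConstants = DEFAULT_CONSTANTS):
    """Light activity factor C_L(PAR); 0 in darkness, → c_L1 as PAR → ∞."""
    p = np.asarray(par, dtype=float)
    if np.any(p < 0):
        raise ValueError("PAR must be non-negative")
    out = k.alpha * k.c_l1 * p / np.sqrt(1.0 + k.alpha ** 2 * p ** 2)
    return float(out) if np.isscalar(par) else out


def ct_temperature(temperature_k, k: StandardizationConstants = DEFAULT_CONSTANTS):
    """Temperature activity factor C_T(T), T in Kelvin."""
    t = np.asarray(temperature_k, dtype=float)
    if np.any(t <= 0):
        raise ValueError("temperature must be positive (Kelvin)")
    num = np.exp(k.c_t1 * (t - k.t_s) / (k.r * k.t_s * t))
    den = 1.0 + np.exp(k.c_t2 * (t - k.t_m) / (k.r * k.t_s * t))
    out = num / den
    return float(out) if np.isscalar(temperature_k) else out


def isoprene_activity(temperature_k, par, k: StandardizationConstants = DEFAULT_CONSTANTS):
    """Combined activity C_T(T)·C_L(PAR)."""
    return ct_temperature(temperature_k, k) * cl_light(par, k)


def _std_factor(temperature_k, par, k: StandardizationConstants,
                t_std: float, par_std: float):
    obs = isoprene_activity(temperature_k, par, k)
    if np.any(np.asarray(obs) == 0):
        raise ValueError("activity factor is zero at the observed conditions "
                         "(PAR = 0); standardization undefined")
    return isoprene_activity(t_std, par_std, k) / obs


def standardize_isoprene(
    value,
    temperature_k,
    par,
    k: StandardizationConstants = DEFAULT_CONSTANTS,
    t_std: float = T_STANDARD_K,
    par_std: float = PAR_STANDARD,
):
    """Project an observed isoprene emission rate to standard conditions.

    Parameters
    ----------
    value
        Observed emission rate (any flux unit; the factor is dimensionless).
    temperature_k, par
        Observed enclosure temperature (K) and PAR (μmol m⁻² s⁻¹); PAR
        must be positive, otherwise the ratio is undefined.
    """
    return value * _std_factor(temperature_k, par, k, t_std, par_std)


def destandardize_isoprene(
    value_std,
    temperature_k,
    par,
    k: StandardizationConstants = DEFAULT_CONSTANTS,
    t_std: float = T_STANDARD_K,
    par_std: float = PAR_STANDARD,
):
    """Inverse of :func:`standardize_isoprene` (round-trip identity)."""
    return value_std / _std_factor(temperature_k, par, k, t_std, par_std)


def standardize_monoterpene(
    value,
    temperature_k,
    k: StandardizationConstants = DEFAULT_CONSTANTS,
    t_std: float = T_STANDARD_K,
):
    """Project a monoterpene emission rate to the standard temperature.

    Monoterpene emission from storage pools responds exponentially to
    temperature: ER_std = ER_obs · exp[β(T_std − T_obs)].
    """
    t = np.asarray(temperature_k, dtype=float)
    return value * np.exp(k.beta_mt * (t_std - t))


def destandardize_monoterpene(
    value_std,
    temperature_k,
    k: StandardizationConstants = DEFAULT_CONSTANTS,
    t_std: float = T_STANDARD_K,
):
    """Inverse of :func:`standardize_monoterpene`."""
    t = np.asarray(temperature_k, dtype=float)
    return value_std * np.exp(k.beta_mt * (t - t_std))
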