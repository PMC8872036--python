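"""MEGAN2.1 temperature-only isoprene emission prediction.

The temperature activity factor γ_T describes how isoprene emission
responds to the current air temperature T and the mean air temperature
over the preceding 10 days, T10 (both Kelvin):

    T_opt = 313 + 0.6·(T10 − 297)
    E_opt = 2·exp[0.08·(T10 − 297)]
    x     = (1/T_opt − 1/T) / 0.00831
    γ_T   = E_opt · 200·e^{95x} / (200 − 95·(1 − e^{200x}))

γ_T is unimodal in T with its maximum E_opt attained exactly at T = T_opt
(x = 0).  The 0.00831 is the molar gas constant in kJ mol⁻¹ K⁻¹, and 95 /
200 are the activation-energy-like coefficients CT1 / CT2 of the
temperature response.  The predicted areal flux is

    F_T = C_CE · γ_T · Σ_j κ_j ε_j

where Σ κ_j ε_j is the landscape-weighted standard-condition emission
factor (2766 μg m⁻² h⁻¹ for the tussock-tundra site modeled here) and the
canopy environment coefficient C_CE is calibrated so that the product
C_CE·γ_T equals one at standard conditions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "MeganTempInputs",
    "MeganConfig",
    "MeganIntermediates",
    "t_opt",
    "e_opt",
    "gamma_t",
    "calibrate_cce",
    "f_t",
    "warming_ratio_megan",
    "gamma_table",
]

#: Valid Kelvin range for the empirical response curve.
T_VALID = (200.0, 330.0)

# Coefficients of the γ_T closed form.
_CT1 = 95.0
_CT2 = 200.0
_RK = 0.00831  # kJ mol⁻¹ K⁻¹

#: Default standard conditions used for the C_CE calibration (MEGAN2.1
#: convention: T = 303 K, 10-day mean = 297 K).
T_STANDARD_MEGAN = 303.0
T10_STANDARD_MEGAN = 297.0


class UncalibratedError(RuntimeError):
    """Raised when F_T is requested before the C_CE calibration."""


@dataclass(frozen=True)
class MeganTempInputs:
    """Current (t) and trailing 10-day mean (t10) air temperature, Kelvin."""

    t: float
    t10: float

    def __post_init__(self) -> None:
        for name, val in (("t", self.t), ("t10", self.t10)):
            if not (T_VALID[0] < val < T_VALID[1]):
                raise ValueError(
                    f"{name}={val} K outside the valid range {T_VALID}")


@dataclass(frozen=True)
class MeganConfig:
    """Configuration of the areal-flux prediction F_T.

    ``sum_kappa_eps`` is the coverage-weighted sum of standard-condition
    emission factors over the vegetation types in the grid cell
    (μg m⁻² h⁻¹); ``c_ce`` is None until :func:`calibrate_cce` sets it.
    """

    sum_kappa_eps: float = 2766.0
    c_ce: float | None = None
    t_standard: float = T_STANDARD_MEGAN
    t10_standard: float = T10_STANDARD_MEGAN

    def __post_init__(self) -> None:
        if self.sum_kappa_eps <= 0:
            raise ValueError("sum_kappa_eps must be positive")
        if self.c_ce is not None and self.c_ce <= 0:
            raise ValueError("c_ce must be positive")


@dataclass(frozen=True)
class MeganIntermediates:
    """γ_T together with the intermediates of its evaluation."""

    x: float
    e_opt: float
    t_opt: float
    gamma_t: float


def t_opt(t10_k: float) -> float:
    """Optimum temperature (K) of the activity curve for a given T10."""
    return 313.0 + 0.6 * (t10_k - 297.0)


def e_opt(t10_k: float) -> float:
    """Maximum activity value for a given T10."""
    return 2.0 * math.exp(0.08 * (t10_k - 297.0))


def _gamma_scalar(t: float, t10: float) -> MeganIntermediates:
    topt = t_opt(t10)
    eopt = e_opt(t10)
    x = (1.0 / topt - 1.0 / t) / _RK
    # Guard the exponentials: for t far below t_opt, x → -∞ and γ → 0;
    # far above, e^{200x} dominates and γ → 0 from the denominator growth.
    a1 = _CT1 * x
    a2 = _CT2 * x
    if a1 < -700.0:
        gamma = 0.0
    elif a2 > 700.0:
        gamma = 0.0
    else:
        num = _CT2 * math.exp(a1)
        den = _CT2 - _CT1 * (1.0 - math.exp(a2))
        gamma = eopt * num / den
    return MeganIntermediates(x=x, e_opt=eopt, t_opt=topt, gamma_t=gamma)


def gamma_t(inputs: MeganTempInputs | None = None, *, t: float | None = None,
            t10: float | None = None) -> MeganIntermediates:
    """Evaluate the temperature activity factor γ_T.

    Either pass a :class:`MeganTempInputs` or the keyword pair ``t`` /
    ``t10`` (Kelvin).  Returns the full set of intermediates.
    """
    if inputs is None:
        if t is None or t10 is None:
            raise TypeError("provide MeganTempInputs or both t and t10")
        inputs = MeganTempInputs(t=t, t10=t10)
    return _gamma_scalar(inputs.t, inputs.t10)


def calibrate_cce(config: MeganConfig) -> MeganConfig:
    """Return a copy of *config* with C_CE set so γ-scaled standard flux is unity.

    C_CE = 1 / γ_T(T_standard, T10_standard); with this choice
    C_CE·γ_T(standard) = 1 exactly and F_T at standard conditions equals
    Σ κ_j ε_j.
    """
    g = _gamma_scalar(config.t_standard, config.t10_standard).gamma_t
    if g <= 0:
        raise ValueError("gamma_t vanishes at the requested standard "
                         "conditions; cannot calibrate C_CE")
    return replace(config, c_ce=1.0 / g)


def f_t(inputs: MeganTempInputs, config: MeganConfig) -> float:
    """Predicted areal isoprene flux F_T = C_CE·γ_T·Σκε (μg m⁻² h⁻¹)."""
    if config.c_ce is None:
        raise UncalibratedError(
            "MeganConfig.c_ce is unset; call calibrate_cce first")
    return config.c_ce * gamma_t(inputs).gamma_t * config.sum_kappa_eps


def warming_ratio_megan(
    t_base_k: float,
    delta_c: float,
    t10_k: float,
    t10_policy: str = "tracking",
) -> float:
    """Emission under warming as a percentage of the baseline emission.

    Evaluates 100·γ_T(T+Δ, T10′)/γ_T(T, T10) where the 10-day mean either
    warms with the scenario (``t10_policy="tracking"``, T10′ = T10 + Δ) or
    is held fixed (``"fixed"``).  C_CE and Σκε cancel in the ratio.
    """
    if delta_c < 0:
        raise ValueError("delta_c must be non-negative")
    if t10_policy not in ("tracking", "fixed"):
        raise ValueError("t10_policy must be 'tracking' or 'fixed'")
    t10_new = t10_k + delta_c if t10_policy == "tracking" else t10_k
    base = _gamma_scalar(t_base_k, t10_k).gamma_t
    if base <= 0:
        raise ValueError("baseline gamma_t is zero; ratio undefined")
    return 100.0 * _gamma_scalar(t_base_k + delta_c, t10_new).gamma_t / base


def gamma_table(t_grid_k, t10_k: float):
    """γ_T over a temperature grid for fixed T10, as a pandas DataFrame."""
    import pandas as pd

    rows = [_gamma_scalar(float(t), t10_k) for t in np.asarray(t_grid_k, dtype=float)]
    return pd.DataFrame({
        "t_k": np.asarray(t_grid_k, dtype=float),
        "t10_k": t10_k,
        "gamma_t": [r.gamma_t for r in rows],
        "x": [r.x for r in rows],
    })
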