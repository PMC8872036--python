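"""Emission–temperature response: normalization, binning, exponential fit.

Surface enclosures differ in enclosed biomass and species mix, so their
absolute emission rates are not comparable.  Each enclosure's fluxes are
therefore divided by that enclosure's own mean emission in the 20 ± 1 °C
reference bin — 20 °C rather than the conventional 30 °C because of the
cold growth environment — which places all enclosures on a common
dimensionless scale with value 1 at the reference temperature.

The pooled normalized emissions are then fit with a single exponential,

    E_norm(T) = exp[â·(T − 20)],

by ordinary least squares of ln(E_norm) on (T − 20).  The warming response
is reported as the percentage of the baseline emission after a Δ°C
warming, 100·exp(â·Δ) — an exponential makes this independent of the
baseline temperature.  Temperature bins (default width 2 °C, half-open
[center−1, center+1)) are used for display counts only; the fit uses the
raw normalized records.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .megan import gamma_t

__all__ = [
    "TemperatureResponseFit",
    "daytime_mask",
    "normalize_by_reference",
    "bin_by_temperature",
    "fit_exponential",
    "warming_percent",
    "compare_to_megan",
]

logger = logging.getLogger(__name__)

REFERENCE_T_C = 20.0
REFERENCE_HALF_WIDTH = 1.0
DAYTIME_WINDOW = (10, 20)  # local hours, [start, end)


@dataclass(frozen=True)
class TemperatureResponseFit:
    """Exponential temperature-response fit of normalized emissions."""

    a_hat: float               # °C⁻¹
    ci95: tuple[float, float]
    intercept: float           # ln-space intercept, diagnostic (≈ 0)
    r_squared: float
    n_used: int
    n_excluded_nonpositive: int
    bin_width: float
    n_per_bin: pd.Series       # display counts, indexed by bin center

    def __post_init__(self) -> None:
        if not (self.ci95[0] <= self.a_hat <= self.ci95[1]):
            raise ValueError("confidence interval must contain the estimate")


def daytime_mask(timestamps: pd.Series, window: tuple[int, int] = DAYTIME_WINDOW) -> pd.Series:
    """True for records whose local hour lies in [start, end)."""
    hours = pd.DatetimeIndex(timestamps).hour
    return pd.Series((hours >= window[0]) & (hours < window[1]),
                     index=timestamps.index)


def normalize_by_reference(
    rates: pd.DataFrame,
    reference_t: float = REFERENCE_T_C,
    half_width: float = REFERENCE_HALF_WIDTH,
) -> pd.DataFrame:
    """Normalize each enclosure by its mean emission in the reference bin.

    Parameters
    ----------
    rates
        Emission-rate table with columns ``enclosure_id, t_enclosure,
        value`` (other columns pass through).
    reference_t, half_width
        The reference bin is ``[reference_t − half_width,
        reference_t + half_width)``.

    Returns the input rows for enclosures whose reference-bin mean is
    positive, with a ``value_norm`` column; enclosures without positive
    reference coverage are dropped with a logged warning.  By construction
    the per-enclosure mean of ``value_norm`` inside the reference bin is
    exactly 1.
    """
    lo, hi = reference_t - half_width, reference_t + half_width
    out_frames = []
    for enc_id, grp in rates.groupby("enclosure_id", sort=False):
        in_ref = (grp["t_enclosure"] >= lo) & (grp["t_enclosure"] < hi)
        if not in_ref.any():
            logger.warning("enclosure %s dropped: no records in the %.0f±%.0f °C "
                           "reference bin", enc_id, reference_t, half_width)
            continue
        ref_mean = grp.loc[in_ref, "value"].mean()
        if ref_mean <= 0:
            logger.warning("enclosure %s dropped: non-positive reference mean %.3g",
                           enc_id, ref_mean)
            continue
        g = grp.copy()
        g["value_norm"] = g["value"] / ref_mean
        out_frames.append(g)
    if not out_frames:
        raise ValueError("no enclosure has positive reference-bin coverage")
    return pd.concat(out_frames, ignore_index=True)


def bin_by_temperature(
    normalized: pd.DataFrame,
    bin_width: float = 2.0,
    value_col: str = "value_norm",
) -> pd.DataFrame:
    """Per-bin mean, sd and count of normalized emissions.

    Bins are half-open intervals ``[center − w/2, center + w/2)`` centered
    on integer multiples of the bin width.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if normalized.empty:
        return pd.DataFrame(columns=["bin_center", "mean", "sd", "n"])
    # floor(x/w + 1/2) keeps the bins half-open: [center − w/2, center + w/2)
    centers = np.floor(normalized["t_enclosure"] / bin_width + 0.5) * bin_width
    g = normalized.groupby(centers)[value_col]
    out = pd.DataFrame({"mean": g.mean(), "sd": g.std(), "n": g.size()})
    out.index.name = "bin_center"
    return out.reset_index()


def fit_exponential(
    normalized: pd.DataFrame,
    daytime_only: bool = True,
    reference_t: float = REFERENCE_T_C,
    bin_width: float = 2.0,
    min_records: int = 10,
) -> TemperatureResponseFit:
    """Least-squares exponential fit of normalized emission vs temperature.

    Regresses ``ln(value_norm)`` on ``(T − reference_t)``; non-positive
    normalized values cannot enter the log fit and are excluded with their
    count reported.  When *daytime_only* is set, records outside the
    10:00–20:00 local window are excluded first (isoprene emission at
    night is light-limited and would bias a temperature-only fit).
    """
    df = normalized
    if daytime_only and "timestamp" in df.columns:
        df = df[daytime_mask(df["timestamp"]).values]
    positive = df["value_norm"] > 0
    n_excl = int((~positive).sum())
    df = df[positive]
    if len(df) < min_records:
        raise ValueError(f"only {len(df)} positive records; need ≥ {min_records}")

    x = df["t_enclosure"].to_numpy(dtype=float) - reference_t
    y = np.log(df["value_norm"].to_numpy(dtype=float))
    res = sm.OLS(y, sm.add_constant(x)).fit()
    ci = res.conf_int(alpha=0.05)
    # constant y has zero total sum of squares; the (perfect) fit gets r² = 1
    r2 = float(res.rsquared) if res.centered_tss > 0 else 1.0
    counts = bin_by_temperature(df, bin_width=bin_width).set_index("bin_center")["n"]
    return TemperatureResponseFit(
        a_hat=float(res.params[1]),
        ci95=(float(ci[1, 0]), float(ci[1, 1])),
        intercept=float(res.params[0]),
        r_squared=r2,
        n_used=int(len(df)),
        n_excluded_nonpositive=n_excl,
        bin_width=bin_width,
        n_per_bin=counts,
    )


def warming_percent(fit: TemperatureResponseFit, delta_c: float) -> float:
    """Emission after Δ°C warming as a percentage of baseline: 100·exp(â·Δ)."""
    if delta_c < 0:
        raise ValueError("delta_c must be non-negative")
    return 100.0 * float(np.exp(fit.a_hat * delta_c))


def compare_to_megan(
    fit: TemperatureResponseFit,
    t10_k: float = 284.15,
    t_grid_c: np.ndarray | None = None,
    reference_t: float = REFERENCE_T_C,
) -> pd.DataFrame:
    """Observed exponential fit vs the MEGAN2.1 γ_T curve on a shared scale.

    Both curves are normalized to 1 at the reference temperature so they
    can be overlaid; the default 10-day mean temperature (284.15 K ≈ 11 °C)
    is an Arctic midsummer value.  The output is a table — the comparison
    is visual/tabular, no closeness statistic is asserted.
    """
    if t_grid_c is None:
        t_grid_c = np.arange(0.0, 40.0 + 1e-9, 1.0)
    t_grid_c = np.asarray(t_grid_c, dtype=float)
    obs = np.exp(fit.a_hat * (t_grid_c - reference_t))
    g_ref = gamma_t(t=reference_t + 273.15, t10=t10_k).gamma_t
    if g_ref <= 0:
        raise ValueError("MEGAN gamma is zero at the reference temperature")
    meg = np.array([gamma_t(t=tc + 273.15, t10=t10_k).gamma_t for tc in t_grid_c]) / g_ref
    return pd.DataFrame({
        "t_c": t_grid_c,
        "observed_fit_norm": obs,
        "megan_gamma_norm": meg,
    })
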