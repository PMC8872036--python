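"""Ambient mixing-ratio series: drift correction, aggregation, QC.

Long-running chromatographic systems lose sensitivity (detector drift,
adsorbent aging).  Long-lived chlorofluorocarbons (CFC-11, CFC-113) are
essentially constant in ambient air over a campaign, so their peak areas
track instrument sensitivity; dividing analyte responses by the smoothed,
normalized CFC areas removes the drift.

The remaining operations are campaign summaries: mean diurnal cycles,
local-time window means (daytime 10:00–20:00, midday 11:00–14:00,
nighttime 23:00–05:00, Alaska standard time UTC−9), two-instrument
intercomparison, event enhancement ratios, oxidation-product ratios, and
blank filtering of balloon vertical profiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

__all__ = [
    "DEFAULT_WINDOWS",
    "drift_correct",
    "diurnal_cycle",
    "window_means",
    "intercompare",
    "enhancement_ratio",
    "ratio_mean",
    "profile_filter",
]

logger = logging.getLogger(__name__)

#: Local-time aggregation windows, [start, end) hours; nighttime wraps
#: midnight.
DEFAULT_WINDOWS = {
    "daytime": (10, 20),
    "midday": (11, 14),
    "nighttime": (23, 5),
}


def _hour_in_window(hours: np.ndarray, window: tuple[int, int]) -> np.ndarray:
    start, end = window
    if start <= end:
        return (hours >= start) & (hours < end)
    return (hours >= start) | (hours < end)  # wraps midnight


def drift_correct(
    samples: pd.DataFrame,
    value_col: str = "value_pptv",
    smoothing_window: str = "24h",
) -> pd.DataFrame:
    """Correct analyte responses for detector sensitivity drift.

    The per-sample sensitivity proxy is the geometric mean of the CFC-11
    and CFC-113 peak areas, each normalized by its campaign median (both
    tracers are used with equal weight since neither takes precedence).
    The proxy is smoothed with a running median (default 24 h) and each
    analyte value is multiplied by its reciprocal.  Samples with a
    non-positive CFC area are flagged ``drift_uncorrectable`` and returned
    unchanged.

    Returns a copy with ``value_corrected`` and ``drift_factor`` columns.
    Applying the correction twice is idempotent up to the smoothing of an
    already-flat proxy.
    """
    for col in ("cfc11_area", "cfc113_area"):
        if col not in samples.columns:
            raise ValueError(f"missing column {col}")
    df = samples.reset_index(drop=True).copy()
    ok = (df["cfc11_area"] > 0) & (df["cfc113_area"] > 0)
    if not ok.all():
        logger.warning("%d samples with non-positive CFC areas left uncorrected",
                       int((~ok).sum()))

    # one proxy value per timestamp (areas repeat across compounds)
    per_time = (df.loc[ok, ["timestamp", "cfc11_area", "cfc113_area"]]
                  .drop_duplicates("timestamp")
                  .sort_values("timestamp"))
    n11 = per_time["cfc11_area"] / per_time["cfc11_area"].median()
    n113 = per_time["cfc113_area"] / per_time["cfc113_area"].median()
    proxy = np.sqrt(n11.to_numpy() * n113.to_numpy())
    smoothed = (pd.Series(proxy, index=pd.DatetimeIndex(per_time["timestamp"]))
                .rolling(smoothing_window, center=True, min_periods=1)
                .median())
    factors = pd.DataFrame({"timestamp": per_time["timestamp"].to_numpy(),
                            "drift_factor": 1.0 / smoothed.to_numpy()})
    df = df.merge(factors, on="timestamp", how="left")  # preserves row order
    df["drift_factor"] = df["drift_factor"].where(
        ok.to_numpy() & df["drift_factor"].notna().to_numpy(), 1.0)
    df["value_corrected"] = df[value_col] * df["drift_factor"]
    df["drift_uncorrectable"] = ~ok
    return df


def diurnal_cycle(
    samples: pd.DataFrame,
    value_col: str = "value_pptv",
) -> pd.DataFrame:
    """Mean, sd and count of *value_col* per local hour of day (0–23).

    The count-weighted mean of the hourly means equals the overall mean
    exactly (the hours partition the data).
    """
    hours = pd.DatetimeIndex(samples["timestamp"]).hour
    g = samples.groupby(hours)[value_col]
    out = pd.DataFrame({"mean": g.mean(), "sd": g.std(), "n": g.size()})
    out.index.name = "hour"
    return out.reset_index()


def window_means(
    rates: pd.DataFrame,
    value_col: str = "value",
    windows: dict[str, tuple[int, int]] | None = None,
    group_cols: tuple[str, ...] = (),
    temperature_col: str | None = "t_enclosure",
) -> pd.DataFrame:
    """Per-window mean ± sd (and mean temperature) of a timed series.

    Windows are local-time hour intervals ``[start, end)``; an interval
    with start > end wraps midnight (nighttime).  ``group_cols`` (e.g.
    vegetation class, compound) produce one row per group and window;
    windows with no data are reported with NaN values.
    """
    wins = windows or DEFAULT_WINDOWS
    hours = pd.DatetimeIndex(rates["timestamp"]).hour.to_numpy()
    if temperature_col is not None and temperature_col not in rates.columns:
        temperature_col = None

    groups = ([((), rates)] if not group_cols
              else [(k if isinstance(k, tuple) else (k,), g)
                    for k, g in rates.groupby(list(group_cols), sort=False)])
    rows = []
    for key, grp in groups:
        grp_hours = pd.DatetimeIndex(grp["timestamp"]).hour.to_numpy()
        for name, win in wins.items():
            sel = grp[_hour_in_window(grp_hours, win)]
            row = dict(zip(group_cols, key))
            row.update({
                "window": name,
                "mean": sel[value_col].mean() if len(sel) else np.nan,
                "sd": sel[value_col].std() if len(sel) > 1 else np.nan,
                "n": len(sel),
            })
            if temperature_col is not None:
                row["t_mean"] = sel[temperature_col].mean() if len(sel) else np.nan
            rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class IntercompareResult:
    slope: float
    intercept: float
    pearson_r: float
    n_pairs: int


def intercompare(
    series_a: pd.DataFrame,
    series_b: pd.DataFrame,
    value_col: str = "value_pptv",
    tolerance: str = "15min",
) -> IntercompareResult:
    """Pair two instruments' series in time and regress one on the other.

    Samples are matched nearest-neighbor within *tolerance*; ordinary
    least squares of B on A plus the Pearson correlation are returned.
    """
    a = series_a[["timestamp", value_col]].sort_values("timestamp")
    b = series_b[["timestamp", value_col]].sort_values("timestamp")
    paired = pd.merge_asof(a, b, on="timestamp", tolerance=pd.Timedelta(tolerance),
                           direction="nearest", suffixes=("_a", "_b")).dropna()
    if len(paired) < 3:
        raise ValueError(f"only {len(paired)} time-matched pairs; need ≥ 3")
    x = paired[f"{value_col}_a"].to_numpy(dtype=float)
    y = paired[f"{value_col}_b"].to_numpy(dtype=float)
    res = scipy.stats.linregress(x, y)
    return IntercompareResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        pearson_r=float(scipy.stats.pearsonr(x, y).statistic),
        n_pairs=int(len(paired)),
    )


def enhancement_ratio(
    samples: pd.DataFrame,
    event_window: tuple,
    background_window: tuple,
    value_col: str = "value_pptv",
) -> float:
    """Mean mixing ratio in an event window over the background-window mean.

    Windows are (start, end) timestamp pairs, half-open on the right, and
    must not overlap.
    """
    e0, e1 = pd.Timestamp(event_window[0]), pd.Timestamp(event_window[1])
    b0, b1 = pd.Timestamp(background_window[0]), pd.Timestamp(background_window[1])
    if max(e0, b0) < min(e1, b1):
        raise ValueError("event and background windows overlap")
    ts = pd.DatetimeIndex(samples["timestamp"])
    ev = samples.loc[(ts >= e0) & (ts < e1), value_col]
    bg = samples.loc[(ts >= b0) & (ts < b1), value_col]
    if ev.empty or bg.empty:
        raise ValueError("event and background windows must both be nonempty")
    bg_mean = bg.mean()
    if bg_mean <= 0:
        raise ValueError("background mean is non-positive; ratio undefined")
    return float(ev.mean() / bg_mean)


def ratio_mean(
    samples: pd.DataFrame,
    compound_x: str,
    compound_y: str,
    threshold: float = 2.0,
    value_col: str = "value_pptv",
) -> tuple[float, int]:
    """Mean per-sample ratio x/y over pairs with both compounds quantified.

    Samples of the two compounds are paired on exact timestamps; pairs
    where either value is below *threshold* (the LOQ) are excluded.
    Returns (mean ratio, number of qualifying pairs).
    """
    x = samples[samples["compound"] == compound_x][["timestamp", value_col]]
    y = samples[samples["compound"] == compound_y][["timestamp", value_col]]
    paired = x.merge(y, on="timestamp", suffixes=("_x", "_y"))
    q = paired[(paired[f"{value_col}_x"] >= threshold)
               & (paired[f"{value_col}_y"] >= threshold)]
    if q.empty:
        raise ValueError("no pairs with both compounds above the threshold")
    ratios = q[f"{value_col}_x"] / q[f"{value_col}_y"]
    return float(ratios.mean()), int(len(q))


def profile_filter(profiles: pd.DataFrame) -> pd.DataFrame:
    """Drop profile samples whose mixing ratio is below the flight blank.

    Samples equal to the blank are retained (strict ``<``); the number of
    discarded samples is logged.
    """
    keep = profiles["value_pptv"] >= profiles["blank_pptv"]
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("profile_filter: discarded %d of %d samples below blank",
                    n_drop, len(profiles))
    return profiles[keep].reset_index(drop=True)
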