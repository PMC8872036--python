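"""CSV schemas binding the pipeline stages together.

All tables are UTF-8 CSV with a header row; timestamps are ISO-8601 local
time with an explicit UTC offset (Alaska standard time, −09:00); missing
values are empty cells; censored mixing ratios are marked by the string
``<LOQ`` in a dedicated flag column, never by sentinel numbers.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "read_enclosure_csv",
    "write_enclosure_csv",
    "read_rates_csv",
    "write_rates_csv",
    "read_ambient_csv",
    "write_ambient_csv",
    "read_profile_csv",
]

ENCLOSURE_COLUMNS = ["timestamp", "enclosure_id", "kind", "vegetation_class",
                     "compound", "c_in", "c_out", "q", "s", "m_dry",
                     "t_enclosure", "par"]
AMBIENT_COLUMNS = ["timestamp", "compound", "value_pptv", "loq_flag",
                   "cfc11_area", "cfc113_area", "instrument"]
PROFILE_COLUMNS = ["flight_id", "altitude_m", "value_pptv", "blank_pptv"]


class SchemaError(ValueError):
    """A CSV is missing required columns."""


def _require(df: pd.DataFrame, columns, what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} CSV missing column(s): {missing}")


def _parse_times(df: pd.DataFrame) -> pd.DataFrame:
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    return df


def read_enclosure_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, [c for c in ENCLOSURE_COLUMNS if c not in ("s", "m_dry")],
             "enclosure")
    for opt in ("s", "m_dry"):
        if opt not in df.columns:
            df[opt] = float("nan")
    return _parse_times(df)


def write_enclosure_csv(df: pd.DataFrame, path) -> None:
    cols = [c for c in ENCLOSURE_COLUMNS if c in df.columns]
    extra = [c for c in df.columns if c not in cols]
    df[cols + extra].to_csv(path, index=False)


def read_rates_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, ["timestamp", "enclosure_id", "compound", "value", "basis",
                  "t_enclosure", "par"], "emission-rate")
    if "qc_flags" in df.columns:
        df["qc_flags"] = df["qc_flags"].fillna("")
    return _parse_times(df)


def write_rates_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_ambient_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, ["timestamp", "compound", "value_pptv"], "ambient")
    df["censored"] = (df["loq_flag"].fillna("") == "<LOQ") \
        if "loq_flag" in df.columns else False
    return _parse_times(df.drop(columns=["loq_flag"], errors="ignore"))


def write_ambient_csv(df: pd.DataFrame, path) -> None:
    out = df.copy()
    if "censored" in out.columns:
        out["loq_flag"] = out["censored"].map({True: "<LOQ", False: ""})
        out = out.drop(columns=["censored"])
    cols = [c for c in AMBIENT_COLUMNS if c in out.columns]
    extra = [c for c in out.columns if c not in cols]
    out[cols + extra].to_csv(path, index=False)


def read_profile_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, PROFILE_COLUMNS, "profile")
    return df
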