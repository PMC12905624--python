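"""CSV dialects and writers.

All files are comma-separated UTF-8 with dot decimals and ISO-8601
timezone-naive timestamps (CGM and EMA share the device clock; regional
decimal commas of vendor exports are out of scope and must be converted
first).

* ``cgm.csv`` — participant_id, timestamp, glucose_mg_dl, sensor_id
* ``ema.csv`` — participant_id, timestamp, happy, sad, hunger, satiety
* ``participants.csv`` — participant_id, sex, age, bmi,
  fasting_glucose_1..3, fasting_insulin_1..3, triglycerides_1..3
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "read_cgm_csv", "read_ema_csv", "read_participants_csv",
    "write_cgm_csv", "write_ema_csv", "write_participants_csv",
    "write_ground_truth_json",
]

_CGM_COLUMNS = ["participant_id", "timestamp", "glucose_mg_dl", "sensor_id"]
_EMA_COLUMNS = ["participant_id", "timestamp", "happy", "sad",
                "hunger", "satiety"]


def _parse_timestamps(raw: pd.Series, path) -> pd.Series:
    ts = pd.to_datetime(raw, format="ISO8601", errors="coerce")
    if ts.isna().any():
        row = int(ts.index[ts.isna()][0]) + 2  # header + 1-based
        raise ValueError(f"{path}: malformed timestamp at row {row}")
    return ts


def _parse_numeric(raw: pd.Series, name: str, path,
                   positive: bool = False) -> pd.Series:
    vals = pd.to_numeric(raw, errors="coerce")
    bad = vals.isna() & raw.notna()
    if bad.any():
        row = int(bad.index[bad][0]) + 2
        raise ValueError(f"{path}: non-numeric {name} at row {row}")
    if positive:
        neg = vals <= 0
        if neg.any():
            row = int(neg.index[neg][0]) + 2
            raise ValueError(f"{path}: non-positive {name} at row {row}")
    return vals


def read_cgm_csv(path) -> pd.DataFrame:
    """Read a CGM export; sorts per participant and collapses duplicate
    (participant, sensor, timestamp) rows to their mean with a warning."""
    df = pd.read_csv(path)
    missing = set(_CGM_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    df["timestamp"] = _parse_timestamps(df["timestamp"], path)
    df["glucose_mg_dl"] = _parse_numeric(df["glucose_mg_dl"],
                                         "glucose", path, positive=True)
    n0 = len(df)
    df = (df.groupby(["participant_id", "sensor_id", "timestamp"],
                     as_index=False)["glucose_mg_dl"].mean())
    if len(df) < n0:
        warnings.warn(f"{path}: collapsed {n0 - len(df)} duplicate "
                      "timestamp rows to their mean", stacklevel=2)
    return (df[_CGM_COLUMNS]
            .sort_values(["participant_id", "timestamp"])
            .reset_index(drop=True))


def read_ema_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(_EMA_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    df["timestamp"] = _parse_timestamps(df["timestamp"], path)
    for col in ("happy", "sad", "hunger", "satiety"):
        df[col] = _parse_numeric(df[col], col, path)
    return (df.sort_values(["participant_id", "timestamp"])
            .reset_index(drop=True))


def read_participants_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "participant_id" not in df.columns:
        raise ValueError(f"{path}: missing participant_id column")
    for col in df.columns:
        if col.startswith(("fasting_", "triglycerides_")) or col in ("age", "bmi"):
            df[col] = _parse_numeric(df[col], col, path)
    return df


def _write(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, date_format="%Y-%m-%dT%H:%M:%S")
    return path


def write_cgm_csv(df: pd.DataFrame, path) -> Path:
    return _write(df[_CGM_COLUMNS], path)


def write_ema_csv(df: pd.DataFrame, path) -> Path:
    return _write(df[_EMA_COLUMNS], path)


def write_participants_csv(df: pd.DataFrame, path) -> Path:
    return _write(df, path)


def write_ground_truth_json(truth, path) -> Path:
    """JSON sidecar with the generator's oracle quantities (no traces)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "a": {k: float(v) for k, v in truth.a.items()},
        "b": float(truth.b),
        "c_prime": float(truth.c_prime),
        "acme": truth.acme,
        "ade": truth.ade,
        "total": truth.total,
        "basal": {k: float(v) for k, v in truth.basal.items()},
    }
    path.write_text(json.dumps(payload, indent=1, sort_keys=True))
    return path
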