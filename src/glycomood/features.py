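"""Composite affect/metabolic scores and standardised model inputs.

Mood state = happy − sad and metabolic state = hunger − satiety are bipolar
composites on −100…100 (positive mood state = happier; positive metabolic
state = hungrier). Matched glucose is ln-transformed (right-skewed) and all
continuous predictors are z-standardised across all observations (grand
moments, not within person) so fixed effects are comparable across scales.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["compute_composites", "transform_glucose", "z_standardise",
           "build_aligned_table"]


def _check_vas(values, name: str) -> None:
    arr = np.asarray(values, dtype=float)
    finite = arr[np.isfinite(arr)]
    if finite.size and (finite.min() < 0 or finite.max() > 100):
        raise ValueError(f"{name} ratings must lie in [0, 100]")


def compute_composites(records: pd.DataFrame) -> pd.DataFrame:
    """Add ``mood_state`` (happy − sad) and ``metabolic_state``
    (hunger − satiety) columns; a missing item yields a missing composite."""
    for col in ("happy", "sad", "hunger", "satiety"):
        if col in records.columns:
            _check_vas(records[col], col)
    out = records.copy()
    out["mood_state"] = records["happy"] - records["sad"]
    out["metabolic_state"] = records["hunger"] - records["satiety"]
    return out


def transform_glucose(values) -> np.ndarray:
    """Natural log of glucose (mg/dL); inputs must be strictly positive."""
    arr = np.asarray(values, dtype=float)
    if np.any(arr[np.isfinite(arr)] <= 0):
        raise ValueError("glucose must be positive for ln transform")
    return np.log(arr)


def z_standardise(values) -> np.ndarray:
    """Grand z-scores: centre by the mean, scale by the sample (n−1) SD,
    pooled over all observations. NaNs are ignored for the moments and
    propagate through. Raises on zero variance."""
    arr = np.asarray(values, dtype=float)
    finite = arr[np.isfinite(arr)]
    if np.unique(finite).size < 2:
        raise ValueError("need >= 2 distinct values to z-standardise")
    sd = np.std(finite, ddof=1)
    if sd == 0:
        raise ValueError("zero variance")
    return (arr - finite.mean()) / sd


def build_aligned_table(ema: pd.DataFrame, matched_glucose: pd.Series,
                        min_runs: int = 20) -> pd.DataFrame:
    """Assemble the modelling table from EMA records and lag-matched glucose.

    Adds composites, ln glucose and grand z-scores (``z_ln_glucose``,
    ``z_metabolic_state``), an ``included`` flag per participant
    (>= ``min_runs`` concurrent runs), and drops nothing: downstream models
    subset on ``included`` and listwise-complete rows. Standardisation is
    computed after QC inclusion, over included concurrent observations only.
    """
    out = compute_composites(ema)
    out["glucose_mg_dl"] = matched_glucose.to_numpy()
    concurrent = out["glucose_mg_dl"].notna()
    runs = concurrent.groupby(out["participant_id"]).sum()
    included_ids = set(runs[runs >= min_runs].index)
    out["included"] = out["participant_id"].isin(included_ids)
    out["ln_glucose"] = np.where(concurrent,
                                 np.log(out["glucose_mg_dl"].where(concurrent)),
                                 np.nan)
    basis = out["included"] & concurrent
    out["z_ln_glucose"] = _z_on_basis(out["ln_glucose"], basis)
    out["z_metabolic_state"] = _z_on_basis(out["metabolic_state"], basis)
    return out


def _z_on_basis(values: pd.Series, basis: pd.Series) -> np.ndarray:
    ref = values[basis & values.notna()]
    mu, sd = ref.mean(), ref.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise ValueError("zero variance on standardisation basis")
    return ((values - mu) / sd).to_numpy()
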