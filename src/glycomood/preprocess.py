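"""CGM signal conditioning.

The chain mirrors established physiological signal-correction practice for
wearable glucose sensors:

1. split each participant's record into segments at missing-data gaps
   longer than 20 min (and at sensor changes);
2. fill shorter gaps by linear interpolation on the 5-min grid;
3. remove slow non-physiological per-segment drift (calibration dynamics,
   sensor–tissue interaction) with a sliding-window quantile baseline;
4. re-reference every segment to a participant-specific stable baseline
   taken from the lowest-variability overnight (00:00–08:00) hour,
   minimum across nights — a common anchor for both sensors;
5. Gaussian-smooth (5 taps ≈ 25 min) within segments;
6. bin to a standard 5-min grid; and
7. extract, for each momentary assessment, the glucose recorded 5–10 min
   later (the vascular→interstitial transport delay).

All functions operate on tidy DataFrames with a ``timestamp`` column
(timezone-naive device clock) and ``glucose_mg_dl`` values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

__all__ = [
    "PreprocessConfig",
    "StableBaseline",
    "segment_by_gaps",
    "interpolate_short_gaps",
    "correct_drift",
    "compute_stable_baseline",
    "rebaseline",
    "gaussian_smooth",
    "resample_to_grid",
    "align_glucose_to_ema",
    "qc_participant",
    "preprocess_participant",
]


@dataclass(frozen=True)
class PreprocessConfig:
    """Tunable parameters of the conditioning chain (durations in minutes)."""

    max_gap_min: float = 20.0
    grid_step_min: float = 5.0
    smooth_window: int = 5
    smooth_sigma: float = 1.0          # in grid steps
    overnight_start_h: float = 0.0
    overnight_end_h: float = 8.0
    baseline_window_min: float = 60.0
    baseline_step_min: float = 5.0
    drift_window_min: float = 240.0
    drift_step_min: float = 60.0
    drift_quantile: float = 0.10
    min_drift_segment_min: float = 120.0
    lag_start_min: float = 5.0
    lag_end_min: float = 10.0

    def validate(self) -> None:
        if self.max_gap_min <= self.grid_step_min:
            raise ValueError("max_gap_min must exceed grid_step_min")
        if self.smooth_window % 2 != 1:
            raise ValueError("smooth_window must be odd")
        if not self.lag_start_min < self.lag_end_min:
            raise ValueError("lag window must have positive length")
        if not 0 < self.drift_quantile < 1:
            raise ValueError("drift_quantile must lie in (0, 1)")


@dataclass(frozen=True)
class StableBaseline:
    """Participant-specific fasting reference glucose.

    ``fallback`` marks the 5th-percentile substitute used when no night
    offers a full low-variability window.
    """

    value: float
    source_night: pd.Timestamp | None
    source_window_start: pd.Timestamp | None
    fallback: bool = False


def _check_sorted(ts: pd.Series) -> None:
    if not ts.is_monotonic_increasing:
        raise ValueError("timestamps must be sorted increasing")


def segment_by_gaps(samples: pd.DataFrame,
                    max_gap_min: float = 20.0) -> list[pd.DataFrame]:
    """Split a sorted sample table at gaps strictly longer than ``max_gap_min``.

    A sensor change also starts a new segment (different calibration regime),
    even without a time gap. Concatenating the returned segments reproduces
    the input rows exactly.
    """
    if len(samples) == 0:
        return []
    _check_sorted(samples["timestamp"])
    dt = samples["timestamp"].diff().dt.total_seconds().to_numpy() / 60.0
    new = np.zeros(len(samples), dtype=bool)
    new[0] = True
    new |= np.nan_to_num(dt, nan=0.0) > max_gap_min
    if "sensor_id" in samples.columns:
        sid = samples["sensor_id"].to_numpy()
        new[1:] |= sid[1:] != sid[:-1]
    seg_id = np.cumsum(new)
    return [g.reset_index(drop=True)
            for _, g in samples.groupby(seg_id, sort=True)]


def interpolate_short_gaps(segment: pd.DataFrame,
                           grid_step_min: float = 5.0) -> pd.DataFrame:
    """Fill missing grid points inside a segment by linear interpolation.

    The grid spans the segment's own extent snapped to multiples of
    ``grid_step_min`` from midnight; nothing is extrapolated beyond the first
    or last observation. Observed samples are preserved at their grid slot.
    """
    if len(segment) == 0:
        return segment.copy()
    _check_sorted(segment["timestamp"])
    ts = segment["timestamp"]
    step = pd.Timedelta(minutes=grid_step_min)
    start = ts.iloc[0].ceil(f"{int(grid_step_min * 60)}s")
    end = ts.iloc[-1].floor(f"{int(grid_step_min * 60)}s")
    if start > end:
        out = segment[["timestamp", "glucose_mg_dl"]].copy()
        out["interpolated"] = False
        if "sensor_id" in segment.columns:
            out["sensor_id"] = segment["sensor_id"].to_numpy()
        return out
    grid = pd.date_range(start, end, freq=step)
    t_num = ts.astype("int64").to_numpy() / 1e9
    g_num = grid.astype("int64").to_numpy() / 1e9
    vals = np.interp(g_num, t_num, segment["glucose_mg_dl"].to_numpy())
    observed = np.isin(g_num, t_num)
    out = pd.DataFrame({"timestamp": grid, "glucose_mg_dl": vals,
                        "interpolated": ~observed})
    if "sensor_id" in segment.columns:
        out["sensor_id"] = segment["sensor_id"].iloc[0]
    return out


def _sliding_quantile_baseline(t_min: np.ndarray, values: np.ndarray,
                               config: PreprocessConfig) -> np.ndarray:
    """Slow baseline: windowed low quantile, PCHIP-joined at window centres."""
    span = t_min[-1] - t_min[0]
    w = config.drift_window_min
    starts = np.arange(t_min[0], t_min[0] + max(span - w, 0.0) + 1e-9,
                       config.drift_step_min)
    centers, anchors = [], []
    for s in starts:
        mask = (t_min >= s) & (t_min <= s + w)
        if mask.sum() >= 2:
            centers.append(s + w / 2.0)
            anchors.append(np.quantile(values[mask], config.drift_quantile))
    if len(anchors) == 0:
        return np.full_like(values, np.quantile(values, config.drift_quantile))
    if len(anchors) == 1:
        return np.full_like(values, anchors[0])
    interp = PchipInterpolator(centers, anchors, extrapolate=False)
    base = interp(np.clip(t_min, centers[0], centers[-1]))
    return base


def correct_drift(segment: pd.DataFrame,
                  config: PreprocessConfig | None = None) -> pd.DataFrame:
    """Subtract the slow per-segment baseline (drift + offset removal).

    A low quantile (default 0.10) tracked in sliding windows (default 4 h,
    1-h steps) follows the fasting envelope without chasing meal peaks; the
    window-anchored points are joined by a monotone cubic (PCHIP) curve and
    subtracted. Segments shorter than ``min_drift_segment_min`` carry too
    little support for a baseline and pass through unchanged with
    ``drift_corrected=False`` and a warning.
    """
    config = config or PreprocessConfig()
    config.validate()
    out = segment.copy()
    if len(segment) < 2:
        out["drift_corrected"] = False
        return out
    ts = segment["timestamp"]
    t_min = (ts - ts.iloc[0]).dt.total_seconds().to_numpy() / 60.0
    if t_min[-1] - t_min[0] < config.min_drift_segment_min:
        warnings.warn("segment too short for drift correction; passed through",
                      stacklevel=2)
        out["drift_corrected"] = False
        return out
    base = _sliding_quantile_baseline(t_min, segment["glucose_mg_dl"].to_numpy(),
                                      config)
    out["glucose_mg_dl"] = segment["glucose_mg_dl"].to_numpy() - base
    out["drift_corrected"] = True
    return out


def compute_stable_baseline(raw: pd.DataFrame,
                            config: PreprocessConfig | None = None) -> StableBaseline:
    """Fasting reference from raw overnight values.

    Per night, a 1-h window slides in 5-min steps across 00:00–08:00; the
    night's candidate is the mean of its lowest-SD full window, and the
    returned baseline is the minimum candidate across nights. With no
    complete overnight window anywhere, falls back to the 5th percentile of
    all raw values (flagged).
    """
    config = config or PreprocessConfig()
    if len(raw) == 0:
        raise ValueError("no raw samples")
    ts = raw["timestamp"]
    vals = raw["glucose_mg_dl"].to_numpy()
    night = ts.dt.normalize()
    hours = ts.dt.hour + ts.dt.minute / 60.0 + ts.dt.second / 3600.0
    in_window = (hours >= config.overnight_start_h) & (hours < config.overnight_end_h)
    # a full 1-h window at the nominal grid step
    need = int(round(config.baseline_window_min / config.grid_step_min))

    best_value = np.inf
    best_night = None
    best_start = None
    for night_date, mask in ((d, (night == d) & in_window)
                             for d in night[in_window].unique()):
        t_sub = ts[mask]
        v_sub = vals[mask.to_numpy()]
        if len(t_sub) < need:
            continue
        t_num = ((t_sub - night_date).dt.total_seconds() / 60.0).to_numpy()
        night_best_sd = np.inf
        night_cand = None
        night_start = None
        start = config.overnight_start_h * 60.0
        stop = config.overnight_end_h * 60.0 - config.baseline_window_min
        for s in np.arange(start, stop + 1e-9, config.baseline_step_min):
            wmask = (t_num >= s) & (t_num < s + config.baseline_window_min)
            if wmask.sum() < need:
                continue
            sd = np.std(v_sub[wmask], ddof=1)
            if sd < night_best_sd:
                night_best_sd = sd
                night_cand = float(np.mean(v_sub[wmask]))
                night_start = night_date + pd.Timedelta(minutes=s)
        if night_cand is not None and night_cand < best_value:
            best_value = night_cand
            best_night = night_date
            best_start = night_start
    if best_night is None:
        return StableBaseline(value=float(np.percentile(vals, 5)),
                              source_night=None, source_window_start=None,
                              fallback=True)
    return StableBaseline(value=best_value, source_night=best_night,
                          source_window_start=best_start, fallback=False)


def rebaseline(segment: pd.DataFrame, baseline: StableBaseline) -> pd.DataFrame:
    """Add the participant's stable baseline to a drift-removed segment."""
    out = segment.copy()
    out["glucose_mg_dl"] = segment["glucose_mg_dl"].to_numpy() + baseline.value
    return out


def gaussian_smooth(segment: pd.DataFrame, smooth_window: int = 5,
                    sigma: float = 1.0) -> pd.DataFrame:
    """Gaussian smoothing within a segment (never across segment boundaries).

    Kernel: ``smooth_window`` taps, sigma in grid steps, truncated at the
    half-window and renormalised to sum 1 — at segment edges the kernel is
    renormalised over the available samples, so a constant signal is exactly
    preserved.
    """
    if smooth_window % 2 != 1:
        raise ValueError("smooth_window must be odd")
    out = segment.copy()
    n = len(segment)
    if n == 0 or smooth_window == 1:
        return out
    half = smooth_window // 2
    k = np.exp(-0.5 * (np.arange(-half, half + 1) / sigma) ** 2)
    vals = segment["glucose_mg_dl"].to_numpy(dtype=float)
    num = np.convolve(vals, k, mode="full")[half:half + n]
    den = np.convolve(np.ones(n), k, mode="full")[half:half + n]
    out["glucose_mg_dl"] = num / den
    return out


def resample_to_grid(series: pd.DataFrame,
                     grid_step_min: float = 5.0) -> pd.DataFrame:
    """Assign samples to a global grid of left-closed bins ``[t, t+step)``.

    Bins are labelled by their left edge; multiple samples in one bin are
    averaged; empty bins stay absent (gaps are not bridged here).
    """
    if len(series) == 0:
        return series.copy()
    binned = series["timestamp"].dt.floor(f"{int(grid_step_min * 60)}s")
    out = (series.assign(timestamp=binned)
           .groupby("timestamp", as_index=False)["glucose_mg_dl"].mean())
    return out


def align_glucose_to_ema(gridded: pd.DataFrame, ema_timestamps: pd.Series,
                         lag_start_min: float = 5.0,
                         lag_end_min: float = 10.0) -> pd.Series:
    """Glucose matched to each assessment: mean of grid samples recorded
    in ``[t + lag_start, t + lag_end]`` minutes after the assessment (on a
    5-min grid both endpoints satisfy the physiological lag).

    An empty lag window yields NaN (no concurrent glucose; the observation
    is dropped from modelling and from the concurrent-run count).
    """
    if len(gridded) == 0:
        return pd.Series(np.nan, index=ema_timestamps.index, name="glucose_mg_dl")
    g_ts = gridded["timestamp"].astype("int64").to_numpy() / 60e9  # minutes
    g_val = gridded["glucose_mg_dl"].to_numpy()
    order = np.argsort(g_ts)
    g_ts, g_val = g_ts[order], g_val[order]
    e_ts = ema_timestamps.astype("int64").to_numpy() / 60e9
    lo = np.searchsorted(g_ts, e_ts + lag_start_min, side="left")
    hi = np.searchsorted(g_ts, e_ts + lag_end_min, side="right")
    out = np.full(e_ts.size, np.nan)
    for i, (a, b) in enumerate(zip(lo, hi)):
        if b > a:
            out[i] = g_val[a:b].mean()
    return pd.Series(out, index=ema_timestamps.index, name="glucose_mg_dl")


def qc_participant(matched: pd.Series, min_runs: int = 20) -> bool:
    """Include a participant iff they have >= ``min_runs`` assessments with
    concurrent (lag-matched, non-missing) glucose."""
    return int(matched.notna().sum()) >= min_runs


def preprocess_participant(cgm: pd.DataFrame,
                           config: PreprocessConfig | None = None):
    """Run the full conditioning chain for one participant.

    Returns ``(grid, report)``: the preprocessed series on the global 5-min
    grid and a report dict (segment count, interpolated points, stable
    baseline and its source night, sample conservation counts).
    """
    config = config or PreprocessConfig()
    config.validate()
    baseline = compute_stable_baseline(cgm, config)
    segments = segment_by_gaps(cgm, config.max_gap_min)
    n_interp = 0
    pieces = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # short-segment passthrough is reported
        for seg in segments:
            filled = interpolate_short_gaps(seg, config.grid_step_min)
            n_interp += int(filled.get("interpolated",
                                       pd.Series(dtype=bool)).sum())
            corrected = correct_drift(filled, config)
            was_corrected = (len(corrected) > 0
                             and bool(corrected["drift_corrected"].iloc[0]))
            if was_corrected:
                corrected = rebaseline(corrected, baseline)
            smoothed = gaussian_smooth(corrected, config.smooth_window,
                                       config.smooth_sigma)
            pieces.append(smoothed)
    if pieces:
        combined = pd.concat(pieces, ignore_index=True)
    else:
        combined = pd.DataFrame(columns=["timestamp", "glucose_mg_dl"])
    grid = resample_to_grid(combined, config.grid_step_min)
    report = {
        "n_segments": len(segments),
        "n_interpolated": n_interp,
        "n_raw_samples": len(cgm),
        "baseline_value": baseline.value,
        "baseline_night": (str(baseline.source_night.date())
                           if baseline.source_night is not None else None),
        "baseline_fallback": baseline.fallback,
        "n_uncorrected_segments": sum(
            1 for p in pieces
            if len(p) and "drift_corrected" in p and not p["drift_corrected"].iloc[0]),
    }
    return grid, report
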