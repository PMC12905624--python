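"""Synthetic CGM + EMA cohort generator with known ground truth.

Emulates a four-week observational study of healthy adults wearing a
5-min interstitial glucose sensor while answering twice-daily momentary
questionnaires (visual-analogue ratings of happy, sad, hunger, satiety).
The generative model encodes an indirect-only mediation structure:

* latent metabolic state  m = a_i * z(ln glucose) + noise, with a
  heterogeneous, predominantly negative per-person coupling a_i
  (lower glucose → hungrier);
* mood latent  y = c' * z(ln glucose) + b * m + noise, with the direct
  path c' ≈ 0 so that the glucose→mood association is carried by the
  consciously sensed metabolic state.

Because every trace, rating and lab value derives from a seeded
:class:`numpy.random.Generator` substream, the generator doubles as an
oracle: recovery of ``a_i``, ``b`` and the mediation decomposition can be
checked against :class:`GroundTruth`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CohortParams",
    "GroundTruth",
    "SimulatedTrace",
    "simulate_glucose_trace",
    "simulate_ema",
    "simulate_cohort",
    "simulate_observations",
]

_MIN_GLUCOSE = 40.0
_MAX_GLUCOSE = 250.0


@dataclass(frozen=True)
class CohortParams:
    """Generative parameters for a synthetic cohort.

    Defaults encode the emulated study: ~90 participants, 28 days, 5-min
    sensor sampling with a sensor swap after two weeks, two assessments
    per day at least 2 h apart with ~85% completion (mean ≈ 48 of 56
    scheduled), and an indirect-only mediation with a·b = 1.5, c' = 0.

    Glucose units are mg/dL; durations are minutes unless suffixed;
    path coefficients act on the grand-standardised ln-glucose scale.
    """

    n_participants: int = 90
    n_days: int = 28
    grid_step_min: float = 5.0
    start: str = "2024-01-01"

    # glucose signal
    basal_mean: float = 85.0
    basal_sd: float = 7.0
    meal_times_h: tuple[float, ...] = (8.0, 13.0, 19.0)
    meal_jitter_sd_h: float = 0.75
    meal_amplitude: float = 45.0
    meal_amplitude_cv: float = 0.25
    meal_rise_tau_min: float = 20.0
    meal_decay_tau_min: float = 60.0
    circadian_amplitude: float = 5.0
    circadian_peak_hour: float = 16.0

    # sensor artefacts
    drift_amplitude: float = 10.0
    sensor_offset_sd: float = 5.0
    noise_sd: float = 3.0
    ar_coef: float = 0.6
    short_gap_rate: float = 1.0      # events/day, gaps < 20 min
    long_gap_rate: float = 0.15      # events/day, gaps > 20 min
    long_gap_min_min: float = 30.0
    long_gap_max_min: float = 240.0
    sensor_swap_day: int = 14

    # mediation paths (standardised units)
    a_mean: float = -0.5
    a_sd: float = 0.2
    b: float = -3.0
    c_prime: float = 0.0
    metabolic_noise_sd: float = 0.6
    hunger_scale: float = 20.0       # VAS points per latent unit
    hunger_intercept_sd: float = 8.0   # between-person mean-hunger spread, VAS
    satiety_noise_sd: float = 4.0
    mood_noise_sd_base: float = 8.0
    mood_noise_accuracy_coupling: float = 6.0
    mood_intercept_sd: float = 12.0    # between-person mean-mood spread, VAS

    # EMA schedule
    ema_per_day: int = 2
    ema_min_gap_h: float = 2.0
    ema_completion: float = 0.85
    wake_start_h: float = 8.0
    wake_end_h: float = 23.0

    # demographics / labs
    female_fraction: float = 46.0 / 90.0
    age_mean: float = 24.3
    age_sd: float = 3.6
    bmi_mean: float = 24.7
    bmi_sd: float = 4.1
    insulin_bmi_slope: float = 0.06  # ln(mU/L) per BMI unit
    n_draws: int = 3

    seed: int = 0

    def validate(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")
        for name in ("grid_step_min", "meal_rise_tau_min", "meal_decay_tau_min",
                     "ema_min_gap_h"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not abs(self.ar_coef) < 1:
            raise ValueError("ar_coef must lie in (-1, 1)")
        if not 0 <= self.ema_completion <= 1:
            raise ValueError("ema_completion must lie in [0, 1]")
        if self.wake_end_h <= self.wake_start_h:
            raise ValueError("wake window must have positive length")


@dataclass
class GroundTruth:
    """Oracle quantities for recovery tests.

    ``acme``/``ade`` are implied by linearity: the true indirect effect is
    mean(a_i)·b and the direct effect is c'; their sum is the total effect.
    """

    a: pd.Series                 # per-participant glucose→metabolic slope
    b: float
    c_prime: float
    basal: pd.Series             # per-participant basal glucose, mg/dL
    mood_noise_sd: pd.Series     # per-participant mood noise scale
    drift: dict = field(default_factory=dict)   # pid -> {sensor_id: np.ndarray}
    truth_traces: dict = field(default_factory=dict)  # pid -> DataFrame

    @property
    def acme(self) -> float:
        return float(self.a.mean() * self.b)

    @property
    def ade(self) -> float:
        return float(self.c_prime)

    @property
    def total(self) -> float:
        return self.acme + self.ade


@dataclass
class SimulatedTrace:
    """One participant's sensor record plus its noise/drift-free truth."""

    observed: pd.DataFrame   # timestamp, glucose_mg_dl, sensor_id (gaps removed)
    truth: pd.DataFrame      # timestamp, glucose_mg_dl on the full grid
    drift: dict              # sensor_id -> drift array on the full grid


def _bi_exponential(t_min: np.ndarray, rise: float, decay: float) -> np.ndarray:
    """Unit-peak bi-exponential meal excursion, zero before onset."""
    if decay <= rise:
        decay = rise * 1.5
    shape = np.where(t_min >= 0,
                     np.exp(-np.maximum(t_min, 0.0) / decay)
                     - np.exp(-np.maximum(t_min, 0.0) / rise),
                     0.0)
    t_peak = rise * decay / (decay - rise) * math.log(decay / rise)
    peak = math.exp(-t_peak / decay) - math.exp(-t_peak / rise)
    return shape / peak


def simulate_glucose_trace(profile: dict, params: CohortParams,
                           rng: np.random.Generator) -> SimulatedTrace:
    """Simulate a 5-min CGM record for one participant.

    ``profile`` needs a ``basal`` entry (mg/dL); the observed trace adds a
    per-sensor smooth cubic drift, a per-sensor calibration step offset and
    AR(1) measurement noise to the physiological truth
    (basal + circadian sinusoid + bi-exponential meal excursions), clamps to
    [40, 250] mg/dL, and deletes samples to create short (<20 min) and long
    (>20 min) gaps at the configured daily rates.
    """
    params.validate()
    basal = float(profile["basal"])
    step = params.grid_step_min
    n = int(round(params.n_days * 24 * 60 / step))
    start = pd.Timestamp(params.start)
    ts = start + pd.to_timedelta(np.arange(n) * step, unit="m")
    t_min = np.arange(n) * step
    hour = (t_min / 60.0) % 24.0

    # nonnegative daytime elevation with zero overnight trough, so "basal"
    # is the overnight fasting floor the stable-baseline stage estimates
    circadian = params.circadian_amplitude * 0.5 * (1.0 + np.cos(
        2 * np.pi * (hour - params.circadian_peak_hour) / 24.0))

    meals = np.zeros(n)
    for day in range(params.n_days):
        for mt in params.meal_times_h:
            onset_h = day * 24 + mt + rng.normal(0.0, params.meal_jitter_sd_h)
            amp = params.meal_amplitude * math.exp(
                rng.normal(0.0, params.meal_amplitude_cv))
            meals += amp * _bi_exponential(t_min - onset_h * 60.0,
                                           params.meal_rise_tau_min,
                                           params.meal_decay_tau_min)

    truth_vals = np.clip(basal + circadian + meals, _MIN_GLUCOSE, _MAX_GLUCOSE)

    # sensor wear periods: swap at sensor_swap_day (or single sensor if the
    # study is shorter than the swap day)
    swap_idx = int(round(params.sensor_swap_day * 24 * 60 / step))
    if 0 < swap_idx < n:
        periods = [("S1", 0, swap_idx), ("S2", swap_idx, n)]
    else:
        periods = [("S1", 0, n)]

    drift_total = np.zeros(n)
    offsets = np.zeros(n)
    sensor_id = np.empty(n, dtype=object)
    drift_curves: dict[str, np.ndarray] = {}
    for sid, lo, hi in periods:
        u = np.linspace(0.0, 1.0, hi - lo)
        coef = rng.normal(size=4)
        d = coef[0] + coef[1] * u + coef[2] * u ** 2 + coef[3] * u ** 3
        # unidirectional calibration bias: nonnegative, touching zero within
        # the wear period, so the raw overnight minimum still sees basal
        d -= d.min()
        dmax = np.max(d)
        scale = params.drift_amplitude * rng.uniform(0.5, 1.0)
        d = d / dmax * scale if dmax > 0 else d
        drift_total[lo:hi] = d
        offsets[lo:hi] = rng.normal(0.0, params.sensor_offset_sd)
        sensor_id[lo:hi] = sid
        drift_curves[sid] = d

    # AR(1) noise with stationary sd = noise_sd
    innov_sd = params.noise_sd * math.sqrt(1 - params.ar_coef ** 2)
    eps = rng.normal(0.0, 1.0, n)
    noise = np.empty(n)
    noise[0] = eps[0] * params.noise_sd
    for i in range(1, n):
        noise[i] = params.ar_coef * noise[i - 1] + innov_sd * eps[i]

    observed_vals = np.clip(truth_vals + drift_total + offsets + noise,
                            _MIN_GLUCOSE, _MAX_GLUCOSE)

    keep = np.ones(n, dtype=bool)
    n_short = rng.poisson(params.short_gap_rate * params.n_days)
    n_long = rng.poisson(params.long_gap_rate * params.n_days)
    for _ in range(n_short):
        i0 = rng.integers(0, n)
        keep[i0:i0 + rng.integers(1, 3)] = False        # 10–15 min gap
    for _ in range(n_long):
        dur = rng.uniform(params.long_gap_min_min, params.long_gap_max_min)
        width = max(int(round(dur / step)), 5)          # >= 25 min gap
        i0 = rng.integers(0, max(n - width, 1))
        keep[i0:i0 + width] = False

    observed = pd.DataFrame({
        "timestamp": ts[keep],
        "glucose_mg_dl": observed_vals[keep],
        "sensor_id": sensor_id[keep],
    })
    truth = pd.DataFrame({"timestamp": ts, "glucose_mg_dl": truth_vals})
    return SimulatedTrace(observed=observed, truth=truth, drift=drift_curves)


def _draw_ema_times(params: CohortParams, rng: np.random.Generator) -> np.ndarray:
    """Assessment times (minutes from study start), >= min-gap apart in wake hours."""
    times = []
    lo, hi = params.wake_start_h, params.wake_end_h
    gap = params.ema_min_gap_h
    for day in range(params.n_days):
        for _ in range(200):
            cand = np.sort(rng.uniform(lo, hi, params.ema_per_day))
            if params.ema_per_day < 2 or np.all(np.diff(cand) >= gap):
                break
        else:  # pragma: no cover - rejection virtually always succeeds
            cand = np.linspace(lo, hi, params.ema_per_day)
        times.extend((day * 24 + h) * 60.0 for h in cand)
    return np.round(np.asarray(times))  # device logs whole minutes


def _latents_to_vas(z_glu: np.ndarray, profile: dict, params: CohortParams,
                    rng: np.random.Generator) -> pd.DataFrame:
    """Map standardised glucose to the four VAS items via the latent paths.

    ``profile`` carries the per-person coupling ``a`` and the between-person
    intercepts ``hunger_offset`` / ``mood_offset`` (VAS points; default 0).
    """
    a_i = float(profile["a"])
    h_off = float(profile.get("hunger_offset", 0.0))
    y_off = float(profile.get("mood_offset", 0.0))
    m = a_i * z_glu + rng.normal(0.0, params.metabolic_noise_sd, z_glu.size)
    hunger = np.clip(50.0 + h_off + params.hunger_scale * m, 0.0, 100.0)
    satiety = np.clip(100.0 - hunger
                      + rng.normal(0.0, params.satiety_noise_sd, z_glu.size),
                      0.0, 100.0)
    sd_i = (params.mood_noise_sd_base
            + params.mood_noise_accuracy_coupling * (1.0 - min(abs(a_i), 1.0)))
    mood_latent = (params.c_prime * z_glu + params.b * m
                   + rng.normal(0.0, sd_i, z_glu.size))
    happy = np.clip(60.0 + 0.5 * (mood_latent + y_off), 0.0, 100.0)
    sad = np.clip(40.0 - 0.5 * (mood_latent + y_off), 0.0, 100.0)
    return pd.DataFrame({"happy": happy, "sad": sad,
                         "hunger": hunger, "satiety": satiety})


def simulate_ema(trace_truth: pd.DataFrame, profile: dict, params: CohortParams,
                 rng: np.random.Generator,
                 glucose_ref: tuple[float, float] | None = None) -> pd.DataFrame:
    """Simulate the EMA log for one participant against a clean glucose trace.

    ``trace_truth`` is the physiological (drift/noise-free) trace; ratings
    are driven by ln-glucose at the assessment time, standardised either by
    ``glucose_ref = (mean, sd)`` (cohort-level moments, used by
    :func:`simulate_cohort`) or, by default, by the within-trace moments of
    ln-glucose at the drawn assessment times.
    """
    params.validate()
    if len(trace_truth) == 0:
        raise ValueError("glucose trace is empty")

    times_min = _draw_ema_times(params, rng)
    kept = rng.random(times_min.size) < params.ema_completion
    times_min = times_min[kept]

    t0 = trace_truth["timestamp"].iloc[0]
    trace_min = (trace_truth["timestamp"] - t0).dt.total_seconds().to_numpy() / 60.0
    glu = np.interp(times_min, trace_min, trace_truth["glucose_mg_dl"].to_numpy())
    ln_glu = np.log(glu)
    if glucose_ref is None:
        mu, sd = float(np.mean(ln_glu)), float(np.std(ln_glu, ddof=1))
        sd = sd if sd > 0 else 1.0
    else:
        mu, sd = glucose_ref
    z_glu = (ln_glu - mu) / sd

    vas = _latents_to_vas(z_glu, profile, params, rng)
    vas.insert(0, "timestamp", t0 + pd.to_timedelta(times_min, unit="m"))
    return vas


def _participant_profiles(params: CohortParams,
                          rng: np.random.Generator) -> pd.DataFrame:
    n = params.n_participants
    n_female = int(round(params.female_fraction * n))
    sex = np.array(["female"] * n_female + ["male"] * (n - n_female))
    rng.shuffle(sex)
    age = np.clip(rng.normal(params.age_mean, params.age_sd, n), 18, 40)
    bmi = np.clip(rng.normal(params.bmi_mean, params.bmi_sd, n), 17.5, 40)
    basal = np.clip(rng.normal(params.basal_mean, params.basal_sd, n), 60, 120)
    a_i = rng.normal(params.a_mean, params.a_sd, n)
    prof = pd.DataFrame({
        "participant_id": [f"P{i + 1:03d}" for i in range(n)],
        "sex": sex,
        "age": np.round(age, 1),
        "bmi": np.round(bmi, 1),
        "basal": basal,
        "a": a_i,
        "hunger_offset": rng.normal(0.0, params.hunger_intercept_sd, n),
        "mood_offset": rng.normal(0.0, params.mood_intercept_sd, n),
    })
    return prof


def _fasting_labs(prof: pd.DataFrame, params: CohortParams,
                  rng: np.random.Generator) -> pd.DataFrame:
    """Up to 3 fasting draws consistent with a healthy-cohort HOMA-IR range."""
    n = len(prof)
    cols = {}
    ln_insulin_mu = (math.log(6.5)
                     + params.insulin_bmi_slope * (prof["bmi"].to_numpy()
                                                   - params.bmi_mean)
                     + rng.normal(0.0, 0.35, n))
    ln_tg_mu = math.log(105.0) + rng.normal(0.0, 0.28, n)
    for j in range(1, params.n_draws + 1):
        cols[f"fasting_glucose_{j}"] = np.round(
            np.clip(prof["basal"].to_numpy() + rng.normal(0.0, 4.0, n), 60, 130), 1)
        cols[f"fasting_insulin_{j}"] = np.round(
            np.exp(ln_insulin_mu + rng.normal(0.0, 0.15, n)), 2)
        cols[f"triglycerides_{j}"] = np.round(
            np.exp(ln_tg_mu + rng.normal(0.0, 0.12, n)), 1)
    labs = pd.DataFrame(cols)
    labs.insert(0, "participant_id", prof["participant_id"].to_numpy())
    return labs


def simulate_cohort(params: CohortParams | None = None):
    """Generate a full cohort bundle and its ground truth.

    Returns ``(bundle, truth)`` where ``bundle`` is a dict with DataFrames
    ``cgm`` (participant_id, timestamp, glucose_mg_dl, sensor_id), ``ema``
    (participant_id, timestamp, happy, sad, hunger, satiety) and
    ``participants`` (demographics + fasting draws).

    The EMA latents are defined on the cohort-grand-standardised ln-glucose
    scale (two passes over participants), matching the downstream modelling
    convention so that the generative slopes are the estimands of the fitted
    mixed models. All randomness derives from per-participant substreams of
    ``params.seed``; reruns are bit-identical.
    """
    params = params or CohortParams()
    params.validate()
    ss = np.random.SeedSequence(params.seed)
    cohort_ss, *participant_ss = ss.spawn(params.n_participants + 1)
    cohort_rng = np.random.Generator(np.random.PCG64(cohort_ss))

    prof = _participant_profiles(params, cohort_rng)
    labs = _fasting_labs(prof, params, cohort_rng)

    # pass 1: glucose traces and assessment times
    traces: dict[str, SimulatedTrace] = {}
    ema_parts: list[dict] = []
    for row, pss in zip(prof.itertuples(index=False), participant_ss):
        trace_ss, times_ss, latent_ss = pss.spawn(3)
        trace = simulate_glucose_trace({"basal": row.basal}, params,
                                       np.random.Generator(np.random.PCG64(trace_ss)))
        traces[row.participant_id] = trace
        times_rng = np.random.Generator(np.random.PCG64(times_ss))
        times_min = _draw_ema_times(params, times_rng)
        times_min = times_min[times_rng.random(times_min.size)
                              < params.ema_completion]
        t0 = trace.truth["timestamp"].iloc[0]
        trace_min = ((trace.truth["timestamp"] - t0)
                     .dt.total_seconds().to_numpy() / 60.0)
        glu = np.interp(times_min, trace_min,
                        trace.truth["glucose_mg_dl"].to_numpy())
        ema_parts.append({"pid": row.participant_id,
                          "profile": row._asdict(), "t0": t0,
                          "times_min": times_min, "ln_glu": np.log(glu),
                          "latent_ss": latent_ss})

    all_ln = np.concatenate([p["ln_glu"] for p in ema_parts])
    mu, sd = float(np.mean(all_ln)), float(np.std(all_ln, ddof=1))
    sd = sd if sd > 0 else 1.0

    # pass 2: ratings from grand-standardised glucose
    ema_frames = []
    for p in ema_parts:
        rng = np.random.Generator(np.random.PCG64(p["latent_ss"]))
        vas = _latents_to_vas((p["ln_glu"] - mu) / sd, p["profile"], params, rng)
        vas.insert(0, "timestamp", p["t0"] + pd.to_timedelta(p["times_min"], unit="m"))
        vas.insert(0, "participant_id", p["pid"])
        ema_frames.append(vas)
    ema = pd.concat(ema_frames, ignore_index=True)

    cgm_frames = []
    for pid, trace in traces.items():
        obs = trace.observed.copy()
        obs.insert(0, "participant_id", pid)
        cgm_frames.append(obs)
    cgm = pd.concat(cgm_frames, ignore_index=True)

    participants = (prof.drop(columns=["basal", "a", "hunger_offset",
                                       "mood_offset"])
                    .merge(labs, on="participant_id"))

    pid_index = prof["participant_id"]
    mood_sd = (params.mood_noise_sd_base
               + params.mood_noise_accuracy_coupling
               * (1.0 - np.minimum(np.abs(prof["a"].to_numpy()), 1.0)))
    truth = GroundTruth(
        a=pd.Series(prof["a"].to_numpy(), index=pid_index, name="a"),
        b=params.b,
        c_prime=params.c_prime,
        basal=pd.Series(prof["basal"].to_numpy(), index=pid_index, name="basal"),
        mood_noise_sd=pd.Series(mood_sd, index=pid_index, name="mood_noise_sd"),
        drift={pid: tr.drift for pid, tr in traces.items()},
        truth_traces={pid: tr.truth for pid, tr in traces.items()},
    )
    bundle = {"cgm": cgm, "ema": ema, "participants": participants}
    return bundle, truth


def simulate_observations(params: CohortParams | None = None,
                          seed: int | None = None):
    """Observation-level fast path: aligned records without the sensor layer.

    Draws standardised ln-glucose directly (unit grand variance split into a
    between-person component, sd 0.4, and a within-person remainder) and maps
    it through the same latent→VAS machinery as the full generator. Intended
    for statistical calibration studies (estimator recovery, type-I error,
    CI coverage) where simulating and preprocessing the 5-min sensor layer
    adds runtime but no information; the sensor layer is exercised by the
    preprocessing tests and the end-to-end pipeline.

    Returns ``(obs, truth)``; ``obs`` has one row per completed assessment
    with columns participant_id, z_ln_glucose, happy, sad, hunger, satiety.
    """
    params = params or CohortParams()
    params.validate()
    ss = np.random.SeedSequence(params.seed if seed is None else seed)
    cohort_ss, *participant_ss = ss.spawn(params.n_participants + 1)
    rng0 = np.random.Generator(np.random.PCG64(cohort_ss))
    prof = _participant_profiles(params, rng0)

    between_sd = 0.4
    within_sd = math.sqrt(1.0 - between_sd ** 2)
    frames = []
    n_sched = params.n_days * params.ema_per_day
    for row, pss in zip(prof.itertuples(index=False), participant_ss):
        rng = np.random.Generator(np.random.PCG64(pss))
        n_obs = int(rng.binomial(n_sched, params.ema_completion))
        if n_obs == 0:
            continue
        z = rng.normal(0.0, between_sd) + rng.normal(0.0, within_sd, n_obs)
        vas = _latents_to_vas(z, row._asdict(), params, rng)
        vas.insert(0, "z_ln_glucose", z)
        vas.insert(0, "participant_id", row.participant_id)
        frames.append(vas)
    obs = pd.concat(frames, ignore_index=True)

    mood_sd = (params.mood_noise_sd_base
               + params.mood_noise_accuracy_coupling
               * (1.0 - np.minimum(np.abs(prof["a"].to_numpy()), 1.0)))
    truth = GroundTruth(
        a=pd.Series(prof["a"].to_numpy(), index=prof["participant_id"], name="a"),
        b=params.b,
        c_prime=params.c_prime,
        basal=pd.Series(prof["basal"].to_numpy(), index=prof["participant_id"]),
        mood_noise_sd=pd.Series(mood_sd, index=prof["participant_id"]),
    )
    return obs, truth
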