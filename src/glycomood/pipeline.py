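"""End-to-end run: simulate (or load) → preprocess → features → indices →
models → mediation → report, with a reproducibility manifest."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from glycomood import io as gio
from glycomood.features import build_aligned_table
from glycomood.indices import derive_indices
from glycomood.inference import (accuracy_models, fit_lme, interoceptive_accuracy,
                                 model_specs, mood_summary)
from glycomood.mediation import run_mediation
from glycomood.preprocess import (PreprocessConfig, align_glucose_to_ema,
                                  preprocess_participant)
from glycomood.simulate import CohortParams, simulate_cohort

__all__ = ["RunConfig", "run_pipeline", "preprocess_and_align"]


@dataclass(frozen=True)
class RunConfig:
    """Everything a run needs; identical config + seed ⇒ identical bundle."""

    cohort: CohortParams = field(default_factory=CohortParams)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    cgm_path: str | None = None          # load instead of simulate when set
    ema_path: str | None = None
    participants_path: str | None = None
    min_runs: int = 20
    extended_models: bool = False
    accuracy_reverse: bool = False
    tyg_variant: str = "halved"
    n_sims: int = 10_000
    seed: int = 0
    out_dir: str | None = None

    def config_hash(self) -> str:
        payload = dataclasses.asdict(self)
        payload.pop("out_dir")  # output location does not shape the results
        payload = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def preprocess_and_align(cgm: pd.DataFrame, ema: pd.DataFrame,
                         config: PreprocessConfig | None = None,
                         min_runs: int = 20):
    """Condition every participant's CGM record and lag-match it to the EMA.

    Returns ``(aligned, reports)``: the modelling table (with composites,
    transforms, z-scores and inclusion flags) and per-participant
    preprocessing reports.
    """
    config = config or PreprocessConfig()
    reports = {}
    matched_parts = []
    for pid, sub in ema.groupby("participant_id", sort=True):
        cgm_sub = cgm[cgm["participant_id"] == pid]
        if len(cgm_sub) == 0:
            matched_parts.append(pd.Series(np.nan, index=sub.index))
            reports[pid] = {"n_segments": 0, "n_raw_samples": 0,
                            "concurrent_runs": 0, "included": False}
            continue
        grid, report = preprocess_participant(
            cgm_sub.drop(columns=["participant_id"]), config)
        matched = align_glucose_to_ema(grid, sub["timestamp"],
                                       config.lag_start_min, config.lag_end_min)
        report["concurrent_runs"] = int(matched.notna().sum())
        report["included"] = report["concurrent_runs"] >= min_runs
        reports[pid] = report
        matched_parts.append(matched)
    matched_all = pd.concat(matched_parts).reindex(ema.index)
    aligned = build_aligned_table(ema, matched_all, min_runs=min_runs)
    return aligned, reports


def _fit_to_dict(fit) -> dict:
    return {
        "params": {k: float(v) for k, v in fit.params.items()},
        "se": {k: float(v) for k, v in fit.bse.items()},
        "t": {k: float(v) for k, v in fit.tvalues.items()},
        "p": {k: float(v) for k, v in fit.pvalues.items()},
        "ci": {k: [float(fit.conf_int.loc[k, "lower"]),
                   float(fit.conf_int.loc[k, "upper"])]
               for k in fit.params.index},
        "df": fit.df,
        "n_obs": fit.n_obs,
        "n_participants": fit.n_groups,
        "converged": fit.converged,
        "fallback": fit.fallback,
    }


def run_pipeline(config: RunConfig | None = None) -> dict:
    """Run every stage and return the results bundle.

    With ``out_dir`` set, writes cgm/ema/participants CSVs (when simulated),
    aligned.csv, participants_derived.csv, results.json, mediation.json and
    manifest.json. Any stage failure propagates with the stage named.
    """
    config = config or RunConfig()
    bundle: dict = {"config": config}

    def stage(name, fn):
        try:
            return fn()
        except Exception as err:
            raise RuntimeError(f"pipeline stage '{name}' failed: {err}") from err

    if config.cgm_path:
        for name, p in (("cgm", config.cgm_path), ("ema", config.ema_path),
                        ("participants", config.participants_path)):
            if p is None or not Path(p).exists():
                raise FileNotFoundError(f"missing {name} file: {p}")
        cgm = stage("load", lambda: gio.read_cgm_csv(config.cgm_path))
        ema = stage("load", lambda: gio.read_ema_csv(config.ema_path))
        participants = stage(
            "load", lambda: gio.read_participants_csv(config.participants_path))
        truth = None
    else:
        cohort_params = dataclasses.replace(config.cohort, seed=config.seed)
        (sim, truth) = stage("simulate", lambda: simulate_cohort(cohort_params))
        cgm, ema, participants = sim["cgm"], sim["ema"], sim["participants"]
    bundle["truth"] = truth

    aligned, reports = stage("preprocess", lambda: preprocess_and_align(
        cgm, ema, config.preprocess, config.min_runs))
    bundle["aligned"] = aligned
    bundle["preprocess_reports"] = reports

    derived = stage("indices", lambda: derive_indices(
        participants, tyg_variant=config.tyg_variant))
    bundle["participants_derived"] = derived

    model_data = (aligned[aligned["included"]
                          & aligned["glucose_mg_dl"].notna()]
                  .merge(derived[["participant_id", "bmi", "age", "sex",
                                  "z_homa_ir_residual"]], on="participant_id"))
    for col in ("bmi", "age"):
        model_data[f"z_{col}"] = ((model_data[col] - model_data[col].mean())
                                  / model_data[col].std(ddof=1))

    specs = model_specs(extended=config.extended_models)
    fits = stage("inference", lambda: {k: fit_lme(s, model_data)
                                       for k, s in specs.items()})
    bundle["fits"] = fits

    scores = stage("accuracy", lambda: interoceptive_accuracy(
        model_data, reverse=config.accuracy_reverse))
    moods = mood_summary(model_data)
    scores = scores.merge(moods, on="participant_id")
    bundle["accuracy_scores"] = scores
    bundle["accuracy_fits"] = stage("accuracy", lambda: accuracy_models(
        scores, derived[["participant_id", "bmi", "age", "sex",
                         "z_homa_ir_residual"]]))

    mediation = stage("mediation", lambda: run_mediation(
        model_data, n_sims=config.n_sims, seed=config.seed))
    bundle["mediation"] = mediation

    manifest = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "n_participants": int(aligned["participant_id"].nunique()),
        "n_included": int(aligned.loc[aligned["included"],
                                      "participant_id"].nunique()),
        "n_observations_modelled": int(len(model_data)),
        "versions": _versions(),
    }
    bundle["manifest"] = manifest

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        if truth is not None:
            gio.write_cgm_csv(cgm, out / "cgm.csv")
            gio.write_ema_csv(ema, out / "ema.csv")
            gio.write_participants_csv(participants, out / "participants.csv")
            gio.write_ground_truth_json(truth, out / "ground_truth.json")
        aligned.to_csv(out / "aligned.csv", index=False,
                       date_format="%Y-%m-%dT%H:%M:%S")
        derived.to_csv(out / "participants_derived.csv", index=False)
        results = {k: _fit_to_dict(f) for k, f in fits.items()}
        results["accuracy_models"] = {k: _fit_to_dict(f) for k, f in
                                      bundle["accuracy_fits"].items()}
        (out / "results.json").write_text(json.dumps(results, indent=1,
                                                     sort_keys=True))
        (out / "mediation.json").write_text(
            json.dumps(mediation.to_dict(), indent=1, sort_keys=True))
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                      sort_keys=True))
    return bundle


def _versions() -> dict:
    import scipy
    import statsmodels

    import glycomood

    return {"glycomood": glycomood.__version__, "numpy": np.__version__,
            "pandas": pd.__version__, "scipy": scipy.__version__,
            "statsmodels": statsmodels.__version__}
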