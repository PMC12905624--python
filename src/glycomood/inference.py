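"""Mixed-effects and participant-level models.

The observation-level models are linear mixed-effects regressions with a
random intercept and random slopes per participant (restricted likelihood
by default), fitted on grand-standardised predictors:

* M1  mood_state ~ z_ln_glucose                  (+ covariate block)
* M2a hunger ~ z_ln_glucose, M2b satiety ~ z_ln_glucose,
  M2c z_metabolic_state ~ z_ln_glucose
* M3  mood_state ~ z_metabolic_state
* M4  mood_state ~ z_ln_glucose * z_metabolic_state (+ covariate block)

Interoceptive accuracy is the inverted per-participant slope of M2c
(fixed effect + conditional mode): stronger negative glucose→hunger
coupling means ratings track glucose more closely, hence higher accuracy.
Participant-level ordinary regressions then relate accuracy to mood mean
and mood variability.

Estimation is delegated to :class:`statsmodels.regression.mixed_linear_model.MixedLM`;
this module owns the model contracts, the convergence fallback ladder
(full covariance → uncorrelated random effects → intercept only, each
flagged) and the inference conventions (t statistics on residual
participant-level degrees of freedom).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

__all__ = [
    "LmeSpec",
    "FitResult",
    "model_specs",
    "fit_lme",
    "interoceptive_accuracy",
    "mood_summary",
    "accuracy_models",
    "sensitivity_refit",
]

_COVARIATE_BLOCK = "z_bmi + z_age + sex + z_homa_ir_residual"


@dataclass(frozen=True)
class LmeSpec:
    """Contract for one mixed model: formula, random-effect terms, flavour."""

    name: str
    formula: str
    re_terms: tuple[str, ...] = ()   # random slopes; intercept always included
    reml: bool = True

    def __post_init__(self):
        fixed = self.formula.split("~", 1)[1]
        for term in self.re_terms:
            if term not in fixed:
                raise ValueError(
                    f"random slope {term!r} must also appear as a fixed effect")


@dataclass
class FitResult:
    """Fixed-effect estimates with t-based inference and diagnostics."""

    name: str
    params: pd.Series
    bse: pd.Series
    df: float
    tvalues: pd.Series
    pvalues: pd.Series
    conf_int: pd.DataFrame            # columns: lower, upper
    cov: pd.DataFrame                 # fixed-effect sampling covariance
    random_effects: dict | None
    converged: bool
    fallback: str                     # full | uncorrelated | intercept_only | ols
    n_obs: int
    n_groups: int | None
    warnings_: list = field(default_factory=list)


def model_specs(extended: bool = False) -> dict[str, LmeSpec]:
    """The named observation-level model battery.

    ``extended`` adds the covariate block (z-BMI, z-age, sex, z-residualised
    HOMA-IR) and its interactions with the glucose term (and with metabolic
    state in M4).
    """
    if extended:
        m1 = f"mood_state ~ z_ln_glucose * ({_COVARIATE_BLOCK})"
        m4 = f"mood_state ~ z_ln_glucose * z_metabolic_state * ({_COVARIATE_BLOCK})"
    else:
        m1 = "mood_state ~ z_ln_glucose"
        m4 = "mood_state ~ z_ln_glucose * z_metabolic_state"
    return {
        "M1": LmeSpec("M1", m1, ("z_ln_glucose",)),
        "M2a": LmeSpec("M2a", "hunger ~ z_ln_glucose", ("z_ln_glucose",)),
        "M2b": LmeSpec("M2b", "satiety ~ z_ln_glucose", ("z_ln_glucose",)),
        "M2c": LmeSpec("M2c", "z_metabolic_state ~ z_ln_glucose",
                       ("z_ln_glucose",)),
        "M3": LmeSpec("M3", "mood_state ~ z_metabolic_state",
                      ("z_metabolic_state",)),
        "M4": LmeSpec("M4", m4, ("z_ln_glucose", "z_metabolic_state")),
    }


def _needed_columns(spec: LmeSpec, data: pd.DataFrame) -> list[str]:
    cols = [c for c in data.columns
            if c == "participant_id" or c in spec.formula]
    return cols


def _attempts(spec: LmeSpec):
    """Fallback ladder: correlated REs, then uncorrelated, then intercept only."""
    if spec.re_terms:
        yield "full", "~" + " + ".join(spec.re_terms), None
        yield ("uncorrelated", "~1",
               {f"slope_{t}": f"0 + {t}" for t in spec.re_terms})
    yield "intercept_only", "~1", None


def _extract(result, spec: LmeSpec, level: str, n_groups: int,
             messages: list) -> FitResult:
    fe_names = list(result.fe_params.index)
    params = result.fe_params
    cov_all = result.cov_params()
    cov = cov_all.loc[fe_names, fe_names]
    bse = pd.Series(np.sqrt(np.diag(cov)), index=fe_names)
    df = max(n_groups - len(fe_names), 1)
    tvals = params / bse
    pvals = pd.Series(2 * stats.t.sf(np.abs(tvals), df), index=fe_names)
    tcrit = stats.t.ppf(0.975, df)
    ci = pd.DataFrame({"lower": params - tcrit * bse,
                       "upper": params + tcrit * bse})
    try:
        random_effects = dict(result.random_effects)
    except Exception:
        # singular random-effect covariance: fixed effects remain usable
        random_effects = None
        messages = messages + ["conditional modes unavailable (singular "
                               "random-effect covariance)"]
    return FitResult(
        name=spec.name, params=params, bse=bse, df=float(df),
        tvalues=tvals, pvalues=pvals, conf_int=ci, cov=cov,
        random_effects=random_effects,
        converged=bool(result.converged), fallback=level,
        n_obs=int(result.nobs), n_groups=n_groups, warnings_=messages)


def fit_lme(spec: LmeSpec, data: pd.DataFrame,
            group_col: str = "participant_id") -> FitResult:
    """Fit a mixed model per ``spec`` with the convergence fallback ladder.

    Rows with missing values in any modelled variable are dropped listwise.
    Requires >= 2 participants (no between-person variance otherwise).
    Raises ``RuntimeError`` naming the spec if every rung of the ladder
    fails.
    """
    use = data.dropna(subset=[c for c in _needed_columns(spec, data)
                              if c != group_col])
    n_groups = use[group_col].nunique()
    if n_groups < 2:
        raise ValueError(f"{spec.name}: need >= 2 participants, got {n_groups}")
    messages: list[str] = []
    last_err: Exception | None = None
    for level, re_formula, vc_formula in _attempts(spec):
        try:
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                model = smf.mixedlm(spec.formula, use, groups=use[group_col],
                                    re_formula=re_formula, vc_formula=vc_formula)
                result = model.fit(reml=spec.reml)
            msgs = [str(w.message) for w in caught]
            fe_var = np.diag(result.cov_params()
                             .iloc[:len(result.fe_params),
                                   :len(result.fe_params)])
            ok = (result.converged
                  and np.all(np.isfinite(result.fe_params))
                  and np.all(np.isfinite(fe_var)) and np.all(fe_var > 0))
            if ok:
                if level != "full" and spec.re_terms:
                    messages.append(f"fallback to {level} random effects")
                messages.extend(m for m in msgs if "onverge" in m)
                return _extract(result, spec, level, n_groups, messages)
            last_err = RuntimeError(f"{level}: did not converge")
        except Exception as err:  # singular fits raise LinAlgError etc.
            last_err = err
    raise RuntimeError(f"{spec.name}: all fits failed ({last_err})")


def _participant_slopes(fit: FitResult, term: str) -> pd.Series:
    """Fixed slope + per-participant conditional mode for ``term``."""
    fixed = float(fit.params.get(term, np.nan))
    modes = {}
    for pid, re_vals in (fit.random_effects or {}).items():
        mode = 0.0
        for key, val in re_vals.items():
            if term in str(key):
                mode = float(val)
                break
        modes[pid] = fixed + mode
    return pd.Series(modes, name="slope")


def interoceptive_accuracy(data: pd.DataFrame,
                           reverse: bool = False) -> pd.DataFrame:
    """Per-participant interoceptive accuracy scores.

    Fits z_metabolic_state ~ z_ln_glucose with a random intercept and slope,
    takes each participant's slope (fixed effect + conditional mode, i.e.
    shrunken, not a separate per-person regression) and inverts it so that
    higher scores mean ratings track glucose more closely. ``reverse``
    swaps predictor and outcome (the alternative direction sometimes used
    for such coherence scores).
    """
    if reverse:
        spec = LmeSpec("accuracy_rev", "z_ln_glucose ~ z_metabolic_state",
                       ("z_metabolic_state",))
        term = "z_metabolic_state"
    else:
        spec = LmeSpec("accuracy", "z_metabolic_state ~ z_ln_glucose",
                       ("z_ln_glucose",))
        term = "z_ln_glucose"
    fit = fit_lme(spec, data)
    if fit.random_effects is None:
        raise RuntimeError(f"{spec.name}: conditional modes unavailable")
    slopes = _participant_slopes(fit, term)
    out = pd.DataFrame({"participant_id": slopes.index,
                        "slope": slopes.to_numpy(),
                        "accuracy": -slopes.to_numpy()})
    return out.reset_index(drop=True)


def mood_summary(data: pd.DataFrame) -> pd.DataFrame:
    """Per-participant mean and sample SD of the mood composite.

    Participants with fewer than 2 mood observations get a missing SD.
    """
    g = data.groupby("participant_id")["mood_state"]
    out = pd.DataFrame({"mood_mean": g.mean(), "mood_sd": g.std(ddof=1),
                        "n_mood": g.count()})
    return out.reset_index()


def _zcol(values: pd.Series) -> np.ndarray:
    sd = values.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise ValueError(f"no variance in predictor {values.name!r}")
    return ((values - values.mean()) / sd).to_numpy()


def _ols_result(name: str, formula: str, table: pd.DataFrame) -> FitResult:
    use = table.dropna(subset=[c for c in table.columns if c in formula])
    fit = smf.ols(formula, use).fit()
    if fit.df_resid < 1:
        raise ValueError(f"{name}: more parameters than participants")
    ci = fit.conf_int()
    ci.columns = ["lower", "upper"]
    return FitResult(
        name=name, params=fit.params, bse=fit.bse, df=float(fit.df_resid),
        tvalues=fit.tvalues, pvalues=fit.pvalues, conf_int=ci,
        cov=fit.cov_params(), random_effects=None, converged=True,
        fallback="ols", n_obs=int(fit.nobs), n_groups=None)


def accuracy_models(scores: pd.DataFrame,
                    profiles: pd.DataFrame) -> dict[str, FitResult]:
    """Participant-level regressions on interoceptive accuracy.

    ``scores`` carries accuracy plus mood_mean/mood_sd; ``profiles`` carries
    bmi, age, sex and z_homa_ir_residual. Fits: mood_mean and mood_sd each
    on accuracy × (BMI + age + sex), and accuracy on
    BMI × residual-HOMA-IR × sex + age. Continuous predictors are
    z-standardised across participants.
    """
    table = scores.merge(profiles, on="participant_id")
    table = table.assign(
        z_accuracy=_zcol(table["accuracy"]),
        z_bmi=_zcol(table["bmi"]),
        z_age=_zcol(table["age"]),
    )
    out = {
        "mood_mean": _ols_result(
            "mood_mean", "mood_mean ~ z_accuracy * (z_bmi + z_age + sex)", table),
        "mood_sd": _ols_result(
            "mood_sd", "mood_sd ~ z_accuracy * (z_bmi + z_age + sex)", table),
        "accuracy": _ols_result(
            "accuracy", "accuracy ~ z_bmi * z_homa_ir_residual * sex + z_age",
            table),
    }
    return out


def sensitivity_refit(data: pd.DataFrame, profiles: pd.DataFrame,
                      exclusion: str = "either",
                      bmi_cut: float = 30.0, homa_cut: float = 2.5,
                      min_participants: int = 10,
                      n_sims: int = 10_000, seed: int = 0) -> dict:
    """Refit the model battery and mediation after metabolic exclusions.

    ``exclusion``: 'bmi' (obesity, BMI >= 30), 'homa' (elevated HOMA-IR,
    >= 2.5) or 'either'. Returns the subset fits plus estimate deltas
    versus the full sample. Raises if the subset falls below
    ``min_participants``.
    """
    flags = pd.Series(False, index=profiles.index)
    if exclusion in ("bmi", "either"):
        flags |= profiles["bmi"] >= bmi_cut
    if exclusion in ("homa", "either"):
        flags |= profiles["homa_ir_median"] >= homa_cut
    if exclusion not in ("bmi", "homa", "either"):
        raise ValueError(f"unknown exclusion {exclusion!r}")
    excluded_ids = set(profiles.loc[flags, "participant_id"])
    subset = data[~data["participant_id"].isin(excluded_ids)]
    n_left = subset["participant_id"].nunique()
    if n_left < min_participants:
        raise ValueError(f"only {n_left} participants left after exclusion")

    from glycomood.mediation import run_mediation

    specs = model_specs(extended=False)
    full_fits = {k: fit_lme(s, data) for k, s in specs.items()}
    sub_fits = {k: fit_lme(s, subset) for k, s in specs.items()}
    deltas = {}
    for k in specs:
        common = full_fits[k].params.index.intersection(sub_fits[k].params.index)
        deltas[k] = pd.DataFrame({
            "full": full_fits[k].params[common],
            "subset": sub_fits[k].params[common],
            "delta": sub_fits[k].params[common] - full_fits[k].params[common],
            "full_se": full_fits[k].bse[common],
        })
    med_full = run_mediation(data, n_sims=n_sims, seed=seed)
    med_sub = run_mediation(subset, n_sims=n_sims, seed=seed)
    return {"n_excluded": len(excluded_ids), "n_participants": n_left,
            "fits": sub_fits, "full_fits": full_fits, "deltas": deltas,
            "mediation_full": med_full, "mediation_subset": med_sub}
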