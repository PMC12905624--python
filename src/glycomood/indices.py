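"""Fasting metabolic indices and the residualised insulin-resistance covariate.

HOMA-IR = fasting glucose (mg/dL) × fasting insulin (mU/L) / 405, summarised
per participant as the median over up to three fasting draws; HOMA-IR ≥ 2.5
is flagged as elevated. Because HOMA-IR is right-skewed it is ln-transformed
for parametric use and residualised on BMI, sex and age so the covariate
isolates insulin resistance from correlates.

TyG comes in two variants: the classic ln(TG × G / 2) and a halved variant
ln(TG × G / 2) / 2; both are computed from the same draws and summarised by
the median.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = ["homa_ir", "tyg", "residualise", "derive_indices"]

ELEVATED_HOMA_IR = 2.5


def homa_ir(glucose_mg_dl, insulin_mu_l) -> np.ndarray:
    """Homeostasis model assessment of insulin resistance: G × I / 405."""
    g = np.asarray(glucose_mg_dl, dtype=float)
    i = np.asarray(insulin_mu_l, dtype=float)
    if np.any(g[np.isfinite(g)] <= 0) or np.any(i[np.isfinite(i)] <= 0):
        raise ValueError("glucose and insulin must be positive")
    return g * i / 405.0


def tyg(triglycerides_mg_dl, glucose_mg_dl, variant: str = "classic") -> np.ndarray:
    """Triglyceride–glucose index.

    ``variant='classic'``: ln(TG × G / 2); ``variant='halved'``:
    ln(TG × G / 2) / 2 (an alternative scaling seen in healthy-cohort
    descriptive tables).
    """
    tg = np.asarray(triglycerides_mg_dl, dtype=float)
    g = np.asarray(glucose_mg_dl, dtype=float)
    if np.any(tg[np.isfinite(tg)] <= 0) or np.any(g[np.isfinite(g)] <= 0):
        raise ValueError("triglycerides and glucose must be positive")
    value = np.log(tg * g / 2.0)
    if variant == "classic":
        return value
    if variant == "halved":
        return value / 2.0
    raise ValueError(f"unknown TyG variant: {variant!r}")


def residualise(index_values, covariates: pd.DataFrame) -> np.ndarray:
    """OLS residuals of an (ln-transformed) index on the covariate columns.

    Residuals are exactly orthogonal to every covariate in-sample; a
    near-singular design raises with the condition number. Being a
    projection, applying this twice equals applying it once.
    """
    y = np.asarray(index_values, dtype=float)
    X = sm.add_constant(pd.get_dummies(covariates, drop_first=True, dtype=float))
    cond = np.linalg.cond(X.to_numpy())
    if cond > 1e10:
        raise ValueError(f"collinear covariates (condition number {cond:.3g})")
    fit = sm.OLS(y, X, missing="raise").fit()
    return np.asarray(fit.resid)


def derive_indices(participants: pd.DataFrame, n_draws: int = 3,
                   tyg_variant: str = "halved") -> pd.DataFrame:
    """Participant-level derived indices from the fasting-draw columns.

    Expects ``fasting_glucose_j`` / ``fasting_insulin_j`` /
    ``triglycerides_j`` (j = 1..n_draws; missing draws allowed) plus ``bmi``,
    ``sex``, ``age``. Adds median HOMA-IR, its ln transform, the elevated
    flag, median TyG, the residualised (on BMI + sex + age) ln-HOMA-IR and
    its z-standardised version for modelling.
    """
    out = participants.copy()
    homa_draws, tyg_draws = [], []
    for j in range(1, n_draws + 1):
        g = out.get(f"fasting_glucose_{j}")
        i = out.get(f"fasting_insulin_{j}")
        t = out.get(f"triglycerides_{j}")
        if g is None or i is None:
            homa_draws.append(pd.Series(np.nan, index=out.index))
        else:
            valid = g.notna() & i.notna()
            homa_draws.append(pd.Series(
                np.where(valid, g.fillna(1) * i.fillna(1) / 405.0, np.nan),
                index=out.index))
        if g is None or t is None:
            tyg_draws.append(pd.Series(np.nan, index=out.index))
        else:
            valid = g.notna() & t.notna()
            tyg_draws.append(pd.Series(
                np.where(valid,
                         tyg(t.fillna(1), g.fillna(1), tyg_variant), np.nan),
                index=out.index))
    out["homa_ir_median"] = pd.concat(homa_draws, axis=1).median(axis=1)
    out["tyg_median"] = pd.concat(tyg_draws, axis=1).median(axis=1)
    out["ln_homa_ir"] = np.log(out["homa_ir_median"])
    out["elevated_homa_ir"] = out["homa_ir_median"] >= ELEVATED_HOMA_IR
    cov = out[["bmi", "sex", "age"]]
    complete = out["ln_homa_ir"].notna() & cov.notna().all(axis=1)
    resid = np.full(len(out), np.nan)
    resid[complete.to_numpy()] = residualise(out.loc[complete, "ln_homa_ir"],
                                             cov.loc[complete])
    out["homa_ir_residual"] = resid
    sd = np.nanstd(resid, ddof=1)
    out["z_homa_ir_residual"] = (resid - np.nanmean(resid)) / sd
    return out
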