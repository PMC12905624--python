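"""Quasi-Bayesian multilevel mediation: glucose → metabolic state → mood.

The decomposition follows the product-of-coefficients structure for linear
models without a treatment–mediator interaction. Two mixed models supply
the paths:

* mediator model:  z_metabolic_state ~ z_ln_glucose  (slope a)
* outcome model:   mood_state ~ z_ln_glucose + z_metabolic_state
  (mediator slope b, direct slope c')

Uncertainty is propagated by Monte Carlo: parameter vectors are drawn from
each model's asymptotic sampling distribution (multivariate normal over the
fixed effects with the estimated covariance; random-effect uncertainty
enters through that covariance). Per draw, ACME = a·b, ADE = c',
total = ACME + ADE (exact additivity), proportion mediated = ACME / total.
Point estimates are per-quantity medians of the draws; intervals are
2.5/97.5 percentiles; p-values are twice the smaller tail share of draws on
either side of zero. The ratio is summarised only over draws whose total
effect is bounded away from zero (excluded draws are counted), and an
instability flag is raised whenever the total effect's interval covers
zero — the regime in which the proportion mediated is ill-determined and
its interval expectedly wide.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from glycomood.inference import FitResult, LmeSpec, fit_lme

__all__ = [
    "MediationInput",
    "MediationResult",
    "quasi_bayesian_mediate",
    "proportion_mediated",
    "run_mediation",
]


@dataclass(frozen=True)
class MediationInput:
    """Fitted mediator and outcome models plus Monte-Carlo settings."""

    mediator_fit: FitResult
    outcome_fit: FitResult
    treatment: str = "z_ln_glucose"
    mediator: str = "z_metabolic_state"
    n_sims: int = 10_000
    seed: int = 0

    def validate(self) -> None:
        if self.n_sims < 1_000:
            raise ValueError("n_sims must be >= 1000")
        if self.treatment not in self.mediator_fit.params.index:
            raise ValueError("treatment term missing from mediator model")
        for term in (self.treatment, self.mediator):
            if term not in self.outcome_fit.params.index:
                raise ValueError(f"{term!r} missing from outcome model")


@dataclass
class _Summary:
    estimate: float
    ci_lower: float
    ci_upper: float
    p_value: float


@dataclass
class MediationResult:
    """ACME/ADE/total/proportion-mediated summaries with per-draw arrays."""

    acme: _Summary
    ade: _Summary
    total: _Summary
    prop_mediated: _Summary
    draws: dict = field(default_factory=dict)   # name -> np.ndarray
    n_sims: int = 0
    n_ratio_excluded: int = 0
    ratio_unstable: bool = False

    def to_dict(self) -> dict:
        def unpack(s: _Summary) -> dict:
            return {"estimate": s.estimate, "ci_lower": s.ci_lower,
                    "ci_upper": s.ci_upper, "p_value": s.p_value}
        return {
            "acme": unpack(self.acme), "ade": unpack(self.ade),
            "total": unpack(self.total),
            "prop_mediated": unpack(self.prop_mediated),
            "n_sims": self.n_sims,
            "n_ratio_excluded": self.n_ratio_excluded,
            "ratio_unstable": self.ratio_unstable,
        }


def _summarise(draws: np.ndarray) -> _Summary:
    lo, hi = np.percentile(draws, [2.5, 97.5])
    p = 2.0 * min(np.mean(draws <= 0), np.mean(draws >= 0))
    return _Summary(float(np.median(draws)), float(lo), float(hi),
                    float(min(p, 1.0)))


def _draw_fixed_effects(fit: FitResult, n: int,
                        rng: np.random.Generator) -> pd.DataFrame:
    mean = fit.params.to_numpy()
    cov = fit.cov.to_numpy()
    if not np.all(np.isfinite(cov)):
        raise ValueError(f"{fit.name}: fixed-effect covariance unavailable")
    cov = (cov + cov.T) / 2.0
    draws = rng.multivariate_normal(mean, cov, size=n, method="svd")
    return pd.DataFrame(draws, columns=fit.params.index)


def quasi_bayesian_mediate(inp: MediationInput) -> MediationResult:
    """Monte-Carlo decomposition of the treatment effect.

    See module docstring for the algorithm; every draw satisfies
    ACME + ADE = total exactly.
    """
    inp.validate()
    rng = np.random.default_rng(inp.seed)
    med_draws = _draw_fixed_effects(inp.mediator_fit, inp.n_sims, rng)
    out_draws = _draw_fixed_effects(inp.outcome_fit, inp.n_sims, rng)
    a = med_draws[inp.treatment].to_numpy()
    b = out_draws[inp.mediator].to_numpy()
    c_prime = out_draws[inp.treatment].to_numpy()
    acme = a * b
    ade = c_prime
    total = acme + ade

    result = MediationResult(
        acme=_summarise(acme), ade=_summarise(ade), total=_summarise(total),
        prop_mediated=_Summary(np.nan, np.nan, np.nan, np.nan),
        draws={"a": a, "b": b, "c_prime": c_prime, "acme": acme,
               "ade": ade, "total": total},
        n_sims=inp.n_sims,
    )
    prop, n_excluded, unstable = proportion_mediated(acme, total)
    result.prop_mediated = prop
    result.n_ratio_excluded = n_excluded
    result.ratio_unstable = unstable
    result.draws["prop_mediated"] = acme / np.where(
        np.abs(total) > 0, total, np.nan)
    return result


def proportion_mediated(acme_draws: np.ndarray, total_draws: np.ndarray):
    """Summarise the per-draw ratio ACME / total.

    Draws whose |total| falls below a machine-scaled epsilon are excluded
    and counted; the summary is the median plus percentile interval over
    the remaining draws. The instability flag is raised when the total
    effect's own 95% interval covers zero (ratio sign flips expected, wide
    interval). Raises if every draw is excluded.
    """
    acme_draws = np.asarray(acme_draws, dtype=float)
    total_draws = np.asarray(total_draws, dtype=float)
    scale = max(1.0, float(np.max(np.abs(total_draws), initial=0.0)))
    eps = np.sqrt(np.finfo(float).eps) * scale
    keep = np.abs(total_draws) > eps
    n_excluded = int((~keep).sum())
    if keep.sum() == 0:
        raise ValueError("all draws excluded: total effect numerically zero")
    ratio = acme_draws[keep] / total_draws[keep]
    lo, hi = np.percentile(total_draws, [2.5, 97.5])
    unstable = bool(lo <= 0.0 <= hi)
    return _summarise(ratio), n_excluded, unstable


def run_mediation(data: pd.DataFrame, n_sims: int = 10_000, seed: int = 0,
                  treatment: str = "z_ln_glucose",
                  mediator: str = "z_metabolic_state",
                  outcome: str = "mood_state") -> MediationResult:
    """Fit the mediator and outcome mixed models on an aligned table and run
    the quasi-Bayesian decomposition."""
    med_spec = LmeSpec("mediator", f"{mediator} ~ {treatment}", (treatment,))
    out_spec = LmeSpec("outcome", f"{outcome} ~ {treatment} + {mediator}",
                       (treatment, mediator))
    med_fit = fit_lme(med_spec, data)
    out_fit = fit_lme(out_spec, data)
    return quasi_bayesian_mediate(MediationInput(
        mediator_fit=med_fit, outcome_fit=out_fit, treatment=treatment,
        mediator=mediator, n_sims=n_sims, seed=seed))
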