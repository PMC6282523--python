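"""Stabilized inverse-probability-of-treatment weights.

For a treatment history A_0..A_K, the stabilized weight of subject i is

    sw_i = prod_k [ p*_ki^a_ki (1-p*_ki)^(1-a_ki) ]
         / prod_k [ p_ki^a_ki (1-p_ki)^(1-a_ki) ]

where p*_ki is the fitted probability from the *numerator* model
logit P(A_k = 1 | A_{k-1}, X_0)  (lagged treatment + baseline covariates)
and p_ki from the *denominator* model
logit P(A_k = 1 | A_{k-1}, X-bar_k)  (lagged treatment + full covariate
history), with a_{-1} = 0.  Weighting the cohort by sw breaks the
covariate -> treatment arrows while the numerator keeps the weights
stable (mean ~= 1).

At k = 0 there is no lagged treatment and the only covariate is X_0, so
numerator and denominator designs coincide and their per-subject factors
cancel exactly; both models are still fitted for diagnostics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .cpm_fit import FitError, _newton_logistic

__all__ = [
    "TreatmentModel",
    "TreatmentModelPair",
    "StabilizedWeights",
    "fit_treatment_models",
    "compute_stabilized_weights",
    "stabilized_weight_factors",
    "PROB_CLIP",
]

#: fitted probabilities are clipped to [PROB_CLIP, 1 - PROB_CLIP] before
#: forming weight ratios, so structural zeros (e.g. RCT never-starters)
#: cannot produce infinite weights
PROB_CLIP = 1e-6


@dataclass
class TreatmentModel:
    """One fitted logistic treatment-assignment model."""

    columns: tuple[str, ...]  # design columns after the intercept
    coef: np.ndarray  # intercept first, then `columns`

    def predict(self, df: pd.DataFrame) -> np.ndarray:
        X = np.column_stack([np.ones(len(df))] + [df[c].to_numpy(float) for c in self.columns])
        return expit(X @ self.coef)


def _fit_logit(df: pd.DataFrame, outcome: str, columns: tuple[str, ...]) -> TreatmentModel:
    X = np.column_stack([np.ones(len(df))] + [df[c].to_numpy(float) for c in columns])
    y = df[outcome].to_numpy(float)
    fit = _newton_logistic(X, y)
    if not fit.converged or not np.all(np.isfinite(fit.coef)):
        raise FitError(
            f"treatment model for {outcome!r} on {columns} did not converge "
            "(possible perfect separation)"
        )
    return TreatmentModel(columns=columns, coef=fit.coef)


@dataclass
class TreatmentModelPair:
    """Numerator/denominator treatment models for each timepoint k = 0, 1.

    ``absorbing=True`` means treatment is an absorbing state (once treated,
    always treated): the time-1 models are then fitted only on the
    at-risk-of-initiation rows (a0 = 0) without the structurally redundant
    lagged-treatment term, and the time-1 factor for already-treated
    subjects is exactly 1.
    """

    numerator: dict[int, TreatmentModel]
    denominator: dict[int, TreatmentModel]
    absorbing: bool = False


def fit_treatment_models(cohort: pd.DataFrame, *, absorbing: bool = False) -> TreatmentModelPair:
    """Fit the numerator and denominator treatment models on a two-timepoint cohort.

    Requires both treated and untreated subjects at each timepoint; an
    all-treated or all-untreated timepoint leaves the model degenerate and
    is rejected.  Quasi-separation from structural zeros (the RCT rule
    "untreated at baseline stay untreated") is tolerated: the fit converges
    with the separated predictions numerically at 0, which is exactly the
    probability the mechanism implies.
    """
    for col in ("a0", "a1"):
        vals = cohort[col].to_numpy()
        if np.all(vals == vals[0]):
            raise ValueError(f"cohort is degenerate: {col} is constant ({vals[0]:g})")

    # k = 0: a_{-1} == 0 drops the lagged term; numerator and denominator
    # designs coincide (only covariate is x0), so fit once and share.
    k0 = _fit_logit(cohort, "a0", ("x0",))
    numerator = {0: k0}
    denominator = {0: k0}

    if absorbing:
        at_risk = cohort[cohort["a0"] == 0]
        if at_risk["a1"].nunique() < 2:
            raise ValueError("absorbing: no variation in treatment initiation at time 1")
        numerator[1] = _fit_logit(at_risk, "a1", ("x0",))
        denominator[1] = _fit_logit(at_risk, "a1", ("x0", "x1"))
    else:
        numerator[1] = _fit_logit(cohort, "a1", ("a0", "x0"))
        denominator[1] = _fit_logit(cohort, "a1", ("a0", "x0", "x1"))
    return TreatmentModelPair(numerator=numerator, denominator=denominator, absorbing=absorbing)


def stabilized_weight_factors(
    p_num: np.ndarray, p_den: np.ndarray, a: np.ndarray, clip: float = PROB_CLIP
) -> np.ndarray:
    """Per-timepoint stabilized-weight factor for observed treatment ``a``.

    factor = [p*_k^a (1-p*_k)^(1-a)] / [p_k^a (1-p_k)^(1-a)], with both
    probabilities clipped away from {0, 1}.
    """
    pn = np.clip(np.asarray(p_num, float), clip, 1.0 - clip)
    pd_ = np.clip(np.asarray(p_den, float), clip, 1.0 - clip)
    a = np.asarray(a, float)
    return np.where(a == 1, pn / pd_, (1.0 - pn) / (1.0 - pd_))


@dataclass
class StabilizedWeights:
    """Per-subject stabilized weights, with per-timepoint factors retained."""

    sw: np.ndarray
    factors: dict[int, np.ndarray] = field(default_factory=dict)
    n_clipped: int = 0

    def summary(self) -> dict[str, float]:
        """Weight diagnostics (min/max/mean/SD and tail quantiles)."""
        q01, q99 = np.quantile(self.sw, [0.01, 0.99])
        return {
            "n": int(len(self.sw)),
            "min": float(self.sw.min()),
            "max": float(self.sw.max()),
            "mean": float(self.sw.mean()),
            "sd": float(self.sw.std(ddof=1)),
            "q01": float(q01),
            "q99": float(q99),
            "n_clipped": int(self.n_clipped),
        }

    def summary_json(self) -> str:
        return json.dumps(self.summary(), indent=2)


def compute_stabilized_weights(
    cohort: pd.DataFrame,
    models: TreatmentModelPair,
    *,
    clip: float = PROB_CLIP,
    truncate: tuple[float, float] | None = None,
) -> StabilizedWeights:
    """Evaluate the stabilized-weight formula for every subject.

    Each factor uses the subject's own observed history.  ``truncate``
    optionally winsorizes the final weights at the given (lower, upper)
    percentiles, e.g. ``(1, 99)``; the default is untruncated.
    """
    factors: dict[int, np.ndarray] = {}
    n_clipped = 0
    for k, (treat_col,) in ((0, ("a0",)), (1, ("a1",))):
        a = cohort[treat_col].to_numpy(float)
        if models.absorbing and k == 1:
            at_risk = cohort["a0"].to_numpy(float) == 0
            f = np.ones(len(cohort))
            sub = cohort[at_risk]
            pn = models.numerator[1].predict(sub)
            pd_ = models.denominator[1].predict(sub)
            n_clipped += int(np.sum((pn < clip) | (pn > 1 - clip) | (pd_ < clip) | (pd_ > 1 - clip)))
            f[at_risk] = stabilized_weight_factors(pn, pd_, a[at_risk], clip)
        else:
            pn = models.numerator[k].predict(cohort)
            pd_ = models.denominator[k].predict(cohort)
            n_clipped += int(np.sum((pn < clip) | (pn > 1 - clip) | (pd_ < clip) | (pd_ > 1 - clip)))
            f = stabilized_weight_factors(pn, pd_, a, clip)
        factors[k] = f
    sw = factors[0] * factors[1]
    if truncate is not None:
        lo, hi = np.percentile(sw, truncate)
        sw = np.clip(sw, lo, hi)
    if np.any(sw <= 0) or not np.all(np.isfinite(sw)):
        raise FitError("non-positive or non-finite stabilized weights")
    return StabilizedWeights(sw=sw, factors=factors, n_clipped=n_clipped)
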