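"""Predictive-performance metrics and the three evaluation settings.

Calibration is measured on the log-odds scale:

* calibration-in-the-large (CITL): the intercept of a logistic regression
  of the outcome on the model's linear predictor entered as a fixed
  offset.  0 means observed and predicted rates agree; positive means the
  model under-predicts.
* calibration slope: the coefficient of the linear predictor in a
  univariate logistic recalibration; 1 for a perfectly calibrated model.

Discrimination is the exact Mann-Whitney AUC (probability that a random
event outranks a random non-event, ties counted half), and overall
accuracy the Brier score.

Models are evaluated under three settings:

* MT  ("mix of treatment")   — observed-regime predictions on a test
  cohort drawn like the development data (estimand E1);
* NBT ("no baseline treatment") — the same cohort restricted to subjects
  untreated at baseline (E2);
* NTT ("no treatment throughout") — a cohort in which treatment is
  withheld from everyone, with predictions under the never-treated
  regime (the treatment-naive estimand E3).  Only under NTT is the
  treatment-allocation curve computed: the fraction of subjects whose
  predicted treatment-naive risk exceeds each threshold in a 5%-70% grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import rankdata

from .cpm_fit import FittedCPM, NEVER_TREATED, OBSERVED, Regime, _newton_logistic, FitError, linear_predictor
from .synthetic_dgm import subset_nbt

__all__ = [
    "SETTINGS",
    "DEFAULT_THRESHOLDS",
    "PerformanceReport",
    "calibration_in_the_large",
    "calibration_slope",
    "auc",
    "brier",
    "treatment_allocation",
    "evaluate",
]

SETTINGS = ("MT", "NBT", "NTT")

#: treatment thresholds "from 5% to 70%", in steps of 5 percentage points
DEFAULT_THRESHOLDS = tuple(np.round(np.arange(0.05, 0.7001, 0.05), 2))


def _check_binary_mixed(y: np.ndarray) -> None:
    if y.min() < 0 or y.max() > 1 or not np.all((y == 0) | (y == 1)):
        raise ValueError("y must be binary (0/1)")
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("need at least one event and one non-event")


def calibration_in_the_large(y, linear_predictor) -> float:
    """Intercept of logit(y) ~ offset(lp): positive means under-prediction."""
    y = np.asarray(y, float)
    lp = np.asarray(linear_predictor, float)
    _check_binary_mixed(y)
    X = np.ones((len(y), 1))
    fit = _newton_logistic(X, y, offset=lp)
    if not fit.converged:
        raise FitError("CITL recalibration fit did not converge")
    return float(fit.coef[0])


def calibration_slope(y, linear_predictor) -> float:
    """Slope of logit(y) ~ lp: 1 for a perfectly calibrated model."""
    y = np.asarray(y, float)
    lp = np.asarray(linear_predictor, float)
    _check_binary_mixed(y)
    if np.var(lp) == 0:
        raise ValueError("calibration slope is undefined for a constant linear predictor")
    X = np.column_stack([np.ones(len(y)), lp])
    fit = _newton_logistic(X, y)
    if not fit.converged:
        raise FitError("calibration-slope fit did not converge")
    return float(fit.coef[1])


def auc(y, risk) -> float:
    """Exact Mann-Whitney AUC, ties counted half."""
    y = np.asarray(y, float)
    r = np.asarray(risk, float)
    _check_binary_mixed(y)
    ranks = rankdata(r)
    n1 = int(y.sum())
    n0 = len(y) - n1
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def brier(y, risk) -> float:
    """Mean squared difference between predicted risk and outcome."""
    y = np.asarray(y, float)
    r = np.asarray(risk, float)
    return float(np.mean((r - y) ** 2))


def treatment_allocation(e3_risk, thresholds=DEFAULT_THRESHOLDS) -> dict[float, float]:
    """Fraction of subjects whose treatment-naive risk exceeds each threshold."""
    r = np.asarray(e3_risk, float)
    if len(r) == 0:
        raise ValueError("empty risk vector")
    t = np.asarray(thresholds, float)
    if np.any(t <= 0) or np.any(t >= 1) or np.any(np.diff(t) <= 0):
        raise ValueError("thresholds must be strictly increasing within (0, 1)")
    return {float(ti): float(np.mean(r > ti)) for ti in t}


@dataclass
class PerformanceReport:
    """Metric values for one model in one performance setting."""

    setting: str
    citl: float
    cal_slope: float
    auc: float
    brier: float
    n_eval: int
    allocation: dict[float, float] | None = None

    def to_dict(self) -> dict:
        d = {
            "setting": self.setting,
            "citl": self.citl,
            "cal_slope": self.cal_slope,
            "auc": self.auc,
            "brier": self.brier,
            "n_eval": self.n_eval,
        }
        if self.allocation is not None:
            d["allocation"] = {f"{k:.2f}": v for k, v in self.allocation.items()}
        return d


def evaluate(
    model: FittedCPM,
    setting: str,
    test_mt: pd.DataFrame | None = None,
    test_ntt: pd.DataFrame | None = None,
    thresholds=DEFAULT_THRESHOLDS,
) -> PerformanceReport:
    """Evaluate a fitted model in one of the MT / NBT / NTT settings.

    MT and NBT need ``test_mt`` (a cohort drawn like the development
    data); NTT needs ``test_ntt`` (the never-treated cohort).  Predictions
    use the observed regime for MT/NBT and the never-treated regime for
    NTT; treatment-free models (ignore / naive) carry their linear
    predictor unchanged across settings.
    """
    if setting not in SETTINGS:
        raise ValueError(f"setting must be one of {SETTINGS}")
    if setting in ("MT", "NBT"):
        if test_mt is None:
            raise ValueError(f"setting {setting} requires test_mt")
        data = test_mt if setting == "MT" else subset_nbt(test_mt)
        regime: Regime = OBSERVED
    else:
        if test_ntt is None:
            raise ValueError("setting NTT requires test_ntt")
        data = test_ntt
        regime = NEVER_TREATED

    lp = linear_predictor(model, data, regime)
    risk = expit(lp)
    y = data["y"].to_numpy(float)
    allocation = treatment_allocation(risk, thresholds) if setting == "NTT" else None
    return PerformanceReport(
        setting=setting,
        citl=calibration_in_the_large(y, lp),
        cal_slope=calibration_slope(y, lp),
        auc=auc(y, risk),
        brier=brier(y, risk),
        n_eval=len(data),
        allocation=allocation,
    )
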