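"""Prediction-model strategies for cohorts with treatment drop-in.

Implements the four competing ways of handling treatment when developing a
clinical prediction model (CPM) on a two-timepoint cohort:

``ignore``
    logit E[Y | X0] = b0 + bx*x0, fitted on every subject.
``naive``
    the same design, fitted only on subjects untreated at baseline
    (the "treatment-naive" cohort).
``baseline_treatment``
    adds a baseline-treatment term: b0 + bx*x0 + ba0*a0.
``msm``
    the marginal structural model — adds the full treatment pathway
    (b0 + bx*x0 + ba0*a0 + ba1*a1) and is fitted by *weighted* maximum
    likelihood with stabilized inverse-probability-of-treatment weights,
    so the fitted treatment coefficients carry a causal interpretation.

The numerical core, :func:`weighted_logistic_mle`, maximizes the
weight-multiplied Bernoulli log-likelihood

    l(beta) = sum_i sw_i * [y_i log(pi_i) + (1 - y_i) log(1 - pi_i)]

by Newton-Raphson with step-halving.  It is the single logistic optimizer
used throughout the package (weight models, recalibration fits, pooled
discrete-time models), which keeps the simulation pipeline deterministic
and fast.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = [
    "FitError",
    "LogisticFit",
    "weighted_logistic_mle",
    "FittedCPM",
    "Regime",
    "OBSERVED",
    "NEVER_TREATED",
    "UNTREATED_NOW",
    "TREATED_NOW",
    "ALWAYS_TREATED",
    "STRATEGIES",
    "fit_strategy",
    "linear_predictor",
    "predict_risk",
]

STRATEGIES = ("ignore", "naive", "baseline_treatment", "msm")


class FitError(RuntimeError):
    """A logistic fit could not be completed (rank deficiency, divergence...)."""


# ---------------------------------------------------------------------------
# Newton-Raphson weighted logistic regression
# ---------------------------------------------------------------------------


@dataclass
class LogisticFit:
    """Raw result of a Newton-Raphson logistic fit."""

    coef: np.ndarray
    converged: bool
    n_iter: int
    loglik: float


def _loglik(eta: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    # w * (y*eta - log(1 + exp(eta))), computed stably
    return float(np.sum(w * (y * eta - np.logaddexp(0.0, eta))))


def _newton_logistic(
    X: np.ndarray,
    y: np.ndarray,
    weights: np.ndarray | None = None,
    offset: np.ndarray | None = None,
    max_iter: int = 100,
    ll_tol: float = 1e-8,
    grad_tol: float = 1e-6,
) -> LogisticFit:
    """Newton-Raphson with step-halving; lstsq fallback for singular Hessians.

    Quasi-separated data (e.g. a structural zero such as "untreated at
    baseline never treated at follow-up" in an RCT) drives some linear
    predictors to -inf; the step-halving iteration then converges in the
    |delta loglik| sense with the remaining coefficients at their MLE and
    the separated predictions numerically at 0/1, which is the behaviour
    required for stable weight ratios.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    off = np.zeros(n) if offset is None else np.asarray(offset, dtype=float)

    beta = np.zeros(p)
    eta = off + X @ beta
    ll = _loglik(eta, y, w)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        mu = expit(eta)
        grad = X.T @ (w * (y - mu))
        if np.max(np.abs(grad)) < grad_tol:
            converged = True
            break
        wt = w * mu * (1.0 - mu)
        H = X.T @ (X * wt[:, None])
        try:
            step = np.linalg.solve(H, grad)
            if not np.all(np.isfinite(step)):
                raise np.linalg.LinAlgError
        except np.linalg.LinAlgError:
            step, *_ = np.linalg.lstsq(H, grad, rcond=None)
        # step-halving line search on the log-likelihood
        t = 1.0
        cand, eta_c, ll_c = beta, eta, ll
        for _ in range(30):
            cand = beta + t * step
            eta_c = off + X @ cand
            ll_c = _loglik(eta_c, y, w)
            if ll_c >= ll - 1e-12:
                break
            t *= 0.5
        beta, eta = cand, eta_c
        if abs(ll_c - ll) < ll_tol:
            ll = ll_c
            converged = True
            break
        ll = ll_c
    return LogisticFit(coef=beta, converged=converged, n_iter=it, loglik=ll)


def _check_rank(X: np.ndarray, names: Sequence[str] | None = None) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        import scipy.linalg

        _, _, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
        bad = sorted(piv[rank:])
        label = [names[j] if names else str(j) for j in bad]
        raise FitError(f"design matrix is rank deficient; offending columns: {label}")


def weighted_logistic_mle(
    design_matrix: np.ndarray,
    y: np.ndarray,
    weights: np.ndarray | None = None,
    offset: np.ndarray | None = None,
    *,
    column_names: Sequence[str] | None = None,
    max_iter: int = 100,
) -> np.ndarray:
    """Maximize the weighted Bernoulli log-likelihood; return the coefficients.

    Parameters
    ----------
    design_matrix : (n, p) array, full column rank (include the intercept
        column explicitly).
    y : binary outcome vector.
    weights : strictly positive per-observation weights (stabilized weights
        for an MSM fit); ``None`` means ordinary maximum likelihood.
    offset : optional fixed offset added to the linear predictor (used by
        the calibration-in-the-large recalibration fit).

    Raises
    ------
    FitError
        on rank deficiency (offending columns identified) or if the
        iteration fails to converge within ``max_iter`` steps.
    """
    X = np.asarray(design_matrix, dtype=float)
    yv = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] != yv.shape[0]:
        raise ValueError("design_matrix and y have incompatible shapes")
    if not np.all((yv == 0) | (yv == 1)):
        raise ValueError("y must be binary (0/1)")
    if weights is not None:
        wv = np.asarray(weights, dtype=float)
        if np.any(wv <= 0) or not np.all(np.isfinite(wv)):
            raise ValueError("weights must be strictly positive and finite")
    _check_rank(X, column_names)
    fit = _newton_logistic(X, yv, weights, offset, max_iter=max_iter)
    if not fit.converged:
        raise FitError(f"logistic fit did not converge in {max_iter} iterations")
    return fit.coef


# ---------------------------------------------------------------------------
# Treatment regimes (the estimand being predicted)
# ---------------------------------------------------------------------------

_REGIME_VALUES = (0, 1, "observed")


@dataclass(frozen=True)
class Regime:
    """Treatment setting under which a risk is predicted.

    ``a0`` / ``a1`` are each 0, 1 or ``"observed"``.  The estimand ladder:
    observed/observed evaluates the model as fitted (E1/E2 settings);
    (0, 0) is the treatment-naive risk E3; (1, "observed") and (1, 1)
    correspond to treat-now (E4) and sustained treatment (E5).
    """

    a0: int | str = "observed"
    a1: int | str = "observed"

    def __post_init__(self) -> None:
        for v in (self.a0, self.a1):
            if v not in _REGIME_VALUES:
                raise ValueError(f"regime values must be 0, 1 or 'observed'; got {v!r}")


OBSERVED = Regime("observed", "observed")
NEVER_TREATED = Regime(0, 0)  # E3
UNTREATED_NOW = Regime(0, "observed")  # E2
TREATED_NOW = Regime(1, "observed")  # E4
ALWAYS_TREATED = Regime(1, 1)  # E5


# ---------------------------------------------------------------------------
# Strategy fitting
# ---------------------------------------------------------------------------


@dataclass
class FittedCPM:
    """A fitted prediction model: strategy tag + named coefficients."""

    strategy: str
    coefs: dict[str, float]
    converged: bool = True
    n_used: int = 0
    weighted: bool = False
    dropped: tuple[str, ...] = field(default_factory=tuple)

    def to_json(self) -> str:
        return json.dumps(
            {
                "strategy": self.strategy,
                "coefs": self.coefs,
                "converged": self.converged,
                "n_used": self.n_used,
                "weighted": self.weighted,
                "dropped": list(self.dropped),
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "FittedCPM":
        d = json.loads(text)
        return cls(
            strategy=d["strategy"],
            coefs={k: float(v) for k, v in d["coefs"].items()},
            converged=bool(d.get("converged", True)),
            n_used=int(d.get("n_used", 0)),
            weighted=bool(d.get("weighted", False)),
            dropped=tuple(d.get("dropped", ())),
        )


def _strategy_terms(strategy: str, interactions: bool) -> list[str]:
    terms = ["intercept", "x0"]
    if strategy == "baseline_treatment":
        terms += ["a0"]
        if interactions:
            terms += ["a0:x0"]
    elif strategy == "msm":
        terms += ["a0", "a1"]
        if interactions:
            terms += ["a0:x0", "a1:x0"]
    return terms


def _term_column(df: pd.DataFrame, term: str) -> np.ndarray:
    if term == "intercept":
        return np.ones(len(df))
    if ":" in term:
        a, b = term.split(":")
        return df[a].to_numpy(float) * df[b].to_numpy(float)
    return df[term].to_numpy(float)


def fit_strategy(
    cohort: pd.DataFrame,
    strategy: str,
    weights=None,
    *,
    interactions: bool = False,
) -> FittedCPM:
    """Fit one of the four prediction-model strategies on a two-timepoint cohort.

    ``weights`` (stabilized weights — a :class:`~msmcpm.weight_engine.
    StabilizedWeights` or a plain array aligned to the cohort rows) are
    required for ``strategy="msm"`` and rejected for the unweighted
    strategies.

    Treatment design columns that are identically zero in the fitting data
    (e.g. ``a1`` in a cohort with no follow-up treatment) are dropped and
    reported with coefficient 0, so degenerate cohorts still yield a usable
    model rather than a rank-deficiency error.
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; expected one of {STRATEGIES}")
    if strategy == "msm":
        if weights is None:
            raise ValueError("strategy 'msm' requires stabilized weights")
    elif weights is not None:
        raise ValueError(f"strategy {strategy!r} is fitted unweighted; do not pass weights")

    sw = None
    if weights is not None:
        sw = np.asarray(getattr(weights, "sw", weights), dtype=float)
        if len(sw) != len(cohort):
            raise ValueError("weights are not aligned to the cohort")

    df = cohort
    if strategy == "naive":
        df = cohort[cohort["a0"] == 0]
        if len(df) == 0:
            raise ValueError("naive strategy: no untreated-at-baseline rows to fit on")

    terms = _strategy_terms(strategy, interactions)
    kept, dropped = [], []
    for t in terms:
        col = _term_column(df, t)
        if t != "intercept" and ("a0" in t or "a1" in t) and np.all(col == 0):
            dropped.append(t)
        else:
            kept.append(t)
    X = np.column_stack([_term_column(df, t) for t in kept])
    y = df["y"].to_numpy(float)

    fit = _newton_logistic(X, y, weights=sw)
    if not fit.converged:
        raise FitError(f"strategy {strategy!r}: outcome model did not converge")
    coefs = {t: float(b) for t, b in zip(kept, fit.coef)}
    for t in dropped:
        coefs[t] = 0.0
    return FittedCPM(
        strategy=strategy,
        coefs=coefs,
        converged=fit.converged,
        n_used=len(df),
        weighted=sw is not None,
        dropped=tuple(dropped),
    )


# ---------------------------------------------------------------------------
# Prediction under a regime
# ---------------------------------------------------------------------------


def _treatment_value(model: FittedCPM, term: str, setting, data: pd.DataFrame) -> np.ndarray:
    has_term = term in model.coefs
    if setting == "observed":
        if not has_term:
            return np.zeros(len(data))  # treatment-free model disregards it
        if term not in data.columns:
            raise ValueError(f"regime 'observed' for {term} needs column {term!r} in the data")
        return data[term].to_numpy(float)
    val = float(setting)
    if not has_term and val != 0.0:
        raise ValueError(
            f"regime sets {term}={val:g} but the {model.strategy!r} model has no {term} term"
        )
    return np.full(len(data), val)


def linear_predictor(model: FittedCPM, data: pd.DataFrame, regime: Regime = OBSERVED) -> np.ndarray:
    """Linear predictor of ``model`` on ``data`` with treatment fixed per ``regime``."""
    if not model.converged:
        raise FitError("cannot predict from a non-converged model")
    x0 = data["x0"].to_numpy(float)
    a0 = _treatment_value(model, "a0", regime.a0, data)
    a1 = _treatment_value(model, "a1", regime.a1, data)
    vals = {"intercept": np.ones(len(data)), "x0": x0, "a0": a0, "a1": a1,
            "a0:x0": a0 * x0, "a1:x0": a1 * x0}
    lp = np.zeros(len(data))
    for term, beta in model.coefs.items():
        lp += beta * vals[term]
    return lp


def predict_risk(model: FittedCPM, data: pd.DataFrame, regime: Regime = OBSERVED) -> np.ndarray:
    """Predicted outcome probability under the given treatment regime."""
    return expit(linear_predictor(model, data, regime))
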