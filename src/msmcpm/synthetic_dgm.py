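"""Two-timepoint synthetic cohorts with treatment drop-in.

The data-generating mechanism has one continuous covariate and one binary
treatment, each measured at baseline (time 0) and once more before the
binary outcome is observed:

1. X0 ~ N(0, 1)
2. A0 ~ Bernoulli(expit(alpha0 + phi*x0))
3. X1 ~ N(X0 + gamma*A0, 1)        (gamma: covariate-lowering treatment effect)
4. A1 ~ Bernoulli(expit(alpha1 + phi*x1 + theta*a0))   observational design
   A1 ~ Bernoulli(theta * a0)                          RCT design
5. Y  ~ Bernoulli(expit(alpha_y + bx0*x0 + bx1*x1 + ba0*a0 + ba1*a1))

In the RCT design, theta is a *retention probability*: treated subjects
remain treated with probability theta and untreated subjects never start.
In the observational design, theta is the log-odds carry-over of prior
treatment and phi the log-odds of treatment per unit of the current
covariate, so treatment uptake tracks the (possibly treatment-lowered)
covariate — the "treatment drop-in" that contaminates naive risk models.

The intercepts alpha0, alpha1 and alpha_y are never specified directly;
scenarios state target marginal rates (e.g. P(Y=1) = 0.2) and
:func:`calibrate_scenario` solves for the intercepts that achieve them,
sequentially along the mechanism (alpha0, then alpha1 given the induced
A0/X1 distribution, then alpha_y given everything).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

__all__ = [
    "ScenarioConfig",
    "rct_10pct_dropout",
    "obs_50pct_treated",
    "obs_20pct_treated",
    "PRESETS",
    "GAMMA_GRID",
    "calibrate_intercept",
    "calibrate_scenario",
    "generate_development",
    "generate_test_mt",
    "generate_test_ntt",
    "subset_nbt",
    "read_cohort",
    "write_cohort",
    "load_scenario",
    "save_scenario",
    "CalibrationError",
]

#: gamma sweep used in the simulation study (treatment's covariate-lowering effect)
GAMMA_GRID = (-3.0, -2.5, -2.0, -1.5, -1.0, -0.5, 0.0)

#: fixed internal stream for Monte-Carlo intercept calibration
_CALIBRATION_SEED = 714025
_CALIBRATION_N = 200_000

COHORT_COLUMNS = ("x0", "a0", "x1", "a1", "y")


class CalibrationError(RuntimeError):
    """Intercept calibration failed (non-bracketing interval, bad target...)."""


@dataclass
class ScenarioConfig:
    """All parameters defining one two-timepoint simulation scenario.

    Intercepts (``alpha0``, ``alpha1``, ``alpha_y``) start as ``None`` and
    are filled in by :func:`calibrate_scenario` so that the target marginal
    rates are achieved. ``theta`` is a retention probability in [0, 1] for
    the RCT design and an unrestricted log-odds carry-over otherwise.
    """

    name: str
    design: str  # "rct" | "observational"
    phi: float
    theta: float
    gamma: float = 0.0
    beta_x0: float = math.log(1.5)
    beta_x1: float = math.log(1.5)
    beta_a0: float = math.log(0.5)
    beta_a1: float = math.log(0.5)
    target_pA0: float = 0.5
    target_pA1: float | None = None
    target_pY: float = 0.2
    alpha0: float | None = None
    alpha1: float | None = None
    alpha_y: float | None = None
    n_dev: int = 10_000
    n_test: int = 100_000

    def __post_init__(self) -> None:
        if self.design not in ("rct", "observational"):
            raise ValueError("design must be 'rct' or 'observational'")
        if self.design == "rct" and not 0.0 <= self.theta <= 1.0:
            raise ValueError("RCT design: theta is a retention probability in [0, 1]")
        for label, p in (("target_pA0", self.target_pA0), ("target_pY", self.target_pY)):
            if not 0.0 < p < 1.0:
                raise ValueError(f"{label} must lie in (0, 1)")
        if self.design == "observational":
            if self.target_pA1 is None or not 0.0 < self.target_pA1 < 1.0:
                raise ValueError("observational design: target_pA1 must lie in (0, 1)")

    @property
    def calibrated(self) -> bool:
        need_a1 = self.design == "observational"
        return (
            self.alpha0 is not None
            and self.alpha_y is not None
            and (self.alpha1 is not None or not need_a1)
        )


def rct_10pct_dropout(gamma: float = 0.0) -> ScenarioConfig:
    """RCT with 50% treated at baseline and 10% treatment dropout."""
    return ScenarioConfig(name="rct_10pct_dropout", design="rct", phi=0.0, theta=0.9,
                          gamma=gamma, target_pA0=0.5, target_pA1=None)


def obs_50pct_treated(gamma: float = 0.0) -> ScenarioConfig:
    """Observational study with 50% treated at each timepoint."""
    return ScenarioConfig(name="obs_50pct_treated", design="observational",
                          phi=math.log(2), theta=math.log(2), gamma=gamma,
                          target_pA0=0.5, target_pA1=0.5)


def obs_20pct_treated(gamma: float = 0.0) -> ScenarioConfig:
    """Observational study with 20% treated at each timepoint."""
    return ScenarioConfig(name="obs_20pct_treated", design="observational",
                          phi=math.log(2), theta=math.log(2), gamma=gamma,
                          target_pA0=0.2, target_pA1=0.2)


PRESETS: dict[str, Callable[..., ScenarioConfig]] = {
    "rct_10pct_dropout": rct_10pct_dropout,
    "obs_50pct_treated": obs_50pct_treated,
    "obs_20pct_treated": obs_20pct_treated,
}


# ---------------------------------------------------------------------------
# Intercept calibration
# ---------------------------------------------------------------------------


def calibrate_intercept(
    target_prob: float,
    marginal_prob_fn: Callable[[float], float],
    *,
    bracket: tuple[float, float] = (-8.0, 8.0),
    max_bracket: float = 40.0,
    tol: float = 1e-3,
) -> float:
    """Solve marginal_prob_fn(alpha) = target_prob for the intercept alpha.

    ``marginal_prob_fn`` must be monotone increasing (e.g. a fixed-seed
    Monte-Carlo estimate of a marginal event rate as a function of the
    intercept, or a Gauss-Hermite quadrature of the logistic-normal
    marginal).  The search bracket is doubled until it contains the target;
    failure to bracket reports the achieved bounds.
    """
    if not 0.0 < target_prob < 1.0:
        raise CalibrationError(f"target probability must lie in (0, 1); got {target_prob}")
    lo, hi = bracket
    f_lo, f_hi = marginal_prob_fn(lo), marginal_prob_fn(hi)
    while f_lo > target_prob and lo > -max_bracket:
        lo *= 2.0
        f_lo = marginal_prob_fn(lo)
    while f_hi < target_prob and hi < max_bracket:
        hi *= 2.0
        f_hi = marginal_prob_fn(hi)
    if not (f_lo <= target_prob <= f_hi):
        raise CalibrationError(
            "could not bracket the target: "
            f"f({lo:g})={f_lo:.6f}, f({hi:g})={f_hi:.6f}, target={target_prob:g}"
        )
    root = brentq(lambda a: marginal_prob_fn(a) - target_prob, lo, hi, xtol=1e-10)
    achieved = marginal_prob_fn(root)
    if abs(achieved - target_prob) >= tol:
        raise CalibrationError(
            f"calibration tolerance not met: achieved {achieved:.6f} for target {target_prob:g}"
        )
    return float(root)


def _gauss_hermite_marginal(phi: float, n_nodes: int = 101) -> Callable[[float], float]:
    """E[expit(alpha + phi*X)] for X ~ N(0,1), by Gauss-Hermite quadrature."""
    nodes, wts = np.polynomial.hermite.hermgauss(n_nodes)
    x = nodes * math.sqrt(2.0)
    w = wts / math.sqrt(math.pi)

    def marginal(alpha: float) -> float:
        return float(np.sum(w * expit(alpha + phi * x)))

    return marginal


def calibrate_scenario(
    config: ScenarioConfig,
    *,
    n_mc: int = _CALIBRATION_N,
    mc_seed: int = _CALIBRATION_SEED,
    tol: float = 1e-3,
) -> ScenarioConfig:
    """Return a copy of ``config`` with alpha0, alpha1 and alpha_y calibrated.

    alpha0 is solved by Gauss-Hermite quadrature (its marginal has the
    logistic-normal closed form); alpha1 and alpha_y by bracketed root
    finding on a fixed-seed Monte-Carlo estimate (common random numbers
    make the estimated marginal smooth and monotone in the intercept),
    walking forward along the generating mechanism so each intercept is
    calibrated against the distribution induced by the previous ones.
    """
    rng = np.random.default_rng(mc_seed)
    x0 = rng.standard_normal(n_mc)
    u_a0 = rng.random(n_mc)
    z1 = rng.standard_normal(n_mc)
    u_a1 = rng.random(n_mc)

    alpha0 = calibrate_intercept(config.target_pA0, _gauss_hermite_marginal(config.phi), tol=tol)
    a0 = (u_a0 < expit(alpha0 + config.phi * x0)).astype(float)
    x1 = x0 + config.gamma * a0 + z1

    if config.design == "rct":
        alpha1 = None
        a1 = (u_a1 < config.theta * a0).astype(float)
    else:
        def marginal_a1(alpha: float) -> float:
            return float(np.mean(expit(alpha + config.phi * x1 + config.theta * a0)))

        alpha1 = calibrate_intercept(config.target_pA1, marginal_a1, tol=tol)
        a1 = (u_a1 < expit(alpha1 + config.phi * x1 + config.theta * a0)).astype(float)

    lp_y = (config.beta_x0 * x0 + config.beta_x1 * x1
            + config.beta_a0 * a0 + config.beta_a1 * a1)

    def marginal_y(alpha: float) -> float:
        return float(np.mean(expit(alpha + lp_y)))

    alpha_y = calibrate_intercept(config.target_pY, marginal_y, tol=tol)
    return replace(config, alpha0=alpha0, alpha1=alpha1, alpha_y=alpha_y)


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------


def _require_calibrated(config: ScenarioConfig) -> None:
    if not config.calibrated:
        raise ValueError(
            f"scenario {config.name!r} has uncalibrated intercepts; "
            "run calibrate_scenario(config) first"
        )


def _as_frame(x0, a0, x1, a1, y) -> pd.DataFrame:
    return pd.DataFrame(
        {"x0": x0, "a0": a0.astype(np.int64), "x1": x1,
         "a1": a1.astype(np.int64), "y": y.astype(np.int64)}
    )


def generate_development(config: ScenarioConfig, n: int | None = None, seed=0) -> pd.DataFrame:
    """Draw a development cohort of ``n`` subjects under the five-step mechanism.

    ``seed`` may be an int or a tuple of ints (a documented stream key);
    identical (config, n, seed) always reproduces the identical cohort.
    """
    _require_calibrated(config)
    n = config.n_dev if n is None else int(n)
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    x0 = rng.standard_normal(n)
    a0 = (rng.random(n) < expit(config.alpha0 + config.phi * x0)).astype(float)
    x1 = x0 + config.gamma * a0 + rng.standard_normal(n)
    if config.design == "rct":
        # retention: treated stay treated w.p. theta; untreated never start
        a1 = (rng.random(n) < config.theta * a0).astype(float)
    else:
        a1 = (rng.random(n) < expit(config.alpha1 + config.phi * x1 + config.theta * a0)).astype(float)
    pi_y = expit(config.alpha_y + config.beta_x0 * x0 + config.beta_x1 * x1
                 + config.beta_a0 * a0 + config.beta_a1 * a1)
    y = (rng.random(n) < pi_y).astype(float)
    return _as_frame(x0, a0, x1, a1, y)


def generate_test_mt(config: ScenarioConfig, n: int | None = None, seed=0) -> pd.DataFrame:
    """Test cohort under the development mechanism (the "mix of treatment" set).

    The mechanism is identical to :func:`generate_development`; callers are
    expected to pass an independent seed stream.
    """
    n = config.n_test if n is None else n
    return generate_development(config, n, seed)


def generate_test_ntt(config: ScenarioConfig, n: int | None = None, seed=0) -> pd.DataFrame:
    """Test cohort with treatment withheld throughout (probes the E3 estimand).

    X1 ~ N(X0, 1) (no treatment, so no covariate-lowering shift) and the
    outcome is drawn with both treatment terms zero.
    """
    _require_calibrated(config)
    n = config.n_test if n is None else int(n)
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    x0 = rng.standard_normal(n)
    x1 = x0 + rng.standard_normal(n)
    zeros = np.zeros(n)
    pi_y = expit(config.alpha_y + config.beta_x0 * x0 + config.beta_x1 * x1)
    y = (rng.random(n) < pi_y).astype(float)
    return _as_frame(x0, zeros, x1, zeros, y)


def subset_nbt(cohort: pd.DataFrame) -> pd.DataFrame:
    """Rows untreated at baseline (a0 = 0), order preserved."""
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    out = cohort[cohort["a0"] == 0].reset_index(drop=True)
    if len(out) == 0:
        warnings.warn("no untreated-at-baseline rows; returning an empty cohort", stacklevel=2)
    return out


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def write_cohort(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False, columns=list(COHORT_COLUMNS))


def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"cohort file {path} lacks columns {sorted(missing)}")
    return df


def save_scenario(config: ScenarioConfig, path) -> None:
    path = Path(path)
    d = {k: v for k, v in config.__dict__.items()}
    if path.suffix in (".yaml", ".yml"):
        import yaml

        path.write_text(yaml.safe_dump(d, sort_keys=False))
    else:
        path.write_text(json.dumps(d, indent=2))


def load_scenario(path) -> ScenarioConfig:
    path = Path(path)
    if path.suffix in (".yaml", ".yml"):
        import yaml

        d = yaml.safe_load(path.read_text())
    else:
        d = json.loads(path.read_text())
    return ScenarioConfig(**d)
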