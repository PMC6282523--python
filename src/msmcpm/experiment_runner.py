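"""Orchestration of the simulation study: scenario x gamma x replicate.

One replicate draws a development cohort, estimates stabilized weights,
fits the four modeling strategies, draws the two test cohorts, and
evaluates every strategy under the MT / NBT / NTT settings.  The runner
repeats this over a gamma grid and many replicates and aggregates each
metric to its mean and empirical standard error (SD across replicates /
sqrt(n_reps)).

Randomness discipline: every replicate is keyed by the tuple
(root_seed, scenario_index, gamma_index, replicate), and the three
cohorts of a replicate by appending a role code (0 = development,
1 = MT test, 2 = NTT test).  The tuple seeds a ``numpy`` SeedSequence,
so any cell can be recomputed in isolation and in any order with
identical results.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .cpm_fit import STRATEGIES, fit_strategy
from .performance import DEFAULT_THRESHOLDS, SETTINGS, PerformanceReport, evaluate
from .synthetic_dgm import (
    GAMMA_GRID,
    ScenarioConfig,
    calibrate_scenario,
    generate_development,
    generate_test_mt,
    generate_test_ntt,
)
from .weight_engine import compute_stabilized_weights, fit_treatment_models

__all__ = [
    "ExperimentPlan",
    "ExperimentResult",
    "run_replicate",
    "run_experiment",
    "ROLE_DEV",
    "ROLE_TEST_MT",
    "ROLE_TEST_NTT",
]

log = logging.getLogger(__name__)

ROLE_DEV, ROLE_TEST_MT, ROLE_TEST_NTT = 0, 1, 2

#: share of failed replicates above which a cell is flagged unreliable
MAX_FAILURE_SHARE = 0.05

# calibrated-scenario cache, keyed by the generating parameters
_CALIBRATION_CACHE: dict[tuple, ScenarioConfig] = {}


def calibrated(config: ScenarioConfig, gamma: float | None = None) -> ScenarioConfig:
    """Calibrated copy of ``config`` (optionally at a different gamma), cached."""
    if gamma is not None:
        config = replace(config, gamma=gamma, alpha0=None, alpha1=None, alpha_y=None)
    key = (config.design, config.phi, config.theta, config.gamma,
           config.beta_x0, config.beta_x1, config.beta_a0, config.beta_a1,
           config.target_pA0, config.target_pA1, config.target_pY)
    if key not in _CALIBRATION_CACHE:
        _CALIBRATION_CACHE[key] = calibrate_scenario(config)
    return _CALIBRATION_CACHE[key]


@dataclass
class ExperimentPlan:
    """Scenarios, gamma grid and replication settings for one experiment."""

    scenarios: Sequence[ScenarioConfig]
    gamma_grid: Sequence[float] = GAMMA_GRID
    n_dev: int = 10_000
    n_test: int = 100_000
    n_reps: int = 1000
    root_seed: int = 0
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if len(self.gamma_grid) == 0:
            raise ValueError("gamma_grid must be non-empty")


def run_replicate(
    config: ScenarioConfig,
    seed,
    *,
    thresholds=DEFAULT_THRESHOLDS,
    n_dev: int | None = None,
    n_test: int | None = None,
) -> dict[tuple[str, str], PerformanceReport]:
    """One full replicate; returns {(strategy, setting): PerformanceReport}.

    ``config`` must already be calibrated (see :func:`calibrated`).
    ``seed`` is an int or tuple; the replicate derives its three cohort
    streams by appending the role codes 0/1/2.
    """
    key = seed if isinstance(seed, tuple) else (seed,)
    dev = generate_development(config, n_dev, seed=key + (ROLE_DEV,))
    models = fit_treatment_models(dev)
    sw = compute_stabilized_weights(dev, models)
    fits = {
        s: fit_strategy(dev, s, sw if s == "msm" else None) for s in STRATEGIES
    }
    test_mt = generate_test_mt(config, n_test, seed=key + (ROLE_TEST_MT,))
    test_ntt = generate_test_ntt(config, n_test, seed=key + (ROLE_TEST_NTT,))
    out: dict[tuple[str, str], PerformanceReport] = {}
    for s, model in fits.items():
        for setting in SETTINGS:
            out[(s, setting)] = evaluate(model, setting, test_mt, test_ntt, thresholds)
    return out


def _flatten(reports: dict[tuple[str, str], PerformanceReport]) -> Iterable[dict]:
    for (strategy, setting), rep in reports.items():
        base = {"strategy": strategy, "setting": setting}
        for metric in ("citl", "cal_slope", "auc", "brier"):
            yield {**base, "metric": metric, "value": getattr(rep, metric)}
        if rep.allocation is not None:
            for t, frac in rep.allocation.items():
                yield {**base, "metric": f"alloc@{t:.2f}", "value": frac}


@dataclass
class ExperimentResult:
    """Replicate-level values plus their aggregation.

    ``replicates`` is a long table (scenario, gamma, rep, strategy,
    setting, metric, value); ``summary`` aggregates each cell to its mean,
    empirical SE (SD / sqrt(count); missing when count == 1) and count.
    """

    replicates: pd.DataFrame
    failures: pd.DataFrame
    unreliable: set = field(default_factory=set)

    @property
    def summary(self) -> pd.DataFrame:
        g = self.replicates.groupby(
            ["scenario", "gamma", "strategy", "setting", "metric"], sort=False
        )["value"]
        out = g.agg(estimate="mean", sd="std", n_reps="count").reset_index()
        out["empirical_se"] = out["sd"] / np.sqrt(out["n_reps"])
        out.loc[out["n_reps"] == 1, "empirical_se"] = np.nan
        return out.drop(columns="sd")

    def get(self, scenario, gamma, strategy, setting, metric) -> tuple[float, float]:
        """(mean, empirical SE) for one cell of the summary."""
        s = self.summary
        row = s[
            (s.scenario == scenario) & (s.gamma == gamma) & (s.strategy == strategy)
            & (s.setting == setting) & (s.metric == metric)
        ]
        if len(row) != 1:
            raise KeyError((scenario, gamma, strategy, setting, metric))
        return float(row["estimate"].iloc[0]), float(row["empirical_se"].iloc[0])

    def replicate_values(self, scenario, gamma, strategy, setting, metric) -> np.ndarray:
        r = self.replicates
        m = r[
            (r.scenario == scenario) & (r.gamma == gamma) & (r.strategy == strategy)
            & (r.setting == setting) & (r.metric == metric)
        ].sort_values("rep")
        return m["value"].to_numpy()


def run_experiment(plan: ExperimentPlan, *, progress: bool = False) -> ExperimentResult:
    """Run the full scenario x gamma x replicate grid and aggregate."""
    rows: list[dict] = []
    failures: list[dict] = []
    unreliable: set = set()
    for s_idx, scenario in enumerate(plan.scenarios):
        for g_idx, gamma in enumerate(plan.gamma_grid):
            cfg = calibrated(scenario, gamma)
            n_fail = 0
            for rep in range(plan.n_reps):
                seed = (plan.root_seed, s_idx, g_idx, rep)
                try:
                    reports = run_replicate(
                        cfg, seed, thresholds=plan.thresholds,
                        n_dev=plan.n_dev, n_test=plan.n_test,
                    )
                except Exception as exc:  # noqa: BLE001 — flagged, not fatal
                    n_fail += 1
                    failures.append(
                        {"scenario": scenario.name, "gamma": gamma, "rep": rep,
                         "reason": f"{type(exc).__name__}: {exc}"}
                    )
                    log.warning("replicate failed: %s gamma=%g rep=%d: %s",
                                scenario.name, gamma, rep, exc)
                    continue
                for rec in _flatten(reports):
                    rows.append({"scenario": scenario.name, "gamma": gamma, "rep": rep, **rec})
            if n_fail > MAX_FAILURE_SHARE * plan.n_reps:
                unreliable.add((scenario.name, gamma))
                log.warning("cell (%s, gamma=%g) unreliable: %d/%d replicates failed",
                            scenario.name, gamma, n_fail, plan.n_reps)
            if progress:
                log.info("done: %s gamma=%g (%d reps, %d failed)",
                         scenario.name, gamma, plan.n_reps, n_fail)
    rep_frame = pd.DataFrame(rows)
    fail_frame = pd.DataFrame(failures, columns=["scenario", "gamma", "rep", "reason"])
    return ExperimentResult(replicates=rep_frame, failures=fail_frame, unreliable=unreliable)
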