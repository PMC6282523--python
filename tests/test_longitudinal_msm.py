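"""Person-period generator, spline basis, longitudinal weights and pooled MSM."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from msmcpm import (
    LongitudinalConfig,
    PooledFit,
    fit_longitudinal_weights,
    fit_pooled_msm,
    generate_longitudinal,
    predict_cumulative_risk,
    rcs_basis,
)


@pytest.fixture(scope="module")
def dev_table():
    return generate_longitudinal(LongitudinalConfig(), n=8_000, K=10, seed=11)


class TestGenerator:
    def test_treatment_is_absorbing(self, dev_table):
        diffs = dev_table.groupby("id")["a"].diff().dropna()
        assert (diffs >= 0).all()
        # a_prev is last period's a
        shifted = dev_table.groupby("id")["a"].shift(1).fillna(0.0)
        assert np.allclose(dev_table["a_prev"], shifted)

    def test_rows_stop_at_first_exit(self, dev_table):
        last = dev_table.groupby("id").tail(1)
        exited = (last["y"] == 1) | (last["c"] == 1) | (last["k"] == 9)
        assert exited.all()
        # events and censorings only on last rows; at most one event per subject
        not_last = dev_table.drop(last.index)
        assert not_last["y"].sum() == 0 and not_last["c"].sum() == 0
        assert dev_table.groupby("id")["y"].sum().max() <= 1

    def test_person_period_accounting(self, dev_table):
        per_subject = dev_table.groupby("id")["k"].agg(["min", "max", "count"])
        assert (per_subject["min"] == 0).all()
        assert (per_subject["count"] == per_subject["max"] + 1).all()

    def test_no_censoring_switch(self):
        t = generate_longitudinal(LongitudinalConfig().no_censoring(), 2_000, K=5, seed=1)
        assert t["c"].sum() == 0

    def test_no_treatment_switch(self):
        t = generate_longitudinal(LongitudinalConfig().no_treatment(), 2_000, K=5, seed=2)
        assert t["a"].max() == 0

    def test_determinism(self):
        cfg = LongitudinalConfig()
        a = generate_longitudinal(cfg, 1_000, K=6, seed=9)
        b = generate_longitudinal(cfg, 1_000, K=6, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_cumulative_incidence_matches_product_of_hazards(self):
        """Without treatment or censoring the K-year incidence for a subject
        is 1 - (1 - h(x0, b))^K; compare the realized rate to the
        closed-form average over the simulated baseline distribution."""
        cfg = LongitudinalConfig().no_treatment().no_censoring()
        K, n = 5, 100_000
        t = generate_longitudinal(cfg, n, K=K, seed=33)
        base = t[t["k"] == 0]
        h = expit(cfg.event_intercept + cfg.event_x0 * base["x0"] + cfg.event_b * base["b"])
        closed_form = float(np.mean(1.0 - (1.0 - h) ** K))
        realized = t.groupby("id")["y"].max().mean()
        assert abs(realized - closed_form) < 0.005

    def test_invalid_sizes_rejected(self):
        with pytest.raises(ValueError):
            generate_longitudinal(LongitudinalConfig(), 0, K=5)
        with pytest.raises(ValueError):
            generate_longitudinal(LongitudinalConfig(), 10, K=1)


class TestRCSBasis:
    def test_dimension_is_knots_minus_one(self):
        periods = np.repeat(np.arange(10), 50)
        for m in (3, 4, 5):
            basis = rcs_basis(periods, n_knots=m)
            assert basis.transform(periods).shape[1] == m - 1

    def test_linear_beyond_boundary_knots(self):
        basis = rcs_basis(np.repeat(np.arange(10), 20), n_knots=4)
        grid = np.linspace(basis.knots[-1], basis.knots[-1] + 5, 50)
        vals = basis.transform(grid)
        for j in range(vals.shape[1]):
            second_diff = np.diff(vals[:, j], n=2)
            assert np.max(np.abs(second_diff)) < 1e-8

    def test_too_few_periods_rejected(self):
        with pytest.raises(ValueError):
            rcs_basis(np.array([0, 1, 2]), n_knots=4)
        with pytest.raises(ValueError):
            rcs_basis(np.arange(10), n_knots=2)

    def test_flat_hazard_recovered_as_flat_spline(self):
        """A constant event hazard must come back as near-constant fitted
        per-period hazards despite the spline's flexibility."""
        cfg = replace(LongitudinalConfig().no_treatment().no_censoring(),
                      event_x0=0.0, event_b=0.0, event_intercept=-3.5)
        t = generate_longitudinal(cfg, 40_000, K=10, seed=44)
        fit = fit_pooled_msm(t, strategy="naive", baseline_cols=())
        base = pd.DataFrame(index=[0])
        hazards = np.array([fit.hazard(base, k)[0] for k in range(10)])
        assert hazards.max() - hazards.min() < 0.006
        assert abs(hazards.mean() - expit(-3.5)) < 0.003


class TestLongitudinalWeights:
    def test_mean_cumulative_weight_near_one(self, dev_table):
        w = fit_longitudinal_weights(dev_table)
        assert abs(w.sw.mean() - 1.0) < 0.03
        per_period = pd.Series(w.sw).groupby(dev_table["k"]).mean()
        assert np.max(np.abs(per_period - 1.0)) < 0.15

    def test_post_initiation_factors_are_one(self, dev_table):
        w = fit_longitudinal_weights(dev_table)
        treated_prev = dev_table["a_prev"].to_numpy() == 1
        assert np.all(w.treat_factor[treated_prev] == 1.0)

    def test_no_censoring_gives_unit_censoring_factors(self):
        t = generate_longitudinal(LongitudinalConfig().no_censoring(), 3_000, K=6, seed=5)
        w = fit_longitudinal_weights(t)
        assert np.all(w.cens_factor == 1.0)

    def test_weights_positive_finite(self, dev_table):
        w = fit_longitudinal_weights(dev_table)
        assert np.all(w.sw > 0) and np.all(np.isfinite(w.sw))


class TestPooledMSM:
    def test_recovers_generating_coefficients(self):
        """Correctly specified pooled MSM recovers the event-hazard
        coefficients within ~3 Monte-Carlo SEs at this cohort size."""
        cfg = LongitudinalConfig()
        t = generate_longitudinal(cfg, 30_000, K=10, seed=55)
        w = fit_longitudinal_weights(t)
        fit = fit_pooled_msm(t, weights=w)
        coef = dict(zip(fit.columns, fit.coef))
        assert abs(coef["x0"] - cfg.event_x0) < 0.09
        assert abs(coef["b"] - cfg.event_b) < 0.15
        assert abs(coef["a_prev"] - cfg.event_a) < 0.20
        assert coef["a_prev"] < 0  # protective treatment

    def test_null_effect_no_confounding_msm_equals_naive(self):
        """With a null treatment effect and initiation independent of the
        covariates, MSM and naive baseline coefficients coincide within
        Monte-Carlo error."""
        cfg = replace(LongitudinalConfig(), event_a=0.0, init_x=0.0, init_b=0.0,
                      gamma=0.0)
        t = generate_longitudinal(cfg, 20_000, K=8, seed=66)
        w = fit_longitudinal_weights(t)
        msm = fit_pooled_msm(t, weights=w)
        naive = fit_pooled_msm(t, strategy="naive")
        cm = dict(zip(msm.columns, msm.coef))
        cn = dict(zip(naive.columns, naive.coef))
        assert abs(cm["x0"] - cn["x0"]) < 0.05
        assert abs(cm["b"] - cn["b"]) < 0.08
        assert abs(cm["a_prev"]) < 0.25

    def test_no_initiation_msm_matches_naive_exactly(self):
        """With the treatment hazard switched off the treatment column is
        identically zero, so the MSM collapses onto the naive fit."""
        t = generate_longitudinal(
            LongitudinalConfig().no_treatment().no_censoring(), 4_000, K=6, seed=7)
        w = fit_longitudinal_weights(t)
        assert np.allclose(w.sw, 1.0)
        msm = fit_pooled_msm(t, weights=w)
        naive = fit_pooled_msm(t, strategy="naive")
        shared = dict(zip(naive.columns, naive.coef))
        fitted = dict(zip(msm.columns, msm.coef))
        for name, val in shared.items():
            assert fitted[name] == pytest.approx(val, abs=1e-6)

    def test_naive_must_be_unweighted(self, dev_table):
        with pytest.raises(ValueError):
            fit_pooled_msm(dev_table, weights=np.ones(len(dev_table)), strategy="naive")


class TestCumulativeRisk:
    def _constant_fit(self, h: float, max_period: int = 9) -> PooledFit:
        return PooledFit(
            strategy="naive", coef=np.array([logit(h)]), columns=["intercept"],
            basis=None, baseline_cols=(), converged=True, n_used=1,
            weighted=False, max_period=max_period,
        )

    def test_zero_hazard_gives_zero_risk(self):
        fit = self._constant_fit(1e-12)
        risk = predict_cumulative_risk(fit, pd.DataFrame(index=[0]), K=10)
        assert risk[0] < 1e-10

    def test_constant_hazard_closed_form(self):
        h = 0.07
        fit = self._constant_fit(h)
        for K in (1, 5, 10):
            risk = predict_cumulative_risk(fit, pd.DataFrame(index=[0]), K=K)
            assert risk[0] == pytest.approx(1.0 - (1.0 - h) ** K, abs=1e-12)

    def test_risk_nondecreasing_in_horizon(self):
        fit = self._constant_fit(0.03)
        risks = [predict_cumulative_risk(fit, pd.DataFrame(index=[0]), K=k)[0]
                 for k in range(1, 11)]
        assert all(a <= b for a, b in zip(risks, risks[1:]))

    def test_extrapolation_beyond_support_rejected(self):
        fit = self._constant_fit(0.05, max_period=4)
        with pytest.raises(ValueError, match="support"):
            predict_cumulative_risk(fit, pd.DataFrame(index=[0]), K=6)

    def test_risk_increasing_in_positive_coefficient_covariate(self, dev_table):
        w = fit_longitudinal_weights(dev_table)
        fit = fit_pooled_msm(dev_table, weights=w)
        base = pd.DataFrame({"x0": np.linspace(-2, 2, 9), "b": 0.0})
        risk = predict_cumulative_risk(fit, base, K=10)
        assert np.all(np.diff(risk) > 0)
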