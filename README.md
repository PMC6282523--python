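# msmcpm

Marginal structural models (MSMs) for developing clinical prediction
models (CPMs) that estimate **treatment-naive risk** in the presence of
**treatment drop-in** — patients who start a protective treatment after
baseline but before the outcome is observed.

## The problem

A CPM used to decide whether to *start* treatment must predict the risk a
patient would face **if no treatment were given, now or later**.  But
development cohorts are contaminated: some patients initiate treatment
during follow-up (e.g. statins before a cardiovascular event), which
deflates the apparent risk of "untreated" covariate profiles.  Models
that ignore treatment, restrict to a treatment-naive baseline cohort, or
adjust only for baseline treatment all under-estimate the no-treatment
risk and therefore under-allocate treatment.

With treatment `A_k` and covariates `X_k` recorded at times `k = 0..K`,
the estimands form a ladder (risk of outcome `Y` given baseline
covariates `X_0`):

* **E1** `E[Y | X0]` — disregarding treatment;
* **E2** `E[Y(A0=0) | X0]` — no treatment now;
* **E3** `E[Y(Ā=0̄) | X0]` — no treatment now *or later*: the
  treatment-naive risk that should drive initiation decisions;
* **E4/E5** — treat now / sustained treatment.

## The method

The MSM targets E3 by inverse-probability-of-treatment weighting.  Each
subject gets a stabilized weight

```
sw_i = Π_k  p̂*_ki^{a_ki} (1 − p̂*_ki)^{1−a_ki}
      ────────────────────────────────────────
       Π_k  p̂_ki^{a_ki} (1 − p̂_ki)^{1−a_ki}
```

where `p̂*` comes from the numerator model
`logit P(A_k=1 | A_{k−1}, X0)` and `p̂` from the denominator model
`logit P(A_k=1 | A_{k−1}, X̄_k)`.  The outcome model

```
logit P(Y=1 | X0, Ā) = β0 + βX x0 + Σ_k βAk a_k
```

is then fitted by maximizing the **weighted** Bernoulli log-likelihood
`l(β) = Σ_i sw_i [y_i log π_i + (1−y_i) log(1−π_i)]` (Newton–Raphson with
step-halving).  Setting the treatment indicators to zero in the fitted
model yields E3 predictions; other regimes give E2/E4/E5.

The package provides:

* `synthetic_dgm` — two-timepoint cohort generators (RCT and
  observational designs) with Monte-Carlo calibration of intercepts to
  target marginal rates;
* `weight_engine` — stabilized-weight estimation with diagnostics;
* `cpm_fit` — the four competing strategies (`ignore`, `naive`,
  `baseline_treatment`, `msm`) and prediction under treatment regimes;
* `performance` — calibration-in-the-large, calibration slope,
  Mann-Whitney AUC, Brier score and treatment-allocation curves under the
  MT / NBT / NTT evaluation settings;
* `experiment_runner` — the full scenario × γ × replicate simulation
  study with empirical standard errors, plus a `msmcpm` CLI;
* `longitudinal_msm` — a discrete-time person-period generalization with
  annual reviews, absorbing treatment, right censoring handled as a
  second time-varying "treatment", a restricted-cubic-spline
  year-specific intercept, and K-year cumulative risk prediction.

## Worked example

```python
import numpy as np
from msmcpm import (obs_50pct_treated, generate_development, generate_test_ntt,
                    fit_treatment_models, compute_stabilized_weights,
                    fit_strategy, evaluate)
from msmcpm.experiment_runner import calibrated

cfg = calibrated(obs_50pct_treated(), gamma=0.0)   # solve the intercepts
dev = generate_development(cfg, 10_000, seed=(1, 0))
sw = compute_stabilized_weights(dev, fit_treatment_models(dev))
print(f"mean stabilized weight: {sw.sw.mean():.3f}")

ntt = generate_test_ntt(cfg, 50_000, seed=(1, 2))
for strategy in ("ignore", "naive", "baseline_treatment", "msm"):
    model = fit_strategy(dev, strategy, sw if strategy == "msm" else None)
    rep = evaluate(model, "NTT", test_ntt=ntt)
    print(f"{strategy:20s} CITL={rep.citl:+.3f}  slope={rep.cal_slope:.3f} "
          f"alloc@40%={rep.allocation[0.40]*100:.1f}%")
```

prints

```
mean stabilized weight: 1.001
ignore               CITL=+0.685  slope=1.442 alloc@40%=2.3%
naive                CITL=+0.310  slope=1.115 alloc@40%=14.7%
baseline_treatment   CITL=+0.317  slope=1.167 alloc@40%=13.7%
msm                  CITL=+0.033  slope=1.028 alloc@40%=26.9%
```

Read: on a test population where treatment is withheld from everyone
(the E3 setting), the conventional strategies under-predict risk
(positive calibration-in-the-large) and would start treatment in far
fewer patients at a 40% risk threshold, while the MSM is calibrated
(CITL ≈ 0, slope ≈ 1).  Averaged over 200 replicates the four
allocations settle near 2.8%, 14.5%, 14.7% and 28.5% (see
`scripts/acceptance.py` below).

The CLI exposes the same machinery, e.g.

```
msmcpm simulate --scenario obs_50pct_treated --n 10000 --out dev.csv
msmcpm sweep --scenario obs_50pct_treated --gammas "-3,-1.5,0" --reps 200 --out-dir results/
msmcpm longitudinal --n 10000 --k 10 --out person_periods.csv
```

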