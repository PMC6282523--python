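# Methods

This note documents the models implemented in `msmcpm`, the synthetic
data-generating mechanisms, the numerical choices, and the design
decisions that were genuinely open.

## Two-timepoint model and estimands

One continuous covariate `X` and one binary treatment `A` are recorded at
baseline (time 0) and at one follow-up review (time 1), before a binary
outcome `Y`.  Treatment is protective and the covariate harmful; the
follow-up treatment decision may depend on the follow-up covariate, which
itself may have been lowered by baseline treatment (parameter `gamma`).
This is the minimal structure in which "treatment drop-in" biases a
prediction model: subjects who look high-risk at baseline initiate
treatment before the outcome, so their observed outcomes under-state the
no-treatment risk of their covariate profile.

The estimand that should drive a treatment-initiation decision is the
treatment-naive risk `E3 = E[Y(Ā=0̄) | X0]`.  Standard strategies —
ignoring treatment, fitting only untreated-at-baseline subjects
("treatment-naive" cohort), or adjusting for baseline treatment — target
something between E1 and E2 and under-predict E3.

## Stabilized weights

Weight models are logistic regressions per timepoint: the numerator
conditions on lagged treatment and the baseline covariate, the
denominator additionally on the full covariate history.  Note two
properties the implementation exploits:

* at time 0 there is no lagged treatment and the only covariate is `X0`,
  so the numerator and denominator models coincide and the time-0 factors
  cancel exactly; both are still fitted for diagnostics.
* the numerator deliberately retains `X0` (all baseline *prognostic*
  variables, not only effect modifiers), because the outcome model
  conditions on `X0` anyway; the weights only need to break the arrows
  from post-baseline covariates to treatment.

Fitted probabilities are clipped to `[1e-6, 1 - 1e-6]` before ratios are
formed.  Structural zeros — e.g. the RCT rule that untreated subjects
never start — produce quasi-separated weight models whose separated
predictions go to 0; clipping keeps the weights finite while leaving
well-behaved scenarios untouched (in practice no observation is clipped
there).  Weights are not truncated by default; percentile truncation is
available behind an option for pathological cohorts.

## Weighted logistic maximum likelihood

All logistic fits in the package (weight models, the four outcome
strategies, recalibration fits, pooled person-period models) use one
optimizer: Newton-Raphson on the weight-multiplied Bernoulli
log-likelihood with step-halving, convergence declared at
`|Δ loglik| < 1e-8` or gradient sup-norm `< 1e-6`, and a least-squares
fallback for (near-)singular Hessians.  Rank-deficient designs are
rejected with the offending columns named.  Quasi-separated fits (the RCT
structural zero) converge in the `Δ loglik` sense with the separated
linear predictors at large negative values, which is the correct limit
for the weight ratios.  Unit tests pin the unit-weight case to
statsmodels' independent optimizer at `1e-6` and integer-weight fits to
their row-expanded equivalents.

The `ignore`/`naive` strategies carry no treatment terms; when evaluated
under no-treatment regimes their linear predictor is used unchanged.
Treatment design columns that are identically zero in a degenerate cohort
are dropped with coefficient 0 rather than rejected, so the strategies
collapse onto each other gracefully when nobody is treated.
Treatment-covariate interaction terms (`a_k * x0`) are off by default,
matching the simulation design, and can be enabled per fit.  No variance
estimation is attached to coefficients: the pipeline consumes predictions
only.

## Intercept calibration

Scenarios specify target marginal rates (`P(A0=1)`, `P(A1=1)`, `P(Y=1)`)
rather than intercepts.  `calibrate_scenario` solves for the intercepts
sequentially along the generating mechanism: `alpha0` by Gauss-Hermite
quadrature of the logistic-normal marginal (closed form available),
then `alpha1` and `alpha_y` by Brent root-finding on a fixed-seed
Monte-Carlo estimate (N = 200 000 draws, common random numbers across
intercept values so the estimated marginal is smooth and monotone).
Tolerance is 1e-3 on the probability scale; the search bracket doubles
until the target is enclosed and reports the achieved bounds on failure.
Sequential calibration matters because the follow-up treatment marginal
depends on the induced `X1` distribution (hence on `gamma`), and the
outcome marginal on everything upstream.

## Simulation study

Scenario presets: an RCT with 50% treated and 10% dropout (retention
`theta = 0.9`; untreated never start), and observational designs with 50%
or 20% treated at each timepoint (`phi = theta = log 2`).  Outcome
coefficients are `log 1.5` per covariate unit and `log 0.5` per treatment
indicator; the covariate-lowering effect `gamma` sweeps
`(-3, -2.5, ..., 0)` (positive values are excluded from presets — the
setting of interest is a risk-lowering treatment).

Each replicate: development cohort (n = 10 000 by default), weight
models, four strategy fits, and two test cohorts evaluated under three
settings — MT (drawn like the development data, observed regime), NBT
(MT restricted to untreated-at-baseline), NTT (treatment withheld
throughout, never-treat regime).  Treatment-allocation curves (fraction
of NTT subjects whose E3 risk exceeds thresholds 5%–70% in 5-point
steps) are computed only under NTT, where E3 is the relevant estimand.
Aggregation reports the mean and empirical SE (SD across replicates /
√n_reps) per (scenario, gamma, strategy, setting, metric).

Randomness: every replicate is keyed by the tuple (root seed, scenario
index, gamma index, replicate), each cohort by appending a role code
(0 dev / 1 MT / 2 NTT); the tuples seed numpy `SeedSequence`s, so any
cell reruns in isolation, in any order, bit-identically.

Problem sizes in the shipped test suite and acceptance script are desk
scale, chosen to keep Monte-Carlo error well below the effects being
measured: 200 replicates, test cohorts of 20 000 (grid sweeps) or 50 000
(the headline allocation numbers), and the reduced gamma grid
`(-3, -1.5, 0)`.  At these sizes the empirical SE of a calibration
intercept is ~0.003 and of an allocation proportion ~0.15 pp, an order
of magnitude below the between-strategy differences of interest.

## Evaluation metrics

* Calibration-in-the-large: intercept of a logistic recalibration with
  the model's linear predictor as a fixed offset (log-odds scale;
  positive = under-prediction).  The offset-intercept definition, rather
  than a probability-scale mean difference, is the convention in the
  prediction-model literature and is exactly zero in-sample by the
  likelihood score equation.
* Calibration slope: coefficient of the linear predictor in a univariate
  logistic recalibration (1 = perfect).
* AUC: exact Mann-Whitney statistic with ties counted half —
  deterministic and tie-safe, cross-checked against scikit-learn.
* Brier score: mean squared error of the predicted probability.

## Discrete-time longitudinal extension

The person-period module emulates a primary-prevention cohort reviewed
annually for up to K = 10 years: baseline covariates (a continuous risk
score and a binary comorbidity), a time-updated covariate that drifts as
a random walk and is lowered by treatment, an absorbing treatment
(initiation only, no discontinuation — initiation in period k affects
hazards from period k+1 on, reproducing the "at least one year before the
event" lag), right censoring, and a discrete-time event.

Default hazards (annual, logit scale): initiation `-2.5 + 0.7 x_k +
0.4 b` (~8%/year at the covariate mean — deliberately heavier drop-in
than a registry would show, so the bias being corrected is well resolved
at desk scale); censoring `-3.5 + 0.1 x_k` (~3%/year); event `-4.5 +
0.5 x0 + 0.5 b + log(0.5) a_{k-1}` (~10% 10-year risk untreated).  All
hazards are logit-linear in exactly the covariates the corresponding
fitted models condition on, so the weight and outcome models are
correctly specified by construction — passing tests therefore
demonstrate correctness of the estimation machinery, not robustness to
misspecification, informative observation, or missing data, none of
which the generator produces.

The pooled logistic MSM is `logit h_k = s(k) + β'X0 + β_A a_{k-1}` with
`s(k)` a restricted cubic spline (default 4 knots at the 5/35/65/95th
percentiles of the observed periods; linear tails).  Weights multiply a
treatment factor (pooled initiation models on the at-risk rows only;
factor 1 after initiation) and a censoring factor (censoring treated as
a second time-varying "treatment": numerator on baseline covariates and
prior treatment, denominator adding the time-updated covariate, both
including the period terms), cumulated within subject.  Rows censored
within a period are excluded from the outcome fit; the censoring weights
account for their loss.  K-year risk under no treatment is
`1 - Π_k (1 - h_k(x0, A=0))`, with no extrapolation beyond the fitted
periods.

Weight models support three time parameterizations: the spline
(default), none, and fully period-separate fits; the last makes a K = 2
cohort reduce exactly to the two-timepoint engine under its
absorbing-treatment convention, which the test suite exploits as a
cross-module consistency check.

## Known limitations

* Single treatment, single covariate in the two-timepoint engine; no
  unmeasured confounding anywhere (weights assume conditional
  ignorability).
* No doubly-robust or covariate-balancing estimators; no variance
  estimation for MSM coefficients (predictions only).
* The treatment-naive and baseline-treatment strategies produce E3
  allocation curves that coincide only approximately (their fits share
  the untreated stratum's information differently); the coincidence is
  exact when the treatment-covariate interaction is enabled, because the
  likelihood then factorizes over baseline-treatment strata.
* The longitudinal generator produces complete, regularly observed data;
  real registry features (irregular measurement, missingness, treatment
  discontinuation, competing risks) are out of scope.
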