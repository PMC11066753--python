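# Methods

`tvvarnet` estimates person-specific, time-varying lag-1 networks from daily
diary data. This note documents the model, the numerical choices, and what
the synthetic-data studies do and do not show.

## Model

For one participant with p daily variables (z-standardized), the working
model is a VAR(1) whose parameters may change over the series:

    x_t = c(t) + B(t) x_{t-1} + eps_t,    eps_t ~ N(0, diag(sigma(t)^2))

`B(t)[i, j]` is the effect of variable j on day t-1 on variable i on day t:
diagonal entries are autoregressive effects ("inertia"), off-diagonal entries
cross-lagged effects. The nonzero entries of `B(t)` are the directed edges of
the symptom network at time t.

Estimation is local: days are mapped to normalized time tau = (t-1)/(T-1),
and at each of `n_points` (default 20) equidistant estimation points
e_k = (k-1)/(n_points-1) a local VAR is fitted with Gaussian kernel weights

    w_t(e) = exp(-(tau_t - e)^2 / (2 b^2)),

renormalized to maximum 1, over the T-1 lag pairs (indexed by their response
day). The bandwidth b (normalized-time units) sets the flexibility: b ~ 0.01
uses only a few weeks around each point, b >= 1 is nearly stationary. With the
grid convention above, estimation points 2/10/19 of 20 on a 301-day series
correspond to days 17/143/285 (day = round(1 + e_k (T-1))).

Each local fit consists of p independent nodewise lasso regressions
(intercept unpenalized):

    min_{b0, b}  (1/(2 S)) sum_t w_t (y_t - b0 - x_{t-1}' b)^2 + lambda ||b||_1,

with S = sum of weights. The L1 penalty produces exact zeros, so networks can
be sparse or empty; this is also why standardization is mandatory (the
penalty is scale sensitive) and enforced — `fit_tvvar` refuses
non-standardized input.

### Solver

The solver is cyclic coordinate descent on the weighted Gram matrix
(covariance updating): after weighted centering, each coordinate update is a
soft-thresholding step using `G = X'WX/S` and `c = X'Wy/S` only, making a
solve O(p^2) per sweep independent of T. Convergence tolerance 1e-12 on the
max coefficient change, capped at 10^4 sweeps. Predictors with zero weighted
variance get coefficient 0; an all-degenerate design is an error. The solver
is verified in the test suite against an independent convex solve of the same
objective (split-variable L-BFGS-B) and against the orthonormal-design
soft-threshold closed form.

Bandwidths >= 100 are treated as the exact uniform-weight limit (the kernel's
relative variation there is below 5e-5, under coefficient noise), which makes
the identity "large-bandwidth tv-VAR = stationary lasso VAR" exact rather
than approximate.

### Penalty selection

`lam="auto"` selects lambda per nodewise regression by the extended BIC over
a 50-value log-spaced path from lambda_max (null model) down 4 decades:

    EBIC = S log(wMSE) + df (log S + 2 * 0.25 * log p),

df = number of nonzero coefficients, S = effective (weighted) sample size.
This choice was made after comparing selection rules on two synthetic
benchmarks the estimator must satisfy simultaneously: on iid noise (T=300)
EBIC leaves >= 90% of coefficients exactly zero at every estimation point
(minimum-CV keeps spurious small coefficients, ~82% zeros on average), while
a true cross-lagged effect of 0.5 (T=400) is estimated with bias ~0.06
(the 1-SE CV rule shrinks it to ~0.27). EBIC is also deterministic, which
keeps the whole pipeline exactly reproducible. Minimum-CV selection remains
available as `lam="cv"` (10-fold, seeded folds), and any fixed float is
accepted — the scaled-down simulation studies use a fixed penalty so that
observed and bootstrap-null datasets are processed identically at low cost.

An estimation point whose effective sample size sum(w) < p+1 is returned as a
flagged all-zero fit ("low_ess") rather than an error; the two boundary
points carry an "endpoint" flag because only one side of the series informs
them.

## Data preparation

* **Screening**: include a participant iff the series spans >= 130 days and
  every variable's missing fraction (over the full loaded span) is < 30%.
* **Segment selection**: item-wise missing runs of strictly more than 7
  consecutive days split the series into phases; the longest phase is kept
  (ties: earliest). A run of exactly 7 days splits nothing and survives to be
  imputed — runs longer than that are never imputed.
* **Imputation**: per variable, maximum-likelihood fit of a local linear
  trend structural model (local level fallback on non-convergence) via the
  Kalman filter; missing entries take the smoothed level. Observed entries
  are never modified. Deterministic.
* **Standardization**: z-transform per variable (sample SD) after imputation,
  since estimation consumes complete data; scaling parameters are kept for
  inverse transforms.

## Bandwidth selection

Candidates (default {0.009, 0.01, 0.05, 0.12, 0.23, 0.34, 0.45, 0.7, 1.0},
bracketing the range such analyses select in practice) are compared by
time-stratified 5-fold CV: every consecutive block of 5 lag pairs spreads one
pair into each fold, so each fold spans the whole series and the maximum
within-fold gap is 2k-1 days. Held-out pairs are removed as *responses* only
(their values still serve as lagged predictors of retained pairs; removing
the days entirely would break the lag structure). Per candidate and fold the
tv-VAR is refit on the training pairs (penalty re-selected, no leakage),
held-out responses are predicted by the kernel-mixture rule below, and the
RMSE is pooled over variables. Minimum mean RMSE wins; ties go to the larger
(smoother) bandwidth.

Prediction at day t mixes the local models with weights proportional to each
estimation point's kernel evaluated at tau_t, normalized to sum 1 — so the
model behaves as one smoothly-varying VAR, not 20 disconnected ones.

## Stationarity test

Null hypothesis: the data-generating process is stationary. Test statistic:

    stat = CV-RMSE(stationary lasso VAR) - min_b CV-RMSE(tv-VAR at bandwidth b)

computed on the same folds. Its null distribution comes from a parametric
bootstrap: simulate B datasets from the fitted stationary model (Gaussian
innovations at the fitted residual SDs, same T, 100-step burn-in),
re-standardize each, and recompute the statistic with the same fold seeds.
p = (1 + #{null >= observed}) / (B + 1); reject iff p < alpha. Since the
smallest attainable p is 1/(B+1), B must exceed 1/alpha - 1 to ever reject
(B = 39 suffices at alpha = .05; B >= 19 is the hard floor). If the fitted
stationary matrix is numerically unstable (spectral radius >= 0.999) it is
shrunk to radius 0.98 before simulation and the result flagged.

Calibration, measured by the acceptance suite at desk scale (T=100 nulls, 100
runs, B=50): type-I error ~ alpha and approximately uniform p-values; power
1.0 against a cross-lagged effect flipping +0.5 to -0.5 mid-series (T=300).
Power degrades when the change is confined to one edge among many variables,
because the statistic pools prediction error over all variables — visible in
the analysis scripts' 6-variable cohort, where a single drifting edge often
goes undetected at these run sizes.

## Bootstrap stability

Uncertainty bands come from a circular moving-block bootstrap over lag pairs
(block length ceil(sqrt(n)) by default), which preserves the within-pair
predictor/response linkage and local serial dependence; each resampled pair
keeps its original normalized time for the kernel. The penalty is re-selected
per replicate. Default 5%/95% quantile bands per coefficient per estimation
point. Lasso zeros make the bands asymmetric and often not bracket the point
estimate; bands are reported as-is. On realistic scales (T ~ 300, p ~ 4-6)
the bands at nonzero edges are wider than the typical estimate — point
estimates of single edges should not be over-interpreted.

## Prediction metrics

At each estimation point, residuals of the kernel-mixed predictions are
aggregated under that point's kernel weights: R^2 = 1 - wMSE/wVar (weighted
variance of the response around its weighted mean) and RMSE = sqrt(wMSE) on
the standardized scale. R^2 can be negative for bad local fits and is not
clamped. Participant-level summaries are plain means over the
(estimation point, variable) grid. The kernel-weighted (rather than global)
residual aggregation is this package's documented choice.

Raw-scale data quality: a variable is flagged for floor/ceiling pileup iff
the fraction of observed entries exactly at the scale minimum or maximum
strictly exceeds 50%; flagged participants' networks should not be
interpreted (the working model assumes continuous, roughly Gaussian scores).

## Synthetic data generator

`TrajectorySpec` assigns each coefficient a tagged trajectory over normalized
time — constant, linear ramp, step, or sigmoid — plus intercept trajectories
and innovation SDs (default 1). Stability (spectral radius of B(t) < 1) is
enforced at every day. Series are simulated with a 100-step burn-in under the
day-1 parameters. Missingness injection mixes per-variable blocks of 2-7
consecutive days with isolated MCAR holes to hit a target fraction exactly
(default 5.5%, the study regime); a monotone squash (`logistic` or `clip`)
maps the latent series onto bounded visual-analog scales, and a large shift
before clipping manufactures the >50% pileup regime on purpose.

The scenario bank mirrors the study regime: p=6, T in {154, 204, 300, 539},
missingness 1.4-19.6%, and constant/ramp/step/sigmoid dynamics.

What the generator does **not** emulate: discreteness and skew of real
visual-analog responses (except via the squash), missingness that depends on
symptom severity (everything here is MCAR-like), contemporaneous residual
correlation, measurement reactivity, or weekly/seasonal cycles. Passing
recovery tests on these data therefore shows the estimator works when its
assumptions hold — not that real diaries satisfy them.

## Problem sizes and seeds

The simulation studies in the test and acceptance suites run at desk scale,
chosen once: recovery and bandwidth studies at T=300 with 10-20 seeds;
stationarity calibration at T=100 with B=50 and 100 runs, power at T=300
with 50 runs; bootstrap checks at 20-30 replicates. Every random component
(generator, fold assignment, bootstrap) is driven by an explicit integer
seed, and identical configurations reproduce outputs byte-for-byte — the
pipeline manifest records a sha256 checksum of every stage output to make
this checkable.

## Known limitations

* Lag 1 only; no contemporaneous (residual) network; no moderation.
* Univariate imputation ignores cross-variable information, and imputation
  uncertainty is not propagated into the VAR.
* The exact per-point day mapping is a convention; boundary estimates use
  one-sided data and deserve caution (they are flagged, not suppressed).
* The stationarity statistic pools over variables; localized change in one
  edge dilutes power as p grows.
* Shrinkage biases coefficient magnitudes toward zero; trajectories are more
  trustworthy in rank/shape than in absolute size.
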