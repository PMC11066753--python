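# tvvarnet

Idiographic (single-person) time-varying network analysis of daily diary
data. Given one participant's daily multivariate series — e.g. anhedonia,
feeling down, rumination, quantity and quality of social contacts, sleep —
the package estimates how each variable predicts every variable on the next
day, and how those lag-1 relations themselves change over months of
observation. It is aimed at researchers working with intensive longitudinal
(EMA / daily diary) data who want person-specific dynamic networks rather
than group averages.

## The model

The core is a time-varying vector autoregression of lag 1 estimated by kernel
smoothing: for standardized data,

```
x_t = c(t) + B(t) x_{t-1} + eps_t
```

where `B(t)[i, j]` is the time-varying effect of variable *j* at day *t−1* on
variable *i* at day *t* (diagonal = autoregressive "inertia", off-diagonal =
cross-lagged effects; nonzero entries are the directed edges of the network).
Local VAR models are fitted at 20 equidistant estimation points, each by
nodewise lasso regression with Gaussian kernel weights of bandwidth *b* on
normalized time — small *b* gives flexible local estimates, *b* ≳ 1
approaches a stationary fit. The pipeline around the estimator:

1. **screen** — include a series iff ≥ 130 days and < 30% missingness per
   variable; keep the longest phase free of item-wise gaps > 7 days;
2. **impute** — Kalman smoothing of remaining gaps (structural state-space
   model per variable), then z-standardize;
3. **test stationarity** — parametric bootstrap of the cross-validated
   prediction-error gain of the best time-varying bandwidth over a
   stationary lasso VAR;
4. **select bandwidth** — time-stratified 5-fold CV minimizing held-out RMSE;
5. **fit** the tv-VAR; **bootstrap** coefficient bands (circular block
   bootstrap over lag pairs); report time-varying **R² / RMSE** per variable
   and the most time-varying edges; export edge lists and graphs.

A synthetic-data module generates diary-like datasets from known
time-varying VAR processes (drifting, jumping, sigmoid or constant edges,
realistic missingness, bounded scales), so every stage can be validated
against ground truth.

## Worked example

```python
import tvvarnet as tv

# a diary-like series with a cross-lagged edge drifting 0 -> 0.4 over 300 days
spec = tv.TrajectorySpec(4, {(0, 1): tv.EdgeTrajectory("linear_ramp", 0.0, 0.4)})
sds = tv.generate_tvvar_series(spec, T=300, seed=3)
ds, _ = tv.z_standardize(sds.ds)

cv = tv.cv_select_bandwidth(ds, [0.05, 0.12, 0.23, 0.45, 1.0], seed=3)
model = tv.fit_tvvar(ds, cv.selected, n_points=20, seed=3)
pm = tv.prediction_errors(model, ds)

print("selected bandwidth:", cv.selected)
print("estimated V2 -> V1 trajectory:", model.coef_array()[::4, 0, 1].round(2))
print("mean R2: %.3f   mean RMSE: %.3f" % (pm.mean_r2, pm.mean_rmse))
```

Output:

```
selected bandwidth: 0.23
estimated V2 -> V1 trajectory: [0.   0.   0.15 0.25 0.43]
mean R2: 0.033   mean RMSE: 0.980
```

The estimated edge is exactly zero early on (the lasso prunes it while the
true effect is still weak), then grows toward ~0.4 — the planted drift. The
bandwidth CV picked a moderately
local fit (0.23), and the modest mean R² on the standardized scale is typical
for noisy single-subject diary data: most day-to-day variance is innovation,
not predictable structure.

The same pipeline runs from the shell on CSV diaries
(`tvvarnet run-all config.yaml`, plus `screen`, `impute`,
`select-bandwidth`, `test-stationarity`, `bootstrap`, `simulate`, ...), and
the numbered scripts under `analysis/` walk a synthetic cohort through every
stage, writing tables under `results/`.

## Layout

```
src/tvvarnet/      library: datasets, impute, lasso, tvvar, bandwidth,
                   stationarity, bootstrap, metrics, synthetic, pipeline, cli
analysis/          numbered drivers over a synthetic cohort (01 simulate,
                   02 screen/prepare, 03 stationarity, 04 fit, 05 bootstrap,
                   06 networks/figures)
tests/             pytest suite incl. acceptance properties
docs/methods.md    model, numerical choices, generator scope, limitations
```
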