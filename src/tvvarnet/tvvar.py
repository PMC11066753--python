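"""Time-varying VAR(1) estimation by kernel-smoothed nodewise lasso regression.

The model: each variable at day t is regressed on all variables at day t-1
(autoregressive effect on itself, cross-lagged effects from the others). The
parameters are allowed to change over time by fitting a *local* VAR at each of
``n_points`` equidistant estimation points on normalized time [0, 1], with
observations weighted by a Gaussian kernel centred at the estimation point.
The kernel bandwidth controls the flexibility: small bandwidths give highly
local (fast-changing, noisy) estimates; bandwidths well above 1 weight all
observations equally and recover a stationary fit.

Each local fit is a set of p independent nodewise lasso regressions, which can
set coefficients exactly to zero — edges of the network are exactly the
nonzero coefficients. Input must be standardized (the L1 penalty is scale
sensitive) and complete (impute first).

Coefficient orientation: ``B[i, j]`` is the effect of variable j at day t-1 on
variable i at day t (row = response, column = predictor).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import lasso as _lasso
from .datasets import DiaryDataset

__all__ = [
    "STATIONARY_BANDWIDTH",
    "KernelSpec",
    "LocalVarFit",
    "TvVarModel",
    "make_estimation_grid",
    "kernel_weights",
    "fit_nodewise_lasso",
    "fit_tvvar",
    "predict_at_day",
    "predict_all_days",
]

# Bandwidths at or above this are numerically indistinguishable from the
# uniform-weight limit on a [0, 1] time axis (relative weight variation below
# 5e-5), so the exact stationary limit is returned instead of the kernel.
STATIONARY_BANDWIDTH = 100.0

_WEIGHT_FLOOR = 1e-10


@dataclass
class KernelSpec:
    """Gaussian kernel on normalized time with an equidistant estimation grid."""

    bandwidth: float
    n_estimation_points: int = 20
    estimation_grid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.bandwidth <= 0:
            raise ValueError("bandwidth must be positive")
        if self.estimation_grid is None:
            self.estimation_grid = make_estimation_grid(self.n_estimation_points)


@dataclass
class LocalVarFit:
    """One local VAR(1): intercepts, lag-1 matrix B, residual scales.

    ``B[i, j]``: effect of predictor j (day t-1) on response i (day t).
    ``flags`` may contain "endpoint" (boundary estimation point; fewer data on
    one side) or "low_ess" (effective sample size below p+1; the fit is forced
    empty rather than estimated).
    """

    intercepts: np.ndarray
    B: np.ndarray
    residual_sd: np.ndarray
    lambda_used: np.ndarray
    flags: list[str] = field(default_factory=list)


@dataclass
class TvVarModel:
    """A sequence of local VAR(1) fits over the estimation grid."""

    kernel: KernelSpec
    fits: list[LocalVarFit]
    T: int
    var_names: list[str]

    @property
    def n_points(self) -> int:
        return len(self.fits)

    @property
    def p(self) -> int:
        return len(self.var_names)

    def coef_array(self) -> np.ndarray:
        """(n_points, p, p) stack of lag-1 coefficient matrices."""
        return np.stack([f.B for f in self.fits])

    def grid_days(self) -> np.ndarray:
        """1-based day equivalent of each estimation point."""
        return np.rint(1 + self.kernel.estimation_grid * (self.T - 1)).astype(int)

    def to_json(self, path) -> None:
        obj = {
            "bandwidth": self.kernel.bandwidth,
            "n_estimation_points": self.kernel.n_estimation_points,
            "estimation_grid": self.kernel.estimation_grid.tolist(),
            "T": self.T,
            "var_names": self.var_names,
            "coefficient_orientation": "B[i,j] = effect of j at t-1 on i at t",
            "fits": [
                {
                    "intercepts": f.intercepts.tolist(),
                    "B": f.B.tolist(),
                    "residual_sd": f.residual_sd.tolist(),
                    "lambda_used": f.lambda_used.tolist(),
                    "flags": f.flags,
                }
                for f in self.fits
            ],
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1, sort_keys=True)

    def edge_list(self, point: int) -> pd.DataFrame:
        """Nonzero edges at a 1-based estimation point as (from, to, weight)."""
        B = self.fits[point - 1].B
        rows = [
            {"from": self.var_names[j], "to": self.var_names[i], "weight": B[i, j]}
            for i in range(self.p)
            for j in range(self.p)
            if B[i, j] != 0.0
        ]
        return pd.DataFrame(rows, columns=["from", "to", "weight"])


def make_estimation_grid(n_points: int = 20) -> np.ndarray:
    """Equidistant normalized times e_k = (k-1)/(n_points-1), k = 1..n_points."""
    if n_points < 2:
        raise ValueError("need at least 2 estimation points")
    return np.linspace(0.0, 1.0, n_points)


def _pair_times(T: int) -> np.ndarray:
    """Normalized times of the T-1 lag pairs, indexed by the response day 2..T."""
    return np.arange(1, T) / (T - 1)


def _raw_kernel(times: np.ndarray, t_e: float, bandwidth: float) -> np.ndarray:
    if bandwidth >= STATIONARY_BANDWIDTH:
        return np.ones_like(times)
    return np.exp(-((times - t_e) ** 2) / (2.0 * bandwidth**2))


def kernel_weights(t_e: float, T: int, bandwidth: float) -> np.ndarray:
    """Gaussian kernel weights over the T-1 lag pairs, renormalized to max 1.

    Weights below 1e-10 (after normalization) are zeroed to bound cost.
    """
    if T < 3:
        raise ValueError("need T >= 3")
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    w = _raw_kernel(_pair_times(T), t_e, bandwidth)
    w = w / w.max()
    w[w < _WEIGHT_FLOOR] = 0.0
    return w


def fit_nodewise_lasso(
    X: np.ndarray,
    y: np.ndarray,
    w: np.ndarray,
    lam: float | str = "auto",
    seed: int = 0,
    lam_folds: int = 10,
    lam_path: tuple[int, float] = (50, 4.0),
) -> tuple[float, np.ndarray, float, float]:
    """One weighted lasso regression: returns (intercept, coefs, residual_sd, lambda).

    Penalty selection over a log-spaced path (``lam_path`` = (length, decades
    below lam_max)):
      "auto" / "ebic" — extended BIC (gamma 0.25), deterministic;
      "cv"            — weighted ``lam_folds``-fold cross-validation at the
                        minimum CV error, folds drawn from ``seed``;
      a float         — used as given.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    w = np.asarray(w, float)
    if lam in ("auto", "ebic"):
        lam = _lasso.ebic_lambda(X, y, w, 0.25, *lam_path)
    elif lam == "cv":
        rng = np.random.default_rng(seed)
        lam = _lasso.cv_lambda(X, y, w, rng, lam_folds, *lam_path)
    b0, b = _lasso.weighted_lasso(X, y, w, float(lam))
    resid = y - b0 - X @ b
    S = w.sum()
    residual_sd = float(np.sqrt((w * resid**2).sum() / S))
    return b0, b, residual_sd, float(lam)


def _nodewise_seed(seed: int, response: int) -> int:
    # independent of the estimation point so that the uniform-weight limit of
    # every local fit coincides exactly with the stationary fit
    return (int(seed) * 1_000_003 + 7919 * (response + 1)) % (2**31)


def _fit_local(
    X: np.ndarray,
    Y: np.ndarray,
    w: np.ndarray,
    lam: float | str,
    seed: int,
    lam_folds: int,
    lam_path: tuple[int, float],
    flags: list[str],
) -> LocalVarFit:
    """All p nodewise regressions at one estimation point."""
    p = Y.shape[1]
    if w.sum() < p + 1:
        # too little local information: report an empty network, not an error
        sd = np.sqrt((w @ Y**2) / max(w.sum(), 1e-300)) if w.sum() > 0 else np.ones(p)
        return LocalVarFit(
            intercepts=np.zeros(p),
            B=np.zeros((p, p)),
            residual_sd=np.asarray(sd, float),
            lambda_used=np.full(p, np.nan),
            flags=flags + ["low_ess"],
        )
    intercepts = np.empty(p)
    B = np.empty((p, p))
    rsd = np.empty(p)
    lams = np.empty(p)
    for i in range(p):
        b0, b, sd, lam_i = fit_nodewise_lasso(
            X, Y[:, i], w, lam, _nodewise_seed(seed, i), lam_folds, lam_path
        )
        intercepts[i], B[i], rsd[i], lams[i] = b0, b, sd, lam_i
    return LocalVarFit(intercepts, B, rsd, lams, flags)


def fit_local_models(
    times: np.ndarray,
    X: np.ndarray,
    Y: np.ndarray,
    kernel: KernelSpec,
    lam: float | str = "auto",
    seed: int = 0,
    lam_folds: int = 10,
    lam_path: tuple[int, float] = (50, 4.0),
    pair_weights: np.ndarray | None = None,
) -> list[LocalVarFit]:
    """Local VAR fits over the grid for arbitrary (time, predictor, response) triples.

    This is the engine shared by plain fitting, cross-validation (where
    held-out pairs get ``pair_weights`` 0) and the block bootstrap (where
    pairs are resampled but keep their original times).
    """
    fits = []
    grid = kernel.estimation_grid
    stationary = kernel.bandwidth >= STATIONARY_BANDWIDTH
    for k, t_e in enumerate(grid):
        flags = ["endpoint"] if k in (0, len(grid) - 1) else []
        if stationary and fits:
            # uniform weights at every grid point: the local fits coincide
            first = fits[0]
            if "low_ess" in first.flags:
                flags = flags + ["low_ess"]
            fits.append(
                LocalVarFit(
                    first.intercepts.copy(),
                    first.B.copy(),
                    first.residual_sd.copy(),
                    first.lambda_used.copy(),
                    flags,
                )
            )
            continue
        w = _raw_kernel(times, t_e, kernel.bandwidth)
        if pair_weights is not None:
            w = w * pair_weights
        wmax = w.max()
        if wmax > 0:
            w = w / wmax
        w[w < _WEIGHT_FLOOR] = 0.0
        fits.append(_fit_local(X, Y, w, lam, seed, lam_folds, lam_path, flags))
    return fits


def _check_ready(ds: DiaryDataset) -> None:
    if not ds.complete:
        raise ValueError("dataset has missing entries; impute first")
    if not ds.standardized:
        raise ValueError("dataset is not standardized; the lasso requires z-scores")
    if not np.all(np.isfinite(ds.values)):
        raise ValueError("non-finite values in dataset")


def fit_tvvar(
    ds: DiaryDataset,
    bandwidth: float,
    n_points: int = 20,
    lam: float | str = "auto",
    seed: int = 0,
    lam_folds: int = 10,
    lam_path: tuple[int, float] = (50, 4.0),
    pair_weights: np.ndarray | None = None,
) -> TvVarModel:
    """Fit the full time-varying VAR(1) on a complete standardized dataset."""
    _check_ready(ds)
    if ds.T < 30:
        raise ValueError("series too short for time-varying estimation (T < 30)")
    kernel = KernelSpec(bandwidth=bandwidth, n_estimation_points=n_points)
    X = ds.values[:-1]
    Y = ds.values[1:]
    fits = fit_local_models(
        _pair_times(ds.T), X, Y, kernel, lam, seed, lam_folds, lam_path, pair_weights
    )
    return TvVarModel(kernel, fits, ds.T, list(ds.var_names))


def _point_mixture(model: TvVarModel, times: np.ndarray) -> np.ndarray:
    """(n_days, n_points) convex weights of each local model at each day time."""
    grid = model.kernel.estimation_grid
    W = np.stack(
        [_raw_kernel(times, t_e, model.kernel.bandwidth) for t_e in grid], axis=1
    )
    return W / W.sum(axis=1, keepdims=True)


def predict_all_days(model: TvVarModel, ds: DiaryDataset) -> np.ndarray:
    """(T-1, p) predictions for days 2..T by kernel-mixing the local models."""
    if ds.p != model.p or ds.T != model.T:
        raise ValueError("dataset dimensions do not match model")
    X = ds.values[:-1]
    times = _pair_times(ds.T)
    V = _point_mixture(model, times)
    pred = np.zeros((ds.T - 1, model.p))
    for k, f in enumerate(model.fits):
        pred += V[:, k][:, None] * (f.intercepts[None, :] + X @ f.B.T)
    return pred


def predict_at_day(model: TvVarModel, ds: DiaryDataset, day: int) -> np.ndarray:
    """Predicted values for a 1-based ``day`` (>= 2) from the previous day.

    The prediction is the kernel-weight-normalized combination of the local
    models' predictions, each estimation point weighted by its kernel
    evaluated at the day's normalized time.
    """
    if not 2 <= day <= ds.T:
        raise ValueError("day out of range (need 2 <= day <= T)")
    return predict_all_days(model, ds)[day - 2]
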