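"""Parametric-bootstrap test of the null hypothesis that the process is stationary.

Test statistic: the cross-validated prediction-error improvement of the best
time-varying bandwidth over a stationary lasso VAR(1) fit,

    stat = CV-RMSE(stationary) - min over candidate bandwidths of CV-RMSE(tv).

Under the null this improvement is only selection noise; its null distribution
is obtained by refitting the statistic on B datasets simulated from the
stationary model fitted to the observed data (parametric bootstrap, Gaussian
innovations with the fitted residual SDs, same T, same fold seeds). The
p-value uses the add-one estimator (1 + #{null >= observed}) / (B + 1), which
can never be exactly zero.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .bandwidth import cv_select_bandwidth, make_time_stratified_folds
from .datasets import DiaryDataset, z_standardize
from .tvvar import (
    STATIONARY_BANDWIDTH,
    LocalVarFit,
    fit_tvvar,
)

__all__ = [
    "StationarityTestResult",
    "fit_stationary_var",
    "simulate_from_var",
    "stationarity_test",
]


@dataclass
class StationarityTestResult:
    observed_stat: float
    null_stats: np.ndarray
    p_value: float
    alpha: float
    reject: bool
    B: int
    seed: int
    stabilized: bool = False

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "observed_stat": self.observed_stat,
                    "null_stats": self.null_stats.tolist(),
                    "p_value": self.p_value,
                    "alpha": self.alpha,
                    "reject": self.reject,
                    "B": self.B,
                    "seed": self.seed,
                    "stabilized": self.stabilized,
                },
                fh,
                indent=1,
                sort_keys=True,
            )


def fit_stationary_var(
    ds: DiaryDataset,
    seed: int = 0,
    lam: float | str = "auto",
    lam_folds: int = 10,
    lam_path: tuple[int, float] = (50, 4.0),
) -> LocalVarFit:
    """Single lasso VAR(1) with uniform weights (the large-bandwidth limit)."""
    model = fit_tvvar(
        ds,
        STATIONARY_BANDWIDTH,
        n_points=2,
        lam=lam,
        seed=seed,
        lam_folds=lam_folds,
        lam_path=lam_path,
    )
    return model.fits[0]


def simulate_from_var(
    fit: LocalVarFit, T: int, seed: int = 0, participant_id: str = "simulated"
) -> DiaryDataset:
    """Simulate a complete daily series from a fitted stationary VAR(1).

    x_t = c + B x_{t-1} + eps_t with independent Gaussian innovations at the
    fitted residual SDs; a 100-step burn-in is discarded.
    """
    B = np.asarray(fit.B, float)
    p = B.shape[0]
    rho = float(np.max(np.abs(np.linalg.eigvals(B)))) if p else 0.0
    if rho >= 1.0:
        raise ValueError(f"unstable coefficient matrix (spectral radius {rho:.3f})")
    if np.any(np.asarray(fit.residual_sd) < 0):
        raise ValueError("negative residual SD")
    rng = np.random.default_rng(seed)
    burn = 100
    x = np.zeros(p)
    out = np.empty((T, p))
    eps = rng.standard_normal((burn + T, p)) * np.asarray(fit.residual_sd)[None, :]
    for t in range(burn + T):
        x = fit.intercepts + B @ x + eps[t]
        if t >= burn:
            out[t - burn] = x
    dates = pd.date_range("2020-01-01", periods=T, freq="D")
    return DiaryDataset(
        participant_id,
        dates,
        out,
        np.ones((T, p), dtype=bool),
        [f"V{j + 1}" for j in range(p)],
    )


def _cv_stat(
    ds: DiaryDataset,
    candidates,
    folds,
    n_points,
    seed,
    lam,
    lam_folds,
    lam_path,
) -> float:
    """CV-RMSE(stationary) minus best time-varying CV-RMSE, on given folds."""
    res = cv_select_bandwidth(
        ds,
        list(candidates) + [STATIONARY_BANDWIDTH],
        n_points=n_points,
        seed=seed,
        lam=lam,
        lam_folds=lam_folds,
        lam_path=lam_path,
        folds=folds,
    )
    stationary_rmse = res.mean_rmse[res.candidates >= STATIONARY_BANDWIDTH][0]
    tv_rmse = res.mean_rmse[res.candidates < STATIONARY_BANDWIDTH].min()
    return float(stationary_rmse - tv_rmse)


def stationarity_test(
    ds: DiaryDataset,
    candidates,
    B: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
    k: int = 5,
    n_points: int = 20,
    lam: float | str = "auto",
    lam_folds: int = 10,
    lam_path: tuple[int, float] = (50, 4.0),
) -> StationarityTestResult:
    """Parametric-bootstrap stationarity test on a complete standardized series.

    ``candidates`` are the time-varying bandwidths to search over (all < the
    stationary limit). The fitted stationary model is simulated B times; if
    its coefficient matrix is (numerically) unstable it is shrunk to spectral
    radius 0.98 first and the result flagged ``stabilized``.
    """
    if B < 19:
        raise ValueError("need B >= 19 bootstrap replicates")
    candidates = [float(c) for c in candidates]
    if any(c >= STATIONARY_BANDWIDTH for c in candidates):
        raise ValueError("candidates must be below the stationary limit")
    folds = make_time_stratified_folds(ds.T, k, seed)
    observed = _cv_stat(ds, candidates, folds, n_points, seed, lam, lam_folds, lam_path)

    null_fit = fit_stationary_var(ds, seed=seed, lam=lam, lam_folds=lam_folds, lam_path=lam_path)
    stabilized = False
    rho = float(np.max(np.abs(np.linalg.eigvals(null_fit.B))))
    if rho >= 0.999:
        null_fit = replace(null_fit, B=null_fit.B * (0.98 / rho))
        stabilized = True

    null_stats = np.empty(B)
    for b in range(B):
        sim = simulate_from_var(null_fit, ds.T, seed=(seed * 2654435761 + b + 1) % 2**31)
        sim_std, _ = z_standardize(sim)
        null_stats[b] = _cv_stat(
            sim_std, candidates, folds, n_points, seed, lam, lam_folds, lam_path
        )
    p_value = (1.0 + float(np.sum(null_stats >= observed))) / (B + 1.0)
    return StationarityTestResult(
        observed_stat=observed,
        null_stats=null_stats,
        p_value=p_value,
        alpha=alpha,
        reject=p_value < alpha,
        B=B,
        seed=seed,
        stabilized=stabilized,
    )
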