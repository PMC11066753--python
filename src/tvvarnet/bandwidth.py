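"""Bandwidth selection by time-stratified K-fold cross-validation.

Candidate bandwidths are compared on out-of-sample prediction: lag pairs are
partitioned into K folds stratified over time (each consecutive block of K
pairs contributes one pair to every fold, so every fold spans the whole
series), the time-varying VAR is refit with each fold's pairs removed as
responses, and the bandwidth minimizing the pooled test RMSE wins. Small
bandwidths win when parameters genuinely drift or jump; under a stationary
process the largest candidate wins (bias-variance trade-off).

Held-out days are removed only as responses — their values still serve as
lagged predictors of retained pairs, since removing them outright would break
the lag-1 structure.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datasets import DiaryDataset
from .tvvar import fit_tvvar, predict_all_days

__all__ = [
    "DEFAULT_CANDIDATES",
    "CvBandwidthResult",
    "make_time_stratified_folds",
    "cv_select_bandwidth",
]

# brackets the per-participant bandwidths such daily-diary analyses select in
# practice (roughly 0.009 through 1.0 on the normalized time scale)
DEFAULT_CANDIDATES = (0.009, 0.01, 0.05, 0.12, 0.23, 0.34, 0.45, 0.7, 1.0)


@dataclass
class CvBandwidthResult:
    """Candidate-by-fold test-error table and the selected bandwidth."""

    candidates: np.ndarray
    fold_rmse: np.ndarray  # (n_candidates, k)
    mean_rmse: np.ndarray
    selected: float

    def to_frame(self) -> pd.DataFrame:
        k = self.fold_rmse.shape[1]
        return pd.DataFrame(
            [
                {"candidate": c, "fold": f, "rmse": self.fold_rmse[i, f]}
                for i, c in enumerate(self.candidates)
                for f in range(k)
            ]
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "candidates": self.candidates.tolist(),
                    "mean_rmse": self.mean_rmse.tolist(),
                    "selected": self.selected,
                },
                fh,
                indent=1,
                sort_keys=True,
            )


def make_time_stratified_folds(T: int, k: int = 5, seed: int = 0) -> np.ndarray:
    """Fold labels (0..k-1) for the T-1 lag pairs, stratified over time.

    Each consecutive block of k pairs is a random permutation of the k fold
    labels; a shorter trailing block gets distinct random labels. Every fold
    therefore spans the full time range, and within any fold consecutive
    members are at most 2k-1 apart.
    """
    if k < 1:
        raise ValueError("need k >= 1")
    n = T - 1
    if T < 3 * k:
        raise ValueError("series too short for this many folds (need T >= 3k)")
    if k == 1:
        return np.zeros(n, dtype=int)
    rng = np.random.default_rng(seed)
    labels = np.empty(n, dtype=int)
    for start in range(0, n, k):
        block = min(k, n - start)
        labels[start : start + block] = rng.permutation(k)[:block]
    return labels


def cv_select_bandwidth(
    ds: DiaryDataset,
    candidates=DEFAULT_CANDIDATES,
    k: int = 5,
    n_points: int = 20,
    seed: int = 0,
    lam: float | str = "auto",
    lam_folds: int = 10,
    lam_path: tuple[int, float] = (50, 4.0),
    folds: np.ndarray | None = None,
) -> CvBandwidthResult:
    """Compare candidate bandwidths by K-fold CV and select the RMSE minimizer.

    For each candidate and fold, the tv-VAR is fit with the held-out pairs'
    response weights set to zero (the penalty is re-selected within each
    training fit), held-out responses are predicted, and the RMSE is pooled
    over variables. Ties in mean RMSE resolve toward the larger bandwidth
    (prefer the smoother, more stationary model).
    """
    candidates = np.asarray(sorted(candidates), dtype=float)
    if candidates.size == 0 or np.any(candidates <= 0):
        raise ValueError("candidates must be nonempty and positive")
    if folds is None:
        folds = make_time_stratified_folds(ds.T, k, seed)
    k_eff = int(folds.max()) + 1
    Y = ds.values[1:]
    fold_rmse = np.empty((len(candidates), k_eff))
    for ci, bw in enumerate(candidates):
        for f in range(k_eff):
            train_w = (folds != f).astype(float)
            model = fit_tvvar(
                ds,
                bw,
                n_points,
                lam,
                seed=seed * 613 + f,
                lam_folds=lam_folds,
                lam_path=lam_path,
                pair_weights=train_w,
            )
            pred = predict_all_days(model, ds)
            held = folds == f
            fold_rmse[ci, f] = float(
                np.sqrt(np.mean((Y[held] - pred[held]) ** 2))
            )
    mean_rmse = fold_rmse.mean(axis=1)
    best = mean_rmse.min()
    # ties toward the larger bandwidth; candidates are sorted ascending
    selected = float(candidates[np.flatnonzero(mean_rmse <= best + 1e-12)[-1]])
    return CvBandwidthResult(candidates, fold_rmse, mean_rmse, selected)
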