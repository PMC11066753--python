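"""Block bootstrap for the sampling distribution of time-varying VAR parameters.

Lasso regularization precludes conventional analytic confidence intervals, so
uncertainty is assessed by resampling. The resampling unit is the lag pair
(x_{t-1}, x_t): circular blocks of consecutive pairs are drawn with random
start positions and concatenated, which preserves both the within-pair
predictor/response linkage and the local serial dependence. Each resampled
pair keeps its original normalized time, so kernel weighting in the replicate
fits refers to real calendar positions. The penalty is re-selected within
every replicate, propagating selection uncertainty into the bands.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datasets import DiaryDataset
from .tvvar import KernelSpec, TvVarModel, _check_ready, _pair_times, fit_local_models

__all__ = ["BootstrapEnsemble", "block_bootstrap_indices", "bootstrap_tvvar"]


@dataclass
class BootstrapEnsemble:
    """Bootstrap replicates of the coefficient trajectories plus quantile bands."""

    n_boot: int
    block_length: int
    coef_samples: np.ndarray  # (n_boot, n_points, p, p)
    band_low: np.ndarray  # (n_points, p, p)
    band_high: np.ndarray
    quantiles: tuple[float, float]
    seed: int
    var_names: list[str]

    def band_width(self) -> np.ndarray:
        return self.band_high - self.band_low

    def to_frame(self) -> pd.DataFrame:
        """Long format: (boot_id, estimation_point, response, predictor, value)."""
        n_boot, n_points, p, _ = self.coef_samples.shape
        b, k, i, j = np.meshgrid(
            np.arange(n_boot), np.arange(n_points), np.arange(p), np.arange(p),
            indexing="ij",
        )
        return pd.DataFrame(
            {
                "boot_id": b.ravel(),
                "estimation_point": k.ravel() + 1,
                "response": np.asarray(self.var_names)[i.ravel()],
                "predictor": np.asarray(self.var_names)[j.ravel()],
                "value": self.coef_samples.ravel(),
            }
        )


def block_bootstrap_indices(n: int, block_length: int, seed: int = 0) -> np.ndarray:
    """Circular moving-block bootstrap indices of length n (0-based).

    Blocks of ``block_length`` consecutive indices (wrapping at n) start at
    uniformly random positions; their concatenation is truncated to n.
    """
    if not 1 <= block_length <= n:
        raise ValueError("need 1 <= block_length <= n")
    rng = np.random.default_rng(seed)
    n_blocks = math.ceil(n / block_length)
    starts = rng.integers(0, n, size=n_blocks)
    idx = (starts[:, None] + np.arange(block_length)[None, :]) % n
    return idx.ravel()[:n]


def bootstrap_tvvar(
    ds: DiaryDataset,
    bandwidth: float,
    n_points: int = 20,
    n_boot: int = 50,
    block_length: int | str = "auto",
    seed: int = 0,
    lam: float | str = "auto",
    lam_folds: int = 10,
    lam_path: tuple[int, float] = (50, 4.0),
    quantiles: tuple[float, float] = (0.05, 0.95),
) -> BootstrapEnsemble:
    """Refit the tv-VAR on block-resampled lag pairs and collect quantile bands.

    ``block_length="auto"`` uses ceil(sqrt(n)), the standard rate-motivated
    default for series of this length.
    """
    _check_ready(ds)
    n = ds.T - 1
    if block_length == "auto":
        block_length = math.ceil(math.sqrt(n))
    block_length = int(block_length)
    X = ds.values[:-1]
    Y = ds.values[1:]
    times = _pair_times(ds.T)
    kernel = KernelSpec(bandwidth=bandwidth, n_estimation_points=n_points)
    p = ds.p
    coef = np.empty((n_boot, n_points, p, p))
    for r in range(n_boot):
        rep_seed = (seed * 69069 + 1 + r) % 2**31
        idx = block_bootstrap_indices(n, block_length, seed=rep_seed)
        fits = fit_local_models(
            times[idx], X[idx], Y[idx], kernel, lam, rep_seed, lam_folds, lam_path
        )
        coef[r] = np.stack([f.B for f in fits])
    lo, hi = quantiles
    band_low = np.quantile(coef, lo, axis=0)
    band_high = np.quantile(coef, hi, axis=0)
    return BootstrapEnsemble(
        n_boot=n_boot,
        block_length=block_length,
        coef_samples=coef,
        band_low=band_low,
        band_high=band_high,
        quantiles=quantiles,
        seed=seed,
        var_names=list(ds.var_names),
    )
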