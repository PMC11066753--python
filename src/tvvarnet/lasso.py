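"""Weighted lasso solver used by every nodewise regression.

Objective, for observation weights w_i >= 0 with S = sum(w):

    (1 / (2 S)) * sum_i w_i (y_i - b0 - x_i . b)^2  +  lam * ||b||_1

The intercept b0 is unpenalized, so the problem reduces (by weighted
centering) to a penalized regression through the origin. The solver is
cyclic coordinate descent on the weighted Gram matrix (covariance updating),
which makes a solve O(p^2) per sweep independent of n — essential because a
single participant's pipeline performs tens of thousands of solves across
estimation points, folds and lambda paths.

At lam >= lam_max = max_j |cov_j| the solution is exactly the null model;
coefficients may hit exact zeros below that, which is what yields sparse
(possibly empty) networks.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "weighted_lasso",
    "lambda_path",
    "ebic_lambda",
    "cv_lambda",
    "weighted_lasso_path",
]

_TOL = 1e-12
_MAX_SWEEPS = 10_000


def _weighted_moments(X: np.ndarray, y: np.ndarray, w: np.ndarray):
    """Weighted means, centered Gram G = X'WX/S and covariance c = X'Wy/S."""
    S = w.sum()
    if S <= 0:
        raise ValueError("weights must not be all zero")
    xm = (w @ X) / S
    ym = float(w @ y) / S
    Xc = X - xm
    yc = y - ym
    Xw = Xc * w[:, None]
    G = (Xw.T @ Xc) / S
    c = (Xw.T @ yc) / S
    return xm, ym, G, c


def _cd_solve(G: np.ndarray, c: np.ndarray, lam: float, b: np.ndarray) -> np.ndarray:
    """Cyclic coordinate descent on the centered Gram system, warm-started at b.

    Operates on plain Python floats: with p <= ~10 predictors the per-sweep
    cost is a handful of scalar ops, far below numpy call overhead.
    """
    p = len(c)
    diag = [float(G[j, j]) for j in range(p)]
    active = [j for j in range(p) if diag[j] > 0]
    if not active:
        raise ValueError("degenerate design: all predictors have zero weighted variance")
    Gl = [[float(v) for v in row] for row in G]
    cl = [float(v) for v in c]
    bl = [float(v) if diag[j] > 0 else 0.0 for j, v in enumerate(b)]
    _cd_core(Gl, cl, diag, active, float(lam), bl)
    out = np.zeros(p)
    out[:] = bl
    return out


def _cd_core(Gl, cl, diag, active, lam, bl) -> None:
    """Inner coordinate-descent loop on pure Python floats; mutates bl."""
    for _ in range(_MAX_SWEEPS):
        delta = 0.0
        for j in active:
            Gj = Gl[j]
            dj = diag[j]
            # partial residual covariance for coordinate j
            rho = cl[j] + dj * bl[j]
            for k in active:
                rho -= Gj[k] * bl[k]
            if rho > lam:
                new = (rho - lam) / dj
            elif rho < -lam:
                new = (rho + lam) / dj
            else:
                new = 0.0
            d = abs(new - bl[j])
            if d > delta:
                delta = d
            bl[j] = new
        if delta < _TOL:
            break


def weighted_lasso(
    X: np.ndarray,
    y: np.ndarray,
    w: np.ndarray,
    lam: float,
    warm: np.ndarray | None = None,
) -> tuple[float, np.ndarray]:
    """Solve the weighted lasso at one penalty. Returns (intercept, coefficients)."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    w = np.asarray(w, float)
    if not (X.shape[0] == len(y) == len(w)):
        raise ValueError("X, y, w lengths differ")
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    xm, ym, G, c = _weighted_moments(X, y, w)
    b0 = np.zeros(X.shape[1]) if warm is None else np.asarray(warm, float)
    b = _cd_solve(G, c, float(lam), b0)
    return ym - float(xm @ b), b


def lambda_path(lam_max: float, n_lambdas: int = 50, decades: float = 4.0) -> np.ndarray:
    """Log-spaced penalty path from lam_max down ``decades`` orders of magnitude."""
    if lam_max <= 0:
        return np.array([0.0])
    return np.geomspace(lam_max, lam_max * 10.0 ** (-decades), n_lambdas)


def weighted_lasso_path(G, c, lams) -> np.ndarray:
    """Warm-started solutions along a decreasing penalty path (n_lambdas, p)."""
    p = len(c)
    diag = [float(G[j, j]) for j in range(p)]
    active = [j for j in range(p) if diag[j] > 0]
    if not active:
        raise ValueError("degenerate design: all predictors have zero weighted variance")
    Gl = [[float(v) for v in row] for row in G]
    cl = [float(v) for v in c]
    bl = [0.0] * p
    out = np.empty((len(lams), p))
    for i, lam in enumerate(lams):
        _cd_core(Gl, cl, diag, active, float(lam), bl)
        out[i] = bl
    return out


def ebic_lambda(
    X: np.ndarray,
    y: np.ndarray,
    w: np.ndarray,
    gamma: float = 0.25,
    n_lambdas: int = 50,
    decades: float = 4.0,
) -> float:
    """Select the penalty by the extended BIC along the path (deterministic).

    EBIC = S log(wMSE) + df log(S) + 2 gamma df log(p), with S the effective
    (weighted) sample size and df the number of nonzero coefficients. Prunes
    aggressively on noise while leaving strong effects nearly unshrunk, which
    is the behaviour sparse network estimation wants.
    """
    active = np.flatnonzero(w > 0)
    Xa, ya, wa = X[active], y[active], w[active]
    xm, ym, G, c = _weighted_moments(Xa, ya, wa)
    lams = lambda_path(float(np.max(np.abs(c))), n_lambdas, decades)
    betas = weighted_lasso_path(G, c, lams)
    S = wa.sum()
    res = (ya - ym)[None, :] - betas @ (Xa - xm).T
    wmse = (res**2 * wa[None, :]).sum(axis=1) / S
    df = (betas != 0).sum(axis=1)
    p = X.shape[1]
    ebic = S * np.log(np.maximum(wmse, 1e-12)) + df * (
        np.log(S) + 2.0 * gamma * np.log(p)
    )
    # lams descend; argmin takes the first (largest-penalty) minimizer
    return float(lams[int(np.argmin(ebic))])


def cv_lambda(
    X: np.ndarray,
    y: np.ndarray,
    w: np.ndarray,
    rng: np.random.Generator,
    n_folds: int = 10,
    n_lambdas: int = 50,
    decades: float = 4.0,
) -> float:
    """Select the penalty by weighted K-fold cross-validation.

    Only rows with positive weight participate. The path runs from the full
    data's lam_max downward; the minimum mean CV error wins, with ties (within
    numerical noise) resolving toward the larger penalty.
    """
    active = np.flatnonzero(w > 0)
    _, _, _, c_full = _weighted_moments(X[active], y[active], w[active])
    lams = lambda_path(float(np.max(np.abs(c_full))), n_lambdas, decades)
    if len(active) < 2 * n_folds:
        n_folds = max(2, len(active) // 3)
        if n_folds < 2:
            return float(lams[0])
    labels = np.asarray(
        [f % n_folds for f in range(len(active))], dtype=int
    )
    rng.shuffle(labels)
    err = np.zeros((len(lams), n_folds))
    for f in range(n_folds):
        tr = active[labels != f]
        te = active[labels == f]
        if len(tr) < 2 or len(te) == 0:
            continue
        xm, ym, G, c = _weighted_moments(X[tr], y[tr], w[tr])
        betas = weighted_lasso_path(G, c, lams)
        # test-set weighted MSE per lambda
        Xte = X[te] - xm
        res = (y[te] - ym)[None, :] - betas @ Xte.T
        err[:, f] = (res**2 * w[te][None, :]).sum(axis=1) / w[te].sum()
    mean = err.mean(axis=1)
    best = float(mean.min())
    # lams descend, so the first qualifying index is the largest such penalty
    return float(lams[np.flatnonzero(mean <= best + 1e-12)[0]])
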