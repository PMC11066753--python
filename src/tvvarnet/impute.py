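"""Item-wise missing-value imputation by Kalman smoothing.

Each variable is modelled separately with a structural (unobserved-components)
state-space model — local linear trend by default, falling back to a local
level model if the trend fit does not converge. Variances are estimated by
maximum likelihood; missing entries are replaced by the smoothed level, so the
imputation borrows strength from both past and future observations. Observed
entries are never touched.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import statsmodels.api as sm

from .datasets import DiaryDataset

__all__ = ["StateSpaceFit", "fit_state_space", "kalman_impute"]

_FORMS = {"local_level": "llevel", "local_linear_trend": "lltrend"}


@dataclass
class StateSpaceFit:
    """A fitted structural model for one series."""

    form: str
    variances: dict[str, float]
    log_likelihood: float
    converged: bool
    smoothed_level: np.ndarray


def fit_state_space(series: np.ndarray, form: str = "local_linear_trend") -> StateSpaceFit:
    """Maximum-likelihood fit of a structural model to one series with gaps.

    Parameters
    ----------
    series : 1-D float array with NaN at missing entries.
    form : "local_level" or "local_linear_trend".

    Deterministic given the data: the optimizer starts from the model's
    canonical start parameters (no randomness).
    """
    if form not in _FORMS:
        raise ValueError(f"unknown model form {form!r}")
    y = np.asarray(series, dtype=float)
    obs = y[np.isfinite(y)]
    if obs.size < 10:
        raise ValueError("need at least 10 observed points")
    if np.nanstd(y) == 0:
        raise ValueError("series is constant")
    mod = sm.tsa.UnobservedComponents(y, level=_FORMS[form])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = mod.fit(method="lbfgs", maxiter=500, disp=0, gtol=1e-8)
    converged = bool(np.isfinite(res.llf)) and bool(
        res.mle_retvals.get("converged", True)
    )
    variances = {
        name: max(float(v), 1e-12) for name, v in zip(res.param_names, res.params)
    }
    return StateSpaceFit(
        form=form,
        variances=variances,
        log_likelihood=float(res.llf),
        converged=converged,
        smoothed_level=np.asarray(res.level["smoothed"], dtype=float),
    )


def kalman_impute(ds: DiaryDataset) -> DiaryDataset:
    """Fill every missing entry of a diary dataset by Kalman smoothing.

    Observed entries pass through bit-for-bit; missing entries take the
    smoothed-level prediction of the per-variable structural model. The local
    linear trend form is tried first; on non-convergence the local level form
    is used instead.
    """
    values = ds.values.copy()
    for j, name in enumerate(ds.var_names):
        col_mask = ds.mask[:, j]
        if col_mask.all():
            continue
        try:
            fit = fit_state_space(ds.values[:, j], "local_linear_trend")
            if not fit.converged:
                fit = fit_state_space(ds.values[:, j], "local_level")
            if not fit.converged:
                raise RuntimeError("state-space fit did not converge")
        except Exception as exc:
            raise RuntimeError(f"imputation failed for variable {name!r}: {exc}") from exc
        missing = ~col_mask
        values[missing, j] = fit.smoothed_level[missing]
    return replace(
        ds,
        values=values,
        mask=np.ones_like(ds.mask, dtype=bool),
    )
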