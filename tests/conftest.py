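import numpy as np
import pandas as pd
import pytest

from tvvarnet import DiaryDataset, EdgeTrajectory, TrajectorySpec, generate_tvvar_series, z_standardize


def make_dataset(values, mask=None, standardized=False, pid="p1"):
    """Wrap a (T, p) array in a DiaryDataset on a daily calendar grid."""
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        values = values[:, None]
    if mask is None:
        mask = np.isfinite(values)
    dates = pd.date_range("2021-01-01", periods=values.shape[0], freq="D")
    names = [f"V{j + 1}" for j in range(values.shape[1])]
    return DiaryDataset(pid, dates, values, np.asarray(mask, bool), names, standardized)


def diag_ar_spec(p, a=0.3, extra=None):
    """Stationary spec: AR(1) diagonal ``a`` plus optional extra edge trajectories."""
    edges = {(i, i): EdgeTrajectory("constant", a) for i in range(p)}
    if extra:
        edges.update(extra)
    return TrajectorySpec(p, edges)


def standardized_var_dataset(spec, T, seed):
    sds = generate_tvvar_series(spec, T, seed=seed)
    ds, _ = z_standardize(sds.ds)
    return ds, sds


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_standardized_ds():
    """T=120, p=3 stationary VAR dataset, standardized — shared across tests."""
    spec = diag_ar_spec(3, extra={(0, 1): EdgeTrajectory("constant", 0.4)})
    ds, _ = standardized_var_dataset(spec, 120, seed=7)
    return ds
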