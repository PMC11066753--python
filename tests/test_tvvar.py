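"""Kernel-weighted nodewise lasso VAR(1): grid, kernel, solver, fitting, prediction."""

import numpy as np
import pytest
from scipy.optimize import minimize

from tvvarnet import (
    EdgeTrajectory,
    fit_nodewise_lasso,
    fit_stationary_var,
    fit_tvvar,
    kernel_weights,
    make_estimation_grid,
    predict_at_day,
)
from tvvarnet.lasso import weighted_lasso
from tvvarnet.tvvar import KernelSpec, LocalVarFit, TvVarModel

from conftest import diag_ar_spec, make_dataset, standardized_var_dataset


def lasso_oracle(X, y, w, lam):
    """Independent solve of the weighted-lasso objective via the smooth
    positive/negative split reformulation and L-BFGS-B."""
    n, p = X.shape
    S = w.sum()

    def f(z):
        b0, bp, bm = z[0], z[1 : p + 1], z[p + 1 :]
        r = y - b0 - X @ (bp - bm)
        return (w * r**2).sum() / (2 * S) + lam * (bp.sum() + bm.sum())

    bounds = [(None, None)] + [(0, None)] * (2 * p)
    res = minimize(
        f, np.zeros(1 + 2 * p), method="L-BFGS-B", bounds=bounds,
        options={"ftol": 1e-16, "gtol": 1e-12, "maxiter": 5000},
    )
    return res.x[0], res.x[1 : p + 1] - res.x[p + 1 :]


class TestEstimationGrid:
    def test_default_twenty_points(self):
        g = make_estimation_grid(20)
        assert len(g) == 20 and g[0] == 0 and g[-1] == 1
        np.testing.assert_allclose(np.diff(g), 1 / 19)

    @pytest.mark.parametrize(
        "n,expected",
        [(2, [0, 1]), (5, [0, 0.25, 0.5, 0.75, 1])],
    )
    def test_small_grids(self, n, expected):
        np.testing.assert_allclose(make_estimation_grid(n), expected)

    def test_too_few_points_error(self):
        with pytest.raises(ValueError):
            make_estimation_grid(1)


class TestKernelWeights:
    def test_max_at_nearest_pair(self):
        w = kernel_weights(0.37, T=50, bandwidth=0.1)
        times = np.arange(1, 50) / 49
        assert np.argmax(w) == np.argmin(np.abs(times - 0.37))
        assert w.max() == 1.0
        assert np.all(w >= 0) and np.all(w <= 1)

    def test_huge_bandwidth_is_uniform(self):
        w = kernel_weights(0.5, T=100, bandwidth=1e6)
        assert np.all(np.abs(w - 1) < 1e-9)

    def test_matches_direct_formula(self):
        T, t_e, bw = 6, 0.5, 0.25
        times = np.arange(1, T) / (T - 1)
        expected = np.exp(-((times - t_e) ** 2) / (2 * bw**2))
        expected /= expected.max()
        np.testing.assert_allclose(kernel_weights(t_e, T, bw), expected, atol=1e-12)

    def test_bad_args(self):
        with pytest.raises(ValueError):
            kernel_weights(0.5, 2, 0.2)
        with pytest.raises(ValueError):
            kernel_weights(0.5, 10, 0.0)


class TestNodewiseLasso:
    def test_large_lambda_gives_null_model(self, rng):
        X = rng.normal(size=(40, 3))
        y = rng.normal(size=40)
        w = np.ones(40)
        _, b, _, _ = fit_nodewise_lasso(X, y, w, lam=100.0)
        assert np.all(b == 0)

    def test_zero_lambda_matches_ols(self, rng):
        X = rng.normal(size=(30, 2))
        y = X @ [0.5, -0.3] + rng.normal(0, 0.1, 30)
        b0, b, _, _ = fit_nodewise_lasso(X, y, np.ones(30), lam=0.0)
        A = np.column_stack([np.ones(30), X])
        beta = np.linalg.lstsq(A, y, rcond=None)[0]
        np.testing.assert_allclose(np.r_[b0, b], beta, atol=1e-6)

    def test_soft_threshold_closed_form(self, rng):
        n = 50
        x = rng.normal(size=n)
        x = x - x.mean()
        x /= np.sqrt((x**2).sum() / n)  # orthonormalized: mean 0, x'x/n = 1
        y = 0.4 * x + rng.normal(0, 0.5, n)
        for lam in (0.05, 0.2, 1.0):
            _, b, _, _ = fit_nodewise_lasso(x[:, None], y, np.ones(n), lam=lam)
            ols = float(x @ (y - y.mean())) / n
            expected = np.sign(ols) * max(abs(ols) - lam, 0.0)
            assert b[0] == pytest.approx(expected, abs=1e-10)

    def test_matches_convex_oracle(self, rng):
        """Coordinate descent agrees with an independent convex solver of the
        same weighted objective on random small instances."""
        worst = 0.0
        for _ in range(10):
            n = int(rng.integers(10, 41))
            p = int(rng.integers(1, 4))
            X = rng.normal(size=(n, p))
            y = rng.normal(size=n)
            w = rng.uniform(0.1, 2.0, n)
            lam = float(rng.uniform(0.01, 0.3))
            b0, b = weighted_lasso(X, y, w, lam)
            ob0, ob = lasso_oracle(X, y, w, lam)
            worst = max(worst, abs(b0 - ob0), np.max(np.abs(b - ob)))
        assert worst < 1e-5

    def test_degenerate_design_error(self):
        X = np.zeros((20, 2))
        with pytest.raises(ValueError, match="degenerate"):
            fit_nodewise_lasso(X, np.ones(20), np.ones(20), lam=0.1)


class TestFitTvvar:
    def test_twenty_local_models(self, small_standardized_ds):
        m = fit_tvvar(small_standardized_ds, bandwidth=0.3, n_points=20, seed=1)
        assert m.n_points == 20
        assert all(f.B.shape == (3, 3) for f in m.fits)
        assert "endpoint" in m.fits[0].flags and "endpoint" in m.fits[-1].flags

    def test_noise_yields_sparse_networks(self):
        """iid standard normal data: the lasso prunes nearly everything, at
        every estimation point."""
        for seed in range(4):
            rng = np.random.default_rng(100 + seed)
            ds = make_dataset(rng.standard_normal((300, 6)), standardized=True)
            # exact z-scores for the standardization contract
            v = ds.values
            v -= v.mean(0)
            v /= v.std(0, ddof=1)
            m = fit_tvvar(ds, bandwidth=1.0, n_points=10, seed=seed)
            per_point = (m.coef_array() == 0).mean(axis=(1, 2))
            assert per_point.min() >= 0.90

    def test_recovers_stationary_cross_effect(self):
        spec = diag_ar_spec(2, a=0.2, extra={(0, 1): EdgeTrajectory("constant", 0.5)})
        errs = []
        for seed in range(3):
            ds, _ = standardized_var_dataset(spec, 400, seed=seed)
            m = fit_tvvar(ds, bandwidth=1.0, n_points=10, seed=seed)
            interior = m.coef_array()[1:-1, 0, 1]
            errs.append(np.max(np.abs(interior - 0.5)))
        assert np.median(errs) < 0.15

    def test_requires_standardized(self, small_standardized_ds):
        ds = make_dataset(np.random.default_rng(0).normal(size=(100, 2)))
        with pytest.raises(ValueError, match="standardized"):
            fit_tvvar(ds, 0.2)

    def test_requires_complete(self):
        vals = np.random.default_rng(0).normal(size=(100, 2))
        mask = np.ones((100, 2), bool)
        mask[5, 0] = False
        ds = make_dataset(vals, mask, standardized=True)
        with pytest.raises(ValueError, match="missing"):
            fit_tvvar(ds, 0.2)

    def test_too_short_error(self):
        ds = make_dataset(np.random.default_rng(0).normal(size=(20, 2)), standardized=True)
        with pytest.raises(ValueError, match="short"):
            fit_tvvar(ds, 0.2)

    def test_stationary_limit_equals_stationary_fit(self, small_standardized_ds):
        m = fit_tvvar(small_standardized_ds, bandwidth=1e6, n_points=5, seed=3)
        st = fit_stationary_var(small_standardized_ds, seed=3)
        for f in m.fits:
            np.testing.assert_allclose(f.B, st.B, atol=1e-6)
            np.testing.assert_allclose(f.intercepts, st.intercepts, atol=1e-6)


class TestPredictAtDay:
    @staticmethod
    def _toy_model(T, fits, bandwidth=0.2):
        kernel = KernelSpec(bandwidth=bandwidth, n_estimation_points=len(fits))
        return TvVarModel(kernel, fits, T, [f"V{i + 1}" for i in range(fits[0].B.shape[0])])

    def test_identical_local_models_give_common_prediction(self):
        rng = np.random.default_rng(11)
        B = np.array([[0.3, 0.1], [0.0, -0.2]])
        c = np.array([0.5, -0.5])
        fit = LocalVarFit(c, B, np.zeros(2), np.zeros(2))
        fits = [LocalVarFit(c.copy(), B.copy(), np.zeros(2), np.zeros(2)) for _ in range(4)]
        model = self._toy_model(10, fits)
        ds = make_dataset(rng.normal(size=(10, 2)), standardized=True)
        for day in (2, 5, 10):
            expected = c + B @ ds.values[day - 2]
            np.testing.assert_allclose(predict_at_day(model, ds, day), expected, atol=1e-12)

    def test_hand_computed_mixture(self):
        """T=10, two estimation points with hand-set coefficients: the
        prediction is the kernel-normalized convex mix of both local models."""
        B1 = np.array([[0.5, 0.0], [0.0, 0.0]])
        B2 = np.array([[0.0, 0.0], [0.0, -0.4]])
        c1, c2 = np.array([1.0, 0.0]), np.array([0.0, 1.0])
        fits = [
            LocalVarFit(c1, B1, np.zeros(2), np.zeros(2)),
            LocalVarFit(c2, B2, np.zeros(2), np.zeros(2)),
        ]
        model = self._toy_model(10, fits, bandwidth=0.3)
        rng = np.random.default_rng(12)
        ds = make_dataset(rng.normal(size=(10, 2)), standardized=True)
        day = 4
        tau = (day - 1) / 9
        w1 = np.exp(-((tau - 0.0) ** 2) / (2 * 0.3**2))
        w2 = np.exp(-((tau - 1.0) ** 2) / (2 * 0.3**2))
        v1, v2 = w1 / (w1 + w2), w2 / (w1 + w2)
        x = ds.values[day - 2]
        expected = v1 * (c1 + B1 @ x) + v2 * (c2 + B2 @ x)
        np.testing.assert_allclose(predict_at_day(model, ds, day), expected, atol=1e-12)

    def test_day_out_of_range(self, small_standardized_ds):
        m = fit_tvvar(small_standardized_ds, 0.5, n_points=5, seed=0)
        with pytest.raises(ValueError, match="range"):
            predict_at_day(m, small_standardized_ds, 1)
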