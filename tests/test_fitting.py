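import numpy as np
import pytest

import locpois as lp
from locpois.errors import DegenerateNeighborhoodError, InitializationError
from locpois.fitting import fallback_init

from conftest import make_poisson_data


def unit_design(data):
    return lp.LocalDesign(
        Xc=np.column_stack([np.ones(data.n), data.X]),
        w=np.ones(data.n),
        y=data.y,
        x0=np.zeros(data.p),
    )


class TestFitOptions:
    @pytest.mark.parametrize(
        "kwargs", [{"epsilon": 0.0}, {"epsilon": -1.0}, {"max_iter": 0}, {"ridge": -1e-3}]
    )
    def test_invalid_options_rejected(self, kwargs):
        with pytest.raises(ValueError):
            lp.FitOptions(**kwargs)


class TestOlsInit:
    def test_constant_response(self):
        data = lp.CountDataset(y=[7, 7, 7, 7], X=np.array([[0.0], [1.0], [2.0], [3.0]]))
        init = lp.ols_init(data, [1.5])
        np.testing.assert_allclose(init.beta, [7.0, 0.0], atol=1e-10)

    def test_exact_line_recentered(self):
        x = np.array([0.0, 1.0, 2.0, 4.0])
        data = lp.CountDataset(y=(2 * x).astype(int), X=x)
        init = lp.ols_init(data, [3.0])
        # raw fit (0, 2) becomes centered (0 + 2*3, 2)
        np.testing.assert_allclose(init.beta, [6.0, 2.0], atol=1e-10)

    def test_matches_normal_equations_oracle(self):
        data = make_poisson_data(seed=21, n=20, p=2)
        x0 = np.array([0.4, 1.2])
        init = lp.ols_init(data, x0)
        Xs = np.column_stack([np.ones(20), data.X])
        b = np.linalg.inv(Xs.T @ Xs) @ Xs.T @ data.y
        expected = b.copy()
        expected[0] = b[0] + b[1:] @ x0
        np.testing.assert_allclose(init.beta, expected, rtol=1e-8)

    def test_rank_deficient_raises(self):
        X = np.column_stack([np.arange(6.0), 2 * np.arange(6.0)])
        data = lp.CountDataset(y=np.arange(6), X=X)
        with pytest.raises(InitializationError):
            lp.ols_init(data, [0.0, 0.0])


class TestNewtonRaphson:
    def test_intercept_only_closed_form(self):
        y = np.array([3, 5, 8, 2, 9])
        design = lp.LocalDesign(Xc=np.ones((5, 1)), w=np.ones(5), y=y, x0=np.zeros(0))
        fit = lp.newton_raphson(design, lp.LocalParams(beta=[0.0]))
        assert fit.converged
        assert fit.beta.beta[0] == pytest.approx(np.log(y.mean()), abs=1e-9)

    @pytest.mark.parametrize("seed", [0, 5, 17])
    def test_matches_oracle_glm(self, seed):
        sm = pytest.importorskip("statsmodels.api")
        data = make_poisson_data(seed=seed, n=100, p=2)
        design = unit_design(data)
        init = lp.ols_init(data, np.zeros(2))
        fit = lp.newton_raphson(design, init, lp.FitOptions(epsilon=1e-10))
        oracle = sm.GLM(
            data.y, np.column_stack([np.ones(100), data.X]), family=sm.families.Poisson()
        ).fit(tol=1e-12)
        assert fit.converged
        np.testing.assert_allclose(fit.beta.beta, oracle.params, atol=1e-8)

    def test_fixed_point_converges_immediately(self):
        data = make_poisson_data(seed=3, n=60, p=2)
        design = unit_design(data)
        fit = lp.newton_raphson(design, lp.ols_init(data, np.zeros(2)), lp.FitOptions(epsilon=1e-10))
        refit = lp.newton_raphson(design, fit.beta)
        assert refit.converged and refit.n_iter <= 2

    def test_safeguard_never_decreases_loglik(self):
        data = make_poisson_data(seed=9, n=50, p=2)
        design = unit_design(data)
        init = fallback_init(design)
        ll0 = lp.local_loglik(design, init)
        fit = lp.newton_raphson(design, init)
        assert fit.loglik >= ll0 - 1e-9 * abs(ll0)
        assert fit.score_norm < 1e-4

    def test_bad_init_raises(self):
        data = make_poisson_data(seed=9, n=50, p=2)
        design = unit_design(data)
        with pytest.raises(lp.FitError):
            lp.newton_raphson(design, lp.LocalParams(beta=[1e4, 0.0, 0.0], x0=np.zeros(2)))


class TestFitLocal:
    def test_constant_weight_limit_matches_global(self, small_data):
        opts = lp.FitOptions(epsilon=1e-12)
        g = lp.fit_global(small_data, opts)
        span = small_data.X.max(axis=0) - small_data.X.min(axis=0)
        spec = lp.KernelSpec(bandwidths=1e6 * span)
        x0 = small_data.X[5]
        f = lp.fit_local(small_data, x0, spec, opts)
        np.testing.assert_allclose(f.beta.beta[1:], g.beta[1:], atol=1e-6)
        assert np.exp(f.beta.beta[0]) == pytest.approx(g.mean(x0)[0], rel=1e-6)

    def test_recovers_log_linear_truth(self):
        data = make_poisson_data(seed=42, n=2000, p=2, beta=(1.0, 0.5, -0.3))
        x0 = data.X.mean(axis=0)
        fit = lp.fit_local(data, x0, lp.KernelSpec(bandwidths=[0.75, 0.75]))
        se = np.sqrt(np.diag(np.linalg.inv(fit.fisher)))
        assert abs(fit.beta.beta[1] - 0.5) < 3 * se[1]
        assert abs(fit.beta.beta[2] + 0.3) < 3 * se[2]

    def test_isolated_point_with_compact_kernel(self, small_data):
        spec = lp.KernelSpec(family="epanechnikov", bandwidths=[1e-4, 1e-4])
        with pytest.raises(DegenerateNeighborhoodError):
            lp.fit_local(small_data, [50.0, 50.0], spec)

    def test_window_records_bandwidths(self, small_data):
        spec = lp.KernelSpec(bandwidths=[0.7, 1.4])
        fit = lp.fit_local(small_data, small_data.X[0], spec)
        np.testing.assert_allclose(fit.window[:, 1] - fit.window[:, 0], 2 * spec.bandwidths)

    def test_affine_equivariance_under_predictor_shift(self, small_data):
        spec = lp.KernelSpec(bandwidths=[0.8, 0.8])
        opts = lp.FitOptions(epsilon=1e-10)
        x0 = small_data.X[7]
        f1 = lp.fit_local(small_data, x0, spec, opts)
        shifted = lp.CountDataset(y=small_data.y, X=small_data.X + np.array([5.0, -2.0]))
        f2 = lp.fit_local(shifted, x0 + np.array([5.0, -2.0]), spec, opts)
        np.testing.assert_allclose(f1.beta.beta, f2.beta.beta, atol=1e-7)


class TestFitAtObservations:
    def test_shapes(self):
        data = make_poisson_data(seed=1, n=5, p=2)
        fits = lp.fit_at_observations(data, lp.KernelSpec(bandwidths=[1.0, 1.0]))
        assert len(fits) == 5
        assert all(f.beta.beta.size == 3 for f in fits)
        table = lp.fits_to_frame(fits)
        assert list(table.columns) == [
            "point_id", "x0_1", "x0_2", "beta0", "beta1", "beta2", "converged", "n_iter", "loglik",
        ]

    def test_row_permutation_permutes_fits(self):
        data = make_poisson_data(seed=2, n=12, p=2)
        spec = lp.KernelSpec(bandwidths=[0.9, 0.9])
        opts = lp.FitOptions(epsilon=1e-10)
        fits = lp.fit_at_observations(data, spec, opts)
        perm = np.random.default_rng(4).permutation(12)
        permuted = lp.CountDataset(y=data.y[perm], X=data.X[perm])
        fits_p = lp.fit_at_observations(permuted, spec, opts)
        for k, orig in enumerate(perm):
            np.testing.assert_allclose(fits_p[k].beta.beta, fits[orig].beta.beta, atol=1e-9)

    def test_failures_collected_not_fatal(self):
        data = make_poisson_data(seed=6, n=150, p=1, beta=(1.0, 0.3))
        # isolate one observation: under a compact kernel its neighbourhood
        # holds only itself, tripping the effective-sample guard
        X = data.X.copy()
        X[0, 0] = 1e6
        isolated = lp.CountDataset(y=data.y, X=X)
        fits = lp.fit_at_observations(isolated, lp.KernelSpec("epanechnikov", [0.05]))
        assert len(fits) == 150
        assert not fits[0].converged and fits[0].message
        assert all(f.converged for f in fits[1:])


class TestFitGlobal:
    def test_intercept_only_reduction(self):
        # slopes ~0 when predictors carry no signal is not guaranteed; instead
        # check the definitional identity against a constant-weight local fit
        data = make_poisson_data(seed=13, n=80, p=2)
        opts = lp.FitOptions(epsilon=1e-12)
        g = lp.fit_global(data, opts)
        design = lp.LocalDesign(
            Xc=np.column_stack([np.ones(80), data.X]), w=np.ones(80), y=data.y, x0=np.zeros(2)
        )
        local = lp.newton_raphson(design, lp.ols_init(data, np.zeros(2)), opts)
        np.testing.assert_allclose(g.beta, local.beta.beta, atol=1e-12)

    def test_constant_counts_give_log_mean(self):
        rng = np.random.default_rng(8)
        data = lp.CountDataset(y=np.full(30, 6), X=rng.normal(size=(30, 2)))
        g = lp.fit_global(data, lp.FitOptions(epsilon=1e-12))
        assert g.beta[0] + data.X.mean(axis=0) @ g.beta[1:] == pytest.approx(np.log(6), abs=1e-6)
        np.testing.assert_allclose(g.mean(data.X), 6.0, rtol=1e-6)


class TestDispersion:
    def test_constant_counts_ratio_zero(self):
        data = lp.CountDataset(y=[3, 3, 3], X=np.array([[0.0], [1.0], [2.0]]))
        ratio, table = lp.dispersion_check(data)
        assert ratio == 0.0
        assert table.loc["y", "sd"] == 0.0

    def test_poisson_counts_ratio_near_one(self):
        rng = np.random.default_rng(100)
        y = rng.poisson(110.0, size=100_000)
        data = lp.CountDataset(y=y, X=rng.normal(size=(100_000, 1)))
        ratio, _ = lp.dispersion_check(data)
        assert 0.97 < ratio < 1.03

    def test_alternating_counts_overdispersed(self):
        y = np.tile([0, 2], 10)
        data = lp.CountDataset(y=y, X=np.arange(20.0))
        ratio, _ = lp.dispersion_check(data)
        assert ratio > 1.0
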