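import numpy as np
import pytest
import scipy.sparse as sp
from scipy.optimize import minimize

from tilegam import (Hyperparams, TileModel, build_design, evaluate_basis,
                     gradient, hessian, newton_raphson_fit, penalized_loglik,
                     place_knots, smooth_values)
from tilegam._errors import InvalidArgumentError

from _oracles import dense_newton
from conftest import make_tile_model


def test_hyperparams_validation():
    with pytest.raises(InvalidArgumentError):
        Hyperparams(lam=1.0, theta=0.0)
    with pytest.raises(InvalidArgumentError):
        Hyperparams(lam=-1.0, theta=1.0)


class TestObjective:
    def test_all_zero_counts_closed_form(self):
        """With y = 0, beta = 0, o = 0 every mu is 1 and the NB pmf at zero
        gives n * theta * log(theta / (1 + theta))."""
        kv = place_knots(0, 99, 20)
        basis = evaluate_basis(kv, np.arange(100.0))
        design = build_design(np.array([[1]]), basis)
        theta = 2.5
        m = TileModel(y=np.zeros(100), offsets=np.zeros(100), design=design,
                      hyper=Hyperparams(lam=3.0, theta=theta))
        expected = 100 * theta * np.log(theta / (1 + theta))
        assert np.isclose(penalized_loglik(m, np.zeros(m.n_params)), expected)

    def test_zero_penalty_equals_unpenalized_loglik(self, small_tile):
        model, _, _ = small_tile
        m0 = TileModel(y=model.y, offsets=model.offsets, design=model.design,
                       hyper=Hyperparams(lam=0.0, theta=5.0, epsilon=0.0))
        rng = np.random.default_rng(0)
        beta = rng.normal(0, 0.2, m0.n_params)
        from tilegam import nb_loglik
        mu = np.exp(m0.offsets + m0.design.X @ beta)
        assert np.isclose(penalized_loglik(m0, beta), nb_loglik(m0.y, mu, 5.0))

    def test_objective_linear_in_lambda(self, small_tile):
        model, _, _ = small_tile
        rng = np.random.default_rng(1)
        beta = rng.normal(0, 0.2, model.n_params)
        hyp = model.hyper

        def at(lam):
            m = TileModel(y=model.y, offsets=model.offsets, design=model.design,
                          hyper=Hyperparams(lam=lam, theta=hyp.theta,
                                            epsilon=hyp.epsilon))
            return penalized_loglik(m, beta)

        s_eps = model.S_full + hyp.epsilon * sp.eye(model.n_params)
        pen = beta @ (s_eps @ beta)
        assert np.isclose(at(2 * hyp.lam) - at(hyp.lam), -hyp.lam * pen)

    def test_midpoint_concavity_in_beta(self, small_tile):
        model, _, _ = small_tile
        rng = np.random.default_rng(2)
        for _ in range(20):
            a = rng.normal(0, 0.5, model.n_params)
            b = rng.normal(0, 0.5, model.n_params)
            mid = penalized_loglik(model, (a + b) / 2)
            assert mid >= (penalized_loglik(model, a)
                           + penalized_loglik(model, b)) / 2 - 1e-9


class TestDerivatives:
    @pytest.mark.parametrize("seed", range(5))
    def test_gradient_matches_finite_differences(self, seed):
        model, _, _ = make_tile_model(n_positions=60, spacing=15, seed=seed,
                                      lam=2.0, theta=3.0)
        rng = np.random.default_rng(seed + 100)
        beta = rng.normal(0, 0.3, model.n_params)
        g = gradient(model, beta)
        eps = 1e-5
        fd = np.array([
            (penalized_loglik(model, beta + eps * e)
             - penalized_loglik(model, beta - eps * e)) / (2 * eps)
            for e in np.eye(model.n_params)])
        assert np.abs(g - fd).max() <= 1e-5 * max(1.0, np.abs(fd).max())

    @pytest.mark.parametrize("seed", range(3))
    def test_hessian_matches_finite_differences(self, seed):
        model, _, _ = make_tile_model(n_positions=60, spacing=15, seed=seed)
        rng = np.random.default_rng(seed + 200)
        beta = rng.normal(0, 0.3, model.n_params)
        h = hessian(model, beta).toarray()
        eps = 1e-6
        fd = np.array([
            (gradient(model, beta + eps * e) - gradient(model, beta - eps * e))
            / (2 * eps) for e in np.eye(model.n_params)])
        assert np.abs(h - fd).max() <= 1e-4 * max(1.0, np.abs(fd).max())

    def test_gradient_zero_at_saturated_fit_without_penalty(self):
        model, basis, _ = make_tile_model(n_positions=60, spacing=15, seed=9,
                                          lam=0.0, eps=0.0)
        rng = np.random.default_rng(9)
        beta = rng.normal(0, 0.2, model.n_params)
        mu = np.exp(model.offsets + model.design.X @ beta)
        m = TileModel(y=mu, offsets=model.offsets, design=model.design,
                      hyper=Hyperparams(lam=0.0, theta=model.hyper.theta,
                                        epsilon=0.0))
        assert np.abs(gradient(m, beta)).max() < 1e-8

    def test_hessian_negative_definite_with_positive_penalty(self, small_tile):
        model, _, _ = small_tile
        rng = np.random.default_rng(3)
        beta = rng.normal(0, 0.3, model.n_params)
        eigs = np.linalg.eigvalsh(hessian(model, beta).toarray())
        assert eigs.max() < 0

    def test_hessian_rows_bounded_independent_of_p(self):
        widths = []
        for n in (200, 400, 800):
            model, _, _ = make_tile_model(n_positions=n, seed=0)
            h = hessian(model, np.zeros(model.n_params)).tocsr()
            widths.append(np.diff(h.indptr).max())
        assert widths[0] == widths[1] == widths[2]

    def test_hessian_nnz_linear_in_p(self):
        nnzs, ps = [], []
        for n in (400, 800, 1600):
            model, _, _ = make_tile_model(n_positions=n, seed=0)
            h = hessian(model, np.zeros(model.n_params))
            nnzs.append(h.nnz)
            ps.append(model.n_params)
        # banded: nnz <= 7 nonzero diagonals
        assert all(nnz <= 7 * p for nnz, p in zip(nnzs, ps))


class TestNewtonRaphson:
    def test_constant_counts_fit_constant_log_c(self):
        """Constants lie in the penalty null space, so the penalized MLE of
        flat data is exactly the flat log-mean."""
        c = 7.0
        kv = place_knots(0, 199, 20)
        basis = evaluate_basis(kv, np.arange(200.0))
        design = build_design(np.array([[1]]), basis)
        m = TileModel(y=np.full(200, c), offsets=np.zeros(200), design=design,
                      hyper=Hyperparams(lam=50.0, theta=4.0, epsilon=0.0))
        fit = newton_raphson_fit(m)
        assert fit.converged
        values = smooth_values(design, basis, fit.beta)
        assert np.abs(values - np.log(c)).max() < 1e-6

    @pytest.mark.parametrize("seed", range(4))
    def test_agrees_with_dense_newton_oracle(self, seed):
        model, _, _ = make_tile_model(n_positions=150, seed=seed, lam=5.0,
                                      theta=4.0)
        fit = newton_raphson_fit(model)
        assert fit.converged
        oracle = dense_newton(model.y, model.offsets,
                              model.design.X.toarray(),
                              model.S_full.toarray(), model.hyper.lam,
                              model.hyper.theta, model.hyper.epsilon,
                              beta0=np.zeros(model.n_params))
        assert np.abs(fit.beta - oracle).max() < 1e-6

    def test_agrees_with_generic_dense_optimizer(self):
        model, _, _ = make_tile_model(n_positions=80, spacing=20, seed=5)
        fit = newton_raphson_fit(model)
        res = minimize(lambda b: -penalized_loglik(model, b),
                       np.zeros(model.n_params), jac=lambda b: -gradient(model, b),
                       method="L-BFGS-B",
                       options=dict(maxiter=2000, ftol=1e-14, gtol=1e-10))
        assert np.abs(fit.beta - res.x).max() < 1e-4

    def test_starting_at_optimum_is_a_fixed_point(self, small_tile):
        model, _, _ = small_tile
        fit = newton_raphson_fit(model)
        refit = newton_raphson_fit(model, beta0=fit.beta)
        assert refit.iterations <= 1
        assert np.abs(refit.beta - fit.beta).max() < 1e-8

    def test_objective_monotone_over_iterations(self, small_tile):
        model, _, _ = small_tile
        beta = np.zeros(model.n_params)
        prev = penalized_loglik(model, beta)
        for _ in range(8):
            fit = newton_raphson_fit(model, beta0=beta, max_iter=1)
            cur = penalized_loglik(model, fit.beta)
            assert cur >= prev - 1e-9 * (1 + abs(prev))
            if np.allclose(fit.beta, beta):
                break
            beta, prev = fit.beta, cur

    def test_fit_invariant_to_data_permutation(self, small_tile):
        model, _, _ = small_tile
        rng = np.random.default_rng(7)
        perm = rng.permutation(model.y.size)
        from tilegam.design import FullDesign
        design_p = FullDesign(X=model.design.X[perm].tocsr(), Z=model.design.Z,
                              n_positions=model.design.n_positions,
                              p_k=model.design.p_k)
        model_p = TileModel(y=model.y[perm], offsets=model.offsets[perm],
                            design=design_p, hyper=model.hyper,
                            S_full=model.S_full)
        f1 = newton_raphson_fit(model)
        f2 = newton_raphson_fit(model_p)
        assert np.abs(f1.beta - f2.beta).max() < 1e-8

    def test_max_iter_reached_reports_not_converged(self, small_tile):
        model, _, _ = small_tile
        fit = newton_raphson_fit(model, beta0=np.zeros(model.n_params),
                                 grad_tol=1e-14, obj_tol=0.0, max_iter=1)
        assert not fit.converged

    def test_mu_positive_and_consistent(self, small_tile):
        model, _, _ = small_tile
        fit = newton_raphson_fit(model)
        assert (fit.mu > 0).all()
        assert np.allclose(fit.mu,
                           np.exp(model.offsets + model.design.X @ fit.beta))
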