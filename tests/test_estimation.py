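import numpy as np
import pytest

import _oracles as oracles
from gwlasso import (HyperGrid, HyperParams, ParameterError, SpatialDataset,
                     auto_lambda_grid, fit_gwl, kernel_weights, lambda_max,
                     loo_cv_criterion, pairwise_distances,
                     select_hyperparameters)


def make_dataset(n=30, p=2, seed=0, beta=None):
    rng = np.random.default_rng(seed)
    coords = rng.uniform(0, 10, size=(n, 2))
    X = rng.standard_normal((n, p))
    X = (X - X.mean(0)) / X.std(0, ddof=1)
    beta = np.ones(p) if beta is None else np.asarray(beta, float)
    y = rng.binomial(1, 1 / (1 + np.exp(-(X @ beta)))).astype(float)
    if y.min() == y.max():
        y[0] = 1 - y[0]
    return SpatialDataset(unit_id=np.arange(n), coords=coords, X=X, y=y,
                          covariate_names=[f"x{k}" for k in range(p)])


class TestLOOCriterion:
    def test_lambda_above_all_local_max_gives_null_deviance(self):
        """At full shrinkage every held-out prediction is the weighted mean,
        so the criterion matches the closed-form Bernoulli deviance."""
        ds = make_dataset(n=25, p=2, seed=1)
        D = pairwise_distances(ds.coords).D
        theta = 3.0
        W = kernel_weights(D, theta).W
        idx = np.arange(ds.n)
        lam_big = max(lambda_max(ds.X[idx != i], ds.y[idx != i], W[i, idx != i])
                      for i in range(ds.n)) * 1.01
        row, n_eval, n_degen, det = loo_cv_criterion(ds, theta, np.array([lam_big]))
        expected = 0.0
        for i in range(ds.n):
            keep = np.arange(ds.n) != i
            wt = W[i, keep] / W[i, keep].sum()
            pbar = float(wt @ ds.y[keep])
            expected += -2 * (ds.y[i] * np.log(pbar) + (1 - ds.y[i]) * np.log(1 - pbar))
        assert row[0] == pytest.approx(expected, rel=1e-6)
        assert n_eval[0] == ds.n

    def test_held_out_independence(self):
        """Perturbing y_i changes unit i's criterion contribution but not the
        coefficients of unit i's own LOO fit."""
        ds = make_dataset(n=20, p=2, seed=2)
        lambdas = np.array([0.05, 0.01])
        _, _, _, det = loo_cv_criterion(ds, 3.0, lambdas, keep_fits=True)
        i = 7
        ds2 = make_dataset(n=20, p=2, seed=2)
        ds2.y[i] = 1.0 - ds2.y[i]
        _, _, _, det2 = loo_cv_criterion(ds2, 3.0, lambdas, keep_fits=True)
        for t in range(2):
            np.testing.assert_allclose(det2.fits[i][t].coef, det.fits[i][t].coef,
                                       atol=1e-12)
            assert det2.contributions[i, t] != det.contributions[i, t]

    def test_near_separable_global_limit_has_tiny_deviance(self):
        """A perfectly predictive covariate with a huge bandwidth and no
        penalty drives the held-out deviance to ~0."""
        rng = np.random.default_rng(5)
        n = 24
        coords = rng.uniform(0, 5, size=(n, 2))
        x = np.concatenate([rng.uniform(0.5, 2.0, n // 2), rng.uniform(-2.0, -0.5, n // 2)])
        y = (x > 0).astype(float)
        X = ((x - x.mean()) / x.std(ddof=1))[:, None]
        ds = SpatialDataset(unit_id=np.arange(n), coords=coords, X=X, y=y,
                            covariate_names=["x1"])
        D = pairwise_distances(coords).D
        row, *_ = loo_cv_criterion(ds, 1e6 * D.max(), np.array([0.0]), D=D)
        assert row[0] < 1e-3

    def test_misclassification_criterion(self):
        ds = make_dataset(n=20, p=2, seed=3)
        row, *_ = loo_cv_criterion(ds, 5.0, np.array([0.01]),
                                   criterion="misclassification")
        assert 0 <= row[0] <= ds.n
        assert row[0] == int(row[0])

    def test_needs_three_units(self):
        ds = make_dataset(n=30, p=1, seed=0)
        with pytest.raises(ParameterError):
            loo_cv_criterion(ds.__class__(unit_id=ds.unit_id[:2], coords=ds.coords[:2],
                                          X=ds.X[:2], y=np.array([0.0, 1.0]),
                                          covariate_names=ds.covariate_names),
                             1.0, np.array([0.1]))


class TestSelectHyperparameters:
    def test_singleton_grid_returns_that_pair(self):
        ds = make_dataset(n=15, p=1, seed=4)
        grid = HyperGrid(np.array([2.5]), np.array([0.07]))
        params, cv = select_hyperparameters(ds, grid)
        assert params.theta_hat == 2.5
        assert params.lambda_hat == 0.07
        assert params.criterion_value == cv.criterion[0, 0]

    def test_tie_break_prefers_smallest_theta_then_largest_lambda(self):
        """With the misclassification criterion on an easy dataset all cells
        tie at 0; the tie must break to (min theta, max lambda)."""
        rng = np.random.default_rng(6)
        n = 20
        coords = rng.uniform(0, 5, size=(n, 2))
        x = np.concatenate([np.ones(n // 2), -np.ones(n // 2)])
        x += rng.normal(scale=0.01, size=n)
        X = ((x - x.mean()) / x.std(ddof=1))[:, None]
        y = (x > 0).astype(float)
        ds = SpatialDataset(unit_id=np.arange(n), coords=coords, X=X, y=y,
                            covariate_names=["x1"])
        grid = HyperGrid(np.array([5.0, 10.0]), np.array([0.02, 0.01]))
        params, cv = select_hyperparameters(ds, grid, criterion="misclassification")
        assert cv.criterion.min() == cv.criterion.max() == 0.0
        assert params.theta_hat == 5.0
        assert params.lambda_hat == 0.02

    def test_cost_contract_counts_path_fits(self):
        ds = make_dataset(n=12, p=1, seed=7)
        grid = HyperGrid(np.array([2.0, 4.0, 8.0]), np.array([0.1, 0.01]))
        _, cv = select_hyperparameters(ds, grid)
        assert cv.n_path_fits == 3 * ds.n

    def test_golden_search_runs_and_is_deterministic(self):
        ds = make_dataset(n=20, p=2, seed=8)
        grid = HyperGrid(np.array([0.5, 20.0]), np.array([0.05, 0.01]))
        p1, cv1 = select_hyperparameters(ds, grid, search_mode="golden")
        p2, _ = select_hyperparameters(ds, grid, search_mode="golden")
        assert p1 == p2
        assert 0.5 <= p1.theta_hat <= 20.0
        assert cv1.theta_candidates.size > 2

    def test_empty_grid_rejected(self):
        with pytest.raises(ParameterError):
            HyperGrid(np.array([]), np.array([0.1]))
        with pytest.raises(ParameterError):
            HyperGrid(np.array([1.0]), np.array([0.1, 0.2]))  # ascending lambda


class TestAutoLambdaGrid:
    def test_geometric_anchored_at_most_massive_location(self):
        ds = make_dataset(n=25, p=3, seed=9)
        D = pairwise_distances(ds.coords).D
        lambdas = auto_lambda_grid(ds, theta=4.0, T=8, D=D)
        assert lambdas.size == 8
        assert (np.diff(lambdas) < 0).all()
        W = kernel_weights(D, 4.0).W
        i_star = int(np.argmax(W.sum(axis=1)))
        assert lambdas[0] == pytest.approx(lambda_max(ds.X, ds.y, W[i_star]))
        assert lambdas[-1] == pytest.approx(lambdas[0] * 1e-3)


class TestFitGWL:
    def test_global_limit_matches_unweighted_mle(self):
        """theta -> inf with lambda = 0 collapses to one global logistic fit."""
        ds = make_dataset(n=40, p=2, seed=10)
        D = pairwise_distances(ds.coords).D
        field = fit_gwl(ds, (1e6 * D.max(), 0.0), D=D)
        assert np.max(field.B.max(axis=0) - field.B.min(axis=0)) < 1e-6
        oracle = oracles.newton_weighted_logistic(ds.X, ds.y, np.ones(ds.n))
        np.testing.assert_allclose(field.B[0], oracle, atol=1e-5)

    def test_full_shrinkage_gives_weighted_logit_intercepts(self):
        ds = make_dataset(n=30, p=2, seed=11)
        D = pairwise_distances(ds.coords).D
        theta = 2.0
        W = kernel_weights(D, theta).W
        lam_big = max(lambda_max(ds.X, ds.y, W[i]) for i in range(ds.n)) * 1.001
        field = fit_gwl(ds, (theta, lam_big), D=D)
        assert np.all(field.slopes == 0.0)
        for i in range(ds.n):
            pbar = float(W[i] @ ds.y / W[i].sum())
            assert field.B[i, 0] == pytest.approx(np.log(pbar / (1 - pbar)), abs=1e-6)

    def test_unit_permutation_equivariance(self):
        ds = make_dataset(n=25, p=2, seed=12)
        field = fit_gwl(ds, (3.0, 0.02))
        perm = np.random.default_rng(0).permutation(ds.n)
        ds_p = SpatialDataset(unit_id=ds.unit_id[perm], coords=ds.coords[perm],
                              X=ds.X[perm], y=ds.y[perm],
                              covariate_names=ds.covariate_names)
        field_p = fit_gwl(ds_p, (3.0, 0.02))
        np.testing.assert_allclose(field_p.B, field.B[perm], atol=1e-9)

    def test_accepts_hyperparams_object(self):
        ds = make_dataset(n=15, p=1, seed=13)
        field = fit_gwl(ds, HyperParams(theta_hat=3.0, lambda_hat=0.05,
                                        criterion_value=0.0))
        assert field.B.shape == (15, 2)
        assert field.theta == 3.0 and field.lam == 0.05


class TestHeterogeneityDetection:
    def test_cv_prefers_local_bandwidth_under_strong_heterogeneity(self, small_data):
        """With genuinely location-varying coefficients, a moderate bandwidth
        beats the global-model limit on held-out deviance."""
        _, ds, _ = small_data
        D = pairwise_distances(ds.coords).D
        lambdas = auto_lambda_grid(ds, 1e6 * D.max(), T=6, D=D)
        row_local, *_ = loo_cv_criterion(ds, 2.0, lambdas, D=D)
        row_global, *_ = loo_cv_criterion(ds, 1e6 * D.max(), lambdas, D=D)
        assert row_local.min() < row_global.min()
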