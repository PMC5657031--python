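"""Ridge regression: gradients, closed form, multi-shot = pooled, single-shot."""

import numpy as np
import pytest
from sklearn.base import clone

from consortium_lite.federation import ConsortiumState, split_pooled
from consortium_lite.regression import (
    DecentralizedRidge,
    DesignMatrix,
    RidgeConfig,
    build_design,
    closed_form_oracle,
    fit_multishot,
    fit_singleshot,
    local_objective_gradient,
)
from consortium_lite.synthdata import simulate_freesurfer_volumes


from oracles import centralized_gd_oracle


class TestLocalObjectiveGradient:
    def test_hand_worked_two_row_example(self):
        design = DesignMatrix(np.array([[1.0, 0.0], [1.0, 1.0]]), ["intercept", "x"])
        grad, obj, n = local_objective_gradient(design, np.array([0.0, 1.0]), np.zeros(2))
        np.testing.assert_allclose(grad, [-2.0, -2.0])
        assert obj == 1.0 and n == 2

    def test_zero_gradient_at_ols_solution(self, pooled_volumes):
        design, y = build_design(pooled_volumes)
        beta = closed_form_oracle(design, y)
        grad, _, _ = local_objective_gradient(design, y, beta)
        assert np.linalg.norm(grad) / np.linalg.norm(design.values.T @ y) < 1e-12

    def test_additivity_over_split(self, pooled_volumes):
        design, y = build_design(pooled_volumes)
        w = np.array([100.0, -2.0, 3.0])
        g_all, o_all, _ = local_objective_gradient(design, y, w)
        half = pooled_volumes.n // 2
        d1 = DesignMatrix(design.values[:half], design.coefficient_names)
        d2 = DesignMatrix(design.values[half:], design.coefficient_names)
        g1, o1, _ = local_objective_gradient(d1, y[:half], w)
        g2, o2, _ = local_objective_gradient(d2, y[half:], w)
        np.testing.assert_allclose(g1 + g2, g_all, rtol=1e-12)
        assert np.isclose(o1 + o2, o_all, rtol=1e-12)

    def test_nonfinite_w_rejected(self, pooled_volumes):
        design, y = build_design(pooled_volumes)
        with pytest.raises(ValueError):
            local_objective_gradient(design, y, np.array([np.nan, 0.0, 0.0]))


class TestClosedFormOracle:
    def test_exact_recovery_noiseless(self, rng):
        X = np.column_stack([np.ones(50), rng.standard_normal((50, 3))])
        beta_true = np.array([2.0, -1.0, 0.5, 3.0])
        design = DesignMatrix(X, ["intercept", "a", "b", "c"])
        np.testing.assert_allclose(
            closed_form_oracle(design, X @ beta_true), beta_true, atol=1e-10
        )

    def test_agrees_with_pseudoinverse_ols(self, pooled_volumes):
        design, y = build_design(pooled_volumes)
        beta_pinv = np.linalg.pinv(design.values) @ y
        np.testing.assert_allclose(
            closed_form_oracle(design, y), beta_pinv, rtol=1e-10
        )

    def test_ridge_shrinks_non_intercept_norm(self, pooled_volumes):
        design, y = build_design(pooled_volumes)
        b0 = closed_form_oracle(design, y, 0.0)
        b1 = closed_form_oracle(design, y, 100.0)
        assert np.linalg.norm(b1[1:]) < np.linalg.norm(b0[1:])


class TestMultishot:
    def test_noiseless_recovery(self):
        pooled = simulate_freesurfer_volumes(
            200,
            age_effect_range=(-200, -200),
            group_effect_range=(750, 750),
            noise_scale_range=(0, 0),
            seed=3,
        )
        consortium = ConsortiumState(sites=split_pooled(pooled, 2, seed=0), master_seed=0)
        fit, _ = fit_multishot(
            consortium, RidgeConfig(max_iterations=300, tolerance=1e-12)
        )
        np.testing.assert_allclose(fit.w, [48466.3, -200.0, 750.0], atol=1e-4)
        assert fit.objective_history[-1] < 1e-6

    @pytest.mark.parametrize("n_sites", [1, 2, 4, 8])
    def test_iterates_match_centralized_gradient_descent(self, pooled_volumes, n_sites):
        consortium = ConsortiumState(
            sites=split_pooled(pooled_volumes, n_sites, seed=2), master_seed=0
        )
        config = RidgeConfig(lam=0.5, max_iterations=40, tolerance=1e-12)
        fit, transcript = fit_multishot(consortium, config)
        iterates = [
            np.asarray(r.broadcast["w"])
            for r in transcript.rounds
            if r.broadcast.get("phase") == 1.0
        ]
        ref_iterates, _ = centralized_gd_oracle(
            pooled_volumes.X, pooled_volumes.y, 0.5, 0.25, 40, 1e-12
        )
        assert len(iterates) >= 25
        for ours, ref in zip(iterates, ref_iterates):
            np.testing.assert_allclose(ours, ref, rtol=1e-9, atol=1e-12)

    def test_objective_history_non_increasing(self, volume_consortium):
        fit, _ = fit_multishot(
            volume_consortium, RidgeConfig(learning_rate=0.9, max_iterations=60)
        )
        assert all(
            b <= a * (1 + 1e-9) + 1e-12
            for a, b in zip(fit.objective_history, fit.objective_history[1:])
        )

    def test_shrinkage_monotone_in_lambda(self, pooled_volumes):
        consortium = ConsortiumState(
            sites=split_pooled(pooled_volumes, 2, seed=1), master_seed=0
        )
        norms = []
        for lam in [0.0, 1.0, 10.0, 100.0, 1000.0]:
            fit, _ = fit_multishot(
                consortium, RidgeConfig(lam=lam, max_iterations=300, tolerance=1e-10)
            )
            # shrinkage acts on the standardized (centered) scale
            norms.append(np.linalg.norm(fit.w[1:] * pooled_volumes.X.std(axis=0)))
        assert all(b < a for a, b in zip(norms, norms[1:]))

    def test_site_order_invariance(self, pooled_volumes):
        parts = split_pooled(pooled_volumes, 3, seed=5)
        forward = ConsortiumState(sites=parts, master_seed=0)
        renamed = [
            type(p)(
                site_id=f"z-{2 - i}",
                X=p.X,
                feature_names=p.feature_names,
                feature_types=p.feature_types,
                y=p.y,
                y_name=p.y_name,
            )
            for i, p in enumerate(parts)
        ]
        backward = ConsortiumState(sites=renamed, master_seed=0)
        f1, _ = fit_multishot(forward, RidgeConfig(max_iterations=50))
        f2, _ = fit_multishot(backward, RidgeConfig(max_iterations=50))
        np.testing.assert_allclose(f1.w, f2.w, rtol=1e-9)


class TestSingleshot:
    def test_single_site_equals_closed_form(self, pooled_volumes):
        consortium = ConsortiumState(sites=[pooled_volumes], master_seed=0)
        fit, _ = fit_singleshot(consortium, 0.0)
        design, y = build_design(pooled_volumes)
        np.testing.assert_allclose(fit.w, closed_form_oracle(design, y), rtol=1e-12)

    def test_identical_sites_equal_local_fit(self, pooled_volumes):
        twin = type(pooled_volumes)(
            site_id="twin",
            X=pooled_volumes.X.copy(),
            feature_names=pooled_volumes.feature_names,
            feature_types=pooled_volumes.feature_types,
            y=pooled_volumes.y.copy(),
            y_name=pooled_volumes.y_name,
        )
        consortium = ConsortiumState(sites=[pooled_volumes, twin], master_seed=0)
        fit, _ = fit_singleshot(consortium, 0.0)
        design, y = build_design(pooled_volumes)
        np.testing.assert_allclose(fit.w, closed_form_oracle(design, y), rtol=1e-12)

    def test_heterogeneous_split_differs_from_pooled(self, pooled_volumes):
        # sort rows by age before splitting -> deliberately heterogeneous sites
        order = np.argsort(pooled_volumes.X[:, 0])
        skewed = type(pooled_volumes)(
            site_id="sorted",
            X=pooled_volumes.X[order],
            feature_names=pooled_volumes.feature_names,
            feature_types=pooled_volumes.feature_types,
            y=pooled_volumes.y[order],
            y_name=pooled_volumes.y_name,
        )
        halves = [
            type(pooled_volumes)(
                site_id=f"h{i}",
                X=skewed.X[i * 250 : (i + 1) * 250],
                feature_names=skewed.feature_names,
                feature_types=skewed.feature_types,
                y=skewed.y[i * 250 : (i + 1) * 250],
                y_name=skewed.y_name,
            )
            for i in range(2)
        ]
        consortium = ConsortiumState(sites=halves, master_seed=0)
        fit, _ = fit_singleshot(consortium, 0.0)
        design, y = build_design(pooled_volumes)
        pooled_beta = closed_form_oracle(design, y)
        assert not np.allclose(fit.w, pooled_beta, rtol=1e-6)


class TestEstimatorApi:
    def test_sklearn_contract_and_prediction(self, pooled_volumes):
        est = DecentralizedRidge(alpha=0.0, max_iterations=300, tolerance=1e-10)
        cloned = clone(est)
        assert cloned.get_params() == est.get_params()
        site_labels = np.arange(pooled_volumes.n) % 3
        est.fit(pooled_volumes.X, pooled_volumes.y, sites=site_labels)
        design, y = build_design(pooled_volumes)
        beta = closed_form_oracle(design, y)
        np.testing.assert_allclose(est.intercept_, beta[0], rtol=1e-5)
        np.testing.assert_allclose(est.coef_, beta[1:], rtol=1e-4)
        pred = est.predict(pooled_volumes.X)
        assert pred.shape == (pooled_volumes.n,)
        assert est.score(pooled_volumes.X, pooled_volumes.y) > 0.3
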