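"""t-SNE kernels, the centralized baseline, and the decentralized variant."""

import numpy as np
import pytest
from scipy import optimize
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score, silhouette_score

from consortium_lite.dsne import (
    _DsneSite,
    _Schedule,
    conditional_affinities,
    fit_centralized_tsne,
    fit_dsne,
    kl_divergence,
    tsne_gradient,
    DecentralizedTSNE,
)
from consortium_lite.federation import ConsortiumState
from consortium_lite.synthdata import simulate_gaussian_clusters


def make_consortium(X, labels_or_sites, n_sites, seed=0, master_seed=0):
    rng = np.random.default_rng(seed)
    assign = rng.integers(0, n_sites, size=X.shape[0])
    names = [f"x{j}" for j in range(X.shape[1])]
    sites = [
        _DsneSite(site_id=f"site-{p}", X=X[assign == p], feature_names=list(names))
        for p in range(n_sites)
    ]
    return ConsortiumState(sites=sites, master_seed=master_seed)


class TestConditionalAffinities:
    def test_equilateral_triangle_is_uniform(self):
        X = np.array([[0.0, 0.0], [1.0, 0.0], [0.5, np.sqrt(3) / 2]])
        aff = conditional_affinities(X, perplexity=2.0)
        off = aff.P[~np.eye(3, dtype=bool)]
        np.testing.assert_allclose(off, 1.0 / 6.0, rtol=1e-9)

    def test_entropy_matches_perplexity_target(self, rng):
        X = rng.standard_normal((100, 5))
        aff = conditional_affinities(X, perplexity=15.0)
        # recompute conditional entropies from the bandwidths
        for i in range(100):
            d = np.sum((X - X[i]) ** 2, axis=1)
            d = np.delete(d, i)
            w = np.exp(-d / (2 * aff.sigmas[i] ** 2))
            p = w / w.sum()
            h_bits = -(p[p > 0] * np.log2(p[p > 0])).sum()
            assert abs(h_bits - np.log2(15.0)) < 1e-4

    def test_duplicated_points_stay_normalized(self, rng):
        X = rng.standard_normal((20, 3))
        doubled = np.vstack([X, X])
        aff = conditional_affinities(doubled, perplexity=10.0)
        assert abs(aff.P.sum() - 1.0) < 1e-10
        assert np.all(np.diag(aff.P) == 0)

    def test_perplexity_bounds(self, rng):
        with pytest.raises(ValueError):
            conditional_affinities(rng.standard_normal((5, 2)), perplexity=5.0)


class TestTsneGradient:
    def test_matches_finite_differences_of_kl(self, rng):
        X = rng.standard_normal((10, 4))
        P = conditional_affinities(X, perplexity=5.0).P
        Y = rng.standard_normal((10, 2))
        grad = tsne_gradient(P, Y)
        num = np.zeros_like(Y)
        eps = 1e-6
        for i in range(10):
            for d in range(2):
                Yp, Ym = Y.copy(), Y.copy()
                Yp[i, d] += eps
                Ym[i, d] -= eps
                num[i, d] = (kl_divergence(P, Yp) - kl_divergence(P, Ym)) / (2 * eps)
        np.testing.assert_allclose(grad, num, rtol=1e-6, atol=1e-9)

    def test_translation_invariance(self, rng):
        X = rng.standard_normal((12, 3))
        P = conditional_affinities(X, perplexity=6.0).P
        Y = rng.standard_normal((12, 2))
        np.testing.assert_allclose(
            tsne_gradient(P, Y), tsne_gradient(P, Y + 17.5), rtol=1e-9, atol=1e-12
        )

    def test_gradient_vanishes_at_reference_optimum(self, rng):
        # minimize KL with an independent optimizer, then check our gradient
        X = rng.standard_normal((12, 3))
        P = conditional_affinities(X, perplexity=6.0).P
        y0 = rng.standard_normal(24) * 1e-2
        res = optimize.minimize(
            lambda v: kl_divergence(P, v.reshape(12, 2)),
            y0,
            jac=lambda v: tsne_gradient(P, v.reshape(12, 2)).ravel(),
            method="L-BFGS-B",
            options={"gtol": 1e-9, "maxiter": 2000},
        )
        grad = tsne_gradient(P, res.x.reshape(12, 2))
        assert np.linalg.norm(grad) < 1e-5

    def test_coincident_points_do_not_blow_up(self):
        Y = np.zeros((4, 2))
        P = np.full((4, 4), 1 / 12.0)
        np.fill_diagonal(P, 0.0)
        assert np.all(np.isfinite(tsne_gradient(P, Y)))


class TestCentralizedTsne:
    def test_separates_ten_clusters(self):
        X, labels = simulate_gaussian_clusters(10, 50, 30, separation=10, seed=3)
        Y = fit_centralized_tsne(X, perplexity=30, n_iter=500, seed=0)
        assert silhouette_score(Y, labels) > 0.5
        pred = KMeans(10, n_init=10, random_state=0).fit_predict(Y)
        assert adjusted_rand_score(labels, pred) > 0.8

    def test_seed_determinism(self, rng):
        X = rng.standard_normal((40, 6))
        a = fit_centralized_tsne(X, perplexity=10, n_iter=100, seed=5)
        b = fit_centralized_tsne(X, perplexity=10, n_iter=100, seed=5)
        assert np.array_equal(a, b)


class TestFitDsne:
    def test_reduces_to_centralized_with_empty_sites(self, rng):
        X = rng.standard_normal((50, 5))
        site = _DsneSite(
            site_id="s0", X=np.empty((0, 5)), feature_names=[f"x{j}" for j in range(5)]
        )
        consortium = ConsortiumState(sites=[site], master_seed=9)
        state, _ = fit_dsne(consortium, X, perplexity=12, n_iter=150)
        ref = fit_centralized_tsne(X, perplexity=12, n_iter=150, seed=9)
        assert np.array_equal(state.Y_s, ref)

    def test_empty_reference_rejected(self, rng):
        consortium = make_consortium(rng.standard_normal((30, 4)), None, 2)
        with pytest.raises(ValueError, match="reference required"):
            fit_dsne(consortium, np.empty((0, 4)))

    def test_local_kl_non_increasing_without_momentum(self, rng):
        X, _ = simulate_gaussian_clusters(3, 5, 15, separation=8, seed=1)
        shared = X[::5]
        private = np.delete(X, np.arange(0, len(X), 5), axis=0)
        consortium = make_consortium(private, None, 2, seed=2)
        sched = _Schedule(
            perplexity=8,
            n_iter=120,
            learning_rate=1.0,
            early_exaggeration=1.0,
            exaggeration_iter=0,
            momentum_start=0.0,
            momentum_final=0.0,
            adaptive_gains=False,
        )
        state, _ = fit_dsne(consortium, shared, schedule=sched, track_kl=True)
        for kl in state.kl_history.values():
            diffs = np.diff(kl)
            assert np.all(diffs <= 1e-9)

    def test_cluster_recovery_across_sites(self):
        X, labels = simulate_gaussian_clusters(10, 50, 24, separation=10, seed=7)
        shared_mask = np.zeros(len(X), dtype=bool)
        shared_mask[::6] = True  # 4 reference points per cluster
        private = X[~shared_mask]
        priv_labels = labels[~shared_mask]
        consortium = make_consortium(private, None, 3, seed=4, master_seed=1)
        state, _ = fit_dsne(
            consortium, X[shared_mask], perplexity=20, n_iter=400, record_payloads=False
        )
        # stack per-site embeddings in site order and score against true labels
        assign = np.random.default_rng(4).integers(0, 3, size=private.shape[0])
        stacked, stacked_labels = [state.Y_s], [labels[shared_mask]]
        for p in range(3):
            stacked.append(state.Y_p[f"site-{p}"])
            stacked_labels.append(priv_labels[assign == p])
        Y = np.vstack(stacked)
        truth = np.concatenate(stacked_labels)
        pred = KMeans(10, n_init=10, random_state=0).fit_predict(Y)
        assert adjusted_rand_score(truth, pred) > 0.7


class TestEstimator:
    def test_fit_transform_orders_rows(self):
        X, labels = simulate_gaussian_clusters(5, 10, 20, separation=10, seed=2)
        shared = np.zeros(len(X), dtype=bool)
        shared[::4] = True
        sites = np.arange(len(X)) % 2
        est = DecentralizedTSNE(perplexity=15, n_iter=250, random_state=0)
        Y = est.fit_transform(X, sites=sites, shared=shared)
        assert Y.shape == (len(X), 2)
        pred = KMeans(5, n_init=10, random_state=0).fit_predict(Y)
        assert adjusted_rand_score(labels, pred) > 0.7
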