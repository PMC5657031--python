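"""Decentralized R²/t/p against pooled classical inference oracles."""

import numpy as np
import pytest
import statsmodels.api as sm

from consortium_lite.federation import ConsortiumState, SiteDataset, split_pooled
from consortium_lite.regression import (
    build_design,
    closed_form_oracle,
    fit_singleshot,
)
from consortium_lite.regstats import (
    RegressionReport,
    build_report,
    decentralized_r_squared,
    decentralized_t_stats,
    t_to_pvalue,
)
from consortium_lite.synthdata import simulate_freesurfer_volumes


@pytest.fixture(scope="module")
def fitted():
    pooled = simulate_freesurfer_volumes(400, seed=21)
    design, y = build_design(pooled)
    beta = closed_form_oracle(design, y)
    return pooled, design, y, beta


class TestRSquared:
    def test_noiseless_model_scores_one(self):
        pooled = simulate_freesurfer_volumes(
            100,
            age_effect_range=(-200, -200),
            group_effect_range=(750, 750),
            noise_scale_range=(0, 0),
            seed=2,
        )
        consortium = ConsortiumState(sites=split_pooled(pooled, 2, seed=0), master_seed=0)
        r2, per_site, _ = decentralized_r_squared(
            consortium, np.array([48466.3, -200.0, 750.0])
        )
        assert abs(r2 - 1.0) < 1e-12
        assert all(abs(v - 1.0) < 1e-12 for v in per_site.values())

    def test_null_model_scores_zero(self, fitted):
        pooled, design, y, _ = fitted
        consortium = ConsortiumState(sites=[pooled], master_seed=0)
        w_null = np.array([y.mean(), 0.0, 0.0])  # predictions == global mean
        r2, _, _ = decentralized_r_squared(consortium, w_null)
        assert abs(r2) < 1e-12

    def test_split_invariance_to_pooled_value(self, fitted):
        pooled, design, y, beta = fitted
        resid = y - design.values @ beta
        pooled_r2 = 1.0 - (resid @ resid) / (((y - y.mean()) ** 2).sum())
        consortium = ConsortiumState(sites=split_pooled(pooled, 3, seed=9), master_seed=0)
        r2, _, transcript = decentralized_r_squared(consortium, beta)
        assert abs(r2 - pooled_r2) < 1e-12
        assert len(transcript) == 2  # exactly two communication rounds

    def test_constant_response_rejected(self):
        site = SiteDataset(
            site_id="s",
            X=np.arange(10, dtype=float).reshape(-1, 1),
            feature_names=["x"],
            y=np.full(10, 3.0),
            y_name="y",
        )
        consortium = ConsortiumState(sites=[site], master_seed=0)
        with pytest.raises(Exception, match="degenerate response"):
            decentralized_r_squared(consortium, np.array([3.0, 0.0]))


class TestTStats:
    def test_matches_pooled_statsmodels(self, fitted):
        pooled, design, y, beta = fitted
        consortium = ConsortiumState(sites=split_pooled(pooled, 3, seed=1), master_seed=0)
        stats_, _ = decentralized_t_stats(consortium, beta)
        ols = sm.OLS(y, design.values).fit()
        np.testing.assert_allclose(stats_.t, ols.tvalues, rtol=1e-10)
        np.testing.assert_allclose(stats_.p, ols.pvalues, rtol=1e-8, atol=1e-15)
        assert stats_.df == int(ols.df_resid)

    def test_split_invariance(self, fitted):
        pooled, _, _, beta = fitted
        results = []
        for n_sites, seed in [(1, 0), (4, 3), (8, 5)]:
            consortium = ConsortiumState(
                sites=split_pooled(pooled, n_sites, seed=seed), master_seed=0
            )
            stats_, _ = decentralized_t_stats(consortium, beta)
            results.append(stats_.t)
        np.testing.assert_allclose(results[1], results[0], rtol=1e-10)
        np.testing.assert_allclose(results[2], results[0], rtol=1e-10)

    def test_zero_coefficient_gives_zero_t(self, fitted):
        pooled, _, _, beta = fitted
        w = beta.copy()
        w[2] = 0.0
        consortium = ConsortiumState(sites=[pooled], master_seed=0)
        stats_, _ = decentralized_t_stats(consortium, w)
        assert stats_.t[2] == 0.0

    def test_row_duplication_scales_t_by_sqrt2(self, fitted):
        pooled, design, y, beta = fitted
        doubled = SiteDataset(
            site_id="doubled",
            X=np.vstack([pooled.X, pooled.X]),
            feature_names=pooled.feature_names,
            feature_types=pooled.feature_types,
            y=np.concatenate([y, y]),
            y_name=pooled.y_name,
        )
        c1 = ConsortiumState(sites=[pooled], master_seed=0)
        c2 = ConsortiumState(sites=[doubled], master_seed=0)
        t1, _ = decentralized_t_stats(c1, beta)
        t2, _ = decentralized_t_stats(c2, beta)
        np.testing.assert_allclose(t2.t / t1.t, np.sqrt(2.0), rtol=0.01)

    def test_upload_vocabulary_is_restricted(self, fitted):
        pooled, _, _, beta = fitted
        consortium = ConsortiumState(sites=split_pooled(pooled, 2, seed=0), master_seed=0)
        _, _, tr_r2 = decentralized_r_squared(consortium, beta)
        _, tr_t = decentralized_t_stats(consortium, beta)
        names = {name for _, _, name, _ in tr_r2.iter_uploads()}
        names |= {name for _, _, name, _ in tr_t.iter_uploads()}
        assert names <= {"ybar", "n", "sst", "sse", "gram"}

    def test_collinear_design_reported(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(30)
        site = SiteDataset(
            site_id="s",
            X=np.column_stack([x, 2 * x]),
            feature_names=["a", "b"],
            y=rng.standard_normal(30),
            y_name="y",
        )
        consortium = ConsortiumState(sites=[site], master_seed=0)
        with pytest.raises(Exception, match="collinear"):
            decentralized_t_stats(consortium, np.zeros(3))


class TestTToPvalue:
    def test_reference_values_and_monotonicity(self):
        assert t_to_pvalue(0.0, 5) == 1.0
        assert abs(t_to_pvalue(1.96, 10**6) - 0.05) < 1e-3  # normal limit
        grid = [t_to_pvalue(t, 12) for t in (0.0, 1.0, 2.0, 3.0)]
        assert all(b < a for a, b in zip(grid, grid[1:]))
        with pytest.raises(ValueError):
            t_to_pvalue(1.0, 0)


class TestReport:
    def test_single_site_global_equals_local_block(self, fitted):
        pooled, _, _, _ = fitted
        consortium = ConsortiumState(sites=[pooled], master_seed=0)
        fit, _ = fit_singleshot(consortium, 0.0)
        report = build_report(consortium, fit)
        local = report.per_site[pooled.site_id]
        np.testing.assert_allclose(report.global_stats["beta"], local["beta"], rtol=1e-10)
        np.testing.assert_allclose(report.global_stats["t"], local["t"], rtol=1e-10)
        assert report.global_stats["degrees_of_freedom"] == local["degrees_of_freedom"]

    def test_json_round_trip_lossless(self, fitted):
        pooled, _, _, _ = fitted
        consortium = ConsortiumState(sites=split_pooled(pooled, 2, seed=0), master_seed=0)
        fit, _ = fit_singleshot(consortium, 0.0)
        report = build_report(consortium, fit)
        again = RegressionReport.from_json(report.to_json())
        assert again.to_json() == report.to_json()
        assert again.global_stats == report.global_stats

    def test_tiny_site_gets_insufficient_data_marker(self, fitted):
        pooled, _, _, _ = fitted
        tiny = SiteDataset(
            site_id="tiny",
            X=pooled.X[:3],
            feature_names=pooled.feature_names,
            feature_types=pooled.feature_types,
            y=pooled.y[:3],
            y_name=pooled.y_name,
        )
        consortium = ConsortiumState(sites=[pooled, tiny], master_seed=0)
        fit, _ = fit_singleshot(
            ConsortiumState(sites=[pooled], master_seed=0), 0.0
        )
        report = build_report(consortium, fit)
        assert "insufficient data" in report.per_site["tiny"]["message"]
        assert "beta" in report.per_site[pooled.site_id]

    def test_text_table_lists_global_then_sites(self, fitted):
        pooled, _, _, _ = fitted
        consortium = ConsortiumState(sites=split_pooled(pooled, 2, seed=0), master_seed=0)
        fit, _ = fit_singleshot(consortium, 0.0)
        text = build_report(consortium, fit).to_text()
        assert text.index("Global") < text.index("Site ")
        assert "intercept" in text and "isControl" in text
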