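import numpy as np
import pytest
from sklearn.base import clone

from otsp import (
    BiasModel,
    NegativeBinomialPanelModel,
    fit_nb_single,
    fit_panel,
    independence_spread_bound,
    mean_variance_table,
    pool_batches,
    sample_nb,
    scaling_factor_stability,
    simulate_st_counts,
)
from otsp.nb import NBPanelFit, nb_loglik
from otsp.panel import PanelError, PrimerPanel, STCountMatrix


class TestSingleFit:
    def test_constant_counts_hit_poisson_boundary(self):
        fit = fit_nb_single([7, 7, 7, 7])
        assert fit.m_hat == 7
        assert fit.d_hat == 0.0

    def test_mean_is_arithmetic_mean(self):
        assert fit_nb_single([10, 30]).m_hat == 20

    def test_dispersion_consistency_at_large_n(self, rng):
        counts = sample_nb(200.0, 0.125, size=4000, rng=rng)
        fit = fit_nb_single(counts)
        assert fit.m_hat == pytest.approx(counts.mean())
        assert fit.d_hat == pytest.approx(0.125, rel=0.10)

    def test_all_zero_vector_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            fit_nb_single([0, 0, 0])

    def test_fitted_loglik_is_profile_maximum(self, rng):
        counts = sample_nb(50.0, 0.3, size=200, rng=rng)
        fit = fit_nb_single(counts)
        for d in (0.0, 0.1, 0.5, 1.0):
            assert fit.loglik >= nb_loglik(counts, fit.m_hat, d) - 1e-6


class TestPanelFit:
    def test_identical_columns_give_zero_dispersion(self, small_panel):
        col = np.arange(1, small_panel.n_pairs + 1) * 10
        matrix = STCountMatrix(small_panel, np.column_stack([col] * 4))
        fit = fit_panel(matrix)
        assert np.all(fit.dispersions == 0)
        assert fit.common_dispersion == 0.0
        assert np.allclose(fit.means, col)

    def test_row_means_recovered(self, small_bias_model):
        matrix = simulate_st_counts(small_bias_model, 10, seed=2)
        fit = fit_panel(matrix)
        assert np.allclose(fit.means, matrix.counts.mean(axis=1))
        assert fit.m_bar == pytest.approx(fit.means.mean())

    def test_sample_permutation_invariance(self, small_bias_model):
        matrix = simulate_st_counts(small_bias_model, 8, seed=3)
        fit_a = fit_panel(matrix)
        perm = np.random.default_rng(0).permutation(8)
        matrix_b = STCountMatrix(matrix.panel, matrix.counts[:, perm])
        fit_b = fit_panel(matrix_b)
        assert np.allclose(fit_a.dispersions, fit_b.dispersions)
        assert np.allclose(fit_a.means, fit_b.means)

    def test_single_sample_rejected(self, small_panel):
        matrix = STCountMatrix(small_panel,
                               np.ones((small_panel.n_pairs, 1), dtype=int))
        with pytest.raises(ValueError, match="2 samples"):
            fit_panel(matrix)

    def test_zero_rows_excluded_with_warning(self, small_panel):
        counts = np.full((small_panel.n_pairs, 5), 40)
        counts[2] = 0
        matrix = STCountMatrix(small_panel, counts)
        with pytest.warns(UserWarning, match="all-zero"):
            fit = fit_panel(matrix)
        assert fit.excluded[2]
        assert np.isnan(fit.dispersions[2])
        assert fit.m_bar == 40

    def test_estimator_sklearn_contract(self, small_bias_model):
        X = simulate_st_counts(small_bias_model, 6, seed=4).counts.T
        est = NegativeBinomialPanelModel(d_max=5.0)
        assert clone(est).get_params()["d_max"] == 5.0
        est.fit(X)
        assert est.means_.shape == (X.shape[1],)
        assert est.scaling_factors_ == pytest.approx(
            est.means_ / est.means_.mean())
        assert np.isfinite(est.score(X))


class TestMeanVarianceTable:
    def test_model_line_values(self, small_panel):
        counts = np.column_stack([np.full(small_panel.n_pairs, 90),
                                  np.full(small_panel.n_pairs, 110)])
        table = mean_variance_table(STCountMatrix(small_panel, counts), 0.125)
        assert np.allclose(table["m_hat"], 100)
        assert np.allclose(table["v_model"], 1350)  # 100 + 0.125 * 100^2

    def test_poisson_line_when_d_zero(self, small_bias_model):
        matrix = simulate_st_counts(small_bias_model, 5, seed=5)
        table = mean_variance_table(matrix, 0.0)
        assert np.allclose(table["v_model"], table["m_hat"])
        assert table["m_hat"].is_monotonic_increasing


class TestPooling:
    def test_single_batch_proportional_to_row_means(self, small_bias_model):
        matrix = simulate_st_counts(small_bias_model, 6, seed=6)
        combined = pool_batches([matrix])
        means = matrix.row_means()
        assert np.allclose(combined, means / means.mean())
        assert combined.mean() == pytest.approx(1.0)

    def test_concentration_shift_invariance(self, small_panel, small_bias_model):
        matrix = simulate_st_counts(small_bias_model, 6, seed=7)
        doubled = STCountMatrix(small_panel, matrix.counts * 2,
                                batch_id="double")
        assert np.allclose(pool_batches([matrix]),
                           pool_batches([matrix, doubled]))

    def test_hand_arithmetic_two_batches(self):
        panel = PrimerPanel(("V1",), ("J1", "J2"))
        a = STCountMatrix(panel, np.array([[10, 10], [30, 30]]), batch_id="a")
        b = STCountMatrix(panel, np.array([[20, 20], [60, 60]]), batch_id="b")
        assert np.allclose(pool_batches([a, b]), [0.5, 1.5])

    def test_panel_mismatch_rejected(self, small_panel, small_bias_model):
        other = PrimerPanel(("V1",), ("J1",))
        a = simulate_st_counts(small_bias_model, 3, seed=8)
        b = STCountMatrix(other, np.array([[5, 5, 5]]))
        with pytest.raises(PanelError):
            pool_batches([a, b])


class TestIndependenceBound:
    def test_seed_determinism(self):
        a = independence_spread_bound(500, 0.1, 50, 10, 5, seed=3)
        b = independence_spread_bound(500, 0.1, 50, 10, 5, seed=3)
        assert np.array_equal(a.qratio, b.qratio)
        assert a.summary() == b.summary()

    def test_poisson_cv_matches_closed_form(self):
        # independent Poisson(m): post-normalization CV ~ 1/sqrt(m)
        m = 400.0
        bound = independence_spread_bound(m, 0.0, 200, 40, 20, seed=4)
        assert bound.cv_mean == pytest.approx(1 / np.sqrt(m), rel=0.10)

    def test_spread_shrinks_with_mean(self):
        lo = independence_spread_bound(100, 0.0, 100, 20, 10, seed=5)
        hi = independence_spread_bound(10_000, 0.0, 100, 20, 10, seed=5)
        assert hi.qratio_mean < lo.qratio_mean
        assert hi.cv_mean < lo.cv_mean


class TestStability:
    def _fit_from_means(self, panel, means):
        means = np.asarray(means, dtype=float)
        return NBPanelFit(panel=panel, means=means,
                          dispersions=np.zeros(len(means)),
                          common_dispersion=0.0, m_bar=float(means.mean()),
                          n_samples=10)

    def test_self_correlation_is_one(self, small_panel, small_bias_model):
        matrix = simulate_st_counts(small_bias_model, 10, seed=9)
        fit = fit_panel(matrix)
        assert scaling_factor_stability(fit, fit) == pytest.approx(1.0)

    def test_concentration_rescaled_copy_is_one(self, small_panel):
        means = np.linspace(10, 300, small_panel.n_pairs)
        a = self._fit_from_means(small_panel, means)
        b = self._fit_from_means(small_panel, 7.3 * means)
        assert scaling_factor_stability(a, b) == pytest.approx(1.0)

    def test_independent_replicates_correlate_strongly(self, small_panel):
        model = BiasModel.separable(small_panel, seed=10, mean_level=3000,
                                    log_spread=4.0, dispersion=0.125)
        fit_a = fit_panel(simulate_st_counts(model, 20, seed=11))
        fit_b = fit_panel(simulate_st_counts(model, 20, seed=12))
        assert scaling_factor_stability(fit_a, fit_b) > 0.9

    def test_too_few_shared_templates_rejected(self, small_panel):
        means = np.zeros(small_panel.n_pairs)
        means[:2] = (10, 20)
        a = self._fit_from_means(small_panel, means)
        with pytest.warns(UserWarning, match="zero mean"):
            with pytest.raises(ValueError, match="fewer than 3"):
                scaling_factor_stability(a, a)
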