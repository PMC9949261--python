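import numpy as np
import pytest
from sklearn.base import clone

from otsp import (
    BiasModel,
    ClonotypeTable,
    SpikeInNormalizer,
    batch_scaling_factors,
    clonotype_primer_totals,
    fit_panel,
    nb_scaling_factors,
    normalize_clonotypes,
    normalize_primer_totals,
    simulate_repertoire,
    simulate_st_counts,
    spread_report,
)
from otsp.normalize import ScalingFactorSet
from otsp.panel import PanelError, PrimerPanel, STCountMatrix


@pytest.fixture()
def two_pair_panel():
    return PrimerPanel(("V1",), ("J1", "J2"))


class TestScalingFactors:
    def test_batch_factors_hand_example(self, two_pair_panel):
        matrix = STCountMatrix(two_pair_panel, np.array([[10, 10], [30, 30]]))
        sf = batch_scaling_factors(matrix)
        assert np.allclose(sf.factors, [0.5, 1.5])

    def test_equal_rows_give_unit_factors(self, small_panel):
        matrix = STCountMatrix(small_panel,
                               np.full((small_panel.n_pairs, 3), 25))
        assert np.allclose(batch_scaling_factors(matrix).factors, 1.0)

    def test_factors_average_to_one(self, small_bias_model):
        matrix = simulate_st_counts(small_bias_model, 7, seed=1)
        assert batch_scaling_factors(matrix).factors.mean() == pytest.approx(1.0)

    def test_all_zero_matrix_rejected(self, small_panel):
        matrix = STCountMatrix(small_panel,
                               np.zeros((small_panel.n_pairs, 2), dtype=int))
        with pytest.raises(ValueError):
            batch_scaling_factors(matrix)

    def test_nb_factors_hand_example(self, two_pair_panel):
        sf = nb_scaling_factors(np.array([10.0, 30.0]), panel=two_pair_panel)
        assert np.allclose(sf.factors, [0.5, 1.5])

    def test_batch_and_nb_routes_identical_on_one_batch(self, small_bias_model):
        # the NB mean MLE is the arithmetic mean, so both factor flavours
        # coincide on the matrix they were derived from
        matrix = simulate_st_counts(small_bias_model, 6, seed=2)
        a = batch_scaling_factors(matrix).factors
        b = nb_scaling_factors(fit_panel(matrix)).factors
        assert np.allclose(a, b)

    def test_uniform_means_give_unit_factors(self, small_panel):
        sf = nb_scaling_factors(np.full(small_panel.n_pairs, 5.0),
                                panel=small_panel)
        assert np.allclose(sf.factors, 1.0)


class TestNormalizeTotals:
    def test_hand_example_preserves_total(self, two_pair_panel):
        sf = ScalingFactorSet(two_pair_panel, np.array([0.5, 1.5]))
        out = normalize_primer_totals([10, 30], sf)
        assert np.allclose(out, [20, 20])
        assert out.sum() == 40

    def test_unit_factors_are_identity(self, small_panel):
        sf = ScalingFactorSet(small_panel, np.ones(small_panel.n_pairs))
        totals = np.arange(small_panel.n_pairs, dtype=float)
        assert np.allclose(normalize_primer_totals(totals, sf), totals)

    def test_zero_total_stays_zero(self, two_pair_panel):
        sf = ScalingFactorSet(two_pair_panel, np.array([0.5, 1.5]))
        assert normalize_primer_totals([0, 0], sf).sum() == 0

    def test_missing_factor_with_nonzero_total_errors(self, two_pair_panel):
        sf = ScalingFactorSet(two_pair_panel, np.array([1.0, np.nan]))
        with pytest.raises(PanelError, match="without a scaling factor"):
            normalize_primer_totals([5, 5], sf)

    def test_st_grand_total_conserved_exactly(self, small_bias_model):
        # batch-mean normalization of the factor-generating matrix is an
        # algebraic identity: sum_i C'_i. == sum_i C_i.
        matrix = simulate_st_counts(small_bias_model, 8, seed=3)
        sf = batch_scaling_factors(matrix)
        norm = np.column_stack([
            normalize_primer_totals(matrix.counts[:, j], sf)
            for j in range(matrix.n_samples)
        ])
        assert norm.mean(axis=1).sum() == pytest.approx(
            matrix.row_means().sum(), rel=1e-12)

    def test_idempotence_of_refit_factors(self, small_bias_model):
        matrix = simulate_st_counts(small_bias_model, 8, seed=4)
        sf = batch_scaling_factors(matrix)
        norm = np.column_stack([
            normalize_primer_totals(matrix.counts[:, j], sf)
            for j in range(matrix.n_samples)
        ])
        refit = norm.mean(axis=1) / norm.mean(axis=1).mean()
        assert np.allclose(refit, 1.0)


class TestNormalizeClonotypes:
    def test_hand_example(self, two_pair_panel):
        table = ClonotypeTable.from_records([
            {"cdr3_nt": "AC", "v_name": "V1", "j_name": "J1", "raw_count": 30},
            {"cdr3_nt": "GT", "v_name": "V1", "j_name": "J1", "raw_count": 70},
        ])
        sf = ScalingFactorSet(two_pair_panel, np.array([2.0, 0.5]))
        out = normalize_clonotypes(table, sf)
        assert np.allclose(out.frame["normalized_count"], [15, 35])

    def test_unit_factors_identity(self, two_pair_panel):
        table = ClonotypeTable.from_records([
            {"cdr3_nt": "AC", "v_name": "V1", "j_name": "J2", "raw_count": 12},
        ])
        sf = ScalingFactorSet(two_pair_panel, np.ones(2))
        out = normalize_clonotypes(table, sf)
        assert np.allclose(out.frame["normalized_count"],
                           out.frame["raw_count"])

    def test_within_pair_proportions_invariant(self, small_panel, rng):
        records = [
            {"cdr3_nt": f"C{k}", "v_name": small_panel.v_names[rng.integers(3)],
             "j_name": small_panel.j_names[rng.integers(2)],
             "raw_count": int(rng.integers(1, 200))}
            for k in range(30)
        ]
        table = ClonotypeTable.from_records(records, panel=small_panel)
        factors = rng.uniform(0.3, 3.0, small_panel.n_pairs)
        sf = ScalingFactorSet(small_panel, factors / factors.mean())
        out = normalize_clonotypes(table, sf)
        idx = out.pair_indices(small_panel)
        raw_tot = clonotype_primer_totals(out, small_panel).astype(float)
        norm = out.frame["normalized_count"].to_numpy()
        norm_tot = np.bincount(idx, weights=norm,
                               minlength=small_panel.n_pairs)
        raw = out.frame["raw_count"].to_numpy(dtype=float)
        assert np.allclose(norm / norm_tot[idx], raw / raw_tot[idx])

    def test_bias_removed_in_expectation(self, small_panel):
        # normalizing with the true relative efficiencies restores the
        # 50:50 design: dominant-clone proportion is pulled back to 1/2
        means = np.full(small_panel.n_pairs, 200.0)
        means[0] = 800.0
        model = BiasModel(panel=small_panel, st_means=means, dispersion=0.05)
        sf = nb_scaling_factors(means, panel=small_panel)
        norm_props, raw_props = [], []
        for seed in range(30):
            table = simulate_repertoire([0.5, 0.5], [0, 1], model,
                                        depth=50_000, seed=seed,
                                        drop_unobserved=False)
            out = normalize_clonotypes(table, sf)
            f = out.frame.set_index("clone_id")
            raw_props.append(f["raw_count"]["clone1"]
                             / f["raw_count"].sum())
            norm_props.append(f["normalized_count"]["clone1"]
                              / f["normalized_count"].sum())
        # raw proportions sit near the biased 800/(800+200) = 0.8 ...
        assert np.mean(raw_props) == pytest.approx(0.8, abs=0.05)
        # ... normalization with the true factors restores 1/2 on average
        assert abs(np.mean(norm_props) - 0.5) < 0.03
        assert np.mean(np.abs(np.array(norm_props) - 0.5)) < \
            np.mean(np.abs(np.array(raw_props) - 0.5))


class TestSpreadReport:
    def test_unbiased_matrix_unchanged_by_unit_factors(self, small_panel):
        model = BiasModel.uniform(small_panel, mean_level=1000, dispersion=0.05)
        matrix = simulate_st_counts(model, 6, seed=5)
        sf = ScalingFactorSet(small_panel, np.ones(small_panel.n_pairs))
        rep = spread_report(matrix, sf)
        assert np.allclose(rep.per_sample["qratio_raw"],
                           rep.per_sample["qratio_normalized"])

    def test_normalization_reduces_cv_in_every_sample(self):
        panel = PrimerPanel.default()
        model = BiasModel.separable(panel, seed=6, mean_level=5000,
                                    log_spread=4.0, dispersion=0.125)
        matrix = simulate_st_counts(model, 10, seed=7)
        sf = nb_scaling_factors(fit_panel(matrix))
        rep = spread_report(matrix, sf)
        assert (rep.per_sample["cv_normalized"]
                < rep.per_sample["cv_raw"]).all()
        assert rep.iqr_contrast > 1.0


class TestSpikeInNormalizerEstimator:
    def test_sklearn_contract_and_round_trip(self, small_bias_model):
        X = simulate_st_counts(small_bias_model, 5, seed=8).counts.T.astype(float)
        est = SpikeInNormalizer(kind="batch_mean")
        assert clone(est).get_params()["kind"] == "batch_mean"
        out = est.fit_transform(X)
        assert est.scaling_factors_.mean() == pytest.approx(1.0)
        back = est.inverse_transform(out)
        assert np.allclose(back, X)
        # normalized column means are all equal to the grand mean
        assert np.allclose(out.mean(axis=0), X.mean(axis=0).mean())

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="kind"):
            SpikeInNormalizer(kind="median").fit(np.ones((3, 4)))
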