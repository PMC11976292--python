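"""Tests of the synthetic-data generators."""

import numpy as np
import pandas as pd
import pytest

from methylhet import epiallele as ep
from methylhet.simulate import (
    SimulationConfig,
    simulate_epiallele_data,
    simulate_expression,
    simulate_mixture,
    simulate_tree_data,
)
from methylhet.phylo import check_four_point


class TestConfig:
    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_eloci=0)

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(frac_differential=1.5)

    def test_invalid_concentration_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(disorder_high=-1.0)


class TestEpialleleSimulation:
    def test_seed_determinism(self):
        cfg = SimulationConfig(seed=9, n_eloci=50, n_patients=2,
                               regions_per_patient=2, n_normal=3)
        a = simulate_epiallele_data(cfg)
        b = simulate_epiallele_data(cfg)
        assert np.array_equal(a.counts, b.counts)
        pd.testing.assert_frame_equal(a.truth, b.truth)

    def test_no_differential_when_fraction_zero(self):
        cfg = SimulationConfig(seed=3, n_eloci=80, frac_differential=0.0,
                               n_patients=2, regions_per_patient=2, n_normal=2)
        sim = simulate_epiallele_data(cfg)
        assert sim.truth["differential"].sum() == 0
        assert np.allclose(sim.truth["delta_true"], 0.0)

    def test_ordered_vectors_concentrated_and_low_disorder(self, small_sim):
        # ordered side of differential loci: mass ~1 on one pattern implies
        # epipolymorphism <= 1 - 0.95^2 = 0.0975 whenever mass >= 0.95
        tr = small_sim.truth
        diff = tr[tr["differential"]]
        probs = small_sim.pattern_probs
        idx = {eid: i for i, eid in enumerate(small_sim.elocus_ids)}
        n_conc = 0
        for _, row in diff.iterrows():
            g = 1 if row["disordered_group"] == "tumour" else 0  # ordered side
            p = probs[idx[row["elocus_id"]], g]
            if p.max() >= 0.95:
                n_conc += 1
                assert ep.epipolymorphism(p * 1000) <= 0.0975 + 1e-9
        assert n_conc >= 0.8 * len(diff)

    def test_disordered_vectors_near_uniform(self, small_sim):
        tr = small_sim.truth
        diff = tr[tr["differential"]]
        dis_epi = np.where(
            diff["disordered_group"] == "tumour", diff["epi_tumour"], diff["epi_normal"]
        )
        assert np.all(dis_epi > 0.8)
        # uniform limit: 1 - 16/16^2
        assert ep.epipolymorphism(np.full(16, 1.0)) == pytest.approx(0.9375)

    def test_empirical_disorder_converges_at_high_coverage(self):
        cfg = SimulationConfig(seed=17, n_eloci=60, coverage_mean=10000,
                               coverage_dispersion=50, n_patients=1,
                               regions_per_patient=2, n_normal=2)
        sim = simulate_epiallele_data(cfg)
        epi, _, _ = sim.profile_matrices()
        truth = sim.truth.set_index("elocus_id")
        tum_cols = sim.samples.loc[sim.samples["group"] == "tumour", "sample_id"]
        emp = epi[tum_cols].to_numpy()
        expected = truth.loc[epi.index, "epi_tumour"].to_numpy()[:, None]
        assert np.nanmax(np.abs(emp - expected)) < 0.01

    def test_null_delta_centred_at_zero(self):
        cfg = SimulationConfig(seed=23, n_eloci=400, frac_differential=0.0,
                               n_patients=2, regions_per_patient=3, n_normal=6)
        sim = simulate_epiallele_data(cfg)
        epi, _, _ = sim.profile_matrices()
        g = sim.samples.set_index("sample_id")["group"]
        tum = epi.loc[:, g[epi.columns] == "tumour"].mean(axis=1)
        nor = epi.loc[:, g[epi.columns] == "normal"].mean(axis=1)
        d = (tum - nor).dropna()
        assert abs(d.mean()) < 3 * d.std() / np.sqrt(len(d))

    def test_zero_coverage_yields_missing_profile(self):
        cfg = SimulationConfig(seed=2, n_eloci=300, coverage_mean=1.0,
                               coverage_dispersion=0.3, n_patients=1,
                               regions_per_patient=2, n_normal=2)
        sim = simulate_epiallele_data(cfg)
        epi, _, depth = sim.profile_matrices()
        zero = depth.to_numpy() == 0
        assert zero.any()
        assert np.isnan(epi.to_numpy()[zero]).all()


class TestExpressionSimulation:
    @staticmethod
    def _profiles(seed=5, n_eloci=30):
        cfg = SimulationConfig(seed=seed, n_eloci=n_eloci, n_patients=2,
                               regions_per_patient=3, n_normal=4,
                               coverage_mean=200, coverage_dispersion=20)
        sim = simulate_epiallele_data(cfg)
        epi, meth, _ = sim.profile_matrices()
        return cfg, meth, epi

    def test_exact_affine_when_no_epi_effect_no_noise(self):
        cfg, meth, epi = self._profiles()
        cfg2 = SimulationConfig(**{**cfg.__dict__, "beta_epi": 0.0, "noise_sd": 0.0})
        expr, truth = simulate_expression(meth, epi, cfg2)
        g = 0
        y = expr.iloc[g].to_numpy()
        m = meth.iloc[g].to_numpy()
        pred = truth["b0"].iloc[g] + truth["beta_meth"].iloc[g] * m
        assert np.allclose(y, pred, equal_nan=True)

    def test_full_model_rss_zero_without_noise(self):
        cfg, meth, epi = self._profiles()
        cfg2 = SimulationConfig(**{**cfg.__dict__, "noise_sd": 0.0, "beta_epi": -2.0})
        expr, truth = simulate_expression(meth, epi, cfg2)
        y = expr.iloc[3].to_numpy()
        m = meth.iloc[3].to_numpy()
        e = epi.iloc[3].to_numpy()
        ok = ~(np.isnan(m) | np.isnan(e))
        X = np.column_stack([np.ones(ok.sum()), m[ok], e[ok]])
        beta, _, _, _ = np.linalg.lstsq(X, y[ok], rcond=None)
        rss = np.sum((y[ok] - X @ beta) ** 2)
        assert rss == pytest.approx(0.0, abs=1e-18)

    def test_seed_determinism(self):
        cfg, meth, epi = self._profiles()
        a, _ = simulate_expression(meth, epi, cfg)
        b, _ = simulate_expression(meth, epi, cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_mismatched_inputs_rejected(self):
        cfg, meth, epi = self._profiles()
        with pytest.raises(ValueError):
            simulate_expression(meth, epi.iloc[:, :-1], cfg)


class TestMixtureSimulation:
    def test_proportions_on_simplex(self):
        cfg = SimulationConfig(seed=4, k_true=4)
        D, T0, A0 = simulate_mixture(cfg, n_features=100, n_samples=15)
        assert np.allclose(A0.sum(axis=0), 1.0, atol=1e-12)
        assert D.min() >= 0.0 and D.max() <= 1.0

    def test_single_component_noiseless(self):
        cfg = SimulationConfig(seed=4, k_true=1)
        D, T0, A0 = simulate_mixture(cfg, n_features=50, n_samples=6)
        assert np.allclose(D, np.tile(T0, (1, 6)))

    def test_components_near_poles(self):
        cfg = SimulationConfig(seed=4, k_true=3)
        _, T0, _ = simulate_mixture(cfg, n_features=500, n_samples=5)
        assert np.mean((T0 < 0.2) | (T0 > 0.8)) > 0.9


class TestTreeSimulation:
    def test_distance_matrix_symmetric_zero_diagonal(self):
        _, d, _ = simulate_tree_data(6, seed=1)
        arr = d.to_numpy()
        assert np.allclose(arr, arr.T)
        assert np.allclose(np.diag(arr), 0.0)
        assert (arr[~np.eye(6, dtype=bool)] > 0).all()

    def test_four_point_condition_holds(self):
        for seed in (1, 2, 3):
            _, d, _ = simulate_tree_data(7, seed=seed)
            assert check_four_point(d, atol=1e-9)

    def test_seed_determinism(self):
        t1, d1, f1 = simulate_tree_data(5, seed=11)
        t2, d2, f2 = simulate_tree_data(5, seed=11)
        pd.testing.assert_frame_equal(d1, d2)
        pd.testing.assert_frame_equal(f1, f2)
        assert t1.as_string(schema="newick") == t2.as_string(schema="newick")

    def test_too_few_leaves_rejected(self):
        with pytest.raises(ValueError):
            simulate_tree_data(2, seed=1)

    def test_features_shape(self):
        _, _, f = simulate_tree_data(5, seed=2, n_features=12)
        assert f.shape == (5, 12)
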