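"""Simulator correctness: factor geometry, label logic, count distributions."""

import numpy as np
import pytest

from spami.downstream import grid_rook_adjacency, morans_i
from spami.simulate import (
    GroundTruth,
    SimulationConfig,
    add_gaussian_noise,
    make_spatial_factors,
    simulate_atac,
    simulate_pair,
    simulate_protein,
    simulate_rna,
)


def flat_truth(n_spots: int, activity: float = 1.0) -> GroundTruth:
    """Degenerate spatial field: constant activity, one factor."""
    act = np.full((n_spots, 1), activity)
    return GroundTruth(labels=np.ones(n_spots, dtype=int), factor_activity=act)


def fixed_mean_config(n_spots: int, n_features: int, **kw) -> SimulationConfig:
    """Config whose feature means are exactly `scale` at every entry."""
    rows = n_spots
    base = dict(grid_shape=(rows, 1), n_factors=1, factor_centers=[(0, 0)],
                n_features_per_modality=(n_features, n_features),
                baseline=0.0, loading_range=(1.0, 1.0), domain_sharpness=None,
                seed=0)
    base.update(kw)
    return SimulationConfig(**base)


class TestSpatialFactors:
    def test_activity_is_one_at_center(self):
        cfg = SimulationConfig(grid_shape=(10, 10), n_factors=1,
                               factor_centers=[(4.0, 7.0)])
        truth = make_spatial_factors(cfg)
        i = 4 * 10 + 7
        assert truth.factor_activity[i, 0] == pytest.approx(1.0)

    def test_default_grid_has_five_classes_all_populated(self):
        truth = make_spatial_factors(SimulationConfig())
        classes, counts = np.unique(truth.labels, return_counts=True)
        assert list(classes) == [0, 1, 2, 3, 4]
        assert np.all(counts >= 1)

    def test_huge_bandwidth_removes_background(self):
        cfg = SimulationConfig(factor_bandwidth=1e6)
        truth = make_spatial_factors(cfg)
        assert np.all(truth.factor_activity > 0.999)
        assert not np.any(truth.labels == 0)

    def test_label_rule_matches_threshold_and_argmax(self):
        cfg = SimulationConfig()
        truth = make_spatial_factors(cfg)
        peak = truth.factor_activity.max(axis=1)
        expected = np.where(peak < cfg.background_threshold, 0,
                            truth.factor_activity.argmax(axis=1) + 1)
        np.testing.assert_array_equal(truth.labels, expected)

    def test_too_few_centers_is_an_error(self):
        with pytest.raises(ValueError, match="centers"):
            SimulationConfig(n_factors=4, factor_centers=[(0, 0)])

    def test_factor_fields_are_spatially_smooth(self):
        cfg = SimulationConfig()
        truth = make_spatial_factors(cfg)
        W = grid_rook_adjacency(*cfg.grid_shape)
        scores = morans_i(truth.factor_activity, W)
        assert np.all(scores > 0.5)


class TestCountModels:
    def test_zinb_pi_zero_matches_pure_nb_zero_fraction(self):
        cfg = fixed_mean_config(2500, 20, zinb_params=(5.0, 2.0, 0.0))
        truth = flat_truth(2500)
        counts = simulate_rna(truth, cfg)
        # closed-form NB zero probability (theta/(theta+mu))^theta
        p0 = (2.0 / 7.0) ** 2.0
        se = np.sqrt(p0 * (1 - p0) / counts.size)
        assert abs((counts == 0).mean() - p0) < 4 * se

    def test_zinb_inflation_lower_bounds_zero_fraction(self):
        cfg = fixed_mean_config(1000, 10, zinb_params=(5.0, 2.0, 0.5))
        counts = simulate_rna(flat_truth(1000), cfg)
        assert (counts == 0).mean() >= 0.5 - 0.02

    def test_zinb_mean_matches_closed_form(self):
        mu, theta, pi = 5.0, 2.0, 0.1
        cfg = fixed_mean_config(2500, 20, zinb_params=(mu, theta, pi))
        counts = simulate_rna(flat_truth(2500), cfg)
        expected = (1 - pi) * mu  # 4.5
        var = (1 - pi) * mu * (1 + mu / theta + pi * mu)
        se = np.sqrt(var / counts.size)
        assert abs(counts.mean() - expected) < 3 * se

    def test_nb_variance_matches_closed_form(self):
        mu, theta = 10.0, 1.0
        cfg = fixed_mean_config(2500, 20, nb_params=(mu, theta))
        counts = simulate_protein(flat_truth(2500), cfg)
        expected = mu + mu**2 / theta  # 110
        assert counts.var() == pytest.approx(expected, rel=0.08)

    def test_nb_poisson_limit(self):
        cfg = fixed_mean_config(2500, 20, nb_params=(10.0, 1e7))
        counts = simulate_protein(flat_truth(2500), cfg)
        assert counts.var() / counts.mean() == pytest.approx(1.0, rel=0.05)

    def test_nb_degenerate_field_gives_baseline_mean(self):
        cfg = fixed_mean_config(2500, 20, nb_params=(4.0, 5.0),
                                baseline=0.5, loading_range=(1.0, 1.0))
        truth = flat_truth(2500, activity=0.0)
        counts = simulate_protein(truth, cfg)
        assert counts.mean() == pytest.approx(4.0 * 0.5, rel=0.05)

    def test_zip_zero_fraction_matches_closed_form(self):
        lam, pi = 2.0, 0.3
        cfg = fixed_mean_config(2500, 20, zip_params=(lam, pi))
        counts = simulate_atac(flat_truth(2500), cfg)
        p0 = pi + (1 - pi) * np.exp(-lam)  # 0.3947
        se = np.sqrt(p0 * (1 - p0) / counts.size)
        assert abs((counts == 0).mean() - p0) < 4 * se

    def test_zip_pi_zero_is_poisson(self):
        cfg = fixed_mean_config(2500, 20, zip_params=(2.0, 0.0))
        counts = simulate_atac(flat_truth(2500), cfg)
        assert counts.mean() == pytest.approx(2.0, rel=0.05)
        assert counts.var() / counts.mean() == pytest.approx(1.0, rel=0.06)

    def test_zip_near_total_inflation_gives_near_zero_matrix(self):
        cfg = fixed_mean_config(500, 10, zip_params=(2.0, 0.999))
        counts = simulate_atac(flat_truth(500), cfg)
        assert (counts == 0).mean() > 0.99

    def test_invalid_theta_raises(self):
        with pytest.raises(ValueError, match="theta"):
            SimulationConfig(zinb_params=(5.0, -1.0, 0.1))


class TestNoise:
    def test_sd_zero_is_identity(self):
        X = np.arange(12.0).reshape(3, 4)
        np.testing.assert_array_equal(add_gaussian_noise(X, 0.0, seed=1), X)

    def test_negative_sd_raises(self):
        with pytest.raises(ValueError):
            add_gaussian_noise(np.zeros((2, 2)), -1.0)

    def test_same_seed_is_deterministic(self):
        X = np.ones((50, 50))
        a = add_gaussian_noise(X, 1.0, seed=3)
        b = add_gaussian_noise(X, 1.0, seed=3)
        np.testing.assert_array_equal(a, b)

    def test_clipped_noise_on_zeros_is_half_normal(self):
        X = np.zeros((400, 400))
        out = add_gaussian_noise(X, 1.0, seed=5)
        pos = out[out > 0]
        # positive part of clipped N(0,1): half the entries, mean sqrt(2/pi)
        assert pos.size / out.size == pytest.approx(0.5, abs=0.01)
        assert pos.mean() == pytest.approx(np.sqrt(2 / np.pi), rel=0.02)
        assert np.all(out >= 0)


class TestPairGeneration:
    def test_identical_config_reproduces_bitwise(self):
        cfg = dict(grid_shape=(12, 12), noise_sd=0.7, seed=11)
        a = simulate_pair(SimulationConfig(**cfg))
        b = simulate_pair(SimulationConfig(**cfg))
        np.testing.assert_array_equal(a.X1, b.X1)
        np.testing.assert_array_equal(a.X2, b.X2)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_modality_pair_switch(self):
        atac = simulate_pair(SimulationConfig(grid_shape=(8, 8),
                                              modality_pair="rna_atac", seed=2))
        assert atac.modalities == ("rna", "atac")
        assert atac.X2.shape == (64, 50)

    def test_counts_are_nonnegative_integers_without_noise(self):
        pair = simulate_pair(SimulationConfig(grid_shape=(8, 8), seed=3))
        assert np.all(pair.X1 >= 0) and np.all(pair.X1 == np.round(pair.X1))
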