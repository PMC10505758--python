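"""Generators of the synthetic virtual-species study."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from wedge_sdm.grids import Grid
from wedge_sdm.synth import (LandscapeConfig, VirtualSpeciesTruth,
                             generate_bias_layer, generate_env_stack,
                             make_truth, sample_occurrences,
                             simulate_abundance, simulate_cameras)


def _truth_with_suitability(suit: np.ndarray) -> VirtualSpeciesTruth:
    """Wrap an arbitrary suitability surface in a truth object."""
    grid = Grid(*suit.shape)
    from wedge_sdm.grids import EnvStack
    env = EnvStack(grid, ["e1", "e2", "e3"],
                   np.zeros((3, *suit.shape)))
    return VirtualSpeciesTruth(env, np.zeros(3), np.ones(3), suit)


class TestEnvStack:
    def test_deterministic_given_seed(self):
        cfg = LandscapeConfig(seed=42)
        a = generate_env_stack(cfg)
        b = generate_env_stack(cfg)
        np.testing.assert_array_equal(a.data, b.data)

    def test_collinear_pair_hits_target(self):
        cfg = LandscapeConfig(collinearity=0.95, seed=3)
        env = generate_env_stack(cfg)
        rho = spearmanr(env.data[0].ravel(), env.data[1].ravel()).statistic
        assert abs(rho) >= 0.8
        # Pearson within +-0.1 of the requested mixing
        r = np.corrcoef(env.data[0].ravel(), env.data[1].ravel())[0, 1]
        assert abs(r - 0.95) <= 0.1

    def test_uncorrelated_layers_stay_uncorrelated(self):
        for seed in range(10):
            cfg = LandscapeConfig(n_rows=100, n_cols=100, smoothness=3.0,
                                  collinearity=0.0, seed=seed)
            env = generate_env_stack(cfg)
            flat = env.flat()
            rho = spearmanr(flat).statistic
            off = np.abs(rho[~np.eye(env.n_layers, dtype=bool)])
            assert off.max() < 0.5

    def test_layers_standardized(self):
        env = generate_env_stack(LandscapeConfig(seed=1))
        for k in range(env.n_layers):
            assert abs(env.data[k].mean()) < 1e-10
            assert abs(env.data[k].std() - 1) < 1e-10

    @pytest.mark.parametrize("kw", [
        {"n_rows": 9}, {"n_cols": 5}, {"n_layers": 2},
        {"collinearity": 1.0}, {"collinearity": -0.1}, {"smoothness": 0.0},
        {"collinear_pairs": ((0, 0),)}, {"collinear_pairs": ((0, 99),)},
    ])
    def test_invalid_config_rejected(self, kw):
        with pytest.raises(ValueError):
            LandscapeConfig(**kw)


class TestTruth:
    def test_suitability_one_at_center_and_closed_form(self):
        env = generate_env_stack(LandscapeConfig(n_layers=3, seed=5))
        center = env.flat()[123].copy()
        truth = make_truth(env, center, np.ones(3))
        assert truth.suitability_flat()[123] == pytest.approx(1.0)
        assert truth.true_suitability.max() <= 1.0
        assert truth.true_suitability.min() >= 0.0
        # one predictor offset by exactly one width, others at center
        env.data[:, 0, 0] = center
        env.data[0, 0, 0] = center[0] + 1.0
        t2 = make_truth(env, center, np.ones(3))
        assert t2.true_suitability[0, 0] == pytest.approx(np.exp(-0.5))

    def test_wider_niche_never_decreases_suitability(self):
        env = generate_env_stack(LandscapeConfig(n_layers=3, seed=6))
        t1 = make_truth(env, np.zeros(3), np.ones(3))
        t2 = make_truth(env, np.zeros(3), 2 * np.ones(3))
        assert (t2.true_suitability >= t1.true_suitability).all()

    def test_center_shape_mismatch(self):
        env = generate_env_stack(LandscapeConfig(n_layers=3, seed=0))
        with pytest.raises(ValueError):
            make_truth(env, np.zeros(4), np.ones(4))
        with pytest.raises(ValueError):
            make_truth(env, np.zeros(3), np.array([1.0, -1.0, 1.0]))


class TestOccurrences:
    def test_zero_suitability_region_never_sampled(self):
        suit = np.zeros((20, 20))
        suit[:10, :] = 1.0          # region A: rows 0-9
        truth = _truth_with_suitability(suit)
        occ = sample_occurrences(truth, np.ones((20, 20)), 50, seed=1)
        rows = occ["cell_id"].to_numpy() // 20
        assert (rows < 10).all()

    def test_exhaustion_returns_exact_support(self):
        suit = np.zeros((20, 20))
        suit[3, 4] = suit[7, 2] = suit[15, 15] = 1.0
        truth = _truth_with_suitability(suit)
        occ = sample_occurrences(truth, np.ones((20, 20)), 3, seed=2)
        assert set(occ["cell_id"]) == {3 * 20 + 4, 7 * 20 + 2, 15 * 20 + 15}
        with pytest.raises(ValueError):
            sample_occurrences(truth, np.ones((20, 20)), 4, seed=2)

    def test_bias_shifts_sampling_east(self):
        # uniform suitability, 9:1 bias toward the east half
        truth = _truth_with_suitability(np.ones((20, 20)))
        bias = np.ones((20, 20))
        bias[:, 10:] = 9.0
        east = []
        for seed in range(20):
            occ = sample_occurrences(truth, bias, 100, seed=seed)
            east.append((occ["cell_id"].to_numpy() % 20 >= 10).mean())
        assert np.mean(east) >= 0.7

    def test_dedup_one_presence_per_cell(self):
        truth = _truth_with_suitability(np.ones((20, 20)))
        occ = sample_occurrences(truth, np.ones((20, 20)), 200, seed=3)
        assert occ["cell_id"].is_unique


class TestAbundance:
    def test_wedge_bound_never_exceeded(self):
        env = generate_env_stack(LandscapeConfig(seed=8))
        truth = make_truth(env, np.zeros(5), np.ones(5), a=0.1, b=2.0)
        ab = simulate_abundance(truth, seed=4)
        ceiling = 0.1 + 2.0 * truth.true_suitability
        assert (ab - ceiling).max() <= 0

    def test_zero_ceiling_gives_zero_abundance(self):
        truth = _truth_with_suitability(np.zeros((20, 20)))
        ab = simulate_abundance(truth, seed=5)
        assert (ab == 0).all()

    def test_ratio_to_ceiling_fills_unit_interval(self):
        env = generate_env_stack(LandscapeConfig(seed=9))  # 10,000 cells
        truth = make_truth(env, np.zeros(5), np.ones(5), a=0.5, b=1.0)
        ab = simulate_abundance(truth, seed=6)
        ratio = ab / (0.5 + truth.true_suitability)
        assert 0.97 <= np.quantile(ratio, 0.99) <= 1.0


class TestCameras:
    def test_zero_abundance_station_records_nothing(self, small_grid):
        ab = np.zeros((20, 20))
        log = simulate_cameras(ab, small_grid, 10, 100.0, 1.0, seed=1)
        assert len(log.records) == 0
        assert len(log.effort) == 10

    def test_poisson_mean_matches_rate(self, small_grid):
        # rate_scale * abundance = 0.1/day over 100 days -> mean 10
        ab = np.full((20, 20), 0.2)
        counts = [len(simulate_cameras(ab, small_grid, 1, 100.0, 0.5,
                                       seed=s).records)
                  for s in range(50)]
        assert 8 <= np.mean(counts) <= 12

    def test_rate_proportionality(self, small_grid):
        ab = np.zeros((20, 20))
        ab.ravel()[0] = 0.1
        ab.ravel()[1] = 0.2
        cells = np.array([0, 1])
        r = np.zeros(2)
        for s in range(50):
            log = simulate_cameras(ab, small_grid, 2, 100.0, 1.0, seed=s,
                                   station_cells=cells)
            counts = log.records.groupby("cell_id").size()
            r += counts.reindex([0, 1]).fillna(0).to_numpy()
        assert 1.7 <= r[1] / r[0] <= 2.3

    def test_invalid_inputs(self, small_grid):
        ab = np.ones((20, 20))
        with pytest.raises(ValueError):
            simulate_cameras(ab, small_grid, 2, 100.0, -1.0, seed=0)
        with pytest.raises(ValueError):
            simulate_cameras(ab, small_grid, 2, 100.0, 1.0, seed=0,
                             station_cells=np.array([5, 5]))

    def test_multi_individual_flag_present(self, small_grid):
        ab = np.full((20, 20), 1.0)
        log = simulate_cameras(ab, small_grid, 50, 100.0, 1.0, seed=2,
                               multi_individual_prob=0.5)
        assert set(log.records["n_individuals"].unique()) <= {1, 2}
        assert (log.records["n_individuals"] == 2).mean() > 0.3


def test_bias_layer_strength_zero_is_uniform():
    cfg = LandscapeConfig(seed=11)
    assert (generate_bias_layer(cfg, 0.0) == 1.0).all()
    assert (generate_bias_layer(cfg, 1.0) > 0).all()
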