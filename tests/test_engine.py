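"""Inference orchestration: initialisation, free energy, fit, pruning, matching."""

import itertools

import numpy as np
import pytest
from scipy import integrate

from pfmlab import ModelConfig, MultiRunDataset, fit, initialize, simulate
from pfmlab import engine
from pfmlab._math import gaussian_kl_diag_prior
from pfmlab.datasets import ConfigurationError


class TestInitialize:
    def test_same_seed_bit_identical(self, tiny_sim):
        ds, _ = tiny_sim
        pre = ds.preprocessed()
        a = initialize(pre, ModelConfig(M=3, seed=7))
        b = initialize(pre, ModelConfig(M=3, seed=7))
        for s in a.subjects:
            assert np.array_equal(a.subjects[s].signal_mean,
                                  b.subjects[s].signal_mean)
        assert np.array_equal(a.group_spatial.rho_resp, b.group_spatial.rho_resp)
        key = next(iter(a.temporal_runs))
        assert np.array_equal(a.temporal_runs[key].B_eig_mean,
                              b.temporal_runs[key].B_eig_mean)

    def test_rank_one_data_recovers_map_direction(self, rng):
        v, t = 60, 40
        true_map = rng.standard_normal(v)
        tc = rng.standard_normal(t)
        d = np.outer(true_map, tc)
        ds = MultiRunDataset({(0, 0): d}, np.ones(v, bool), 2.0).preprocessed()
        state = initialize(ds, ModelConfig(M=1, seed=0))
        maps = state.group_maps()
        corr = np.corrcoef(maps[:, 0], true_map)[0, 1]
        assert abs(corr) > 1.0 - 1e-6

    def test_group_maps_correlate_with_truth_on_easy_data(self):
        cfg = simulate.model_matched_preset(n_voxels=300, n_timepoints=120,
                                            n_subjects=3, n_modes=3, snr=5.0,
                                            seed=2)
        ds, truth = simulate.generate(cfg)
        state = initialize(ds.preprocessed(), ModelConfig(M=3, seed=0))
        perm, signs = engine.match_modes(state.group_maps(), truth.group_maps)
        c = engine._column_corr(state.group_maps()[:, perm] * signs,
                                truth.group_maps)
        assert np.mean(np.diag(c)) > 0.5

    def test_overspecified_m_rejected(self, rng):
        ds = MultiRunDataset({(0, 0): rng.standard_normal((10, 8))},
                             np.ones(10, bool), 2.0)
        with pytest.raises(ConfigurationError):
            initialize(ds, ModelConfig(M=9, seed=0))


class TestFreeEnergy:
    def test_gaussian_kl_matches_quadrature(self):
        m_q, v_q, m_p, v_p = 0.7, 0.5, 0.0, 2.0

        def integrand(x):
            q = np.exp(-0.5 * (x - m_q) ** 2 / v_q) / np.sqrt(2 * np.pi * v_q)
            p = np.exp(-0.5 * (x - m_p) ** 2 / v_p) / np.sqrt(2 * np.pi * v_p)
            return q * (np.log(q) - np.log(p))

        oracle, _ = integrate.quad(integrand, -20, 20, limit=200)
        closed = gaussian_kl_diag_prior(np.array([m_q]), np.array([[v_q]]),
                                        m_p, v_p)
        assert closed == pytest.approx(oracle, abs=1e-8)

    def test_each_sweep_step_does_not_decrease_free_energy(self, tiny_sim):
        """Every coordinate update is an exact conditional maximisation, so
        the bound must not decrease after any single step (the positivity
        flip is a sign convention and is allowed a tiny slack)."""
        ds, _ = tiny_sim
        pre = ds.preprocessed()
        cfg = ModelConfig(M=3, seed=3)
        state = initialize(pre, cfg)
        fam = engine._alpha_families(pre, cfg)
        for _ in range(2):
            engine.sweep(state, fam)
        f = engine.compute_free_energy(state)
        for name, step in engine.SWEEP_STEPS:
            step(state, fam)
            f_new = engine.compute_free_energy(state)
            slack = 1e-7 * abs(f) if name == "positivity" else 1e-9 * abs(f)
            assert f_new >= f - slack, f"{name} decreased the bound"
            f = f_new

    def test_finite_on_initial_state(self, tiny_sim):
        ds, _ = tiny_sim
        pre = ds.preprocessed()
        state = initialize(pre, ModelConfig(M=3, seed=0))
        assert np.isfinite(engine.compute_free_energy(state))


class TestFit:
    def test_monotone_and_deterministic(self, tiny_sim, tiny_fit):
        ds, _ = tiny_sim
        fe = np.array(tiny_fit.free_energy)
        diffs = np.diff(fe)
        assert np.all(diffs >= -1e-8 * np.abs(fe[:-1]))
        again = fit(ds, ModelConfig(M=3, seed=1, max_sweeps=30))
        assert np.array_equal(fe, np.array(again.free_energy))
        for s in tiny_fit.subjects:
            assert np.array_equal(tiny_fit.subjects[s].responsibility,
                                  again.subjects[s].responsibility)

    def test_pool_runs_shares_alpha_within_subject(self):
        cfg = simulate.model_matched_preset(n_voxels=120, n_timepoints=50,
                                            n_subjects=2, n_modes=2, seed=4)
        cfg.n_runs = 2
        ds, _ = simulate.generate(cfg)
        res = fit(ds, ModelConfig(M=2, seed=0, max_sweeps=10, pool_runs=True))
        for s in res.subjects:
            assert np.array_equal(res.run_netmat(s, 0), res.run_netmat(s, 1))

    def test_surplus_modes_are_pruned(self):
        """Fitting M=8 to 5-mode data drives surplus modes to zero."""
        cfg = simulate.model_matched_preset(n_voxels=300, n_timepoints=120,
                                            n_subjects=4, n_modes=5, seed=5)
        ds, _ = simulate.generate(cfg)
        res = fit(ds, ModelConfig(M=8, seed=0, max_sweeps=60))
        assert int(np.sum(res.pruned)) >= 1

    def test_strong_modes_not_pruned(self, tiny_fit):
        assert int(np.sum(tiny_fit.pruned)) == 0
        assert len(tiny_fit.active_modes()) == 3


class TestMatchModes:
    def test_identity(self, rng):
        maps = rng.standard_normal((50, 4))
        perm, signs = engine.match_modes(maps, maps)
        assert np.array_equal(perm, np.arange(4))
        assert np.all(signs == 1.0)

    def test_known_permutation_and_flip(self, rng):
        maps = rng.standard_normal((50, 4))
        order = np.array([2, 0, 3, 1])
        flipped = maps[:, order] * np.array([1, -1, 1, 1.0])
        perm, signs = engine.match_modes(flipped, maps)
        aligned = flipped[:, perm] * signs
        c = engine._column_corr(aligned, maps)
        assert np.allclose(np.diag(c), 1.0)

    def test_matches_exhaustive_search(self, rng):
        """Hungarian assignment equals brute force over all 6! pairings."""
        est = rng.standard_normal((40, 6))
        ref = rng.standard_normal((40, 6))
        perm, _ = engine.match_modes(est, ref)
        corr = np.abs(engine._column_corr(est, ref))
        best, best_val = None, -np.inf
        for p in itertools.permutations(range(6)):
            val = sum(corr[p[j], j] for j in range(6))
            if val > best_val:
                best, best_val = p, val
        assert sum(corr[perm[j], j] for j in range(6)) == pytest.approx(best_val)

    def test_dimension_mismatch(self, rng):
        with pytest.raises(ConfigurationError):
            engine.match_modes(rng.standard_normal((10, 2)),
                               rng.standard_normal((11, 2)))
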