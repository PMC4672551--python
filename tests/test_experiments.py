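"""Training loop orchestration, attractor sampling and probe construction."""

import numpy as np
import pytest

from ecomemory import (
    EcosystemState,
    EnvironmentPattern,
    EvoConfig,
    attractor_census,
    corrupt_init,
    cue_init,
    generate_patterns,
    mixture_init,
    overlap_score,
    pattern_state,
    run_evolution,
    sample_attractors,
    uniform_community,
)


class TestEvoConfig:
    def test_full_scale_defaults(self):
        cfg = EvoConfig()
        assert (cfg.N, cfg.m, cfg.s0, cfg.k0) == (400, 0.5, 0.1, 10.0)
        assert (cfg.alpha, cfg.T, cfg.tau, cfg.g) == (0.1, 1, 5000, 0.01)
        assert cfg.omega_offdiag0 == -0.2

    def test_uniform_equilibrium_closed_form(self):
        assert EvoConfig().uniform_equilibrium() == pytest.approx(10 / 80.8)

    @pytest.mark.parametrize("field,value", [("N", 0), ("tau", -1), ("alpha", 11.0),
                                             ("m", 0.0), ("omega_offdiag0", 0.1)])
    def test_invalid_values_rejected(self, field, value):
        with pytest.raises(ValueError):
            EvoConfig(**{field: value})

    def test_rate_model_validation_through_config(self):
        with pytest.raises(ValueError, match="R"):
            EvoConfig(rate_model="linked_linear")


class TestRunEvolution:
    def test_zero_generations_leaves_matrix_unchanged(self, small_config):
        cfg = small_config.with_updates(n_generations=0)
        initial = uniform_community(cfg.N, cfg.omega_offdiag0)
        traj = run_evolution(cfg, initial_matrix=initial)
        assert traj.records == []
        np.testing.assert_array_equal(traj.final_matrix.omega, initial.omega)

    def test_budgets_conserved_every_recorded_generation(self, small_config):
        traj = run_evolution(small_config)
        assert len(traj.records) == small_config.n_generations
        for rec in traj.records:
            assert rec.max_row_residual < small_config.norm_tol
            assert rec.max_col_residual < small_config.norm_tol
            assert rec.max_asymmetry < 1e-9

    def test_snapshot_schedule(self, small_config):
        traj = run_evolution(small_config)
        gens = [g for g, _ in traj.snapshots]
        assert gens == [0, 5, 10]  # stride 5, 10 generations + final
        np.testing.assert_array_equal(
            traj.snapshots[0][1].omega,
            uniform_community(small_config.N, small_config.omega_offdiag0).omega,
        )

    def test_bitwise_deterministic(self, small_config):
        a = run_evolution(small_config)
        b = run_evolution(small_config)
        assert np.array_equal(a.final_matrix.omega, b.final_matrix.omega)
        for ra, rb in zip(a.records, b.records):
            assert np.array_equal(ra.densities, rb.densities)

    def test_environment_alternation_recorded(self, small_config):
        traj = run_evolution(small_config)
        assert [r.env_label for r in traj.records[:4]] == ["E1", "E2", "E1", "E2"]


class TestOverlapScore:
    def test_perfect_match(self):
        p = EnvironmentPattern(np.array([1.0, 1.0, -1.0, -1.0]))
        state = EcosystemState(np.array([2.0, 2.0, 0.5, 0.5]))
        assert overlap_score(state, p) == 1.0

    def test_complemented_state(self):
        p = EnvironmentPattern(np.array([1.0, 1.0, -1.0, -1.0]))
        state = EcosystemState(np.array([0.5, 0.5, 2.0, 2.0]))
        assert overlap_score(state, p) == -1.0

    def test_random_state_near_zero_overlap_at_large_n(self):
        # binomial tail: |score| <= 0.15 with probability >= 0.99 at N=400
        scores = []
        for seed in range(300):
            rng = np.random.default_rng(seed)
            p = generate_patterns(400, 1, seed=seed)[0]
            state = EcosystemState(rng.uniform(0.0, 1.0, 400))
            scores.append(abs(overlap_score(state, p)))
        assert np.mean(np.array(scores) <= 0.15) >= 0.99


class TestProbeStates:
    def setup_method(self):
        self.cfg = EvoConfig.desk_scale(N=20)
        self.p1, self.p2 = generate_patterns(20, 2, seed=9, target_overlap=0.0)

    def test_full_cue_is_pattern_state(self):
        state = cue_init(self.p1, 1.0, 0.1, self.cfg, seed=0)
        np.testing.assert_array_equal(
            state.densities, pattern_state(self.p1, self.cfg).densities
        )

    def test_zero_cue_is_uniform_baseline(self):
        state = cue_init(self.p1, 0.0, 0.07, self.cfg, seed=0)
        np.testing.assert_array_equal(state.densities, np.full(20, 0.07))

    def test_cue_never_zero_density(self):
        state = cue_init(self.p1, 0.3, 0.1, self.cfg, seed=1)
        assert np.all(state.densities > 0)

    def test_uncorrupted_pattern_intact(self):
        state = corrupt_init(self.p1, 0.0, seed=1, config=self.cfg)
        np.testing.assert_array_equal(
            state.densities, pattern_state(self.p1, self.cfg).densities
        )

    def test_full_corruption_is_random_high_low(self):
        state = corrupt_init(self.p1, 1.0, seed=1, config=self.cfg)
        x_bar = self.cfg.uniform_equilibrium()
        assert set(np.unique(state.densities)) <= {0.1 * x_bar, 1.5 * x_bar}

    def test_mixture_endpoints(self):
        s1 = mixture_init(self.p1, self.p2, 1.0, self.cfg, seed=2)
        np.testing.assert_array_equal(
            s1.densities, pattern_state(self.p1, self.cfg).densities
        )
        s0 = mixture_init(self.p1, self.p2, 0.0, self.cfg, seed=2)
        np.testing.assert_array_equal(
            s0.densities, pattern_state(self.p2, self.cfg).densities
        )

    def test_mixture_ratio_realized_exactly_on_disagreements(self):
        state = mixture_init(self.p1, self.p2, 0.6, self.cfg, seed=3)
        s1 = pattern_state(self.p1, self.cfg).densities
        disagree = self.p1.xi != self.p2.xi
        matches_p1 = (state.densities == s1)[disagree]
        assert matches_p1.sum() == round(0.6 * disagree.sum())

    @pytest.mark.parametrize("bad_fraction", [-0.1, 1.1])
    def test_fractions_validated(self, bad_fraction):
        with pytest.raises(ValueError):
            cue_init(self.p1, bad_fraction, 0.1, self.cfg)
        with pytest.raises(ValueError):
            corrupt_init(self.p1, bad_fraction, 0, self.cfg)


class TestSampleAttractors:
    def test_zero_samples_empty_set(self, small_config):
        mat = uniform_community(small_config.N, -0.2)
        aset = sample_attractors(mat, 0, seed=1, config=small_config)
        assert aset.n_attractors == 0
        assert aset.basin_counts == []

    def test_uniform_matrix_has_single_attractor(self, small_config):
        mat = uniform_community(small_config.N, -0.2)
        patterns = generate_patterns(small_config.N, 2, small_config.pattern_seed)
        aset = sample_attractors(mat, 12, seed=1, config=small_config,
                                 patterns=patterns)
        assert aset.n_attractors == 1
        assert aset.basin_counts == [12]
        expected = small_config.uniform_equilibrium()
        np.testing.assert_allclose(aset.attractors[0].densities, expected, rtol=1e-3)

    def test_census_of_empty_trajectory_is_empty(self, small_config):
        cfg = small_config.with_updates(n_generations=0)
        traj = run_evolution(cfg)
        traj.snapshots.clear()
        assert attractor_census(traj, 5, seed=1) == []
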