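import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from swarmsvm import (
    AllWeightsZeroError,
    C_BOUNDS,
    GAMMA_BOUNDS,
    ExpressionDataset,
    PsoConfig,
    apply_threshold,
    decode_particle,
    encode_particle,
    fitness,
    initialize_swarm,
    normalize_weights,
    optimize,
    update_particle,
)
from swarmsvm.pso import Particle, search_bounds


class TestInitialization:
    def test_positions_within_bounds_and_sizes(self):
        cfg = PsoConfig(swarm_size=50, seed=1)
        state = initialize_swarm(6, cfg)
        assert len(state.particles) == 50
        for p in state.particles:
            a, C, gamma = decode_particle(p.position)
            assert np.all((a >= 0) & (a <= 1))
            assert C_BOUNDS[0] <= C <= C_BOUNDS[1]
            assert GAMMA_BOUNDS[0] <= gamma <= GAMMA_BOUNDS[1]
            assert np.array_equal(p.best_position, p.position)

    def test_same_seed_same_swarm(self):
        cfg = PsoConfig(swarm_size=10, seed=42)
        a = initialize_swarm(4, cfg)
        b = initialize_swarm(4, cfg)
        for pa, pb in zip(a.particles, b.particles):
            assert np.array_equal(pa.position, pb.position)
            assert np.array_equal(pa.velocity, pb.velocity)


class TestUpdate:
    def test_stationary_fixed_point(self, constant_rng):
        cfg = PsoConfig(swarm_size=2, seed=0)
        x = np.array([0.5, 1.0, 1.0])
        p = Particle(x.copy(), np.zeros(3), x.copy(), 1.0)
        new = update_particle(p, x, cfg, constant_rng(0.5))
        assert np.array_equal(new.velocity, np.zeros(3))
        assert np.array_equal(new.position, x)

    def test_inertia_only_limit(self, constant_rng):
        """With r1 = r2 = 0 the update reduces to v' = w v, x' = x + w v."""
        cfg = PsoConfig(swarm_size=2, inertia=0.9, seed=0)
        x = np.array([0.5, 10.0, 1.0])
        v = np.array([0.05, 1.0, -0.1])
        p = Particle(x.copy(), v.copy(), x + 1.0, 0.0)
        new = update_particle(p, x - 1.0, cfg, constant_rng(0.0))
        assert np.allclose(new.velocity, 0.9 * v)
        assert np.allclose(new.position, x + 0.9 * v)

    def test_hand_computed_single_step(self, constant_rng):
        """One dimension, frozen randoms 0.5: v' = 0.9*0.1 + 1*(1-0) + 1*(2-0)."""
        cfg = PsoConfig(swarm_size=2, inertia=0.9, c1=2, c2=2, vmax_fraction=0.2, seed=0)
        p = Particle(np.array([0.0]), np.array([0.1]), np.array([1.0]), 0.0)
        bounds = (np.array([-10.0]), np.array([10.0]))  # vmax = 4: no clamping
        new = update_particle(p, np.array([2.0]), cfg, constant_rng(0.5), bounds=bounds)
        assert new.velocity[0] == pytest.approx(3.09, abs=1e-12)
        assert new.position[0] == pytest.approx(3.09, abs=1e-12)

    def test_velocity_clamped_to_vmax(self, constant_rng):
        cfg = PsoConfig(swarm_size=2, inertia=0.9, c1=2, c2=2, vmax_fraction=0.2, seed=0)
        p = Particle(np.array([0.0]), np.array([0.1]), np.array([1.0]), 0.0)
        bounds = (np.array([0.0]), np.array([1.0]))  # vmax = 0.2
        new = update_particle(p, np.array([1.0]), cfg, constant_rng(0.5), bounds=bounds)
        assert new.velocity[0] == pytest.approx(0.2)
        assert new.position[0] == pytest.approx(0.2)

    def test_velocities_decay_without_attraction(self, constant_rng):
        """c1 = c2 = 0 and w < 1: velocities shrink geometrically."""
        cfg = PsoConfig(swarm_size=2, inertia=0.5, c1=0, c2=0, seed=0)
        bounds = (np.array([-100.0]), np.array([100.0]))
        p = Particle(np.array([0.0]), np.array([8.0]), np.array([0.0]), 0.0)
        speeds = []
        for _ in range(6):
            p = update_particle(p, np.array([0.0]), cfg, constant_rng(0.0), bounds=bounds)
            speeds.append(abs(p.velocity[0]))
        assert np.allclose(speeds, 8.0 * 0.5 ** np.arange(1, 7))


class TestEncoding:
    def test_decode_split(self):
        a, C, gamma = decode_particle([0.2, 0.8, 10.0, 0.5])
        assert np.array_equal(a, [0.2, 0.8])
        assert (C, gamma) == (10.0, 0.5)

    def test_minimal_position(self):
        a, C, gamma = decode_particle([0.7, 1.0, 1.0])
        assert np.array_equal(a, [0.7])
        assert (C, gamma) == (1.0, 1.0)

    def test_round_trip(self):
        pos = encode_particle([0.1, 0.9], 250.0, 4.0)
        a, C, gamma = decode_particle(pos)
        assert np.array_equal(encode_particle(a, C, gamma), pos)

    def test_too_short(self):
        with pytest.raises(ValueError):
            decode_particle([1.0, 2.0])


class TestThresholdAndNormalize:
    def test_threshold_example(self):
        assert np.array_equal(
            apply_threshold([0.5, 0.3, 0.2], 0.25), [0.5, 0.3, 0.0]
        )

    def test_delta_zero_keeps_positive_weights(self):
        assert np.array_equal(apply_threshold([0.4, 0.0, 1.0], 0.0), [0.4, 0.0, 1.0])

    def test_delta_one_zeroes_everything(self):
        assert np.array_equal(apply_threshold([0.4, 1.0], 1.0), [0.0, 0.0])

    def test_delta_out_of_range(self):
        with pytest.raises(ValueError):
            apply_threshold([0.5], 1.5)

    def test_normalize_hand_example(self):
        w = normalize_weights([0.5, 0.3, 0.0])
        assert np.allclose(w.alpha, [0.625, 0.375, 0.0], atol=1e-15)

    def test_single_survivor_becomes_one(self):
        w = normalize_weights([0.0, 0.42, 0.0])
        assert w.alpha[1] == 1.0

    def test_all_zero_raises(self):
        with pytest.raises(AllWeightsZeroError):
            normalize_weights([0.0, 0.0])

    @settings(deadline=None, max_examples=100)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=30))
    def test_normalized_sum_is_one(self, raw):
        if sum(raw) == 0:
            return
        assert normalize_weights(raw).alpha.sum() == pytest.approx(1.0, abs=1e-12)


class TestFitness:
    def test_separable_position_scores_one(self, separable_dataset):
        ds, _ = separable_dataset
        pos = encode_particle(np.full(ds.n_genes, 0.8), 10.0, 0.1)
        assert fitness(pos, ds, delta=0.3) == 1.0

    def test_three_of_four_gives_three_quarters(self):
        # contradictory duplicate points: any classifier errs on exactly one
        ds = ExpressionDataset(
            [[0.0], [0.0], [1.0], [1.0]], [1, -1, 1, 1], ["g"], list("abcd")
        )
        pos = encode_particle([1.0], 100.0, 1.0)
        assert fitness(pos, ds, delta=0.0) == 0.75

    def test_degenerate_position_scores_zero(self, separable_dataset):
        ds, _ = separable_dataset
        pos = encode_particle(np.full(ds.n_genes, 0.2), 10.0, 0.1)
        assert fitness(pos, ds, delta=0.5) == 0.0


class TestOptimize:
    def test_history_non_decreasing_and_deterministic(self, separable_dataset, fast_pso):
        ds, _ = separable_dataset
        a = optimize(ds, fast_pso, delta=0.3)
        b = optimize(ds, fast_pso, delta=0.3)
        assert np.all(np.diff(a.history) >= 0)
        assert np.array_equal(a.best_position, b.best_position)
        assert len(a.history) == fast_pso.max_iterations + 1

    def test_positions_stay_in_bounds(self, separable_dataset):
        ds, _ = separable_dataset
        cfg = PsoConfig(swarm_size=4, max_iterations=3, seed=5)
        res = optimize(ds, cfg, delta=0.3)
        lo, hi = search_bounds(ds.n_genes)
        assert np.all(res.best_position >= lo) and np.all(res.best_position <= hi)

    def test_result_weights_satisfy_contract(self, separable_dataset, fast_pso):
        ds, _ = separable_dataset
        res = optimize(ds, fast_pso, delta=0.3)
        assert res.weights.alpha.sum() == pytest.approx(1.0, abs=1e-9)
        a, _, _ = decode_particle(res.best_position)
        surviving = res.weights.surviving_indices()
        assert np.all(a[surviving] > 0.3)  # every survivor beat the gate

    def test_hyperparameter_only_mode(self, separable_dataset):
        ds, _ = separable_dataset
        cfg = PsoConfig(swarm_size=4, max_iterations=2, seed=1)
        res = optimize(ds, cfg, delta=0.3, optimize_weights=False)
        assert res.best_position.size == 2
        assert np.allclose(res.weights.alpha, 1.0 / ds.n_genes)

    def test_initial_positions_override(self, separable_dataset):
        ds, _ = separable_dataset
        cfg = PsoConfig(swarm_size=3, max_iterations=0, seed=1)
        pos = encode_particle(np.ones(ds.n_genes), 1.0, 1.0)
        res = optimize(
            ds, cfg, delta=0.0, initial_positions=np.tile(pos, (3, 1))
        )
        assert np.array_equal(res.best_position, pos)
        assert np.allclose(res.weights.alpha, 1.0 / ds.n_genes)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(swarm_size=1),
            dict(max_iterations=-1),
            dict(c1=-0.5),
            dict(vmax_fraction=0.0),
            dict(vmax_fraction=1.5),
        ],
    )
    def test_bad_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            PsoConfig(**kwargs)


def test_trace_records_iteration_fitness_and_survivors(separable_dataset, fast_pso):
    ds, _ = separable_dataset
    res = optimize(ds, fast_pso, delta=0.3)
    assert res.trace.shape == (fast_pso.max_iterations + 1, 3)
    assert np.array_equal(res.trace[:, 1], res.history)
    assert np.all(res.trace[:, 2] <= ds.n_genes)
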