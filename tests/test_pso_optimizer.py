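import numpy as np
import pytest

from caedge.ca_core import DetectorParams, apply_detector
from caedge.image_synthesis import LabeledSample, PhantomSpec, make_circle_image
from caedge.processing import ScenarioConfig
from caedge.pso_optimizer import (
    NormalizedParams,
    SwarmConfig,
    SwarmState,
    denormalize_params,
    evaluate_fitness,
    normalize_params,
    optimize_dataset,
    optimize_unit,
    update_position,
    update_velocity,
)

FAST = SwarmConfig(n_particles=20, epochs_per_unit=10, seed=7)


class TestNormalization:
    def test_known_values(self):
        n = normalize_params(DetectorParams(delta=255, tau=0.3, rule=511))
        assert (n.delta_n, n.tau, n.rule_n) == (1.0, 0.3, 1.0)
        z = normalize_params(DetectorParams(delta=0, tau=0.0, rule=0))
        assert (z.delta_n, z.tau, z.rule_n) == (0.0, 0.0, 0.0)

    def test_round_half_up(self):
        p = denormalize_params(NormalizedParams(0.5, 0.9, 0.5))
        assert (p.delta, p.rule) == (128, 256)
        assert p.tau == pytest.approx(0.9)

    def test_clamping(self):
        p = denormalize_params(NormalizedParams(1.2, 1.5, -0.1))
        assert p.delta == 255
        assert p.rule == 0
        assert 0 <= p.tau < 1

    def test_roundtrip_exhaustive(self):
        for delta in range(0, 256, 5):
            for rule in range(0, 512, 7):
                p = DetectorParams(delta=delta, tau=0.42, rule=rule)
                assert denormalize_params(normalize_params(p)) == p


class TestKinematics:
    def test_pure_inertia(self, rng):
        cfg = SwarmConfig(omega=1.0, c1=0.0, c2=0.0)
        v = np.array([0.2, -0.1, 0.05])
        x = np.array([0.5, 0.5, 0.5])
        out = update_velocity(v, x, x, x, cfg, rng)
        np.testing.assert_allclose(out, v)

    def test_attraction_vanishes_at_bests(self, rng):
        cfg = SwarmConfig(omega=0.05, c1=2.1, c2=1.2)
        v = np.array([0.1, 0.2, 0.3])
        x = np.array([0.4, 0.4, 0.4])
        out = update_velocity(v, x, x, x, cfg, rng)
        np.testing.assert_allclose(out, cfg.omega * v)

    def test_hand_computed_step(self):
        class HalfRng:
            def random(self, shape):
                return np.full(shape, 0.5)

        cfg = SwarmConfig(omega=0.05, c1=2.1, c2=1.2)
        v = np.array([0.1, 0.0, 0.0])
        x = np.array([0.5, 0.5, 0.5])
        pbest = np.array([0.6, 0.5, 0.5])
        gbest = np.array([0.7, 0.5, 0.5])
        out = update_velocity(v, x, pbest, gbest, cfg, HalfRng())
        # 0.05*0.1 + 0.5*2.1*0.1 + 0.5*1.2*0.2 = 0.23
        assert out[0] == pytest.approx(0.23)
        assert out[1] == out[2] == 0.0

    def test_velocity_clamped(self, rng):
        cfg = SwarmConfig(omega=0.0, c1=50.0, c2=50.0, v_max=0.7)
        out = update_velocity(np.zeros(3), np.zeros(3), np.ones(3), np.ones(3), cfg, rng)
        assert np.all(np.abs(out) <= 0.7)

    def test_position_update_and_clamp(self):
        np.testing.assert_allclose(update_position(np.array([0.2, 0.2, 0.2]),
                                                   np.array([0.1, -0.1, 0.0])),
                                   [0.3, 0.1, 0.2])
        np.testing.assert_allclose(update_position(np.array([0.9, 0.9, 0.9]),
                                                   np.array([0.3, 0.0, 0.0])),
                                   [1.0, 0.9, 0.9])


class TestFitness:
    def test_perfect_and_empty_predictions(self, step_sample):
        p = DetectorParams(delta=0, tau=0.0, rule=0)  # empty mask -> empty map
        assert evaluate_fitness(normalize_params(p), [step_sample]) == 0.0
        truth_params = DetectorParams(delta=100, tau=0.3, rule=495)
        sample = LabeledSample(step_sample.image,
                               apply_detector(step_sample.image, truth_params))
        assert evaluate_fitness(normalize_params(truth_params), [sample]) == 1.0

    def test_batch_mean_and_permutation_invariance(self, rng):
        samples = [
            make_circle_image(PhantomSpec(radius=30, sigma_noise=5.0, seed=s))
            for s in (1, 2, 3)
        ]
        n = normalize_params(DetectorParams(delta=50, tau=0.3, rule=495))
        per = [evaluate_fitness(n, [s]) for s in samples]
        batched = evaluate_fitness(n, samples)
        assert batched == pytest.approx(np.mean(per))
        shuffled = [samples[i] for i in (2, 0, 1)]
        assert evaluate_fitness(n, shuffled) == pytest.approx(batched)

    def test_shape_mismatch_rejected(self, step_sample):
        bad = LabeledSample(step_sample.image, np.zeros((4, 4), np.uint8))
        with pytest.raises(ValueError):
            evaluate_fitness(NormalizedParams(0.5, 0.5, 0.5), [bad])

    def test_prefiltered_fitness_differs_for_pre_post(self, step_sample):
        n = NormalizedParams(0.3, 0.45, 495 / 511)
        plain = evaluate_fitness(n, [step_sample], ScenarioConfig("plain"))
        pre = evaluate_fitness(n, [step_sample], ScenarioConfig("pre_post", 1.5))
        assert plain != pre  # smoothing changes the fitness landscape


class TestOptimization:
    def test_fixed_point_at_known_optimum(self, step_sample):
        truth = apply_detector(step_sample.image, DetectorParams(100, 0.3, 495))
        sample = LabeledSample(step_sample.image, truth)
        opt = normalize_params(DetectorParams(100, 0.3, 495)).as_vector()
        n = 5
        state = SwarmState(
            positions=np.tile(opt, (n, 1)),
            velocities=np.zeros((n, 3)),
            pbest_positions=np.tile(opt, (n, 1)),
            pbest_fitness=np.full(n, -np.inf),
        )
        cfg = SwarmConfig(n_particles=n, epochs_per_unit=5, omega=0.0, seed=1)
        best, fit, _ = optimize_unit([sample], cfg, state=state)
        assert fit == 1.0
        np.testing.assert_allclose(best.as_vector(), opt)

    def test_determinism(self, step_sample):
        a = optimize_unit([step_sample], FAST)
        b = optimize_unit([step_sample], FAST)
        np.testing.assert_array_equal(a[0].as_vector(), b[0].as_vector())
        assert a[1] == b[1]

    def test_gbest_monotone_and_positions_bounded(self, step_sample):
        history = []
        _, _, state = optimize_unit([step_sample], FAST, history=history)
        fits = [row["gbest_fitness"] for row in history]
        assert all(b >= a for a, b in zip(fits, fits[1:]))
        assert np.all(state.positions >= 0.0) and np.all(state.positions <= 1.0)

    def test_dataset_batching_and_history(self, step_sample):
        samples = [step_sample] * 5
        best, history = optimize_dataset(samples, batch_size=2, config=FAST)
        assert isinstance(best, NormalizedParams)
        # ceil(5/2) = 3 units, each logged for init + every epoch
        assert set(history["unit"]) == {0, 1, 2}
        assert len(history) == 3 * (FAST.epochs_per_unit + 1)
        with pytest.raises(ValueError):
            optimize_dataset([], 1, FAST)
        with pytest.raises(ValueError):
            optimize_dataset(samples, 0, FAST)

    def test_single_batch_equals_one_unit(self, step_sample):
        samples = [step_sample] * 3
        best_ds, _ = optimize_dataset(samples, batch_size=3, config=FAST)
        rng = np.random.default_rng(FAST.seed)
        best_unit, _, _ = optimize_unit(samples, FAST, rng=rng)
        np.testing.assert_allclose(best_ds.as_vector(), best_unit.as_vector())
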