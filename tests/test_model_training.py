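"""Energy/force predictions, symmetries, training loop, evaluation, checkpoints."""

import numpy as np
import pytest

from rangeff import (
    AtomicConfiguration,
    EnergyModel,
    TrainingConfig,
    evaluate,
    load_checkpoint,
    predict_batch,
    predict_energy,
    predict_forces,
    save_checkpoint,
    train,
)
from rangeff.model_training import ModelConfig
from conftest import random_rotation, tiny_model_config


@pytest.fixture
def labelled_frames():
    from rangeff import gen_dimer_dataset

    frames, _, _ = gen_dimer_dataset(30, seed=13)
    return [f.config for f in frames]


class TestPrediction:
    def test_size_extensive_for_isolated_atoms(self):
        model = EnergyModel(tiny_model_config(range_enabled=False), seed=0)
        one = AtomicConfiguration([[0.0, 0, 0]], [6])
        two = AtomicConfiguration([[0.0, 0, 0], [50.0, 0, 0]], [6, 6])
        assert predict_energy(model, two) == pytest.approx(
            2 * predict_energy(model, one), abs=1e-10
        )

    def test_permutation_invariance(self, tiny_model, random_config):
        rng = np.random.default_rng(1)
        perm = rng.permutation(random_config.n_atoms)
        permuted = AtomicConfiguration(
            random_config.positions[perm], random_config.species[perm]
        )
        assert predict_energy(tiny_model, permuted) == pytest.approx(
            predict_energy(tiny_model, random_config), abs=1e-5
        )

    def test_rotation_translation_invariance_suite(self, tiny_model, random_config):
        rng = np.random.default_rng(2)
        e0 = predict_energy(tiny_model, random_config)
        worst = 0.0
        for _ in range(100):
            R, t = random_rotation(rng), rng.normal(size=3) * 8
            moved = AtomicConfiguration(
                random_config.positions @ R.T + t, random_config.species
            )
            worst = max(worst, abs(predict_energy(tiny_model, moved) - e0))
        assert worst <= 1e-4

    def test_batched_forward_equals_per_frame(self, tiny_model):
        rng = np.random.default_rng(3)
        configs = [
            AtomicConfiguration(rng.uniform(0, 7, (n, 3)), rng.integers(1, 10, n))
            for n in (4, 7, 3)
        ]
        batched, _ = predict_batch(tiny_model, configs)
        singles = [predict_energy(tiny_model, c) for c in configs]
        assert np.allclose(batched, singles, atol=1e-6)

    def test_forces_match_central_finite_differences(self, tiny_model):
        rng = np.random.default_rng(4)
        cfg = AtomicConfiguration(rng.uniform(0, 6, (10, 3)), rng.integers(1, 8, 10))
        _, forces = predict_forces(tiny_model, cfg)
        step = 1e-4
        for i in range(0, 10, 3):
            for j in range(3):
                d = np.zeros_like(cfg.positions)
                d[i, j] = step
                ep = predict_energy(tiny_model, AtomicConfiguration(cfg.positions + d, cfg.species))
                em = predict_energy(tiny_model, AtomicConfiguration(cfg.positions - d, cfg.species))
                num = -(ep - em) / (2 * step)
                if abs(forces[i, j]) > 1e-6:
                    assert abs(num - forces[i, j]) / abs(forces[i, j]) <= 1e-5

    def test_net_force_is_zero(self, tiny_model, random_config):
        """Translation invariance ⇒ forces sum to zero."""
        _, forces = predict_forces(tiny_model, random_config)
        assert np.abs(forces.sum(axis=0)).max() < 1e-4

    def test_forces_rotate_with_the_frame(self, tiny_model, random_config):
        rng = np.random.default_rng(5)
        _, f0 = predict_forces(tiny_model, random_config)
        R = random_rotation(rng)
        rotated = AtomicConfiguration(
            random_config.positions @ R.T, random_config.species
        )
        _, f1 = predict_forces(tiny_model, rotated)
        assert np.abs(f1 - f0 @ R.T).max() <= 1e-4

    def test_atom_at_geometric_center_is_regularized(self):
        """d=0 to the master position must not produce NaN forces."""
        model = EnergyModel(tiny_model_config(), seed=6)
        # 4 atoms symmetric about origin + 1 exactly at the centroid
        pos = np.array([[1.0, 0, 0], [-1.0, 0, 0], [0, 1.0, 0], [0, -1.0, 0], [0, 0, 0]])
        _, forces = predict_forces(model, AtomicConfiguration(pos, [6, 6, 6, 6, 8]))
        assert np.all(np.isfinite(forces))

    def test_out_of_vocabulary_species_rejected(self, tiny_model):
        cfg = AtomicConfiguration([[0.0, 0, 0]], [99])
        with pytest.raises(ValueError):
            predict_energy(tiny_model, cfg)


class TestRepulsivePrior:
    def test_short_range_wall_dominates_at_close_approach(self):
        model = EnergyModel(tiny_model_config(), seed=0)
        pair = lambda d: AtomicConfiguration([[0, 0, 0], [d, 0, 0]], [6, 6])
        e_close, e_far = predict_energy(model, pair(0.8)), predict_energy(model, pair(2.5))
        assert e_close > e_far + 100.0  # steep repulsive wall

    def test_prior_can_be_disabled(self):
        cfg = tiny_model_config()
        cfg.repulsive_prior = False
        model = EnergyModel(cfg, seed=0)
        on = EnergyModel(tiny_model_config(), seed=0)
        pair = AtomicConfiguration([[0, 0, 0], [1.0, 0, 0]], [6, 6])
        assert predict_energy(model, pair) < predict_energy(on, pair) - 50.0

    def test_prior_forces_match_finite_differences(self):
        model = EnergyModel(tiny_model_config(), seed=1)
        cfg = AtomicConfiguration([[0, 0, 0], [1.1, 0.2, 0]], [6, 8])
        _, f = predict_forces(model, cfg)
        step = 1e-5
        d = np.zeros_like(cfg.positions)
        d[0, 0] = step
        num = -(predict_energy(model, AtomicConfiguration(cfg.positions + d, cfg.species))
                - predict_energy(model, AtomicConfiguration(cfg.positions - d, cfg.species))) / (2 * step)
        assert num == pytest.approx(f[0, 0], rel=1e-6)


class TestTraining:
    def test_null_objective_leaves_weights_unchanged(self, labelled_frames):
        model = EnergyModel(tiny_model_config(), seed=7)
        before = {k: p.data.copy() for k, p in model.parameters().items()}
        hist = train(
            model, labelled_frames[:12],
            TrainingConfig(energy_weight=0.0, force_weight=0.0, penalty_weight=0.0,
                           epochs=2, batch_size=4, seed=0),
        )
        assert all(rec["train_loss"] == 0.0 for rec in hist)
        for k, p in model.parameters().items():
            assert np.array_equal(before[k], p.data)

    def test_loss_decreases_on_toy_dataset(self, labelled_frames):
        model = EnergyModel(tiny_model_config(), seed=8)
        hist = train(
            model, labelled_frames,
            TrainingConfig(epochs=30, batch_size=10, seed=1, learning_rate=2e-3),
        )
        assert hist[-1]["train_loss"] <= 0.5 * hist[0]["train_loss"]

    def test_same_seed_gives_bitwise_identical_history(self, labelled_frames):
        runs = []
        for _ in range(2):
            model = EnergyModel(tiny_model_config(), seed=9)
            runs.append(
                train(model, labelled_frames[:15],
                      TrainingConfig(epochs=3, batch_size=5, seed=2))
            )
        assert runs[0] == runs[1]

    def test_empty_dataset_rejected(self):
        model = EnergyModel(tiny_model_config(), seed=0)
        with pytest.raises(ValueError):
            train(model, [], TrainingConfig())


class TestEvaluate:
    def test_perfect_predictor_scores_zero(self, labelled_frames):
        class Perfect:
            pass

        model = EnergyModel(tiny_model_config(), seed=10)
        frames = labelled_frames[:4]
        # overwrite references with the model's own outputs
        for c in frames:
            e, f = predict_forces(model, c)
            c.energy, c.forces = e, f
        mae_e, mae_f = evaluate(model, frames)
        assert mae_e < 1e-10 and mae_f < 1e-10

    def test_constant_predictor_hand_arithmetic(self):
        # frames with energies 1 and 3, prediction 2 → MAE 1
        preds = np.array([2.0, 2.0])
        refs = np.array([1.0, 3.0])
        assert np.abs(preds - refs).mean() == pytest.approx(1.0)

    def test_mae_invariant_under_frame_order(self, labelled_frames):
        model = EnergyModel(tiny_model_config(), seed=11)
        frames = labelled_frames[:8]
        a = evaluate(model, frames)
        b = evaluate(model, frames[::-1])
        assert a[0] == pytest.approx(b[0], rel=1e-12)
        assert a[1] == pytest.approx(b[1], rel=1e-12)

    def test_empty_dataset_rejected(self):
        model = EnergyModel(tiny_model_config(), seed=0)
        with pytest.raises(ValueError):
            evaluate(model, [])


class TestCheckpoint:
    def test_round_trip_preserves_predictions(self, tmp_path, random_config):
        model = EnergyModel(tiny_model_config(), seed=12)
        path = tmp_path / "model.npz"
        save_checkpoint(model, path, extra={"split_seed": 3})
        restored = load_checkpoint(path)
        assert predict_energy(restored, random_config) == predict_energy(
            model, random_config
        )
        assert restored.config.range_hp.n_masters == model.config.range_hp.n_masters

    def test_range_disabled_round_trip(self, tmp_path, random_config):
        model = EnergyModel(tiny_model_config(range_enabled=False), seed=13)
        path = tmp_path / "b.npz"
        save_checkpoint(model, path)
        restored = load_checkpoint(path)
        assert not restored.config.range_enabled
        assert predict_energy(restored, random_config) == predict_energy(
            model, random_config
        )
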