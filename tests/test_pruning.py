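"""Slot statistics, variance pruning, and integrated-gradients attribution."""

import numpy as np
import pytest

import kinetransfer as kt
from kinetransfer.ann import NeuralCorrector
from kinetransfer.embedding import embed
from kinetransfer.pruning import (feature_weights, integrated_gradients,
                                  prune_loop, slot_statistics)
from kinetransfer.training import TrainingConfig, fit


class TestSlotStatistics:
    def test_constant_output_has_zero_variance(self, trained_fit):
        import dataclasses

        doctored = dataclasses.replace(
            trained_fit, phi_hat=np.full_like(trained_fit.phi_hat, 0.7))
        stats = slot_statistics(doctored)
        assert np.allclose(stats.mean, 0.7)
        assert np.allclose(stats.variance, 0.0)

    def test_two_point_binary_output(self, trained_fit):
        import dataclasses

        phi = np.zeros((1, 2, len(trained_fit.slot_indices)))
        phi[0, 1, :] = 1.0
        stats = slot_statistics(dataclasses.replace(trained_fit, phi_hat=phi))
        assert np.allclose(stats.mean, 0.5)
        assert np.allclose(stats.variance, 0.25)  # population variance

    def test_matches_brute_force_two_pass(self, trained_fit):
        stats = slot_statistics(trained_fit)
        flat = trained_fit.phi_hat.reshape(-1, len(trained_fit.slot_indices))
        for j in range(flat.shape[1]):
            mean = sum(flat[:, j]) / len(flat)
            var = sum((v - mean) ** 2 for v in flat[:, j]) / len(flat)
            assert stats.mean[j] == pytest.approx(mean)
            assert stats.variance[j] == pytest.approx(var)


class TestPruneLoop:
    def test_respects_umax_and_never_reactivates(self, source, target_dataset,
                                                 quick_config):
        skeleton = embed(source, Dmax=3)
        for slot in list(skeleton.slots)[6:]:
            skeleton.deactivate(slot.index)
        pruned, result, trail = prune_loop(skeleton, target_dataset,
                                           quick_config, Umax=3, Vmin=0.0)
        assert pruned.n_active <= 3
        deactivated = [t.slot_index for t in trail if t.action.startswith("pruned")]
        assert len(deactivated) == len(set(deactivated))  # one-way pruning
        active = {s.index for s in pruned.active_slots}
        assert active.isdisjoint(deactivated)

    def test_baseline_generated_data_prunes_slot_by_vmin(self, target):
        """A slot whose data were generated with the correction at baseline
        carries no signal and is removed by the variance threshold."""
        ds = kt.generate_dataset(target, 3, noise_sd=0.0, seed=6)
        skeleton = embed(target, Dmax=3)
        keep = [s.index for s in skeleton.slots][:1]
        for slot in list(skeleton.slots):
            if slot.index not in keep:
                skeleton.deactivate(slot.index)
        cfg = TrainingConfig(seed=0, epochs=120)
        pruned, _, trail = prune_loop(skeleton, ds, cfg, Umax=3, Vmin=0.1)
        assert pruned.n_active == 0
        assert any(t.action == "pruned-vmin" for t in trail)

    def test_planted_correction_beats_decoy(self, source, target):
        """Data from the ground truth against the source skeleton restricted
        to the true decay slot and one decoy: the decoy must be the less
        variable of the two in most seeded runs."""
        wins = 0
        for seed in range(4):
            ds = kt.generate_dataset(target, 3, seed=300 + seed)
            skeleton = embed(source, Dmax=3)
            for slot in list(skeleton.slots):
                if slot.index not in (7, 11):  # decay slot + decoy
                    skeleton.deactivate(slot.index)
            cfg = TrainingConfig(seed=seed, epochs=500)
            result = fit(skeleton, ds, cfg)
            stats = slot_statistics(result)
            v = dict(zip(stats.slot_indices, stats.variance))
            wins += v[7] > v[11]
        assert wins >= 3

    def test_invalid_arguments(self, source, target_dataset, quick_config):
        skeleton = embed(source, Dmax=3)
        with pytest.raises(ValueError):
            prune_loop(skeleton, target_dataset, quick_config, Umax=0)
        with pytest.raises(ValueError):
            prune_loop(skeleton, target_dataset, quick_config, Vmin=-1.0)


class TestIntegratedGradients:
    def _linear_corrector(self, A, b):
        """A corrector that is exactly linear: tiny weights keep tanh in its
        linear regime, compensated by a large output gain."""
        eps = 1e-4
        H, V = A.shape[0], A.shape[1]
        ann = NeuralCorrector(W1=np.eye(V) * eps, b1=np.zeros(V),
                              W2=A.T / eps if False else A / eps,
                              b2=b * 0, gains=np.ones(A.shape[0]))
        return ann

    def test_linear_map_closed_form_for_any_steps(self):
        rng = np.random.default_rng(2)
        A = rng.normal(size=(2, 3))
        eps = 1e-5
        ann = NeuralCorrector(W1=np.eye(3) * eps, b1=np.zeros(3),
                              W2=A / eps, b2=np.zeros(2), gains=np.ones(2))
        x = rng.normal(size=(6, 3))
        baseline = np.zeros(3)
        for steps in (2, 8, 64):
            attr = integrated_gradients(ann, x, baseline, steps=steps)
            expected = A[None, :, :] * (x - baseline)[:, None, :]
            assert np.allclose(attr, expected, atol=1e-6)

    def test_completeness_at_256_steps(self, trained_fit):
        ann = trained_fit.ann
        points = trained_fit.traj_norm.reshape(-1, 3)
        baseline = points.mean(axis=0)
        attr = integrated_gradients(ann, points, baseline, steps=256)
        sums = attr.sum(axis=-1)
        expected = ann.forward(points) - ann.forward(baseline)
        assert np.max(np.abs(sums - expected)) <= 1e-3

    def test_ignored_feature_gets_exactly_zero(self):
        rng = np.random.default_rng(4)
        ann = NeuralCorrector.initialize(3, np.zeros(2), rng)
        ann.W1[:, 2] = 0.0  # no incoming weight from the third feature
        x = rng.uniform(-1, 1, size=(10, 3))
        attr = integrated_gradients(ann, x, np.zeros(3), steps=16)
        assert np.all(attr[:, :, 2] == 0.0)

    def test_too_few_steps_rejected(self, trained_fit):
        with pytest.raises(ValueError):
            integrated_gradients(trained_fit.ann, np.zeros((1, 3)), steps=1)


class TestFeatureWeights:
    def test_single_feature_dependence(self):
        attr = np.zeros((20, 2, 3))
        attr[:, :, 0] = np.random.default_rng(0).normal(size=(20, 2))
        w = feature_weights(attr, (1, 2), ("X", "S", "P"))
        assert np.allclose(w.pi[:, 0], 1.0)
        assert np.allclose(w.pi[:, 1:], 0.0)
        assert w.allowed_features(1) == ["X"]

    def test_symmetric_dependence_splits_evenly(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=(50, 1))
        attr = np.concatenate([vals, vals, np.zeros((50, 1))],
                              axis=1)[:, None, :]
        w = feature_weights(attr, (1,), ("X", "S", "P"))
        assert w.pi[0, 0] == pytest.approx(0.5)
        assert w.pi[0, 1] == pytest.approx(0.5)
        assert w.pi[0, 2] == 0.0
        assert w.excluded[0, 2]

    def test_all_zero_attributions_fall_back_to_uniform(self):
        with pytest.warns(UserWarning, match="uniform"):
            w = feature_weights(np.zeros((5, 1, 3)), (1,), ("X", "S", "P"))
        assert np.allclose(w.pi, 1 / 3)

    def test_rows_sum_to_one(self, trained_fit):
        points = trained_fit.traj_norm.reshape(-1, 3)
        attr = integrated_gradients(trained_fit.ann, points, steps=32)
        w = feature_weights(attr, trained_fit.slot_indices, ("X", "S", "P"))
        assert np.allclose(w.pi.sum(axis=1), 1.0)
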