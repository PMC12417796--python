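"""Hybrid training: objective decomposition, penalty, determinism."""

import numpy as np
import pytest

import kinetransfer as kt
from kinetransfer.ann import NeuralCorrector
from kinetransfer.embedding import baseline_vector, embed
from kinetransfer.training import (CompiledSkeleton, Normalization,
                                   TrainingConfig, fit, gi_regularizer,
                                   objective, _loss_terms)


@pytest.fixture(scope="module")
def setup(source, target_dataset):
    skeleton = embed(source, Dmax=3)
    norm = Normalization.from_dataset(target_dataset)
    rng = np.random.default_rng(3)
    ann = NeuralCorrector.initialize(3, baseline_vector(skeleton), rng)
    theta = dict(source.parameters)
    return skeleton, norm, ann, theta


class TestObjective:
    def test_penalty_zero_at_exact_baseline(self, setup, target_dataset):
        """A corrector emitting exactly b has zero deviation and zero
        Jacobian, so the whole penalty vanishes."""
        skeleton, norm, ann, theta = setup
        const = ann.copy()
        const.W1[...] = 0.0
        const.W2[...] = 0.0
        const.b2[...] = baseline_vector(skeleton) / const.gains
        cfg = TrainingConfig(lam1=0.5, lam2=0.5)
        total, mse, penalty = objective(skeleton, theta, const,
                                        target_dataset, cfg, norm)
        assert penalty == pytest.approx(0.0, abs=1e-15)
        assert total == pytest.approx(mse)

    def test_self_consistent_data_gives_zero_mse(self, source):
        """Data generated by the skeleton's own trajectories is fitted with
        zero residual (integrator self-consistency)."""
        skeleton = embed(source, Dmax=3)
        for slot in list(skeleton.slots):
            skeleton.deactivate(slot.index)
        times = kt.default_sample_times()
        y0 = np.array([0.2, 8.0, 0.0])
        traj = kt.simulate(source, y0, times)
        ds = kt.ExperimentDataset(source.state_names,
                                  [kt.Experiment(y0, times, traj)], 0.0, 0)
        norm = Normalization.from_dataset(ds)
        ann = NeuralCorrector.initialize(3, np.array([]),
                                         np.random.default_rng(0))
        cfg = TrainingConfig(steps_per_interval=8)
        total, mse, penalty = objective(skeleton, source.parameters, ann,
                                        ds, cfg, norm)
        assert penalty == 0.0
        assert mse < 1e-6  # fixed-step integration error only

    def test_jacobian_penalty_matches_finite_differences(self, setup):
        """The penalty's Jacobian component equals central finite
        differences of φ̂ with respect to ŷ, summed over squares."""
        skeleton, norm, ann, theta = setup
        rng = np.random.default_rng(8)
        x = rng.uniform(0.1, 1.0, size=(20, 3))
        eps = 1e-5
        fd_sq = 0.0
        for n in range(x.shape[0]):
            for v in range(3):
                xp, xm = x[n].copy(), x[n].copy()
                xp[v] += eps
                xm[v] -= eps
                dphi = (ann.forward(xp) - ann.forward(xm)) / (2 * eps)
                fd_sq += float(np.sum(dphi ** 2))
        fd_mean = fd_sq / x.shape[0]
        assert ann.jacobian_penalty(x) == pytest.approx(fd_mean, rel=1e-4)


class TestFit:
    def test_strong_anchor_pins_corrections_to_baseline(self, source,
                                                        target_dataset):
        """In the λ2 → large limit every correction trajectory collapses
        onto the baseline vector."""
        skeleton = embed(source, Dmax=3)
        cfg = TrainingConfig(seed=0, epochs=300, lam1=0.0, lam2=1e4,
                             additive_gain=1.0)
        result = fit(skeleton, target_dataset, cfg)
        b = baseline_vector(skeleton)
        assert np.all(np.abs(result.phi_hat - b) < 1e-2)

    def test_seeded_determinism(self, source, target_dataset):
        cfg = TrainingConfig(seed=5, epochs=60)
        skeleton = embed(source, Dmax=3)
        r1 = fit(skeleton, target_dataset, cfg)
        r2 = fit(skeleton, target_dataset, cfg)
        assert np.array_equal(r1.loss_trace, r2.loss_trace)
        assert r1.theta == r2.theta

    def test_loss_decreases_from_start(self, trained_fit):
        trace = trained_fit.loss_trace
        assert trace[-1] < trace[0]
        assert trained_fit.total == pytest.approx(
            trained_fit.mse + trained_fit.penalty, rel=1e-9)

    def test_zero_slot_fit_is_plain_least_squares(self, target,
                                                  noise_free_dense):
        """With all slots off the penalty is identically zero and the fit
        reduces to parameter estimation of the base model."""
        skeleton = embed(target, Dmax=3)
        for slot in list(skeleton.slots):
            skeleton.deactivate(slot.index)
        cfg = TrainingConfig(seed=1, epochs=200)
        result = fit(skeleton, noise_free_dense, cfg)
        assert result.penalty == 0.0
        assert result.phi_hat.shape[-1] == 0

    def test_empty_dataset_rejected(self, source):
        skeleton = embed(source, Dmax=3)
        empty = kt.ExperimentDataset(source.state_names, [], 0.0, 0)
        with pytest.raises(ValueError):
            fit(skeleton, empty, TrainingConfig(epochs=1))


class TestGiRegularizer:
    def test_zero_for_zero_corrections_or_zero_weight(self, source):
        skeleton = embed(source, Dmax=3)
        phi = np.zeros((2, 4, skeleton.n_active))
        assert gi_regularizer(skeleton, phi, weight=2.0) == 0.0
        phi = np.random.default_rng(0).normal(size=(2, 4, skeleton.n_active))
        assert gi_regularizer(skeleton, phi, weight=0.0) == 0.0

    def test_matches_hand_computed_mean_square(self, source):
        skeleton = embed(source, Dmax=3)
        gi_mask = np.array([s.growth_independent for s in skeleton.active_slots])
        rng = np.random.default_rng(1)
        phi = rng.normal(size=(3, 2, skeleton.n_active))
        expected = 0.7 * np.mean(np.sum(phi[..., gi_mask] ** 2, axis=-1))
        assert gi_regularizer(skeleton, phi, weight=0.7) == \
            pytest.approx(expected)
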