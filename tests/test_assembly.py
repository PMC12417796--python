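"""Substitution, fine-tuning, and pass orchestration."""

import numpy as np
import pytest

import kinetransfer as kt
from kinetransfer.assembly import (FinetuneConfig, PipelineConfig,
                                   finetune, run_pass,
                                   substitute_and_simplify)
from kinetransfer.embedding import embed
from kinetransfer.expressions import parse_equation
from kinetransfer.models import loads_model, structural_match
from kinetransfer.simulate import generate_dataset
from kinetransfer.sr import SRConfig
from kinetransfer.training import Normalization, TrainingConfig


@pytest.fixture(scope="module")
def norm(target):
    ds = generate_dataset(target, 5, noise_sd=0.0, seed=42)
    return Normalization.from_dataset(ds), ds


class TestSubstitution:
    def test_identity_substitution_restores_base_model(self, source, norm, rng):
        norm_, _ = norm
        skeleton = embed(source, Dmax=3)
        model = substitute_and_simplify(skeleton, {}, norm_)
        assert structural_match(model, source).matched
        for _ in range(20):
            state = rng.uniform(0.05, 6.0, size=3)
            assert np.allclose(model.evaluate(state), source.evaluate(state),
                               rtol=1e-6)

    def test_canonical_corrections_reconstruct_ground_truth(self, source,
                                                            target, norm):
        """Substituting the three canonical corrections (Contois factor,
        biomass decay, product reversal) into the Monod source yields the
        ground-truth structure."""
        norm_, _ = norm
        Xmax, Smax, Pmax = norm_.y_max
        T = norm_.t_max
        skeleton = embed(source, Dmax=3)
        for slot in list(skeleton.slots):
            if slot.index not in (3, 7, 12):
                skeleton.deactivate(slot.index)
        # expressions are functions of normalized states; constants map the
        # physical corrections X, -mu_d X, -k_d X^2 onto that scale
        exprs = {
            3: parse_equation(f"{float(Xmax)}*X", ["X", "S", "P"], []),
            7: parse_equation(f"0-{float(0.1 * T)}*X", ["X", "S", "P"], []),
            12: parse_equation(f"0-{float(0.07 * Xmax**2 * T / Pmax)}*X*X",
                               ["X", "S", "P"], []),
        }
        model = substitute_and_simplify(skeleton, exprs, norm_,
                                        source.parameters)
        assert structural_match(model, target).matched

    def test_substitution_matches_slotted_evaluation(self, source, norm, rng):
        """Evaluating the substituted model equals evaluating the skeleton
        with the slot outputs replaced by the expressions."""
        norm_, _ = norm
        skeleton = embed(source, Dmax=3)
        for slot in list(skeleton.slots):
            if slot.index not in (6, 7):
                skeleton.deactivate(slot.index)
        exprs = {6: parse_equation("1+0.3*X", ["X", "S", "P"], []),
                 7: parse_equation("0-0.5*S", ["X", "S", "P"], [])}
        model = substitute_and_simplify(skeleton, exprs, norm_,
                                        source.parameters)
        scales = skeleton.slot_scales(norm_.y_max, norm_.t_max)
        scale_by_index = dict(zip((s.index for s in skeleton.active_slots),
                                  scales))
        for _ in range(100):
            state = rng.uniform(0.05, 6.0, size=3)
            xn = state / norm_.y_max
            # slot outputs: multiplicative as-is, additive times its scale
            phi = {6: 1 + 0.3 * xn[0],
                   7: -0.5 * xn[1] * scale_by_index[7]}
            expected = skeleton.evaluate(state, phi)
            assert np.allclose(model.evaluate(state), expected,
                               rtol=1e-6, atol=1e-9)


class TestFinetune:
    def test_ground_truth_recovery_from_noise_free_data(self, target,
                                                        noise_free_dense):
        """Refitting the true structure from perturbed starting values on
        noise-free data recovers every rate constant within 1%."""
        perturbed = target.copy()
        rng = np.random.default_rng(3)
        perturbed.parameters = {k: v * float(1 + 0.3 * rng.standard_normal())
                                for k, v in target.parameters.items()}
        theta, tuned = finetune(perturbed, noise_free_dense,
                                FinetuneConfig(sparsity_weight=0.0,
                                               drop_threshold=0.0,
                                               steps_per_interval=8))
        for name, true_value in kt.TARGET_PARAMS.items():
            assert theta[name] == pytest.approx(true_value, rel=0.01)

    def test_spurious_additive_term_removed(self, target):
        """A planted additive c*S term with true coefficient zero is dropped
        by the sparsity-promoting refit in most seeded runs."""
        removed = 0
        for seed in range(5):
            ds = generate_dataset(target, 3, seed=400 + seed)
            wrong = loads_model("""
param mu_m = 0.1
param K_S  = 5.0
param mu_d = 0.1
param Y_S  = 1.0
param Y_P  = 0.5
param beta = 0.05
param k_d  = 0.07
param c1   = 0.02
rate mu = mu_m*S/(S + K_S*X)
dX/dt = mu*X - mu_d*X
dS/dt = -Y_S*mu*X
dP/dt = Y_P*mu*X + beta*X - k_d*X*X + c1*S
""")
            theta, tuned = finetune(wrong, ds, FinetuneConfig(max_nfev=200))
            if "c1" not in tuned.parameters:
                removed += 1
        assert removed >= 4

    def test_no_sparsity_no_threshold_keeps_all_parameters(self, target):
        ds = generate_dataset(target, 2, seed=5)
        theta, tuned = finetune(target.copy(), ds,
                                FinetuneConfig(sparsity_weight=0.0,
                                               drop_threshold=0.0))
        assert set(tuned.parameters) == set(target.parameters)


class TestRunPass:
    def test_self_transfer_prunes_everything(self, target):
        """With the ground truth as its own source, every correction is
        removed by the variance threshold and the model is unchanged."""
        ds = generate_dataset(target, 3, seed=21)
        cfg = PipelineConfig(
            training=TrainingConfig(seed=0, epochs=300, refit_epochs=100),
            sr=SRConfig(population=100, generations=10, seed=0))
        rec = run_pass(target, ds, cfg)
        assert rec.converged
        assert rec.survivors == ()
        assert structural_match(rec.model, target).matched
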