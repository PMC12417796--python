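"""Hunter–Reiner discrimination objective and experiment design."""

import itertools

import numpy as np
import pytest

import kinetransfer as kt
from kinetransfer.design import (CandidateSet, DesignSpec, design_experiment,
                                 hunter_reiner_objective)
from kinetransfer.models import loads_model
from kinetransfer.simulate import default_sample_times, simulate


@pytest.fixture(scope="module")
def pair(source, target):
    return CandidateSet([source, target], [{}, {}])


class TestObjective:
    def test_identical_candidates_give_zero(self, source):
        cs = CandidateSet([source, source.copy()], [{}, {}])
        for z in ([0.2, 5.0], [0.5, 10.0], [0.1, 1.0]):
            assert hunter_reiner_objective(cs, np.array(z)) == \
                pytest.approx(0.0, abs=1e-12)

    def test_two_candidates_match_direct_pair_sum(self, pair):
        """For nm = 2 the objective equals the directly-summed squared
        trajectory difference (brute-force oracle)."""
        spec = DesignSpec()
        z = np.array([0.3, 7.0])
        J = hunter_reiner_objective(pair, z, spec)
        times = default_sample_times()
        y0 = np.array([z[0], z[1], 0.0])
        ta = simulate(pair.models[0], y0, times)
        tb = simulate(pair.models[1], y0, times)
        y_max = np.maximum(np.maximum(ta.max(axis=0), tb.max(axis=0)), 1e-9)
        expected = float(np.sum(((ta - tb) / y_max) ** 2))
        assert J == pytest.approx(expected, rel=1e-9)

    def test_doubling_sigma_halves_J(self, pair):
        z = np.array([0.3, 7.0])
        y_max = np.ones(3)
        J1 = hunter_reiner_objective(pair, z, DesignSpec(sigma2=1.0), y_max)
        J2 = hunter_reiner_objective(pair, z, DesignSpec(sigma2=2.0), y_max)
        assert J2 == pytest.approx(J1 / 2)

    def test_candidate_relabeling_leaves_J_unchanged(self, source, target,
                                                     low_prior):
        models = [source, target, low_prior]
        z = np.array([0.25, 6.0])
        y_max = np.ones(3)
        J0 = hunter_reiner_objective(CandidateSet(models, [{}] * 3), z,
                                     y_max=y_max)
        for perm in itertools.permutations(models):
            J = hunter_reiner_objective(CandidateSet(list(perm), [{}] * 3),
                                        z, y_max=y_max)
            assert J == pytest.approx(J0, rel=1e-12)
        assert J0 >= 0.0

    def test_single_candidate_rejected(self, source):
        with pytest.raises(ValueError):
            hunter_reiner_objective(CandidateSet([source], [{}]),
                                    np.array([0.2, 5.0]))


class TestDesignExperiment:
    def test_identical_candidates_warn_and_return_center(self, source):
        cs = CandidateSet([source, source.copy()], [{}, {}])
        with pytest.warns(UserWarning, match="indistinguishable"):
            z, J = design_experiment(cs, seed=1)
        spec = DesignSpec()
        lo = [spec.y0_ranges[s][0] for s in spec.design_states]
        hi = [spec.y0_ranges[s][1] for s in spec.design_states]
        assert np.allclose(z, (np.array(lo) + np.array(hi)) / 2)
        assert J == 0.0

    def test_substrate_sensitive_pair_designs_to_boundary(self):
        """Two models differing only in a substrate-saturation constant are
        most distinguishable at extreme substrate loading."""
        a = loads_model("param mu_m = 0.1\nparam K_S = 2.0\n"
                        "rate mu = mu_m*S/(S+K_S)\ndX/dt = mu*X\n"
                        "dS/dt = -mu*X\ndP/dt = 0.1*mu*X\n")
        b = loads_model("param mu_m = 0.1\nparam K_S = 8.0\n"
                        "rate mu = mu_m*S/(S+K_S)\ndX/dt = mu*X\n"
                        "dS/dt = -mu*X\ndP/dt = 0.1*mu*X\n")
        cs = CandidateSet([a, b], [{}, {}])
        z, J = design_experiment(cs, seed=2)
        assert J > 0
        # verify against a coarse audit grid: no grid point beats z*
        spec = DesignSpec()
        xs = np.linspace(0.1, 0.5, 7)
        ss = np.linspace(1.0, 10.0, 7)
        grid_best = max(hunter_reiner_objective(cs, np.array([x, s]), spec)
                        for x in xs for s in ss)
        assert J >= grid_best * (1 - 1e-6)

    def test_design_beats_audit_grid(self, pair):
        z, J = design_experiment(pair, seed=3)
        spec = DesignSpec()
        xs = np.linspace(0.1, 0.5, 7)
        ss = np.linspace(1.0, 10.0, 7)
        for x in xs:
            for s in ss:
                assert J >= hunter_reiner_objective(
                    pair, np.array([x, s]), spec) * (1 - 1e-6)


class TestEnumerateCandidates:
    def test_cartesian_product_with_dedup(self, source, target_dataset):
        """Three slots with two alternatives each give at most 8 candidates;
        structurally identical combinations are merged."""
        from kinetransfer.embedding import embed
        from kinetransfer.expressions import parse_equation
        from kinetransfer.sr import FrontEntry, ParetoFront
        from kinetransfer.training import Normalization
        from kinetransfer.design import enumerate_candidates

        skeleton = embed(source, Dmax=3)
        for slot in list(skeleton.slots):
            if slot.index not in (6, 7, 12):
                skeleton.deactivate(slot.index)
        norm = Normalization.from_dataset(target_dataset)

        def entry(text, c, loss, score):
            e = FrontEntry(parse_equation(text, ["X", "S", "P"], []), c, loss)
            e.score = score
            return e

        fronts = {
            6: ParetoFront([entry("1.0", 1, 0.1, 1.0),
                            entry("X", 1, 0.05, 0.9)]),
            7: ParetoFront([entry("0-X", 3, 0.01, 1.0),
                            entry("0-X*X", 5, 0.02, 0.5)]),
            12: ParetoFront([entry("0-S", 3, 0.01, 1.0),
                             entry("0-S*X", 5, 0.02, 0.4)]),
        }
        from kinetransfer.assembly import FinetuneConfig

        cfg = FinetuneConfig(sparsity_weight=0.0, drop_threshold=0.0,
                             max_nfev=60)
        cs = enumerate_candidates(skeleton, fronts, norm,
                                  dict(source.parameters), target_dataset,
                                  top=2, finetune_config=cfg)
        assert 2 <= cs.nm <= 8
        # pairwise structural distinctness after dedup
        from kinetransfer.models import structural_match

        for i in range(cs.nm):
            for j in range(i + 1, cs.nm):
                assert not structural_match(cs.models[i], cs.models[j]).matched

    def test_single_slot_single_alternative(self, source, target_dataset):
        from kinetransfer.embedding import embed
        from kinetransfer.expressions import parse_equation
        from kinetransfer.sr import FrontEntry, ParetoFront
        from kinetransfer.training import Normalization
        from kinetransfer.design import enumerate_candidates

        skeleton = embed(source, Dmax=3)
        for slot in list(skeleton.slots):
            if slot.index != 7:
                skeleton.deactivate(slot.index)
        norm = Normalization.from_dataset(target_dataset)
        e = FrontEntry(parse_equation("0-X", ["X", "S", "P"], []), 3, 0.01)
        cs = enumerate_candidates(skeleton, {7: ParetoFront([e])}, norm,
                                  dict(source.parameters), target_dataset,
                                  top=2)
        assert cs.nm == 1
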