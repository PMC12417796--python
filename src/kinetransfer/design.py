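"""Model-based design of experiments for structure discrimination.

Several candidate structures can explain a small noisy dataset equally
well.  The generalized Hunter–Reiner criterion scores an initial condition
z = (X0, S0) by the disagreement it induces among the candidates'
predictions,

    J(z) = Σ_i Σ_{m<n} ‖ŷ_i^m − ŷ_i^n‖² / σ²(z),

summed over sample times and unordered candidate pairs on normalized states
(σ² = 1 by default).  The designed experiment z* = argmax J(z) over the
initial-condition box is found by multistart local search from a
Latin-hypercube start set.  The outer loop alternates structure adaptation
on the cumulative data, candidate enumeration from the per-slot Pareto
fronts (top-2 expressions each, combinatorially substituted and
fine-tuned), experiment design, and simulated execution of the designed
batch against a ground-truth oracle, until the budget is exhausted or the
discovered structure stops changing.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.stats import qmc

from . import casestudy
from .assembly import (FinetuneConfig, PassRecord, PipelineConfig,
                       SubstitutionError, finetune, multi_pass, run_pass,
                       substitute_and_simplify)
from .models import KineticModel, structural_match
from .simulate import (Experiment, ExperimentDataset, SimulationError,
                       default_sample_times, generate_dataset, mape, simulate)
from .sr import ParetoFront, select_top
from .training import Normalization

__all__ = ["DesignSpec", "CandidateSet", "MbdoeIteration", "MbdoeState",
           "enumerate_candidates", "hunter_reiner_objective",
           "design_experiment", "mbdoe_loop"]


@dataclass
class DesignSpec:
    """Design box and schedule for new experiments."""

    y0_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(casestudy.Y0_RANGES))
    horizon: float = casestudy.HORIZON_H
    interval: float = casestudy.SAMPLE_INTERVAL_H
    sigma2: float = 1.0
    n_starts: int = 16

    @property
    def design_states(self) -> list[str]:
        """States with a nondegenerate range (the free design variables)."""
        return [s for s, (lo, hi) in self.y0_ranges.items() if hi > lo]


@dataclass
class CandidateSet:
    """Enumerated candidate transfer models with their slot provenance."""

    models: list[KineticModel]
    provenance: list[dict[int, str]]  # per model: slot index -> expression text

    @property
    def nm(self) -> int:
        return len(self.models)


def enumerate_candidates(skeleton, fronts: dict[int, ParetoFront],
                         norm: Normalization, theta: dict[str, float],
                         dataset: ExperimentDataset,
                         top: int = 2,
                         finetune_config: FinetuneConfig | None = None
                         ) -> CandidateSet:
    """Cartesian product of per-slot top-k expressions, fine-tuned and
    deduplicated by structural equivalence.

    Candidate fine-tuning runs with the sparsity penalty off: discrimination
    should compare structures at their best fit, not their sparsest.
    """
    finetune_config = finetune_config or FinetuneConfig(sparsity_weight=0.0,
                                                        drop_threshold=0.0)
    slots = sorted(fronts)
    per_slot = []
    for j in slots:
        entries = select_top(fronts[j], top)
        per_slot.append([(e.text, e.expression) for e in entries])

    models: list[KineticModel] = []
    provenance: list[dict[int, str]] = []
    for combo in itertools.product(*per_slot):
        exprs = {j: expr for j, (_, expr) in zip(slots, combo)}
        try:
            candidate = substitute_and_simplify(skeleton, exprs, norm, theta)
            new_names = set(candidate.parameters) - set(theta)
            _, tuned = finetune(candidate, dataset, finetune_config,
                                new_params=new_names)
        except (SubstitutionError, SimulationError):
            continue
        if any(structural_match(tuned, m).matched for m in models):
            continue  # structurally duplicate combination
        models.append(tuned)
        provenance.append({j: text for j, (text, _) in zip(slots, combo)})
    return CandidateSet(models, provenance)


def hunter_reiner_objective(candidates: CandidateSet | list[KineticModel],
                            z: np.ndarray, spec: DesignSpec | None = None,
                            y_max: np.ndarray | None = None) -> float:
    """Discrimination objective J(z) ≥ 0 at one design point.

    ``z`` holds the free initial concentrations in the order of
    ``spec.design_states``; fixed states start at their range value.  A
    candidate whose simulation fails contributes nothing to J (such designs
    score poorly and are avoided).
    """
    spec = spec or DesignSpec()
    models = candidates.models if isinstance(candidates, CandidateSet) else candidates
    if len(models) < 2:
        raise ValueError("need at least two candidate models")
    state_names = models[0].state_names
    free = spec.design_states
    y0 = np.array([spec.y0_ranges[s][0] for s in state_names])
    for value, name in zip(np.atleast_1d(z), free):
        y0[state_names.index(name)] = value
    times = default_sample_times(spec.horizon, spec.interval)

    trajs = []
    for m in models:
        try:
            trajs.append(simulate(m, y0, times))
        except SimulationError:
            trajs.append(None)
    if y_max is None:
        finite = [t for t in trajs if t is not None]
        if not finite:
            return 0.0
        y_max = np.maximum(np.max([t.max(axis=0) for t in finite], axis=0), 1e-9)

    J = 0.0
    for a, b in itertools.combinations(range(len(models)), 2):
        if trajs[a] is None or trajs[b] is None:
            continue
        diff = (trajs[a] - trajs[b]) / y_max
        J += float(np.sum(diff * diff))
    return J / spec.sigma2


def design_experiment(candidates: CandidateSet | list[KineticModel],
                      spec: DesignSpec | None = None,
                      y_max: np.ndarray | None = None,
                      seed: int = 0) -> tuple[np.ndarray, float]:
    """Maximize J over the design box: Latin-hypercube multistart plus
    Nelder–Mead refinement of the best starts.

    Returns (z*, J(z*)); with indistinguishable candidates (flat J ≡ 0) the
    center of the box is returned with a warning.
    """
    spec = spec or DesignSpec()
    free = spec.design_states
    lo = np.array([spec.y0_ranges[s][0] for s in free])
    hi = np.array([spec.y0_ranges[s][1] for s in free])

    sampler = qmc.LatinHypercube(d=len(free), seed=seed)
    starts = lo + sampler.random(spec.n_starts) * (hi - lo)

    def neg_J(z):
        zc = np.clip(z, lo, hi)
        return -hunter_reiner_objective(candidates, zc, spec, y_max)

    values = np.array([neg_J(z) for z in starts])
    if np.allclose(values, 0.0):
        import warnings

        warnings.warn("flat discrimination objective: candidates are "
                      "indistinguishable over the design box")
        return (lo + hi) / 2, 0.0

    best_z, best_v = None, np.inf
    for i in np.argsort(values)[:3]:
        res = minimize(neg_J, starts[i], method="Nelder-Mead",
                       bounds=list(zip(lo, hi)),
                       options={"maxfev": 60, "xatol": 1e-3, "fatol": 1e-6})
        if res.fun < best_v:
            best_v, best_z = res.fun, np.clip(res.x, lo, hi)
    return best_z, -best_v


@dataclass
class MbdoeIteration:
    iteration: int
    n_candidates: int
    z_star: np.ndarray | None
    J_star: float | None
    model: KineticModel
    fit_mape: float
    prediction_mape: float | None = None


@dataclass
class MbdoeState:
    """Trail of one sequential model-discrimination campaign."""

    iterations: list[MbdoeIteration]
    dataset: ExperimentDataset
    final_model: KineticModel
    stopping_reason: str


def mbdoe_loop(source: KineticModel, dataset: ExperimentDataset,
               oracle: KineticModel, budget: int,
               config: PipelineConfig | None = None,
               spec: DesignSpec | None = None,
               seed: int = 0,
               evaluation: ExperimentDataset | None = None) -> MbdoeState:
    """Sequential design: adapt structure, enumerate candidates, design the
    most discriminating batch, run it in-silico against the oracle, repeat.

    Stops when the budget is exhausted, the structure stops changing between
    iterations, or the candidates become indistinguishable.  ``evaluation``
    (noise-free held-out batches) enables per-iteration prediction MAPE.
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    config = config or PipelineConfig()
    spec = spec or DesignSpec()
    seeds = np.random.SeedSequence(seed).spawn(budget + 1)
    iterations: list[MbdoeIteration] = []
    previous_model: KineticModel | None = None
    current = source
    reason = "budget exhausted"

    for it in range(1, budget + 1):
        model, records = multi_pass(source, dataset, config)
        last_active = next((r for r in reversed(records) if r.fronts), None)

        pred_mape = _prediction_mape(model, evaluation) if evaluation else None
        entry = MbdoeIteration(it, 1, None, None, model,
                               records[-1].fit_mape, pred_mape)
        iterations.append(entry)

        if previous_model is not None and \
                structural_match(model, previous_model).matched:
            reason = "structure stopped updating"
            current = model
            break
        previous_model = model
        current = model

        if it == budget:
            break

        if last_active is None:
            reason = "no correction terms proposed"
            break
        fit_res = last_active.fit
        candidates = enumerate_candidates(
            last_active.skeleton, last_active.fronts,
            fit_res.norm, fit_res.theta, dataset)
        entry.n_candidates = candidates.nm
        if candidates.nm < 2:
            reason = "candidates indistinguishable"
            break

        rep_seed = int(seeds[it].generate_state(1)[0] % (2 ** 31))
        z_star, J_star = design_experiment(candidates, spec, seed=rep_seed)
        entry.z_star, entry.J_star = z_star, J_star

        # execute the designed batch against the ground-truth oracle
        y0 = np.array([spec.y0_ranges[s][0] for s in oracle.state_names])
        for value, name in zip(z_star, spec.design_states):
            y0[oracle.state_names.index(name)] = value
        times = default_sample_times(spec.horizon, spec.interval)
        truth = simulate(oracle, y0, times)
        rng = np.random.default_rng(seeds[it].spawn(1)[0])
        noise = rng.normal(0, dataset.noise_sd_fraction, truth.shape) \
            if dataset.noise_sd_fraction > 0 else 0.0
        obs = np.clip(truth * (1 + noise), 0.0, None)
        dataset = dataset.extended(Experiment(y0, times, obs))

    return MbdoeState(iterations, dataset, current, reason)


def _prediction_mape(model: KineticModel,
                     evaluation: ExperimentDataset) -> float:
    from .study import prediction_mape

    return prediction_mape(model, evaluation)
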