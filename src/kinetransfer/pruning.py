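"""Variance-based slot pruning and integrated-gradients feature attribution.

Unimportant correction slots produce nearly constant outputs over the fitted
trajectories; the slot whose output *varies* least is removed first, the
hybrid model is refitted (warm-started), and the cycle repeats until at most
``Umax`` corrections remain.  Any survivor whose variance is still below
``Vmin`` (on the normalized correction scale) is then dropped too — an empty
survivor set is a valid outcome meaning "no structural correction needed".

For each surviving slot, Integrated Gradients attributes the corrector's
output to its input features along the straight path from a baseline point;
per-feature mean absolute attributions, normalized to sum to one, become the
feature weights π that bias — and, below a threshold, hard-exclude —
variables during symbolic regression.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .ann import NeuralCorrector
from .embedding import HybridSkeleton
from .simulate import ExperimentDataset
from .training import FitResult, TrainingConfig, fit

__all__ = ["SlotStatistics", "AttributionWeights", "PruneTrailEntry",
           "slot_statistics", "prune_loop", "integrated_gradients",
           "feature_weights"]


@dataclass
class SlotStatistics:
    """Mean and population variance of each active slot's fitted output."""

    slot_indices: tuple[int, ...]
    mean: np.ndarray
    variance: np.ndarray

    def as_dict(self) -> dict[int, tuple[float, float]]:
        return {j: (float(m), float(v)) for j, m, v in
                zip(self.slot_indices, self.mean, self.variance)}


def slot_statistics(fit_result: FitResult) -> SlotStatistics:
    """Per-slot mean/variance of φ̂ over the full (experiment × time) grid."""
    phi = fit_result.phi_hat
    if phi.shape[0] * phi.shape[1] < 1:
        raise ValueError("fit has no samples")
    flat = phi.reshape(-1, phi.shape[-1])
    return SlotStatistics(fit_result.slot_indices,
                          flat.mean(axis=0), flat.var(axis=0))


@dataclass
class PruneTrailEntry:
    iteration: int
    slot_index: int
    variance: float
    action: str  # "pruned-umax" | "pruned-vmin" | "kept"


def prune_loop(skeleton: HybridSkeleton, dataset: ExperimentDataset,
               config: TrainingConfig | None = None, Umax: int = 3,
               Vmin: float = 0.1,
               theta0: dict[str, float] | None = None
               ) -> tuple[HybridSkeleton, FitResult, list[PruneTrailEntry]]:
    """Iteratively remove the least-variable corrections.

    One slot is deactivated per refit (sequential, never batch-pruned, and
    never reactivated) until at most ``Umax`` remain; afterwards survivors
    with variance below ``Vmin`` are deactivated and the model refitted once.
    Returns the pruned skeleton, the final fit, and the full trail.
    """
    if Umax < 1:
        raise ValueError("Umax must be >= 1")
    if Vmin < 0:
        raise ValueError("Vmin must be nonnegative")
    config = config or TrainingConfig()
    skeleton = skeleton.copy()
    trail: list[PruneTrailEntry] = []

    result = fit(skeleton, dataset, config, theta0=theta0)
    refit_config = (replace(config, epochs=config.refit_epochs)
                    if config.refit_epochs else config)
    iteration = 0
    while skeleton.n_active > Umax:
        iteration += 1
        stats = slot_statistics(result)
        pos = int(np.argmin(stats.variance))
        victim = stats.slot_indices[pos]
        trail.append(PruneTrailEntry(iteration, victim,
                                     float(stats.variance[pos]), "pruned-umax"))
        skeleton.deactivate(victim)
        result = fit(skeleton, dataset, refit_config,
                     theta0=result.theta, ann0=result.ann.drop_output(pos))

    if skeleton.n_active and config.refit_epochs:
        # converge the survivors fully before judging them — from a fresh
        # start: the warm corrector state inherited from the pruning phase
        # can sit in a baseline-collapsed local minimum that under-expresses
        # exactly the signal the variance threshold is about to judge
        result = fit(skeleton, dataset, config)

    if skeleton.n_active:
        stats = slot_statistics(result)
        below = [(j, v) for j, v in zip(stats.slot_indices, stats.variance)
                 if v < Vmin]
        for j, v in below:
            iteration += 1
            trail.append(PruneTrailEntry(iteration, j, float(v), "pruned-vmin"))
            skeleton.deactivate(j)
        if below:
            # downstream attribution and symbolic regression consume this
            # fit, so refit the remaining corrections from scratch too
            result = fit(skeleton, dataset, config)
        for j, v in zip(stats.slot_indices, stats.variance):
            if j not in {b[0] for b in below}:
                trail.append(PruneTrailEntry(iteration, j, float(v), "kept"))
    return skeleton, result, trail


# -- integrated gradients --------------------------------------------------


def integrated_gradients(corrector: NeuralCorrector, inputs: np.ndarray,
                         baseline: np.ndarray | None = None,
                         steps: int = 256) -> np.ndarray:
    """Path-integral attributions, shape (n_points, n_outputs, n_features).

    The line integral from the baseline to each input is approximated by the
    midpoint rule with ``steps`` segments using the corrector's exact input
    Jacobian; by construction the attributions of a point sum (over
    features) to φ(input) − φ(baseline) as steps → ∞ (completeness).
    """
    if steps < 2:
        raise ValueError("steps must be >= 2")
    inputs = np.atleast_2d(np.asarray(inputs, dtype=float))
    if baseline is None:
        baseline = inputs.mean(axis=0)
    baseline = np.asarray(baseline, dtype=float)
    delta = inputs - baseline  # (n, v)
    alphas = (np.arange(steps) + 0.5) / steps
    # points: (steps, n, v)
    pts = baseline + alphas[:, None, None] * delta
    J = corrector.input_jacobian(pts)          # (steps, n, k, v)
    avg_J = J.mean(axis=0)                     # (n, k, v)
    return avg_J * delta[:, None, :]


@dataclass
class AttributionWeights:
    """Normalized SR feature weights π per slot, with hard exclusions."""

    slot_indices: tuple[int, ...]
    feature_names: tuple[str, ...]
    pi: np.ndarray                 # (n_slots, n_features), rows sum to 1
    excluded: np.ndarray           # boolean, same shape
    drop_threshold: float

    def allowed_features(self, slot_index: int) -> list[str]:
        row = list(self.slot_indices).index(slot_index)
        return [f for f, ex in zip(self.feature_names, self.excluded[row])
                if not ex]

    def pi_for(self, slot_index: int) -> dict[str, float]:
        row = list(self.slot_indices).index(slot_index)
        return dict(zip(self.feature_names, self.pi[row]))


def feature_weights(attributions: np.ndarray, slot_indices: tuple[int, ...],
                    feature_names: tuple[str, ...],
                    drop_threshold: float = 0.05) -> AttributionWeights:
    """Aggregate per-point attributions into per-slot feature weights.

    π_vj = mean over points of |attribution| of feature v for slot j,
    normalized to sum one over v.  Features with π below ``drop_threshold``
    are flagged excluded (hard-removed from the slot's SR search space).
    All-zero attribution rows fall back to uniform weights with a warning.
    """
    agg = np.abs(attributions).mean(axis=0)  # (n_slots, n_features)
    sums = agg.sum(axis=1, keepdims=True)
    pi = np.empty_like(agg)
    uniform_rows = (sums[:, 0] == 0)
    if uniform_rows.any():
        import warnings

        warnings.warn("all-zero attributions for some slots; using uniform π")
    pi[uniform_rows] = 1.0 / agg.shape[1]
    nz = ~uniform_rows
    pi[nz] = agg[nz] / sums[nz]
    excluded = pi < drop_threshold
    # never exclude everything
    for row in range(pi.shape[0]):
        if excluded[row].all():
            excluded[row, int(np.argmax(pi[row]))] = False
    return AttributionWeights(tuple(slot_indices), tuple(feature_names),
                              pi, excluded, drop_threshold)
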