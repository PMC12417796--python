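"""One-step hybrid training: simultaneous fit of θ and the ANN corrector ω.

The slotted model is integrated through the measured batches with a
fixed-step RK4 scheme on normalized time, and the mean squared normalized
trajectory residual is minimized jointly over the kinetic parameters θ
(signed log-magnitude parameterization: multiplicative steps, fixed signs)
and the corrector weights ω
with Adam, an exponentially decaying learning rate, decoupled weight decay
on ω only, and global gradient-norm clipping.

Gradients are exact for the discrete problem: a discrete adjoint is
propagated backward through every RK4 stage, using sympy-generated Jacobians
of the slotted right-hand side with respect to states, parameters and
correction outputs, chained with the corrector's analytic backward pass.

The regularization penalty

    P = λ1 · mean‖∂φ/∂ŷ‖² + λ2 · mean‖φ(ŷ) − b‖²,

weighted by the number of active corrections n_φ, discourages input-
sensitive corrections and pulls every slot toward its do-nothing baseline;
it is evaluated at the fitted trajectory's measurement support, and its
gradient is taken with respect to ω at those (detached) states.  An optional
growth-independent regularizer additionally pins additive state-equation
corrections to zero early in each batch, where growth-associated kinetics
dominate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import sympy as sp

from .ann import NeuralCorrector
from .embedding import HybridSkeleton, baseline_vector
from .simulate import ExperimentDataset

__all__ = ["TrainingConfig", "FitResult", "CompiledSkeleton", "Normalization",
           "objective", "fit", "gi_regularizer"]


@dataclass
class TrainingConfig:
    """Hyperparameters of one-step hybrid training."""

    lam1: float = 1e-6          # weight of the Jacobian (smoothness) penalty
    lam2: float = 1e-4          # weight of the baseline-deviation penalty
    epochs: int = 3000
    learning_rate: float = 0.01
    lr_decay: float = 0.999     # exponential, per epoch
    weight_decay: float = 0.001  # on ω only, decoupled
    clip_norm: float = 1.0
    theta_lr_scale: float = 0.2  # relative learning rate for θ vs ω
    steps_per_interval: int = 4  # RK4 substeps per sampling interval
    hidden: int = 5
    init_scale: float = 0.1
    additive_gain: float = 10.0  # fixed output gain on additive corrections
    gi_weight: float = 0.0      # growth-independent early-batch regularizer
    gi_window_fraction: float = 0.2
    early_stop_rel: float = 1e-6
    early_stop_patience: int = 100
    refit_epochs: int | None = None  # shorter warm-started refits (pruning)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lam1 < 0 or self.lam2 < 0:
            raise ValueError("penalty weights must be nonnegative")


@dataclass
class Normalization:
    """Per-state maxima and the batch horizon used to normalize the problem."""

    y_max: np.ndarray
    t_max: float

    @classmethod
    def from_dataset(cls, dataset: ExperimentDataset) -> "Normalization":
        return cls(dataset.state_maxima(), float(dataset.experiments[0].sample_times[-1]))


class CompiledSkeleton:
    """Lambdified slotted RHS f(y, θ, φ) and its three Jacobians.

    One call evaluates all entries with common-subexpression sharing,
    vectorized over experiments.
    """

    def __init__(self, skeleton: HybridSkeleton, norm: "Normalization | None" = None):
        self.skeleton = skeleton
        base = skeleton.base_model
        self.state_names = base.state_names
        self.param_names = tuple(base.parameters)
        self.slot_indices = tuple(s.index for s in skeleton.active_slots)
        ns = len(self.state_names)

        self.slot_scales = (skeleton.slot_scales(norm.y_max, norm.t_max)
                            if norm is not None
                            else np.ones(len(self.slot_indices)))

        y_syms = [sp.Symbol(s) for s in self.state_names]
        th_syms = [sp.Symbol(p) for p in self.param_names]
        ph_syms = [s.symbol for s in skeleton.active_slots]
        eqs = skeleton.sympy_system(inline_rates=True)
        # corrector outputs enter additive locations on their host-term scale
        scale_subs = {sym: sp.Float(sc) * sym
                      for sym, sc in zip(ph_syms, self.slot_scales) if sc != 1.0}
        eqs = {k: v.subs(scale_subs) for k, v in eqs.items()}
        F = sp.Matrix([eqs[s] for s in self.state_names])
        Jy = F.jacobian(y_syms) if ns else sp.Matrix([])
        Jth = F.jacobian(th_syms) if th_syms else sp.zeros(ns, 0)
        Jph = F.jacobian(ph_syms) if ph_syms else sp.zeros(ns, 0)

        args = y_syms + th_syms + ph_syms
        self._f = sp.lambdify(args, list(F), modules="numpy", cse=True)
        flat = list(F) + list(Jy) + list(Jth) + list(Jph)
        self._all = sp.lambdify(args, flat, modules="numpy", cse=True)
        self._shapes = (ns, (ns, ns), (ns, len(th_syms)), (ns, len(ph_syms)))

    @property
    def n_states(self) -> int:
        return len(self.state_names)

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    @property
    def n_phi(self) -> int:
        return len(self.slot_indices)

    def _args(self, Y: np.ndarray, theta: np.ndarray, Phi: np.ndarray) -> list:
        args = [Y[..., i] for i in range(self.n_states)]
        args += list(theta)
        args += [Phi[..., j] for j in range(self.n_phi)]
        return args

    @staticmethod
    def _assemble(vals: list, batch: tuple) -> np.ndarray:
        out = np.empty(batch + (len(vals),))
        for i, v in enumerate(vals):
            out[..., i] = v  # scalar entries broadcast natively
        # rate/Jacobian evaluations at a pole are sanitized to large finite
        # values: the trajectory loss stays finite and (clipped) gradients
        # keep pushing the parameters back out of the singular region
        return np.nan_to_num(out, nan=0.0, posinf=1e6, neginf=-1e6)

    def f(self, Y: np.ndarray, theta: np.ndarray, Phi: np.ndarray) -> np.ndarray:
        """Rates, shape (..., ns); Y is (..., ns), Phi (..., nφ)."""
        with np.errstate(all="ignore"):
            vals = self._f(*self._args(Y, theta, Phi))
        return self._assemble(vals, Y.shape[:-1])

    def f_and_jacobians(self, Y: np.ndarray, theta: np.ndarray, Phi: np.ndarray):
        """(F, Jy, Jth, Jph) with leading batch dims from Y."""
        batch = Y.shape[:-1]
        ns, sy, sth, sph = self._shapes
        with np.errstate(all="ignore"):
            vals = self._all(*self._args(Y, theta, Phi))
        flat = self._assemble(vals, batch)
        i = 0
        F = flat[..., i:i + ns]; i += ns
        Jy = flat[..., i:i + sy[0] * sy[1]].reshape(*batch, *sy); i += sy[0] * sy[1]
        Jth = flat[..., i:i + sth[0] * sth[1]].reshape(*batch, *sth); i += sth[0] * sth[1]
        Jph = flat[..., i:].reshape(*batch, *sph)
        return F, Jy, Jth, Jph


@dataclass
class FitResult:
    """Everything downstream stages need from one hybrid fit."""

    theta: dict[str, float]
    ann: NeuralCorrector
    slot_indices: tuple[int, ...]
    norm: Normalization
    traj_norm: np.ndarray       # fitted states, normalized, (ne, ni, ns)
    phi_hat: np.ndarray         # fitted corrections at samples, (ne, ni, nφ)
    total: float
    mse: float
    penalty: float
    loss_trace: np.ndarray
    converged: bool
    slot_scales: np.ndarray | None = None
    faults: int = 0
    config: TrainingConfig | None = None

    @property
    def trajectories(self) -> np.ndarray:
        """Fitted states in physical units (ne, ni, ns)."""
        return self.traj_norm * self.norm.y_max


# -- forward machinery -----------------------------------------------------


def _integration_grid(sample_times: np.ndarray, t_max: float, spi: int):
    """Normalized substep grid hitting every sample time exactly."""
    tau = sample_times / t_max
    hs, sample_idx = [], [0]
    for a, b in zip(tau[:-1], tau[1:]):
        hs.extend([(b - a) / spi] * spi)
        sample_idx.append(sample_idx[-1] + spi)
    return np.array(hs), np.array(sample_idx)


def _forward(compiled: CompiledSkeleton, ann: NeuralCorrector, theta: np.ndarray,
             U0: np.ndarray, hs: np.ndarray, norm: Normalization,
             record_stages: bool = False):
    """RK4 integration of the normalized hybrid system for all experiments.

    Returns the state at every substep node, (n_nodes, ne, ns); with
    ``record_stages`` also the four stage slopes per step for the adjoint.
    """
    C = norm.t_max / norm.y_max

    def g(U):
        Phi = ann.forward(U)
        return C * compiled.f(U * norm.y_max, theta, Phi)

    U = U0.copy()
    nodes = [U0.copy()]
    stages = []
    for h in hs:
        k1 = g(U)
        k2 = g(U + h / 2 * k1)
        k3 = g(U + h / 2 * k2)
        k4 = g(U + h * k3)
        if record_stages:
            stages.append((k1, k2, k3))
        U = U + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        # keep the normalized states in a huge but finite box so a pole
        # crossing produces a large finite loss instead of NaNs
        U = np.clip(U, -100.0, 100.0)
        nodes.append(U.copy())
    out = np.array(nodes)
    return (out, stages) if record_stages else out


def gi_regularizer(skeleton: HybridSkeleton, phi_early: np.ndarray,
                   weight: float) -> float:
    """Early-batch penalty on growth-independent corrections.

    ``phi_early`` holds corrector outputs (…, nφ active) at samples inside
    the early window; the addend is weight × mean over those samples of the
    squared values of the growth-independent (additive, state-equation)
    slots.
    """
    if weight == 0 or phi_early.size == 0:
        return 0.0
    mask = np.array([s.growth_independent for s in skeleton.active_slots])
    if not mask.any():
        return 0.0
    vals = phi_early[..., mask]
    return float(weight * np.mean(np.sum(vals ** 2, axis=-1)))


def _loss_terms(compiled: CompiledSkeleton, ann: NeuralCorrector,
                theta: np.ndarray, dataset: ExperimentDataset,
                norm: Normalization, config: TrainingConfig,
                return_states: bool = False):
    """Forward pass → (total, mse, penalty, U_nodes, sample info)."""
    skeleton = compiled.skeleton
    Y0 = np.array([e.y0 for e in dataset.experiments])
    Yobs = np.array([e.observations for e in dataset.experiments]) / norm.y_max
    times = dataset.experiments[0].sample_times
    hs, sample_idx = _integration_grid(times, norm.t_max, config.steps_per_interval)

    U_nodes = _forward(compiled, ann, theta, Y0 / norm.y_max, hs, norm)
    U_samples = U_nodes[sample_idx].transpose(1, 0, 2)  # (ne, ni, ns)

    finite = np.isfinite(U_samples).all()
    if not finite:
        return np.inf, np.inf, 0.0, None, None

    resid = U_samples - Yobs
    mse = float(np.mean(resid ** 2))

    n_phi = compiled.n_phi
    penalty = 0.0
    if n_phi:
        x = U_samples.reshape(-1, compiled.n_states)
        phi = ann.forward(x)
        b = baseline_vector(skeleton)
        dev = float(np.mean(np.sum((phi - b) ** 2, axis=-1)))
        jac = ann.jacobian_penalty(x)
        P = config.lam1 * jac + config.lam2 * dev
        penalty = n_phi * P
        if config.gi_weight > 0:
            early = times <= config.gi_window_fraction * times[-1]
            phi_early = ann.forward(U_samples[:, early, :])
            penalty += gi_regularizer(skeleton, phi_early, config.gi_weight)
    total = mse + penalty
    if return_states:
        return total, mse, penalty, (U_nodes, U_samples, Yobs, hs, sample_idx), None
    return total, mse, penalty, None, None


def objective(skeleton: HybridSkeleton, theta: dict[str, float] | Sequence[float],
              ann: NeuralCorrector, dataset: ExperimentDataset,
              config: TrainingConfig | None = None,
              norm: Normalization | None = None) -> tuple[float, float, float]:
    """(total, mse, penalty) of the training objective at given θ, ω."""
    config = config or TrainingConfig()
    norm = norm or Normalization.from_dataset(dataset)
    compiled = CompiledSkeleton(skeleton, norm)
    if isinstance(theta, dict):
        theta = np.array([theta[p] for p in compiled.param_names])
    else:
        theta = np.asarray(theta, dtype=float)
    total, mse, penalty, _, _ = _loss_terms(compiled, ann, theta, dataset,
                                            norm, config)
    return total, mse, penalty


# -- gradient (discrete adjoint) ------------------------------------------


def _grad(compiled: CompiledSkeleton, ann: NeuralCorrector, theta: np.ndarray,
          dataset: ExperimentDataset, norm: Normalization, config: TrainingConfig):
    """Loss, decomposition and exact gradients wrt (log θ, ω)."""
    skeleton = compiled.skeleton
    Y0 = np.array([e.y0 for e in dataset.experiments])
    Yobs = np.array([e.observations for e in dataset.experiments]) / norm.y_max
    times = dataset.experiments[0].sample_times
    hs, sample_idx = _integration_grid(times, norm.t_max, config.steps_per_interval)
    C = norm.t_max / norm.y_max
    ne, ni, ns = Yobs.shape
    n_phi = compiled.n_phi

    # forward with stages
    (U_nodes, stages) = _forward(compiled, ann, theta, Y0 / norm.y_max, hs, norm,
                                 record_stages=True)
    U_samples = U_nodes[sample_idx].transpose(1, 0, 2)
    if not np.isfinite(U_samples).all():
        return None  # caller handles the fault

    resid = U_samples - Yobs
    mse = float(np.mean(resid ** 2))
    dL_dU_sample = 2 * resid / resid.size  # (ne, ni, ns)

    g_theta = np.zeros(compiled.n_params)
    ann_grads = [np.zeros_like(a) for a in (ann.W1, ann.b1, ann.W2, ann.b2)]

    # adjoint sweep; per step, all four stage Jacobians are evaluated in one
    # batched call (they do not depend on the adjoint), then the small stage
    # recursion runs on the precomputed blocks
    lam = np.zeros((ne, ns))
    n_steps = len(hs)
    sample_set = {int(i): j for j, i in enumerate(sample_idx)}
    if n_steps in sample_set:
        lam += dL_dU_sample[:, sample_set[n_steps], :]
    for n in range(n_steps - 1, -1, -1):
        h = hs[n]
        U_n = U_nodes[n]
        k1, k2, k3 = stages[n]
        S = np.stack([U_n, U_n + h / 2 * k1, U_n + h / 2 * k2, U_n + h * k3])
        Phi, h_cache = ann.forward_cached(S)
        _, Jy, Jth, Jph = compiled.f_and_jacobians(S * norm.y_max, theta, Phi)
        c = h / 6 * np.array([1, 2, 2, 1])

        ms = [None] * 4
        dUs = [None] * 4
        carry = np.zeros((ne, ns))
        scale = [None, h / 2, h / 2, h]
        for i_st in (3, 2, 1, 0):
            m = c[i_st] * lam + (scale[i_st + 1] * carry if i_st < 3 else 0.0)
            lamC = m * C
            ms[i_st] = m
            w_cot = (np.einsum("es,esj->ej", lamC, Jph[i_st]) if n_phi
                     else np.zeros((ne, 0)))
            grads, dx = ann.backward(S[i_st], h_cache[i_st], w_cot)
            dU = np.einsum("es,est->et", lamC, Jy[i_st]) * norm.y_max + dx
            dUs[i_st] = dU
            carry = dU
            g_theta += np.einsum("es,esp->p", lamC, Jth[i_st])
            for acc, a in zip(ann_grads, grads):
                acc += a

        lam = lam + dUs[0] + dUs[1] + dUs[2] + dUs[3]
        if n in sample_set and n > 0:
            lam += dL_dU_sample[:, sample_set[n], :]

    # penalty (evaluated at detached sampled states)
    penalty = 0.0
    if n_phi:
        x = U_samples.reshape(-1, compiled.n_states)
        b = baseline_vector(skeleton)
        phi, h_cache = ann.forward_cached(x)
        dev = float(np.mean(np.sum((phi - b) ** 2, axis=-1)))
        jac_val, jac_grads = ann.jacobian_penalty_grad(x)
        penalty = n_phi * (config.lam1 * jac_val + config.lam2 * dev)
        dev_cot = n_phi * config.lam2 * 2 * (phi - b) / x.shape[0]
        (dW1, db1, dW2, db2), _ = ann.backward(x, h_cache, dev_cot)
        for acc, a, jg in zip(ann_grads, (dW1, db1, dW2, db2), jac_grads):
            acc += a + n_phi * config.lam1 * jg
        if config.gi_weight > 0:
            mask = np.array([s.growth_independent for s in skeleton.active_slots])
            early = times <= config.gi_window_fraction * times[-1]
            if mask.any() and early.any():
                xe = U_samples[:, early, :].reshape(-1, compiled.n_states)
                phi_e, h_e = ann.forward_cached(xe)
                vals = phi_e[:, mask]
                penalty += float(config.gi_weight * np.mean(np.sum(vals ** 2, axis=-1)))
                cot = np.zeros_like(phi_e)
                cot[:, mask] = 2 * config.gi_weight * vals / xe.shape[0]
                (dW1, db1, dW2, db2), _ = ann.backward(xe, h_e, cot)
                for acc, a in zip(ann_grads, (dW1, db1, dW2, db2)):
                    acc += a

    total = mse + penalty
    g_log_theta = g_theta * theta  # chain rule through θ = exp(s)
    return (total, mse, penalty, g_log_theta,
            ann.flat_grad(*ann_grads), U_samples)


# -- optimizer -------------------------------------------------------------


def fit(skeleton: HybridSkeleton, dataset: ExperimentDataset,
        config: TrainingConfig | None = None,
        theta0: dict[str, float] | None = None,
        ann0: NeuralCorrector | None = None,
        norm: Normalization | None = None) -> FitResult:
    """Train the hybrid skeleton on a dataset; deterministic given the seed.

    ``theta0`` / ``ann0`` allow warm starts (the pruning loop re-fits after
    each removal).  Raises ``RuntimeError`` after 50 consecutive non-finite
    evaluations.
    """
    if not dataset.experiments:
        raise ValueError("dataset is empty")
    config = config or TrainingConfig()
    norm = norm or Normalization.from_dataset(dataset)
    compiled = CompiledSkeleton(skeleton, norm)
    rng = np.random.default_rng(config.seed)

    theta0 = dict(theta0 or skeleton.base_model.parameters)
    theta_vec = np.array([theta0[p] for p in compiled.param_names])
    # signed log-magnitude parameterization: θ = sign·exp(s) keeps each
    # parameter's sign fixed while steps act multiplicatively; dθ/ds = θ
    theta_signs = np.where(theta_vec >= 0, 1.0, -1.0)
    s = np.log(np.maximum(np.abs(theta_vec), 1e-10))
    b = baseline_vector(skeleton)
    gains = np.array([config.additive_gain if sl.mode == "additive" else 1.0
                      for sl in skeleton.active_slots])
    ann = (ann0.copy() if ann0 is not None else
           NeuralCorrector.initialize(compiled.n_states, b, rng,
                                      hidden=config.hidden,
                                      scale=config.init_scale,
                                      gains=gains,
                                      input_names=compiled.state_names))
    if ann.n_outputs != compiled.n_phi:
        raise ValueError("corrector output dimension does not match active slots")

    w = ann.get_flat()
    p = np.concatenate([s, w])
    n_s = len(s)
    # decoupled weight decay applies to W1 and W2 only, never to biases
    decay_mask = np.zeros_like(p, dtype=bool)
    i0 = n_s
    for arr, decays in ((ann.W1, True), (ann.b1, False),
                        (ann.W2, True), (ann.b2, False)):
        if decays:
            decay_mask[i0:i0 + arr.size] = True
        i0 += arr.size

    m = np.zeros_like(p)
    v = np.zeros_like(p)
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    lr = config.learning_rate
    trace = []
    best_loss = np.inf
    best_p = p.copy()
    fault_streak = 0
    faults = 0
    stall = 0
    last_check = np.inf

    for epoch in range(config.epochs):
        ann.set_flat(p[n_s:])
        theta = theta_signs * np.exp(p[:n_s])
        out = _grad(compiled, ann, theta, dataset, norm, config)
        if out is None:
            faults += 1
            fault_streak += 1
            if fault_streak >= 50:
                raise RuntimeError("hybrid training diverged: 50 consecutive "
                                   "non-finite trajectory evaluations")
            # back off toward the best point seen and shrink the step
            p = 0.5 * (p + best_p)
            lr *= 0.5
            trace.append(trace[-1] if trace else np.inf)
            continue
        fault_streak = 0
        total, mse, penalty, g_s, g_w, _ = out
        trace.append(total)
        if total < best_loss:
            best_loss = total
            best_p = p.copy()

        grad = np.concatenate([g_s, g_w])
        gn = np.linalg.norm(grad)
        if config.clip_norm and gn > config.clip_norm:
            grad = grad * (config.clip_norm / gn)

        m = beta1 * m + (1 - beta1) * grad
        v = beta2 * v + (1 - beta2) * grad * grad
        mhat = m / (1 - beta1 ** (epoch + 1))
        vhat = v / (1 - beta2 ** (epoch + 1))
        step = lr * mhat / (np.sqrt(vhat) + eps)
        if config.theta_lr_scale != 1.0:
            step[:n_s] *= config.theta_lr_scale
        p = p - step
        if config.weight_decay:
            p[decay_mask] -= lr * config.weight_decay * p[decay_mask]
        lr *= config.lr_decay

        if (epoch + 1) % config.early_stop_patience == 0:
            if last_check - best_loss < config.early_stop_rel * max(abs(last_check), 1e-12):
                break
            last_check = best_loss

    # final evaluation at the best parameters
    p = best_p
    ann.set_flat(p[n_s:])
    theta = theta_signs * np.exp(p[:n_s])
    total, mse, penalty, states, _ = _loss_terms(compiled, ann, theta, dataset,
                                                 norm, config, return_states=True)
    if states is None:
        raise RuntimeError("hybrid training ended in a non-finite state")
    _, U_samples, _, _, _ = states
    phi_hat = (ann.forward(U_samples) if compiled.n_phi
               else np.zeros((*U_samples.shape[:2], 0)))

    return FitResult(
        theta={name: float(t) for name, t in zip(compiled.param_names, theta)},
        ann=ann,
        slot_indices=compiled.slot_indices,
        norm=norm,
        traj_norm=U_samples,
        phi_hat=phi_hat,
        total=float(total), mse=float(mse), penalty=float(penalty),
        loss_trace=np.array(trace),
        converged=len(trace) < config.epochs,
        slot_scales=compiled.slot_scales,
        faults=faults,
        config=config,
    )
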