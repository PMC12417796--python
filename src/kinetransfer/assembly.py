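"""Model assembly: substitute symbolic corrections, fine-tune, iterate passes.

One *pass* of structure modification is: embed correction slots → train and
variance-prune the hybrid model → attribute surviving corrections to input
features → symbolic-regress each survivor → substitute the top expression
back into the equations → sparsity-promoting parameter fine-tune.  Passes
repeat until no correction slot survives pruning (variance below V_min) or
the structure stops changing.

Symbolic corrections are discovered as functions of *normalized* states; on
substitution each state symbol is replaced by state/state-maximum and the
expression is multiplied by its slot's characteristic scale, after which
rational simplification folds all constants and the surviving numeric
coefficients are registered as new named parameters (c1, c2, ...).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np
import sympy as sp
from scipy.optimize import least_squares

from .embedding import HybridSkeleton, embed
from .expressions import ExpressionTree, sympy_to_tree, tree_to_sympy
from .models import KineticModel, StructureDiff, structural_match
from .pruning import (feature_weights, integrated_gradients, prune_loop,
                      slot_statistics)
from .simulate import ExperimentDataset, mape, simulate
from .sr import ParetoFront, SRConfig, SRDataset, run_sr, select_top
from .training import FitResult, Normalization, TrainingConfig

__all__ = ["FinetuneConfig", "PipelineConfig", "PassRecord", "SubstitutionError",
           "substitute_and_simplify", "finetune", "run_pass", "multi_pass"]


class SubstitutionError(ValueError):
    """A candidate substitution produced a structurally invalid model."""


@dataclass
class FinetuneConfig:
    """Final parameter fine-tuning settings."""

    sparsity_weight: float = 1e-3   # L2 penalty on the new (correction) parameters
    drop_threshold: float = 0.01    # on normalized trajectory contribution
    max_drop_rounds: int = 5
    steps_per_interval: int = 4     # RK4 substeps for the refit simulations
    max_nfev: int = 400
    ftol: float = 1e-10

    def __post_init__(self) -> None:
        if self.drop_threshold < 0:
            raise ValueError("drop threshold must be nonnegative")


@dataclass
class PipelineConfig:
    """Everything one pass of structure modification needs."""

    training: TrainingConfig = field(default_factory=TrainingConfig)
    sr: SRConfig = field(default_factory=SRConfig)
    finetune: FinetuneConfig = field(default_factory=FinetuneConfig)
    Dmax: int = 3
    Umax: int = 3
    Vmin: float = 0.1
    treat_shared_rate_as_equation: bool = True
    attribution_drop_threshold: float = 0.05
    ig_steps: int = 64
    max_passes: int = 5


@dataclass
class PassRecord:
    """Everything that happened in one pass of structure modification."""

    pass_number: int
    slots_before: int
    survivors: tuple[int, ...]
    selected: dict[int, str]
    fronts: dict[int, ParetoFront]
    model: KineticModel
    fit_mape: float
    converged: bool
    prune_trail: list = field(default_factory=list)
    attribution: object | None = None
    fit: FitResult | None = None
    skeleton: HybridSkeleton | None = None
    match: StructureDiff | None = None


# -- substitution ----------------------------------------------------------


def _register_constants(tree: ExpressionTree, existing: set[str]
                        ) -> tuple[ExpressionTree, dict[str, float]]:
    """Replace float constants by fresh named parameters c<k>."""
    new_params: dict[str, float] = {}
    counter = 1

    def fresh() -> str:
        nonlocal counter
        while f"c{counter}" in existing:
            counter += 1
        name = f"c{counter}"
        counter += 1
        existing.add(name)
        return name

    def walk(node: ExpressionTree) -> ExpressionTree:
        if node.node_kind == "constant":
            v = node.value
            if v == int(v) and abs(v) <= 1:  # structural 0/±1 stay literal
                return node
            name = fresh()
            new_params[name] = float(v)
            return ExpressionTree("parameter", name=name)
        if node.children:
            return ExpressionTree(node.node_kind, node.operator_symbol,
                                  tuple(walk(c) for c in node.children),
                                  node.name, node.value)
        return node

    return walk(tree), new_params


def substitute_and_simplify(skeleton: HybridSkeleton,
                            expressions: dict[int, ExpressionTree | sp.Expr],
                            norm: Normalization,
                            theta: dict[str, float] | None = None
                            ) -> KineticModel:
    """Build the updated kinetic model from chosen slot expressions.

    ``expressions`` maps active slot indices to correction expressions in
    the *normalized* state variables; slots not in the map revert to their
    baselines.  Raises :class:`SubstitutionError` if a substitution yields a
    structurally zero denominator.
    """
    base = skeleton.base_model
    theta = dict(theta or base.parameters)
    scales = skeleton.slot_scales(norm.y_max, norm.t_max)
    state_subs = {sp.Symbol(s): sp.Symbol(s) / sp.Float(m)
                  for s, m in zip(base.state_names, norm.y_max)}

    subs: dict[sp.Symbol, sp.Expr] = {}
    for slot, scale in zip(skeleton.active_slots, scales):
        if slot.index in expressions:
            e = expressions[slot.index]
            if isinstance(e, ExpressionTree):
                e = tree_to_sympy(e)
            subs[slot.symbol] = sp.Float(scale) * e.subs(state_subs)
        else:
            subs[slot.symbol] = sp.Float(slot.baseline)
    for slot in skeleton.slots:
        if not slot.active:
            subs[slot.symbol] = sp.Float(slot.baseline)

    existing = set(theta)
    new_equations: dict[str, ExpressionTree] = {}
    new_rates: dict[str, ExpressionTree] = {}
    all_new_params: dict[str, float] = {}

    def convert(expr: sp.Expr, host: str) -> ExpressionTree:
        expr = sp.cancel(sp.together(expr.subs(subs)))
        num, den = sp.fraction(expr)
        if den.is_zero or num.has(sp.zoo) or num.has(sp.nan):
            raise SubstitutionError(f"substitution in {host} degenerates")
        tree = sympy_to_tree(expr, variables=list(base.state_names) +
                             list(base.shared_rates) + list(base.control_names),
                             parameters=list(existing))
        tree, new_params = _register_constants(tree, existing)
        all_new_params.update(new_params)
        return tree

    for name, expr in skeleton.slotted_rates.items():
        new_rates[name] = convert(expr, name)
    for s in base.state_names:
        new_equations[s] = convert(skeleton.slotted_equations[s], s)

    params = {**theta, **all_new_params}
    model = KineticModel(base.state_names, new_equations, new_rates, params,
                         dict(base.units), base.control_names)
    return model


# -- fine-tuning -----------------------------------------------------------


def _compile_plain(model: KineticModel):
    syms = [sp.Symbol(s) for s in model.state_names]
    psyms = [sp.Symbol(p) for p in model.parameters]
    eqs = model.sympy_equations(inline_rates=True, substitute_params=False)
    f = sp.lambdify(syms + psyms, [eqs[s] for s in model.state_names],
                    modules="numpy", cse=True)

    def rhs(Y, theta):
        args = [Y[..., i] for i in range(len(syms))] + list(theta)
        with np.errstate(all="ignore"):
            vals = f(*args)
        out = np.empty(Y.shape)
        for i, v in enumerate(vals):
            out[..., i] = v
        return out

    return rhs


def _rk4_trajectories(rhs, theta: np.ndarray, Y0: np.ndarray,
                      times: np.ndarray, spi: int) -> np.ndarray:
    """Fixed-step RK4 over all experiments; returns (ne, ni, ns)."""
    Y = Y0.copy()
    out = [Y0.copy()]
    for a, b in zip(times[:-1], times[1:]):
        h = (b - a) / spi
        for _ in range(spi):
            k1 = rhs(Y, theta)
            k2 = rhs(Y + h / 2 * k1, theta)
            k3 = rhs(Y + h / 2 * k2, theta)
            k4 = rhs(Y + h * k3, theta)
            Y = Y + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        out.append(Y.copy())
    return np.stack(out, axis=1)


def _drop_parameter(model: KineticModel, name: str) -> KineticModel:
    """Set a parameter to zero and simplify the terms it annihilates."""
    sub = {sp.Symbol(name): sp.Integer(0)}
    variables = list(model.state_names) + list(model.shared_rates) + \
        list(model.control_names)
    params = {k: v for k, v in model.parameters.items() if k != name}

    def conv(tree: ExpressionTree) -> ExpressionTree:
        expr = sp.cancel(sp.together(tree_to_sympy(tree).subs(sub)))
        return sympy_to_tree(expr, variables=variables, parameters=list(params))

    equations = {s: conv(t) for s, t in model.equations.items()}
    rates = {r: conv(t) for r, t in model.shared_rates.items()}
    return KineticModel(model.state_names, equations, rates, params,
                        dict(model.units), model.control_names)


def finetune(model: KineticModel, dataset: ExperimentDataset,
             config: FinetuneConfig | None = None,
             new_params: set[str] | None = None
             ) -> tuple[dict[str, float], KineticModel]:
    """Least-squares refit of all parameters with optional sparsity pruning.

    The trajectory MSE (normalized states) is minimized over θ with an L2
    penalty on the *new* parameters (default: those named ``c<k>``); any
    parameter whose removal changes the normalized fitted trajectories by
    less than ``drop_threshold`` (sup-norm) is dropped, the equations
    simplified, and the fit repeated until stable.
    """
    config = config or FinetuneConfig()
    if new_params is None:
        new_params = {p for p in model.parameters if re.fullmatch(r"c\d+", p)}
    norm = Normalization.from_dataset(dataset)
    Y0 = np.array([e.y0 for e in dataset.experiments])
    Yobs = np.array([e.observations for e in dataset.experiments])
    times = dataset.experiments[0].sample_times

    def fit_model(m: KineticModel) -> tuple[dict[str, float], float, np.ndarray]:
        rhs = _compile_plain(m)
        pnames = list(m.parameters)
        new_mask = np.array([p in new_params for p in pnames], dtype=bool)
        p0 = np.array([m.parameters[p] for p in pnames], dtype=float)
        sw = np.sqrt(config.sparsity_weight)

        def residual(p):
            traj = _rk4_trajectories(rhs, p, Y0, times,
                                     config.steps_per_interval)
            r = ((traj - Yobs) / norm.y_max).ravel()
            r = np.where(np.isfinite(r), np.clip(r, -1e6, 1e6), 1e6)
            if config.sparsity_weight > 0 and new_mask.any():
                r = np.concatenate([r, sw * p[new_mask]])
            return r

        if pnames:
            sol = least_squares(residual, p0, method="trf",
                                max_nfev=config.max_nfev, x_scale="jac",
                                ftol=config.ftol, xtol=1e-12)
            p_hat = sol.x
        else:
            p_hat = p0
        traj = _rk4_trajectories(rhs, p_hat, Y0, times,
                                 config.steps_per_interval)
        return dict(zip(pnames, map(float, p_hat))), rhs, traj

    def fit_rms(m: KineticModel) -> tuple[dict[str, float], float]:
        theta_hat, rhs, traj = fit_model(m)
        rms = float(np.sqrt(np.mean(((traj - Yobs) / norm.y_max) ** 2)))
        return theta_hat, rms

    current = model.copy()
    theta_hat, base_rms = fit_rms(current)
    current = KineticModel(current.state_names, dict(current.equations),
                           dict(current.shared_rates), theta_hat,
                           dict(current.units), current.control_names)
    if config.drop_threshold > 0:
        # a new parameter is redundant when removing it (and refitting the
        # rest) barely degrades the fit; remove one at a time, most
        # dispensable first
        for _ in range(config.max_drop_rounds):
            candidates = [p for p in current.parameters if p in new_params]
            if not candidates:
                break
            trials: list[tuple[float, str, KineticModel, dict]] = []
            for pname in candidates:
                try:
                    reduced = _drop_parameter(current, pname)
                    theta_r, rms_r = fit_rms(reduced)
                except Exception:
                    continue
                trials.append((rms_r, pname, reduced, theta_r))
            if not trials:
                break
            trials.sort(key=lambda t: t[0])
            rms_r, pname, reduced, theta_r = trials[0]
            if rms_r - base_rms >= config.drop_threshold:
                break
            current = KineticModel(reduced.state_names, dict(reduced.equations),
                                   dict(reduced.shared_rates), theta_r,
                                   dict(reduced.units), reduced.control_names)
            new_params = new_params - {pname}
            base_rms = rms_r
    return current.parameters, current


# -- pass orchestration ----------------------------------------------------


def _sr_seed(base_seed: int, pass_number: int, slot_index: int) -> int:
    return int(np.random.SeedSequence([base_seed, pass_number, slot_index])
               .generate_state(1)[0] % (2 ** 31))


def run_pass(model: KineticModel, dataset: ExperimentDataset,
             config: PipelineConfig | None = None,
             pass_number: int = 1) -> PassRecord:
    """One full pass: embed → prune → attribute → SR → substitute → finetune."""
    config = config or PipelineConfig()
    skeleton = embed(model, config.Dmax, config.treat_shared_rate_as_equation)
    slots_before = skeleton.n_active
    pruned, fit_result, trail = prune_loop(
        skeleton, dataset, config.training, config.Umax, config.Vmin)

    if pruned.n_active == 0:
        return PassRecord(pass_number, slots_before, (), {}, {}, model,
                          _model_mape(model, dataset), True,
                          prune_trail=trail, fit=fit_result, skeleton=pruned)

    # attribution on the fitted states
    states = fit_result.traj_norm.reshape(-1, len(model.state_names))
    attr = integrated_gradients(fit_result.ann, states, steps=config.ig_steps)
    weights = feature_weights(attr, fit_result.slot_indices,
                              model.state_names,
                              config.attribution_drop_threshold)

    fronts: dict[int, ParetoFront] = {}
    selected: dict[int, str] = {}
    expressions: dict[int, ExpressionTree] = {}
    for pos, j in enumerate(fit_result.slot_indices):
        allowed = weights.allowed_features(j)
        feats = {name: states[:, model.state_names.index(name)]
                 for name in allowed}
        sr_ds = SRDataset(feats, fit_result.phi_hat.reshape(-1,
                          len(fit_result.slot_indices))[:, pos],
                          pi=weights.pi_for(j))
        sr_cfg = replace(config.sr,
                         seed=_sr_seed(config.sr.seed, pass_number, j))
        front = run_sr(sr_ds, sr_cfg)
        fronts[j] = front
        top = select_top(front, 1)[0]
        selected[j] = top.text
        expressions[j] = top.expression

    try:
        candidate = substitute_and_simplify(pruned, expressions,
                                            fit_result.norm, fit_result.theta)
    except SubstitutionError:
        return PassRecord(pass_number, slots_before,
                          fit_result.slot_indices, selected, fronts, model,
                          _model_mape(model, dataset), True,
                          prune_trail=trail, attribution=weights,
                          fit=fit_result, skeleton=pruned)
    new_names = set(candidate.parameters) - set(model.parameters)
    _, tuned = finetune(candidate, dataset, config.finetune,
                        new_params=new_names)
    return PassRecord(pass_number, slots_before, fit_result.slot_indices,
                      selected, fronts, tuned, _model_mape(tuned, dataset),
                      False, prune_trail=trail, attribution=weights,
                      fit=fit_result, skeleton=pruned)


def _model_mape(model: KineticModel, dataset: ExperimentDataset,
                ceiling: float = 1000.0) -> float:
    """Fitting MAPE over the training batches; a batch the model cannot
    integrate contributes the finite failure ceiling."""
    per_batch = []
    for e in dataset.experiments:
        try:
            pred = simulate(model, e.y0, e.sample_times)
            value = mape(pred, e.observations)
            if not np.isfinite(value):
                value = ceiling
        except Exception:
            value = ceiling
        per_batch.append(min(value, ceiling))
    return float(np.mean(per_batch))


def multi_pass(model: KineticModel, dataset: ExperimentDataset,
               config: PipelineConfig | None = None,
               max_passes: int | None = None
               ) -> tuple[KineticModel, list[PassRecord]]:
    """Repeat passes until no correction survives or the structure is fixed."""
    config = config or PipelineConfig()
    max_passes = max_passes or config.max_passes
    if max_passes < 1:
        raise ValueError("max_passes must be >= 1")
    records: list[PassRecord] = []
    current = model
    for k in range(1, max_passes + 1):
        try:
            rec = run_pass(current, dataset, config, pass_number=k)
        except RuntimeError:
            # a later pass diverged (e.g. a substituted structure with a
            # near-singular denominator): keep the best model so far
            records.append(PassRecord(k, 0, (), {}, {}, current,
                                      _model_mape(current, dataset), True))
            break
        records.append(rec)
        if rec.converged:
            break
        # structural fixity: two consecutive passes agreeing means converged
        if structural_match(rec.model, current).matched:
            rec.converged = True
            current = rec.model
            break
        current = rec.model
    return current, records
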