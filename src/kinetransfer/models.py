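"""Kinetic ODE models dy/dt = f(y, θ) and structural comparison.

A :class:`KineticModel` holds one rate expression per dynamic state plus
optional named *shared rates* — auxiliary expressions (the specific growth
rate μ in the fermentation case study) referenced by several equations and
treated as extra prior knowledge during structure adaptation.

:func:`structural_match` decides whether two models have the same equation
*structure*, i.e. whether they describe the same parametric family of rate
laws.  Each model is viewed as a family over its own parameters; the test
jitters one model's parameter values (breaking accidental coincidences such
as two rate constants happening to be equal) and asks whether the other
family can reproduce it exactly at sampled state points, in *both*
directions.  Models differing only in parameter values match, as do
algebraically different but equivalent forms; an extra additive term breaks
the reverse direction and therefore the match, however small its fitted
coefficient.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import sympy as sp

from .expressions import (
    ExpressionTree,
    parse_equation,
    tree_to_sympy,
)

__all__ = ["KineticModel", "StructureDiff", "EvaluationFault", "structural_match",
           "read_model_file", "write_model_file", "loads_model", "dumps_model"]


class EvaluationFault(ArithmeticError):
    """Division by zero (or non-finite result) while evaluating a model."""


@dataclass
class KineticModel:
    """System of kinetic ODEs with named parameters and shared rate terms."""

    state_names: tuple[str, ...]
    equations: dict[str, ExpressionTree]
    shared_rates: dict[str, ExpressionTree] = field(default_factory=dict)
    parameters: dict[str, float] = field(default_factory=dict)
    units: dict[str, str] = field(default_factory=dict)
    control_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.state_names = tuple(self.state_names)
        missing = set(self.state_names) - set(self.equations)
        if missing:
            raise ValueError(f"no equation for states {sorted(missing)}")
        self._check_symbols()
        self._rate_order = self._toposort_rates()

    # -- validation --------------------------------------------------------

    def _check_symbols(self) -> None:
        allowed_vars = set(self.state_names) | set(self.control_names) | set(self.shared_rates)
        for host, tree in self.all_expressions().items():
            for node in tree.nodes():
                if node.node_kind == "variable" and node.name not in allowed_vars:
                    raise ValueError(f"undeclared variable {node.name!r} in {host}")
                if node.node_kind == "parameter" and node.name not in self.parameters:
                    raise ValueError(f"unbound parameter {node.name!r} in {host}")

    def _toposort_rates(self) -> list[str]:
        """Order shared rates so each references only earlier ones (acyclic)."""
        order: list[str] = []
        state: dict[str, int] = {}

        def visit(name: str) -> None:
            if state.get(name) == 2:
                return
            if state.get(name) == 1:
                raise ValueError(f"cyclic shared-rate reference through {name!r}")
            state[name] = 1
            for dep in self.shared_rates[name].leaf_names("variable"):
                if dep in self.shared_rates:
                    visit(dep)
            state[name] = 2
            order.append(name)

        for name in self.shared_rates:
            visit(name)
        return order

    # -- views -------------------------------------------------------------

    def all_expressions(self) -> dict[str, ExpressionTree]:
        out = dict(self.shared_rates)
        out.update(self.equations)
        return out

    def sympy_equations(self, inline_rates: bool = True,
                        substitute_params: bool = False) -> dict[str, sp.Expr]:
        """Right-hand sides as sympy expressions, optionally with shared
        rates inlined and parameter values substituted."""
        rate_exprs: dict[sp.Symbol, sp.Expr] = {}
        for name in self._rate_order:
            e = tree_to_sympy(self.shared_rates[name])
            e = e.subs(rate_exprs)
            rate_exprs[sp.Symbol(name)] = e
        out: dict[str, sp.Expr] = {}
        for s in self.state_names:
            e = tree_to_sympy(self.equations[s])
            if inline_rates:
                e = e.subs(rate_exprs)
            if substitute_params:
                e = e.subs({sp.Symbol(k): sp.Float(v) for k, v in self.parameters.items()})
            out[s] = e
        return out

    # -- evaluation --------------------------------------------------------

    def evaluate(self, state: Sequence[float] | np.ndarray,
                 controls: Mapping[str, float] | None = None) -> np.ndarray:
        """Rate vector dy/dt at one state point (shared rates computed once)."""
        state = np.asarray(state, dtype=float)
        if state.shape[-1] != len(self.state_names):
            raise ValueError("state dimension mismatch")
        env: dict[str, float | np.ndarray] = dict(self.parameters)
        for i, s in enumerate(self.state_names):
            env[s] = state[..., i]
        if controls:
            env.update(controls)
        for name in self._rate_order:
            env[name] = self.shared_rates[name].evaluate(env)
        rates = []
        with np.errstate(divide="ignore", invalid="ignore"):
            for s in self.state_names:
                r = np.asarray(self.equations[s].evaluate(env), dtype=float)
                if not np.all(np.isfinite(r)):
                    raise EvaluationFault(f"non-finite rate in equation d{s}/dt "
                                          f"(division by zero?) at state {state}")
                rates.append(r)
        return np.stack(rates, axis=-1)

    # -- misc --------------------------------------------------------------

    def copy(self) -> "KineticModel":
        return KineticModel(
            self.state_names,
            dict(self.equations),
            dict(self.shared_rates),
            dict(self.parameters),
            dict(self.units),
            self.control_names,
        )

    def content_hash(self) -> str:
        text = dumps_model(self)
        return hashlib.sha256(text.encode()).hexdigest()[:16]


# -- structural comparison -------------------------------------------------


@dataclass
class StructureDiff:
    matched: bool
    per_equation_report: list[tuple[str, bool, str]]


def _family_fit(free: KineticModel, fixed: KineticModel, points: np.ndarray,
                jitter: np.ndarray, rel_tol: float) -> np.ndarray:
    """Fit ``free``'s parameters so its RHS reproduces ``fixed``'s (with
    parameter values multiplied by ``jitter``) at the sampled states.

    Returns the per-equation relative sup-norm residual at the optimum.
    """
    from scipy.optimize import least_squares

    states = list(free.state_names)
    state_syms = [sp.Symbol(s) for s in states]

    fixed_eqs = fixed.sympy_equations(inline_rates=True, substitute_params=False)
    fixed_vals = {sp.Symbol(k): v * j
                  for (k, v), j in zip(fixed.parameters.items(), jitter)}
    targets = []
    for s in states:
        f = sp.lambdify(state_syms, fixed_eqs[s].subs(fixed_vals), modules="numpy")
        with np.errstate(all="ignore"):
            targets.append(np.broadcast_to(f(*points.T), (points.shape[0],)).astype(float))
    targets = np.array(targets)  # (ns, npts)
    scales = np.maximum(np.abs(targets).max(axis=1), 1e-9)

    pnames = list(free.parameters)
    if not pnames:
        free_funcs = [sp.lambdify(state_syms,
                                  free.sympy_equations(True, True)[s], "numpy")
                      for s in states]
        with np.errstate(all="ignore"):
            vals = np.array([np.broadcast_to(f(*points.T), (points.shape[0],))
                             for f in free_funcs], dtype=float)
        return np.abs(vals - targets).max(axis=1) / scales

    psyms = [sp.Symbol(p) for p in pnames]
    free_eqs = free.sympy_equations(inline_rates=True, substitute_params=False)
    free_funcs = [sp.lambdify(state_syms + psyms, free_eqs[s], modules="numpy")
                  for s in states]

    def residual(p):
        out = []
        with np.errstate(all="ignore"):
            for f, t, sc in zip(free_funcs, targets, scales):
                v = np.broadcast_to(f(*points.T, *p), (points.shape[0],)).astype(float)
                r = (v - t) / sc
                out.append(np.where(np.isfinite(r), r, 1e6))
        return np.concatenate(out)

    p0 = np.array([free.parameters[p] for p in pnames], dtype=float)
    rng = np.random.default_rng(12345)
    best = None
    for start in (p0, p0 * (1 + 0.2 * rng.standard_normal(len(p0))),
                  p0 * (1 + 0.5 * rng.standard_normal(len(p0)))):
        sol = least_squares(residual, start, method="lm", xtol=1e-15,
                            ftol=1e-15, gtol=1e-15, max_nfev=1200)
        res = np.abs(residual(sol.x)).reshape(len(states), -1).max(axis=1)
        if best is None or res.max() < best.max():
            best = res
        if best.max() < rel_tol:
            break
        if best.max() > 1e-2:
            # grossly different families: restarts cannot bridge four
            # orders of magnitude to the match tolerance
            break
    return best


def structural_match(candidate: KineticModel, reference: KineticModel,
                     rel_tol: float = 1e-6, seed: int = 0) -> StructureDiff:
    """Do two models describe the same parametric family of rate equations?

    The test is bidirectional: the reference's parameters are jittered (a
    few percent, seeded — this breaks accidental equalities between rate
    constants) and the candidate's parameters are refitted to reproduce it
    exactly over 50 log-uniform state points; then the roles are swapped.
    An equation matches when the fitted relative residual is below
    ``rel_tol`` in both directions.
    """
    if candidate.state_names != reference.state_names:
        raise ValueError("models must share state_names")
    rng = np.random.default_rng(seed)
    points = 10.0 ** rng.uniform(-1, 1, size=(50, len(candidate.state_names)))
    jit_ref = 1 + 0.05 * rng.standard_normal(len(reference.parameters))
    jit_cand = 1 + 0.05 * rng.standard_normal(len(candidate.parameters))

    fwd = _family_fit(candidate, reference, points, jit_ref, rel_tol)
    rev = _family_fit(reference, candidate, points, jit_cand, rel_tol)

    report: list[tuple[str, bool, str]] = []
    for i, s in enumerate(candidate.state_names):
        ok = bool(fwd[i] < rel_tol and rev[i] < rel_tol)
        text = "" if ok else (
            f"family-fit residual fwd={fwd[i]:.2e} rev={rev[i]:.2e}; "
            f"candidate d{s}/dt = "
            f"{sp.nsimplify(candidate.sympy_equations(True, True)[s], rational=True)}"
            f" vs reference d{s}/dt = "
            f"{sp.nsimplify(reference.sympy_equations(True, True)[s], rational=True)}")
        report.append((s, ok, text))
    return StructureDiff(all(ok for _, ok, _ in report), report)


# -- equation text format --------------------------------------------------
#
#   # comment
#   param mu_m = 0.1        # optional trailing unit in []
#   rate mu = mu_m*S/(S+K_S)
#   dX/dt = mu*X


def loads_model(text: str, control_names: Sequence[str] = ()) -> KineticModel:
    param_lines: list[tuple[str, float, str]] = []
    rate_lines: list[tuple[str, str]] = []
    eq_lines: list[tuple[str, str]] = []
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"line {lineno}: expected '=' in {raw!r}")
        lhs, rhs = (part.strip() for part in line.split("=", 1))
        if lhs.startswith("param "):
            name = lhs[len("param "):].strip()
            unit = ""
            if "[" in rhs:
                rhs, unit = rhs.split("[", 1)
                unit = unit.rstrip("]").strip()
            param_lines.append((name, float(rhs), unit))
        elif lhs.startswith("rate "):
            rate_lines.append((lhs[len("rate "):].strip(), rhs))
        elif lhs.startswith("d") and lhs.endswith("/dt"):
            eq_lines.append((lhs[1:-len("/dt")], rhs))
        else:
            raise ValueError(f"line {lineno}: unrecognized declaration {lhs!r}")

    state_names = tuple(s for s, _ in eq_lines)
    params = {name: value for name, value, _ in param_lines}
    units = {name: unit for name, _, unit in param_lines if unit}
    rate_names = [r for r, _ in rate_lines]
    variables = list(state_names) + list(control_names) + rate_names
    shared_rates = {name: parse_equation(src, variables, params)
                    for name, src in rate_lines}
    equations = {s: parse_equation(src, variables, params) for s, src in eq_lines}
    return KineticModel(state_names, equations, shared_rates, params, units,
                        tuple(control_names))


def dumps_model(model: KineticModel) -> str:
    lines = []
    for name, value in model.parameters.items():
        unit = model.units.get(name)
        lines.append(f"param {name} = {value!r}" + (f"  [{unit}]" if unit else ""))
    for name, tree in model.shared_rates.items():
        lines.append(f"rate {name} = {tree.serialize()}")
    for s in model.state_names:
        lines.append(f"d{s}/dt = {model.equations[s].serialize()}")
    return "\n".join(lines) + "\n"


def read_model_file(path: str | Path, control_names: Sequence[str] = ()) -> KineticModel:
    return loads_model(Path(path).read_text(), control_names)


def write_model_file(model: KineticModel, path: str | Path) -> None:
    Path(path).write_text(dumps_model(model))
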