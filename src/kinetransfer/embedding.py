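"""Automatic placement of correction slots in a kinetic model.

Structure adaptation starts by inserting indexed correction placeholders
φ_j into the source equations.  Each right-hand side is viewed through its
expression tree truncated at depth ``Dmax``:

* every *sum level* reachable within the depth budget — the top level of
  each equation, and the numerator and denominator of any quotient entered
  within the budget — receives one **multiplicative** slot per summand term
  and one trailing **additive** slot;
* a term that is itself a quotient entered by the recursion gets no slot of
  its own (the numerator slots already provide that multiplicative freedom);
* parameter-only factors inside a product share their term's slot — a slot
  on a lone constant would be unidentifiable against θ.

With the specific growth rate μ treated as a fourth equation, this places
12 slots in the Monod source model and 8 in the low-prior model at
``Dmax = 3``.  Multiplicative slots have baseline 1, additive slots baseline
0; substituting baselines restores the base model exactly.

Additive slots at the top level of a *state* equation are tagged
growth-independent (decay, maintenance, product reversal): such kinetic
contributions vanish early in a batch, which an optional regularizer can
exploit during training.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import sympy as sp

from .models import KineticModel

__all__ = ["CorrectionSlot", "HybridSkeleton", "embed", "baseline_vector"]


@dataclass(frozen=True)
class CorrectionSlot:
    """One correction placeholder φ_j at a fixed location in an equation."""

    index: int
    host: str          # state name or shared-rate name
    address: str       # human-readable tree location
    mode: str          # "multiplicative" | "additive"
    growth_independent: bool = False
    active: bool = True
    # for additive slots: symbolic characteristic scale of the host sum level
    # (see HybridSkeleton.slot_scales); None for multiplicative slots
    scale_expr: sp.Expr | None = field(default=None, compare=False, repr=False)

    @property
    def baseline(self) -> float:
        return 1.0 if self.mode == "multiplicative" else 0.0

    @property
    def symbol(self) -> sp.Symbol:
        return sp.Symbol(f"phi_{self.index}")


@dataclass
class HybridSkeleton:
    """A kinetic model with embedded correction slots.

    ``slotted_equations`` / ``slotted_rates`` mirror the base model's
    expressions but contain the sympy symbols ``phi_<j>`` of *all* slots;
    deactivated slots are substituted by their baselines on evaluation, so
    indices stay stable across pruning.
    """

    base_model: KineticModel
    slots: list[CorrectionSlot]
    Dmax: int
    slotted_equations: dict[str, sp.Expr]
    slotted_rates: dict[str, sp.Expr]

    @property
    def active_slots(self) -> list[CorrectionSlot]:
        return [s for s in self.slots if s.active]

    @property
    def n_active(self) -> int:
        return len(self.active_slots)

    def slot(self, index: int) -> CorrectionSlot:
        for s in self.slots:
            if s.index == index:
                return s
        raise KeyError(f"no slot with index {index}")

    def deactivate(self, index: int) -> None:
        for i, s in enumerate(self.slots):
            if s.index == index:
                if not s.active:
                    raise ValueError(f"slot {index} already inactive")
                self.slots[i] = replace(s, active=False)
                return
        raise KeyError(f"no slot with index {index}")

    def copy(self) -> "HybridSkeleton":
        return HybridSkeleton(self.base_model, list(self.slots), self.Dmax,
                              dict(self.slotted_equations), dict(self.slotted_rates))

    # -- expression views --------------------------------------------------

    def _baseline_subs(self, active_too: bool = False) -> dict[sp.Symbol, float]:
        return {s.symbol: s.baseline for s in self.slots
                if active_too or not s.active}

    def sympy_system(self, inline_rates: bool = True) -> dict[str, sp.Expr]:
        """Per-state RHS with active-slot symbols; inactive slots at baseline."""
        subs = self._baseline_subs()
        rates = {sp.Symbol(name): expr.subs(subs)
                 for name, expr in self.slotted_rates.items()}
        out = {}
        for s in self.base_model.state_names:
            e = self.slotted_equations[s].subs(subs)
            if inline_rates:
                e = e.subs(rates)
            out[s] = e
        return out

    def baseline_model_equations(self) -> dict[str, sp.Expr]:
        """All slots at baseline — must equal the base model exactly."""
        subs = self._baseline_subs(active_too=True)
        rates = {sp.Symbol(n): e.subs(subs) for n, e in self.slotted_rates.items()}
        return {s: self.slotted_equations[s].subs(subs).subs(rates)
                for s in self.base_model.state_names}

    def slot_scales(self, y_max: np.ndarray, t_max: float) -> np.ndarray:
        """Per-active-slot output scale σ_j, mapping corrector outputs to the
        physical equations.

        Multiplicative slots are dimensionless (σ = 1).  Additive slots live
        on the characteristic scale of their host sum level in the
        nondimensionalized system (states divided by their maxima, time by
        the batch horizon): y_max/T at the top of a state equation, 1/T at
        the top of a shared rate, and quotient numerator/denominator levels
        anchored to the denominator's magnitude at the state maxima.  A
        corrector output of O(1) then corresponds to an O(1) term in the
        normalized equations, which is the scale the variance threshold
        V_min refers to.
        """
        base = self.base_model
        env = {sp.Symbol(k): float(v) for k, v in base.parameters.items()}
        env.update({sp.Symbol(s): float(m)
                    for s, m in zip(base.state_names, y_max)})
        from .expressions import tree_to_sympy

        for name in base._rate_order:
            env[sp.Symbol(name)] = float(
                tree_to_sympy(base.shared_rates[name]).subs(env))
        env[sp.Symbol("_T")] = float(t_max)
        env.update({sp.Symbol(f"_ymax_{s}"): float(m)
                    for s, m in zip(base.state_names, y_max)})
        scales = []
        for s in self.active_slots:
            if s.mode == "multiplicative" or s.scale_expr is None:
                scales.append(1.0)
            else:
                scales.append(max(abs(float(s.scale_expr.subs(env))), 1e-9))
        return np.array(scales)

    def evaluate(self, state: np.ndarray,
                 phi_values: dict[int, float] | None = None) -> np.ndarray:
        """Rate vector at one state with given active-slot values (default
        baselines) — reference-path evaluation for tests and audits."""
        phi_values = phi_values or {}
        subs = {s.symbol: phi_values.get(s.index, s.baseline)
                for s in self.active_slots}
        eqs = self.sympy_system(inline_rates=True)
        env = {sp.Symbol(k): v for k, v in self.base_model.parameters.items()}
        env.update({sp.Symbol(n): float(v)
                    for n, v in zip(self.base_model.state_names, state)})
        return np.array([float(eqs[s].subs(subs).subs(env))
                         for s in self.base_model.state_names])


def baseline_vector(skeleton: HybridSkeleton) -> np.ndarray:
    """b_j = 1 for multiplicative, 0 for additive — over active slots in
    index order (the ANN output is trained to start from this vector)."""
    return np.array([s.baseline for s in skeleton.active_slots])


class _SlotFactory:
    def __init__(self) -> None:
        self.slots: list[CorrectionSlot] = []

    def new(self, host: str, address: str, mode: str, gi: bool = False,
            scale: sp.Expr | None = None) -> CorrectionSlot:
        slot = CorrectionSlot(len(self.slots) + 1, host, address, mode, gi,
                              scale_expr=scale)
        self.slots.append(slot)
        return slot


def _embed_sum(expr: sp.Expr, depth: int, Dmax: int, factory: _SlotFactory,
               host: str, gi_eligible: bool, address: str,
               char: sp.Expr) -> sp.Expr:
    """Slot every term of a sum level and append one additive slot.

    ``char`` is the symbolic characteristic magnitude of this sum level,
    attached to the level's additive slot as its output scale.
    """
    terms = sp.Add.make_args(expr)
    new_terms = []
    n_recursed = 0
    for ti, term in enumerate(terms):
        num, den = term.as_numer_denom()
        if den != 1 and depth + 2 <= Dmax:
            den_char = sp.Abs(den)
            new_num = _embed_sum(num, depth + 2, Dmax, factory, host, False,
                                 f"{address}.term{ti}.num", char * den_char)
            new_den = _embed_sum(den, depth + 2, Dmax, factory, host, False,
                                 f"{address}.term{ti}.den", den_char)
            new_terms.append(new_num / new_den)
            n_recursed += 1
        else:
            slot = factory.new(host, f"{address}.term{ti}", "multiplicative")
            new_terms.append(slot.symbol * term)
    # a sum level that is just one recursed quotient already has additive
    # freedom through its numerator slot — no trailing slot of its own
    if len(terms) == 1 and n_recursed == 1:
        return new_terms[0]
    add_slot = factory.new(host, f"{address}.sum", "additive",
                           gi=gi_eligible and depth == 1, scale=char)
    return sp.Add(*new_terms) + add_slot.symbol


def embed(model: KineticModel, Dmax: int = 3,
          treat_shared_rate_as_equation: bool = True) -> HybridSkeleton:
    """Place correction slots throughout ``model`` down to depth ``Dmax``.

    Shared rates are processed first (as extra equations) when flagged, then
    the state equations in declared order; slot indices follow that
    deterministic traversal.
    """
    if Dmax < 1:
        raise ValueError("Dmax must be >= 1")
    factory = _SlotFactory()
    eqs = model.sympy_equations(inline_rates=False, substitute_params=False)

    T = sp.Symbol("_T")
    slotted_rates: dict[str, sp.Expr] = {}
    for name in model.shared_rates:
        raw = _rate_expr(model, name)
        if treat_shared_rate_as_equation:
            slotted_rates[name] = _embed_sum(raw, 1, Dmax, factory, name, False,
                                             name, 1 / T)
        else:
            slotted_rates[name] = raw

    slotted_equations: dict[str, sp.Expr] = {}
    for s in model.state_names:
        slotted_equations[s] = _embed_sum(eqs[s], 1, Dmax, factory, s, True, s,
                                          sp.Symbol(f"_ymax_{s}") / T)

    return HybridSkeleton(model, factory.slots, Dmax, slotted_equations, slotted_rates)


def _rate_expr(model: KineticModel, name: str) -> sp.Expr:
    from .expressions import tree_to_sympy

    return tree_to_sympy(model.shared_rates[name])
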