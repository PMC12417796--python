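"""Attribution-weighted genetic-programming symbolic regression.

Searches expression trees over {+, -, ×, ÷}, input features and numeric
constants for a parsimonious fit to a fitted-correction dataset
(ŷ_i,e → φ̂_i,e).  Tournament selection with subtree crossover and several
mutation operators evolves the population; whenever a variable leaf is
introduced, the feature is sampled proportionally to the attribution
weights π, and features excluded by attribution never appear.  Candidates
above the complexity cap ``Cmax`` are rejected outright.

The best individual at each represented complexity forms a Pareto front;
constants of archive candidates are refined by local least squares
(Levenberg–Marquardt, multiple restarts).  Each front entry k receives the
score

    S_k = −(log L_k − log L_{k−1}) / (C_k − C_{k−1}),

the negated finite-difference slope of log-loss with respect to complexity,
which is large at the front's accuracy-per-complexity elbows.  Division by a
near-zero denominator during fitness evaluation yields a large finite
sentinel, making such candidates uncompetitive rather than crashing the
search.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
from scipy.optimize import least_squares

from .expressions import (ExpressionTree, const_node, op_node, var_node,
                          PROTECTED_DIV_SENTINEL)

__all__ = ["SRConfig", "SRDataset", "FrontEntry", "ParetoFront",
           "run_sr", "score_front", "select_top"]

_LOSS_FLOOR = 1e-12


@dataclass
class SRConfig:
    """Genetic-programming search settings."""

    population: int = 1200
    generations: int = 1000   # per island
    islands: int = 3          # independent populations, archives merged
    Cmax: int = 7
    tournament_size: int = 5
    p_crossover: float = 0.3
    p_subtree: float = 0.2
    p_point: float = 0.2
    p_insert: float = 0.1
    p_delete: float = 0.1
    p_const_jitter: float = 0.1
    p_leaf_is_variable: float = 0.7
    constant_opt_restarts: int = 3
    max_free_constants: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.Cmax < 1:
            raise ValueError("Cmax must be >= 1")
        if self.population < self.tournament_size:
            raise ValueError("population must be >= tournament size")


@dataclass
class SRDataset:
    """Input features and regression target for one correction slot."""

    features: dict[str, np.ndarray]   # only non-excluded features
    target: np.ndarray
    pi: dict[str, float] | None = None  # attribution weights over features

    def __post_init__(self) -> None:
        n = len(self.target)
        if not self.features:
            raise ValueError("at least one allowed feature is required")
        for name, col in self.features.items():
            if len(col) != n:
                raise ValueError(f"feature {name} has wrong length")

    @property
    def n_points(self) -> int:
        return len(self.target)


@dataclass
class FrontEntry:
    expression: ExpressionTree
    complexity: int
    loss: float
    score: float = 0.0

    @property
    def text(self) -> str:
        return self.expression.serialize()


@dataclass
class ParetoFront:
    """Per-complexity best expressions, complexity strictly increasing and
    loss non-increasing along the front."""

    entries: list[FrontEntry]

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)


# -- random expression machinery -------------------------------------------


class _Sampler:
    def __init__(self, feature_names: list[str], pi: np.ndarray,
                 config: SRConfig, rng: np.random.Generator):
        self.features = feature_names
        self.pi = pi
        self.config = config
        self.rng = rng

    def variable(self) -> ExpressionTree:
        i = self.rng.choice(len(self.features), p=self.pi)
        return var_node(self.features[i])

    def leaf(self) -> ExpressionTree:
        if self.rng.random() < self.config.p_leaf_is_variable:
            return self.variable()
        return const_node(round(float(self.rng.normal(0, 1)), 4) or 1.0)

    def operator(self) -> str:
        return ("+", "-", "*", "/")[self.rng.integers(4)]

    def tree(self, budget: int) -> ExpressionTree:
        """Random tree with complexity <= budget (>= 1)."""
        if budget < 3 or self.rng.random() < 0.3:
            return self.leaf()
        left_budget = int(self.rng.integers(1, budget - 1))
        right_budget = budget - 1 - left_budget
        return op_node(self.operator(), self.tree(left_budget),
                       self.tree(right_budget))


def _evaluate_loss(tree: ExpressionTree, dataset: SRDataset) -> float:
    with np.errstate(all="ignore"):
        pred = tree.evaluate(dataset.features, protected=True)
    pred = np.broadcast_to(np.asarray(pred, dtype=float), dataset.target.shape)
    if not np.all(np.isfinite(pred)) or np.any(np.abs(pred) >= PROTECTED_DIV_SENTINEL):
        return float("inf")
    return float(np.mean((pred - dataset.target) ** 2))


def _constant_paths(tree: ExpressionTree) -> list[tuple[int, ...]]:
    return [p for p in tree.paths() if tree.at(p).node_kind == "constant"]


def _fold_constants(tree: ExpressionTree) -> ExpressionTree:
    """Collapse variable-free subtrees into single constant leaves, so a
    candidate's complexity measures its structure rather than how its
    constants happen to be spelled (e.g. ``(0.16 + -0.26)*X`` → ``-0.1*X``)."""
    if not tree.children:
        return tree
    folded = ExpressionTree(tree.node_kind, tree.operator_symbol,
                            tuple(_fold_constants(c) for c in tree.children),
                            tree.name, tree.value)
    if all(n.node_kind == "constant" for n in folded.nodes()
           if not n.children):
        try:
            value = folded.evaluate({})
        except Exception:
            return folded
        if np.isfinite(value):
            return const_node(float(value))
    return folded


def _with_constants(tree: ExpressionTree, paths, values) -> ExpressionTree:
    for p, v in zip(paths, values):
        tree = tree.replace_at(p, const_node(float(v)))
    return tree


def _optimize_constants(tree: ExpressionTree, dataset: SRDataset,
                        config: SRConfig, rng: np.random.Generator
                        ) -> tuple[ExpressionTree, float]:
    """Local least-squares refinement of a candidate's numeric constants."""
    paths = _constant_paths(tree)
    if not paths or len(paths) > config.max_free_constants:
        return tree, _evaluate_loss(tree, dataset)
    x0 = np.array([tree.at(p).value for p in paths], dtype=float)

    def residual(c):
        t = _with_constants(tree, paths, c)
        with np.errstate(all="ignore"):
            pred = t.evaluate(dataset.features, protected=True)
        pred = np.broadcast_to(np.asarray(pred, dtype=float),
                               dataset.target.shape)
        r = pred - dataset.target
        return np.where(np.isfinite(r), np.clip(r, -1e6, 1e6), 1e6)

    best_tree, best_loss = tree, _evaluate_loss(tree, dataset)
    starts = [x0]
    for _ in range(max(0, config.constant_opt_restarts - 1)):
        starts.append(x0 * (1 + rng.normal(0, 0.5, x0.shape)) +
                      rng.normal(0, 0.1, x0.shape))
    for start in starts:
        try:
            sol = least_squares(residual, start, method="lm", max_nfev=200)
        except Exception:
            continue
        cand = _with_constants(tree, paths, sol.x)
        loss = _evaluate_loss(cand, dataset)
        if loss < best_loss:
            best_tree, best_loss = cand, loss
    return best_tree, best_loss


# -- mutation / crossover --------------------------------------------------


def _mutate(tree: ExpressionTree, sampler: _Sampler, Cmax: int) -> ExpressionTree:
    rng = sampler.rng
    cfg = sampler.config
    r = rng.random()
    paths = tree.paths()
    path = paths[rng.integers(len(paths))]
    node = tree.at(path)

    p_sub = cfg.p_subtree
    p_point = p_sub + cfg.p_point
    p_ins = p_point + cfg.p_insert
    p_del = p_ins + cfg.p_delete
    total = p_del + cfg.p_const_jitter

    r *= total
    if r < p_sub:
        budget = Cmax - (tree.complexity - node.complexity)
        return tree.replace_at(path, sampler.tree(max(1, budget)))
    if r < p_point:
        if node.node_kind == "operator":
            new = op_node(sampler.operator(), *node.children)
        else:
            new = sampler.leaf()
        return tree.replace_at(path, new)
    if r < p_ins:
        if tree.complexity + 2 > Cmax:
            return tree.replace_at(path, sampler.leaf())
        wrapped = (op_node(sampler.operator(), node, sampler.leaf())
                   if rng.random() < 0.5
                   else op_node(sampler.operator(), sampler.leaf(), node))
        return tree.replace_at(path, wrapped)
    if r < p_del:
        op_paths = [p for p in paths if tree.at(p).node_kind == "operator"]
        if not op_paths:
            return sampler.leaf()
        p = op_paths[rng.integers(len(op_paths))]
        child = tree.at(p).children[rng.integers(2)]
        return tree.replace_at(p, child)
    # constant jitter
    c_paths = _constant_paths(tree)
    if not c_paths:
        return tree.replace_at(path, sampler.leaf())
    p = c_paths[rng.integers(len(c_paths))]
    value = tree.at(p).value * (1 + rng.normal(0, 0.3)) + rng.normal(0, 0.05)
    return tree.replace_at(p, const_node(value))


def _crossover(a: ExpressionTree, b: ExpressionTree,
               rng: np.random.Generator, Cmax: int) -> ExpressionTree:
    for _ in range(8):
        pa = a.paths()[rng.integers(len(a.paths()))]
        pb = b.paths()[rng.integers(len(b.paths()))]
        child = a.replace_at(pa, b.at(pb))
        if child.complexity <= Cmax:
            return child
    return a


# -- the evolutionary loop -------------------------------------------------


def run_sr(dataset: SRDataset, config: SRConfig | None = None) -> ParetoFront:
    """Evolve ``config.islands`` independent populations against ``dataset``
    and return the merged Pareto front.

    Separate islands guard against premature convergence of any single
    population onto one structural basin.  Deterministic for a fixed
    ``config.seed``.
    """
    config = config or SRConfig()
    merged: dict[int, tuple[float, ExpressionTree]] = {}
    for island in range(max(1, config.islands)):
        rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, island]))
        archive = _evolve(dataset, config, rng)
        for c, (loss, tree) in archive.items():
            if c not in merged or loss < merged[c][0]:
                merged[c] = (loss, tree)

    entries: list[FrontEntry] = []
    best = float("inf")
    for c in sorted(merged):
        loss, tree = merged[c]
        if loss < best:
            entries.append(FrontEntry(tree, c, loss))
            best = loss
    front = ParetoFront(entries)
    score_front(front)
    return front


def _evolve(dataset: SRDataset, config: SRConfig,
            rng: np.random.Generator) -> dict:
    """One steady-state GP population; returns its per-complexity archive."""
    feature_names = list(dataset.features)
    if dataset.pi:
        raw = np.array([max(dataset.pi.get(f, 0.0), 0.0) for f in feature_names])
        pi = raw / raw.sum() if raw.sum() > 0 else np.full(len(feature_names),
                                                           1 / len(feature_names))
    else:
        pi = np.full(len(feature_names), 1 / len(feature_names))
    sampler = _Sampler(feature_names, pi, config, rng)

    # archive: complexity -> (loss, tree), maintained with constants refined
    archive: dict[int, tuple[float, ExpressionTree]] = {}
    loss_cache: dict[str, float] = {}
    # every structurally new candidate (constants masked) gets one constant
    # refinement, however poor its raw constants — otherwise good structures
    # born with bad constants never displace entrenched archive entries
    struct_cache: dict[str, float] = {}

    def loss_of(tree: ExpressionTree) -> float:
        key = tree.serialize()
        if key not in loss_cache:
            loss_cache[key] = _evaluate_loss(tree, dataset)
        return loss_cache[key]

    def signature(tree: ExpressionTree) -> str:
        parts = []
        for node in tree.nodes():
            if node.node_kind == "operator":
                parts.append(node.operator_symbol)
            elif node.node_kind == "constant":
                parts.append("C")
            else:
                parts.append(node.name)
        return " ".join(parts)

    best_overall = [float("inf")]

    def consider(tree: ExpressionTree, loss: float) -> None:
        tree = _fold_constants(tree)
        c = tree.complexity
        if c > config.Cmax:
            return
        sig = signature(tree)
        best_known = struct_cache.get(sig)
        should_refine = (best_known is None or
                         (np.isfinite(loss) and loss < 0.8 * best_known))
        # a brand-new structure whose raw loss is hopeless relative to the
        # best candidate so far is parked, not refined; a later copy with
        # better constants re-opens it (loss < 0.8x the recorded value)
        if (should_refine and best_known is None and
                np.isfinite(best_overall[0]) and
                not (loss < 100 * best_overall[0] or loss < 1e-4)):
            struct_cache[sig] = loss if np.isfinite(loss) else 1e18
            should_refine = False
        if should_refine:
            refined, rloss = _optimize_constants(tree, dataset, config, rng)
            if rloss <= loss or not np.isfinite(loss):
                tree, loss = refined, rloss
            struct_cache[sig] = min(loss, np.inf if best_known is None
                                    else best_known)
        if not np.isfinite(loss):
            return
        if c not in archive or loss < archive[c][0]:
            archive[c] = (loss, tree)
            best_overall[0] = min(best_overall[0], loss)

    population: list[ExpressionTree] = []
    losses: list[float] = []
    for _ in range(config.population):
        t = sampler.tree(config.Cmax)
        population.append(t)
        l = loss_of(t)
        losses.append(l)
        consider(t, l)

    def tournament() -> int:
        idx = rng.integers(0, len(population), size=config.tournament_size)
        return int(min(idx, key=lambda i: losses[i]))

    for _ in range(config.generations):
        # one generation = population-many steady-state offspring steps
        for _ in range(config.population):
            parent = tournament()
            if rng.random() < config.p_crossover:
                other = tournament()
                child = _crossover(population[parent], population[other], rng,
                                   config.Cmax)
            else:
                child = _mutate(population[parent], sampler, config.Cmax)
            if child.complexity > config.Cmax:
                continue
            l = loss_of(child)
            consider(child, l)
            # child replaces the worst member of a second tournament
            idx = rng.integers(0, len(population), size=config.tournament_size)
            worst = int(max(idx, key=lambda i: losses[i]))
            if l <= losses[worst]:
                population[worst] = child
                losses[worst] = l

    return archive


def score_front(front: ParetoFront) -> list[float]:
    """Assign S_k scores in place and return them.

    The simplest entry gets S = 0 (no finite-difference neighbor); zero
    losses are floored at 1e-12 before taking logarithms.
    """
    scores = []
    for k, entry in enumerate(front.entries):
        if k == 0:
            entry.score = 0.0
        else:
            prev = front.entries[k - 1]
            dlog = (np.log(max(entry.loss, _LOSS_FLOOR)) -
                    np.log(max(prev.loss, _LOSS_FLOOR)))
            entry.score = float(-dlog / (entry.complexity - prev.complexity))
        scores.append(entry.score)
    return scores


def select_top(front: ParetoFront, count: int = 2) -> list[FrontEntry]:
    """The ``count`` highest-scoring entries (ties favor lower complexity)."""
    if not front.entries:
        raise ValueError("empty Pareto front")
    ranked = sorted(front.entries, key=lambda e: (-e.score, e.complexity))
    return ranked[:count]
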