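"""Symbolic expression trees for kinetic rate equations.

Expressions are binary trees over the operator set {+, -, *, /} with three
leaf kinds: state/control variables, named kinetic parameters, and numeric
constants.  The node count of a tree is its *complexity* — the currency used
throughout the package to cap and score symbolic-regression candidates
(every operator, variable, parameter and constant occurrence counts once).

The module deliberately keeps its own lightweight tree type rather than
using :mod:`sympy` expressions directly: genetic-programming mutation needs
stable, addressable nodes and a complexity measure that counts *occurrences*,
while sympy auto-simplifies (``x - x`` → ``0``) and shares subexpressions.
Conversion to and from sympy is provided for simplification, compilation and
canonical comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import sympy as sp

__all__ = [
    "ExpressionTree",
    "ParseError",
    "op_node",
    "var_node",
    "param_node",
    "const_node",
    "parse_equation",
    "complexity",
    "tree_to_sympy",
    "sympy_to_tree",
]

_OPERATORS = ("+", "-", "*", "/")

#: sentinel returned by protected division (see evaluate(..., protected=True))
PROTECTED_DIV_SENTINEL = 1e12
_DIV_EPS = 1e-9


class ParseError(ValueError):
    """Raised for syntax errors or undeclared symbols, with position info."""


@dataclass(frozen=True)
class ExpressionTree:
    """A node in a binary expression tree.

    ``node_kind`` is one of ``"operator"``, ``"variable"``, ``"parameter"``,
    ``"constant"``.  Operator nodes have exactly two children; leaves none.
    """

    node_kind: str
    operator_symbol: str | None = None
    children: tuple["ExpressionTree", ...] = ()
    name: str | None = None
    value: float | None = None

    def __post_init__(self) -> None:
        if self.node_kind == "operator":
            if self.operator_symbol not in _OPERATORS:
                raise ValueError(f"unknown operator {self.operator_symbol!r}")
            if len(self.children) != 2:
                raise ValueError("operator nodes take exactly 2 children")
        elif self.node_kind in ("variable", "parameter"):
            if not self.name:
                raise ValueError(f"{self.node_kind} leaf needs a name")
            if self.children:
                raise ValueError("leaves have no children")
        elif self.node_kind == "constant":
            if self.value is None or not np.isfinite(self.value):
                raise ValueError("constant leaf needs a finite value")
            if self.children:
                raise ValueError("leaves have no children")
        else:
            raise ValueError(f"unknown node kind {self.node_kind!r}")

    # -- structure ---------------------------------------------------------

    @property
    def complexity(self) -> int:
        """Total node count: operators + variables + parameters + constants."""
        return 1 + sum(c.complexity for c in self.children)

    def nodes(self) -> Iterator["ExpressionTree"]:
        """Pre-order iteration over all nodes."""
        yield self
        for child in self.children:
            yield from child.nodes()

    def leaf_names(self, kind: str | None = None) -> set[str]:
        out: set[str] = set()
        for n in self.nodes():
            if n.name is not None and (kind is None or n.node_kind == kind):
                out.add(n.name)
        return out

    # -- evaluation --------------------------------------------------------

    def evaluate(
        self,
        env: Mapping[str, "np.ndarray | float"],
        protected: bool = False,
    ):
        """Numerically evaluate the tree.

        ``env`` maps every variable and parameter name to a scalar or array.
        With ``protected=True`` a division whose denominator has magnitude
        below 1e-9 yields a large finite sentinel instead of inf/nan (the
        convention used inside the genetic-programming fitness loop).
        """
        if self.node_kind == "constant":
            return self.value
        if self.node_kind in ("variable", "parameter"):
            try:
                return env[self.name]
            except KeyError:
                raise KeyError(f"no value bound for symbol {self.name!r}") from None
        a = self.children[0].evaluate(env, protected)
        b = self.children[1].evaluate(env, protected)
        op = self.operator_symbol
        if op == "+":
            return a + b
        if op == "-":
            return a - b
        if op == "*":
            return a * b
        # division
        if protected:
            b_arr = np.asarray(b, dtype=float)
            small = np.abs(b_arr) < _DIV_EPS
            if np.any(small):
                safe = np.where(small, 1.0, b_arr)
                with np.errstate(all="ignore"):
                    out = np.asarray(a, dtype=float) / safe
                return np.where(small, PROTECTED_DIV_SENTINEL, out)
        with np.errstate(all="ignore"):
            return a / b
        raise AssertionError

    # -- serialization -----------------------------------------------------

    def serialize(self) -> str:
        """Infix text form; round-trips through :func:`parse_equation`."""
        return _serialize(self, parent_prec=0, right_side=False)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.serialize()

    # -- editing helpers (used by symbolic regression) ---------------------

    def replace_at(self, path: tuple[int, ...], new: "ExpressionTree") -> "ExpressionTree":
        """Return a copy with the node at ``path`` (child indices) replaced."""
        if not path:
            return new
        i = path[0]
        children = list(self.children)
        children[i] = children[i].replace_at(path[1:], new)
        return ExpressionTree(
            self.node_kind, self.operator_symbol, tuple(children), self.name, self.value
        )

    def paths(self) -> list[tuple[int, ...]]:
        """All node addresses (root = ())."""
        out: list[tuple[int, ...]] = [()]
        for i, child in enumerate(self.children):
            out.extend((i,) + p for p in child.paths())
        return out

    def at(self, path: tuple[int, ...]) -> "ExpressionTree":
        node = self
        for i in path:
            node = node.children[i]
        return node


# -- constructors ----------------------------------------------------------


def op_node(symbol: str, left: ExpressionTree, right: ExpressionTree) -> ExpressionTree:
    return ExpressionTree("operator", symbol, (left, right))


def var_node(name: str) -> ExpressionTree:
    return ExpressionTree("variable", name=name)


def param_node(name: str) -> ExpressionTree:
    return ExpressionTree("parameter", name=name)


def const_node(value: float) -> ExpressionTree:
    return ExpressionTree("constant", value=float(value))


def complexity(tree: ExpressionTree) -> int:
    """Node count of ``tree`` (free-function alias of the property)."""
    return tree.complexity


# -- serialization internals ----------------------------------------------

_PREC = {"+": 1, "-": 1, "*": 2, "/": 2}


def _serialize(node: ExpressionTree, parent_prec: int, right_side: bool) -> str:
    if node.node_kind == "constant":
        v = node.value
        text = repr(float(v))
        if v < 0:
            # keep unary-minus-free grammar: wrap in parens when embedded
            return f"({text})" if parent_prec > 0 else text
        return text
    if node.node_kind in ("variable", "parameter"):
        return node.name  # type: ignore[return-value]
    op = node.operator_symbol
    prec = _PREC[op]
    left = _serialize(node.children[0], prec, False)
    right = _serialize(node.children[1], prec + (1 if op in ("-", "/") else 0), True)
    text = f"{left} {op} {right}" if prec == 1 else f"{left}{op}{right}"
    need_parens = prec < parent_prec or (right_side and prec == parent_prec)
    return f"({text})" if need_parens else text


# -- parser ----------------------------------------------------------------


@dataclass
class _Token:
    kind: str  # "name" | "number" | "op" | "lparen" | "rparen" | "end"
    text: str
    pos: int


def _tokenize(text: str) -> list[_Token]:
    tokens: list[_Token] = []
    i, n = 0, len(text)
    while i < n:
        ch = text[i]
        if ch.isspace():
            i += 1
            continue
        if ch in "+-*/":
            tokens.append(_Token("op", ch, i))
            i += 1
        elif ch == "(":
            tokens.append(_Token("lparen", ch, i))
            i += 1
        elif ch == ")":
            tokens.append(_Token("rparen", ch, i))
            i += 1
        elif ch.isdigit() or ch == ".":
            j = i
            while j < n and (text[j].isdigit() or text[j] in ".eE" or
                             (text[j] in "+-" and j > i and text[j - 1] in "eE")):
                j += 1
            tokens.append(_Token("number", text[i:j], i))
            i = j
        elif ch.isalpha() or ch == "_":
            j = i
            while j < n and (text[j].isalnum() or text[j] == "_"):
                j += 1
            tokens.append(_Token("name", text[i:j], i))
            i = j
        else:
            raise ParseError(f"unexpected character {ch!r} at position {i}")
    tokens.append(_Token("end", "", n))
    return tokens


class _Parser:
    """Recursive-descent parser for +,-,*,/ infix with named symbols.

    Unary minus is desugared to ``(0 - x)`` so operator arity stays 2.
    """

    def __init__(self, tokens: list[_Token], variables: set[str], parameters: set[str]):
        self.tokens = tokens
        self.k = 0
        self.variables = variables
        self.parameters = parameters

    def peek(self) -> _Token:
        return self.tokens[self.k]

    def take(self) -> _Token:
        tok = self.tokens[self.k]
        self.k += 1
        return tok

    def parse(self) -> ExpressionTree:
        tree = self.expr()
        tok = self.peek()
        if tok.kind != "end":
            raise ParseError(f"unexpected {tok.text!r} at position {tok.pos}")
        return tree

    def expr(self) -> ExpressionTree:
        tok = self.peek()
        if tok.kind == "op" and tok.text in "+-":
            self.take()
            operand = self.term()
            node = operand if tok.text == "+" else op_node("-", const_node(0.0), operand)
        else:
            node = self.term()
        while self.peek().kind == "op" and self.peek().text in "+-":
            op = self.take().text
            node = op_node(op, node, self.term())
        return node

    def term(self) -> ExpressionTree:
        node = self.factor()
        while self.peek().kind == "op" and self.peek().text in "*/":
            op = self.take().text
            node = op_node(op, node, self.factor())
        return node

    def factor(self) -> ExpressionTree:
        tok = self.take()
        if tok.kind == "number":
            try:
                return const_node(float(tok.text))
            except ValueError:
                raise ParseError(f"bad numeric literal {tok.text!r} at position {tok.pos}")
        if tok.kind == "name":
            if tok.text in self.variables:
                return var_node(tok.text)
            if tok.text in self.parameters:
                return param_node(tok.text)
            raise ParseError(f"undeclared symbol {tok.text!r} at position {tok.pos}")
        if tok.kind == "lparen":
            node = self.expr()
            closing = self.take()
            if closing.kind != "rparen":
                raise ParseError(f"expected ')' at position {closing.pos}")
            return node
        if tok.kind == "op" and tok.text == "-":
            # nested unary minus, e.g. "--x" or "a*-b"
            return op_node("-", const_node(0.0), self.factor())
        raise ParseError(f"unexpected {tok.text or 'end of input'!r} at position {tok.pos}")


def parse_equation(
    text: str,
    variables: Sequence[str] = (),
    parameters: Sequence[str] = (),
) -> ExpressionTree:
    """Parse an infix rate expression into an :class:`ExpressionTree`.

    Only ``+ - * /``, parentheses, numeric literals and the declared names
    are accepted; anything else raises :class:`ParseError` naming the
    offending token and its character position.
    """
    return _Parser(_tokenize(text), set(variables), set(parameters)).parse()


# -- sympy bridge ----------------------------------------------------------


def tree_to_sympy(tree: ExpressionTree, symbols: Mapping[str, sp.Symbol] | None = None) -> sp.Expr:
    """Convert to a sympy expression (division kept exact, no evaluation tricks)."""

    def conv(node: ExpressionTree) -> sp.Expr:
        if node.node_kind == "constant":
            return sp.Float(node.value)
        if node.node_kind in ("variable", "parameter"):
            if symbols is not None and node.name in symbols:
                return symbols[node.name]
            return sp.Symbol(node.name)
        a, b = (conv(c) for c in node.children)
        return {"+": lambda: a + b, "-": lambda: a - b,
                "*": lambda: a * b, "/": lambda: a / b}[node.operator_symbol]()

    return conv(tree)


def sympy_to_tree(
    expr: sp.Expr,
    variables: Sequence[str] = (),
    parameters: Sequence[str] = (),
) -> ExpressionTree:
    """Convert a rational sympy expression back into an expression tree.

    Integer powers are unrolled into repeated multiplication/division; any
    other function raises ``ValueError`` (the operator set is {+,-,*,/}).
    """
    variables = set(variables)
    parameters = set(parameters)

    def leaf(name: str) -> ExpressionTree:
        if name in variables:
            return var_node(name)
        if name in parameters:
            return param_node(name)
        # default: treat unknown symbols as parameters (caller registers them)
        return param_node(name)

    def conv(e: sp.Expr) -> ExpressionTree:
        if e.is_Symbol:
            return leaf(e.name)
        if e.is_Number:
            return const_node(float(e))
        if e.is_Add:
            args = [conv(a) for a in e.args]
            node = args[0]
            for a in args[1:]:
                node = op_node("+", node, a)
            return node
        if e.is_Mul:
            num_parts: list[ExpressionTree] = []
            den_parts: list[ExpressionTree] = []
            for a in e.args:
                if a.is_Pow and a.exp.is_Integer and a.exp < 0:
                    den_parts.append(conv(sp.Pow(a.base, -a.exp)))
                else:
                    num_parts.append(conv(a))
            if not num_parts:
                num_parts = [const_node(1.0)]
            node = num_parts[0]
            for a in num_parts[1:]:
                node = op_node("*", node, a)
            for d in den_parts:
                node = op_node("/", node, d)
            return node
        if e.is_Pow:
            if not e.exp.is_Integer:
                raise ValueError(f"non-integer power not in operator set: {e}")
            k = int(e.exp)
            base = conv(e.base)
            if k == 0:
                return const_node(1.0)
            node = base
            for _ in range(abs(k) - 1):
                node = op_node("*", node, base)
            if k < 0:
                node = op_node("/", const_node(1.0), node)
            return node
        raise ValueError(f"cannot convert {e!r} to {{+,-,*,/}} expression tree")

    return conv(sp.sympify(expr))
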