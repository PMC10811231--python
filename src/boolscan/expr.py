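"""Boolean update-rule expressions.

Rules over {AND, OR, NOT}, node references and the constants 0/1.  These are
the target functions of a granularity-1 qualitative network: every expression
evaluates to 0 or 1 for any 0/1 assignment of its referenced nodes.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Iterator, Mapping


class BoolExpr:
    """Base class for Boolean rule expressions (immutable)."""

    __slots__ = ()

    def evaluate(self, env: Mapping[str, int]) -> int:
        raise NotImplementedError

    def refs(self) -> frozenset[str]:
        """Names of all nodes referenced by this expression."""
        raise NotImplementedError

    def __and__(self, other: "BoolExpr") -> "BoolExpr":
        return And((self, other))

    def __or__(self, other: "BoolExpr") -> "BoolExpr":
        return Or((self, other))

    def __invert__(self) -> "BoolExpr":
        return Not(self)


@dataclass(frozen=True, slots=True)
class Const(BoolExpr):
    value: int

    def __post_init__(self) -> None:
        if self.value not in (0, 1):
            raise ValueError(f"Boolean constant must be 0 or 1, got {self.value}")

    def evaluate(self, env: Mapping[str, int]) -> int:
        return self.value

    def refs(self) -> frozenset[str]:
        return frozenset()

    def __repr__(self) -> str:
        return str(self.value)


@dataclass(frozen=True, slots=True)
class Var(BoolExpr):
    name: str

    def evaluate(self, env: Mapping[str, int]) -> int:
        return env[self.name]

    def refs(self) -> frozenset[str]:
        return frozenset((self.name,))

    def __repr__(self) -> str:
        return self.name


@dataclass(frozen=True, slots=True)
class Not(BoolExpr):
    arg: BoolExpr

    def evaluate(self, env: Mapping[str, int]) -> int:
        return 1 - self.arg.evaluate(env)

    def refs(self) -> frozenset[str]:
        return self.arg.refs()

    def __repr__(self) -> str:
        return f"NOT {self.arg!r}" if isinstance(self.arg, (Var, Const)) else f"NOT ({self.arg!r})"


@dataclass(frozen=True, slots=True)
class And(BoolExpr):
    args: tuple[BoolExpr, ...]

    def __post_init__(self) -> None:
        if len(self.args) < 2:
            raise ValueError("AND needs at least two operands")

    def evaluate(self, env: Mapping[str, int]) -> int:
        for a in self.args:
            if a.evaluate(env) == 0:
                return 0
        return 1

    def refs(self) -> frozenset[str]:
        return frozenset().union(*(a.refs() for a in self.args))

    def __repr__(self) -> str:
        return "(" + " AND ".join(repr(a) for a in self.args) + ")"


@dataclass(frozen=True, slots=True)
class Or(BoolExpr):
    args: tuple[BoolExpr, ...]

    def __post_init__(self) -> None:
        if len(self.args) < 2:
            raise ValueError("OR needs at least two operands")

    def evaluate(self, env: Mapping[str, int]) -> int:
        for a in self.args:
            if a.evaluate(env) == 1:
                return 1
        return 0

    def refs(self) -> frozenset[str]:
        return frozenset().union(*(a.refs() for a in self.args))

    def __repr__(self) -> str:
        return "(" + " OR ".join(repr(a) for a in self.args) + ")"


def and_all(args: list[BoolExpr]) -> BoolExpr:
    """Conjunction of ``args``, collapsing the 0/1-operand cases."""
    if not args:
        return Const(1)
    if len(args) == 1:
        return args[0]
    return And(tuple(args))


def or_all(args: list[BoolExpr]) -> BoolExpr:
    if not args:
        return Const(0)
    if len(args) == 1:
        return args[0]
    return Or(tuple(args))


def truth_table(expr: BoolExpr, names: list[str] | None = None) -> list[int]:
    """Exhaustive truth table of ``expr`` over ``names`` (sorted refs by default).

    Row i assigns bit j of i to the j-th name (little-endian).  Used by the
    round-trip tests and by semantic rule comparison; guarded at 16 variables.
    """
    if names is None:
        names = sorted(expr.refs())
    if len(names) > 16:
        raise ValueError(f"truth table over {len(names)} variables refused")
    rows = []
    for i in range(1 << len(names)):
        env = {name: (i >> j) & 1 for j, name in enumerate(names)}
        rows.append(expr.evaluate(env))
    return rows


def semantically_equal(a: BoolExpr, b: BoolExpr) -> bool:
    names = sorted(a.refs() | b.refs())
    return truth_table(a, names) == truth_table(b, names)


def iter_subexpressions(expr: BoolExpr) -> Iterator[BoolExpr]:
    yield expr
    if isinstance(expr, Not):
        yield from iter_subexpressions(expr.arg)
    elif isinstance(expr, (And, Or)):
        for a in expr.args:
            yield from iter_subexpressions(a)


def eval_over_sets(expr: BoolExpr, sets: Mapping[str, frozenset[int]],
                   exact_limit: int = 12) -> frozenset[int]:
    """Possible values of ``expr`` when each referenced node ranges over a set.

    Exact image (product enumeration) when the expression references at most
    ``exact_limit`` nodes; otherwise a compositional abstract evaluation, which
    is a sound superset of the exact image (it ignores correlations between
    repeated references, e.g. A AND NOT A abstracts to {0,1}).
    """
    names = sorted(expr.refs())
    if len(names) <= exact_limit:
        multi = [n for n in names if len(sets[n]) > 1]
        single = {n: next(iter(sets[n])) for n in names if len(sets[n]) == 1}
        out = set()
        for bits in product((0, 1), repeat=len(multi)):
            env = dict(single)
            env.update(zip(multi, bits))
            out.add(expr.evaluate(env))
            if len(out) == 2:
                break
        return frozenset(out)
    return _abstract_eval(expr, sets)


def _abstract_eval(expr: BoolExpr, sets: Mapping[str, frozenset[int]]) -> frozenset[int]:
    if isinstance(expr, Const):
        return frozenset((expr.value,))
    if isinstance(expr, Var):
        return sets[expr.name]
    if isinstance(expr, Not):
        return frozenset(1 - v for v in _abstract_eval(expr.arg, sets))
    if isinstance(expr, And):
        out = {1}
        for a in expr.args:
            s = _abstract_eval(a, sets)
            out = {x & y for x in out for y in s}
        return frozenset(out)
    if isinstance(expr, Or):
        out = {0}
        for a in expr.args:
            s = _abstract_eval(a, sets)
            out = {x | y for x in out for y in s}
        return frozenset(out)
    raise TypeError(f"unknown expression node {type(expr).__name__}")
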