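"""Synchronous dynamics and the two-phase stability proof.

All nodes update simultaneously: the successor of a state assigns to every
non-input node the value of its rule evaluated on the *previous* state, while
input nodes keep their externally clamped values.  The long-run behaviour per
input condition is established in two phases, the way qualitative-network
stability provers work:

1. **Range reduction** — each node's possible value set is narrowed
   iteratively from {0,1} to the image of its rule over its regulators'
   current sets, starting from the clamped input singletons.  If every set
   collapses to a singleton, that vector is the unique attractor and the
   model is stable under these inputs.
2. **Cycle search** — otherwise the (small) reduced space, which provably
   contains every attractor state and is closed under the update map, is
   enumerated exhaustively when it fits the search budget: the model is
   stable iff its functional graph has exactly one fixed point and no cycle
   of length >= 2.  Beyond the budget a seeded simulation fallback can still
   disprove stability (by exhibiting a cycle or a second fixed point) but
   returns ``inconclusive`` rather than guessing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Mapping

from .errors import IncompleteAssignmentError, NonterminationError
from .expr import eval_over_sets
from .model import BooleanModel, State

#: Seed of the pseudo-random stream used by the simulation fallback of
#: :func:`prove_stability`; fixed so runs are reproducible.
FALLBACK_SEED = 0x1D872B41

STATUS_STABLE = "stable"
STATUS_NOT_STABLE = "not_stable"
STATUS_INCONCLUSIVE = "inconclusive"


@dataclass(frozen=True)
class Attractor:
    """A steady state (one state) or a simple cycle (>= 2 states)."""

    kind: str  # "steady" | "cyclic"
    states: tuple[State, ...]
    input_valuation: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("steady", "cyclic"):
            raise ValueError(f"unknown attractor kind {self.kind!r}")
        if self.kind == "steady" and len(self.states) != 1:
            raise ValueError("steady attractor must hold exactly one state")
        if self.kind == "cyclic" and len(self.states) < 2:
            raise ValueError("cyclic attractor must hold at least two states")
        object.__setattr__(self, "input_valuation", dict(self.input_valuation))

    def __len__(self) -> int:
        return len(self.states)


@dataclass(frozen=True)
class StabilityResult:
    status: str
    steady_state: State | None = None
    witness_cycle: Attractor | None = None
    fixed_points: tuple[State, ...] = ()
    reduced_ranges: Mapping[str, frozenset[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "reduced_ranges", dict(self.reduced_ranges))

    @property
    def multiple_fixed_points(self) -> bool:
        return self.status == STATUS_NOT_STABLE and len(self.fixed_points) > 1


def _full_valuation(model: BooleanModel, inputs: Mapping[str, int]) -> dict[str, int]:
    missing = set(model.input_names) - set(inputs)
    if missing:
        raise IncompleteAssignmentError(f"inputs without a value: {sorted(missing)}")
    return {k: int(inputs[k]) for k in model.input_names}


def sync_step(model: BooleanModel, state: State, inputs: Mapping[str, int]) -> State:
    """One synchronous update: all rules applied to the previous state."""
    valuation = _full_valuation(model, inputs)
    env = dict(zip(model.node_names, state))
    out = []
    for node in model.nodes:
        if node.kind == "input" or node.name not in model.rules:
            out.append(valuation[node.name])
        else:
            out.append(model.rules[node.name].evaluate(env))
    return tuple(out)


def default_max_steps(model: BooleanModel) -> int:
    """Step cap for knockout time courses: 2 x node count + 10."""
    return 2 * len(model.nodes) + 10


def simulate(model: BooleanModel, initial_state: State, inputs: Mapping[str, int],
             max_steps: int | None = None) -> tuple[list[State], Attractor]:
    """Iterate sync_step until a state repeats; return trajectory + attractor.

    The trajectory includes the repeated occurrence, so a fixed-point start
    yields a length-2 trajectory.  A repeat of the immediately preceding
    state is a steady attractor; otherwise the segment between the two
    occurrences is a cyclic attractor.
    """
    if max_steps is None:
        max_steps = default_max_steps(model)
    if max_steps < 1:
        raise ValueError("max_steps must be >= 1")
    valuation = _full_valuation(model, inputs)
    seen: dict[State, int] = {initial_state: 0}
    trajectory: list[State] = [initial_state]
    state = initial_state
    for _ in range(max_steps):
        state = sync_step(model, state, valuation)
        trajectory.append(state)
        if state in seen:
            first = seen[state]
            cycle = tuple(trajectory[first:-1])
            kind = "steady" if len(cycle) == 1 else "cyclic"
            return trajectory, Attractor(kind=kind, states=cycle,
                                         input_valuation=valuation)
        seen[state] = len(trajectory) - 1
    raise NonterminationError(
        f"no state repeated within {max_steps} steps (state space not exhausted)"
    )


def trajectory_rows(model: BooleanModel, trajectory: list[State]) -> list[tuple[int, str, int]]:
    """(step, node, value) rows for time-course TSV export."""
    return [(t, name, value)
            for t, state in enumerate(trajectory)
            for name, value in zip(model.node_names, state)]


def range_reduction(model: BooleanModel,
                    inputs: Mapping[str, int]) -> dict[str, frozenset[int]]:
    """Narrow every node's value set to a fixpoint of the rule images.

    Inputs start (and stay) at their clamped singleton; every other node
    starts at {0,1} and is repeatedly replaced by the image of its rule over
    the product of its regulators' current sets.  The result is closed under
    the synchronous update map and contains every attractor state, hence is a
    conservative superset of each node's long-run reachable values.
    """
    valuation = _full_valuation(model, inputs)
    sets: dict[str, frozenset[int]] = {}
    for node in model.nodes:
        if node.name in model.rules:
            sets[node.name] = frozenset((0, 1))
        else:
            sets[node.name] = frozenset((valuation[node.name],))
    changed = True
    while changed:
        changed = False
        for target, expr in model.rules.items():
            new = eval_over_sets(expr, sets)
            if new != sets[target]:
                sets[target] = new
                changed = True
    return sets


def _reduced_space_attractors(model: BooleanModel, valuation: Mapping[str, int],
                              ranges: Mapping[str, frozenset[int]]
                              ) -> tuple[list[State], list[tuple[State, ...]]]:
    """Exact fixed points and cycles of the update map over the reduced space."""
    names = model.node_names
    unresolved = [n for n in names if len(ranges[n]) > 1]
    base = {n: next(iter(ranges[n])) for n in names if len(ranges[n]) == 1}

    states: list[State] = []
    for bits in product((0, 1), repeat=len(unresolved)):
        env = dict(base)
        env.update(zip(unresolved, bits))
        states.append(tuple(env[n] for n in names))

    succ = {s: sync_step(model, s, valuation) for s in states}
    fixed = [s for s in states if succ[s] == s]

    cycles: list[tuple[State, ...]] = []
    color: dict[State, int] = {}  # 0 in-progress path, 1 done
    for start in states:
        path: list[State] = []
        s = start
        while s not in color:
            color[s] = 0
            path.append(s)
            s = succ[s]
        if color[s] == 0:  # found a new cycle; s is on the current path
            i = path.index(s)
            cyc = tuple(path[i:])
            if len(cyc) >= 2:
                cycles.append(cyc)
        for p in path:
            color[p] = 1
    return fixed, cycles


def prove_stability(model: BooleanModel, inputs: Mapping[str, int],
                    search_budget: int = 1 << 16) -> StabilityResult:
    """Two-phase stability proof for one fully valued input condition."""
    valuation = _full_valuation(model, inputs)
    ranges = range_reduction(model, valuation)
    unresolved = [n for n in model.node_names if len(ranges[n]) > 1]

    if not unresolved:
        steady = tuple(next(iter(ranges[n])) for n in model.node_names)
        assert sync_step(model, steady, valuation) == steady
        return StabilityResult(status=STATUS_STABLE, steady_state=steady,
                               fixed_points=(steady,), reduced_ranges=ranges)

    if (1 << len(unresolved)) <= search_budget:
        fixed, cycles = _reduced_space_attractors(model, valuation, ranges)
        if cycles:
            witness = Attractor(kind="cyclic", states=cycles[0],
                                input_valuation=valuation)
            return StabilityResult(status=STATUS_NOT_STABLE, witness_cycle=witness,
                                   fixed_points=tuple(fixed), reduced_ranges=ranges)
        if len(fixed) != 1:
            # a finite functional graph with no >=2-cycle has >=1 fixed point,
            # so this branch means multiple steady states
            return StabilityResult(status=STATUS_NOT_STABLE,
                                   fixed_points=tuple(fixed), reduced_ranges=ranges)
        steady = fixed[0]
        assert sync_step(model, steady, valuation) == steady
        return StabilityResult(status=STATUS_STABLE, steady_state=steady,
                               fixed_points=(steady,), reduced_ranges=ranges)

    # fallback: seeded simulations can disprove stability but not prove it
    import numpy as np

    rng = np.random.default_rng(FALLBACK_SEED)
    names = model.node_names
    base = {n: next(iter(ranges[n])) for n in names if len(ranges[n]) == 1}
    n_seeds = max(8, min(256, search_budget // max(1, 2 * len(names))))
    found_fixed: set[State] = set()
    for _ in range(n_seeds):
        env = dict(base)
        for n in unresolved:
            env[n] = int(rng.integers(0, 2))
        start = tuple(env[n] for n in names)
        try:
            _, att = simulate(model, start, valuation,
                              max_steps=4 * len(names) + 16)
        except NonterminationError:
            continue
        if att.kind == "cyclic":
            return StabilityResult(status=STATUS_NOT_STABLE, witness_cycle=att,
                                   reduced_ranges=ranges)
        found_fixed.add(att.states[0])
        if len(found_fixed) > 1:
            return StabilityResult(status=STATUS_NOT_STABLE,
                                   fixed_points=tuple(sorted(found_fixed)),
                                   reduced_ranges=ranges)
    return StabilityResult(status=STATUS_INCONCLUSIVE,
                           fixed_points=tuple(sorted(found_fixed)),
                           reduced_ranges=ranges)
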