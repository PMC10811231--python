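"""Synthetic fixtures and independent oracles.

Everything here exists so the scan/calibration/knockout pipeline can be
exercised and verified without downloading any published model:

* seeded random Boolean models (optionally acyclic) with default-logic rules,
* a brute-force attractor oracle that enumerates the full synchronous
  transition graph (exact fixed points and cycles, guarded at 20 nodes),
* planted observation vectors for calibration-recovery tests,
* a hand-built ~20-node toy macrophage model that mimics the naming
  conventions of curated inflammation maps (``_M1_macrophage`` /
  ``_signal`` phenotype suffixes), with an NF-kB-like hub whose knockout
  flips apoptosis on and proliferation off, and a JAK-like redundant pair
  whose double knockout is synergistic.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Mapping, Sequence

import numpy as np

from .calibration import ObservationVector
from .dynamics import sync_step
from .errors import GenerationError
from .expr import BoolExpr, Const, Not, Var, and_all, or_all
from .model import BooleanModel, Node, State, classify_nodes


@dataclass(frozen=True, slots=True)
class FixtureSpec:
    n_internal: int
    n_inputs: int
    max_in_degree: int = 3
    acyclic: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_internal < 1 or self.n_inputs < 0 or self.max_in_degree < 1:
            raise GenerationError(
                "need n_internal >= 1, n_inputs >= 0, max_in_degree >= 1"
            )


def random_boolean_model(spec: FixtureSpec) -> BooleanModel:
    """Seeded random model with default-logic rules; pure function of spec.

    Internal node ``k`` draws 1..max_in_degree distinct signed regulators —
    from earlier nodes only when ``acyclic`` (giving a DAG), from any node
    otherwise.  Rules follow the default-logic construction: (OR of
    activators) AND NOT (OR of inhibitors).  An acyclic node whose allowed
    pool is empty (no inputs) gets a constant rule.
    """
    rng = np.random.default_rng(spec.seed)
    input_names = [f"I{j:02d}" for j in range(spec.n_inputs)]
    internal_names = [f"N{j:02d}" for j in range(spec.n_internal)]
    all_names = input_names + internal_names

    rules: dict[str, BoolExpr] = {}
    for k, target in enumerate(internal_names):
        pool = input_names + internal_names[:k] if spec.acyclic else all_names
        if not pool:
            rules[target] = Const(int(rng.integers(0, 2)))
            continue
        d = int(rng.integers(1, min(spec.max_in_degree, len(pool)) + 1))
        regulators = [pool[i] for i in rng.choice(len(pool), size=d, replace=False)]
        signs = rng.integers(0, 2, size=d)  # 1 = activator
        acts = [Var(r) for r, s in zip(regulators, signs) if s == 1]
        inhs = [Var(r) for r, s in zip(regulators, signs) if s == 0]
        if acts and inhs:
            rules[target] = and_all([or_all(acts), Not(or_all(inhs))])
        elif acts:
            rules[target] = or_all(acts)
        else:
            rules[target] = Not(or_all(inhs))
    nodes = tuple(
        Node(name=n, kind="input" if n in input_names else "internal")
        for n in all_names
    )
    return BooleanModel(nodes=nodes, rules=rules,
                        name=f"random_s{spec.seed}")


ORACLE_NODE_GUARD = 20


def brute_force_attractors(model: BooleanModel, inputs: Mapping[str, int]
                           ) -> tuple[list[State], list[tuple[State, ...]]]:
    """Exact attractors by enumerating all 2^n states of the non-input nodes.

    Returns (fixed points, cycles).  Each cycle is reported once, rotated to
    start at its lexicographically smallest state.  This is the independent
    oracle the stability prover is tested against; refuse above
    ``ORACLE_NODE_GUARD`` non-input nodes.
    """
    free_nodes = [n for n in model.node_names if n in model.rules]
    if len(free_nodes) > ORACLE_NODE_GUARD:
        raise GenerationError(
            f"oracle refuses {len(free_nodes)} non-input nodes (> {ORACLE_NODE_GUARD})"
        )
    names = model.node_names
    clamped = {n: int(inputs[n]) for n in model.input_names}

    states: list[State] = []
    for bits in product((0, 1), repeat=len(free_nodes)):
        env = dict(clamped)
        env.update(zip(free_nodes, bits))
        states.append(tuple(env[n] for n in names))

    succ = {s: sync_step(model, s, clamped) for s in states}
    fixed = [s for s in states if succ[s] == s]

    cycles: list[tuple[State, ...]] = []
    color: dict[State, int] = {}
    for start in states:
        path, s = [], start
        while s not in color:
            color[s] = 0
            path.append(s)
            s = succ[s]
        if color[s] == 0:
            i = path.index(s)
            cyc = path[i:]
            if len(cyc) >= 2:
                j = cyc.index(min(cyc))
                cycles.append(tuple(cyc[j:] + cyc[:j]))
        for p in path:
            color[p] = 1
    return fixed, cycles


def plant_observation(model: BooleanModel, steady_state: State, n_flips: int,
                      seed: int = 0) -> ObservationVector:
    """Observation equal to a verified fixed point except at n seeded flips."""
    if not 0 <= n_flips <= len(model.nodes):
        raise ValueError("n_flips out of range")
    inputs = {n: steady_state[i] for n, i in model.index.items()
              if n in model.input_names}
    if sync_step(model, steady_state, inputs) != steady_state:
        raise ValueError("steady_state is not a fixed point of the model")
    rng = np.random.default_rng(seed)
    flip_at = set(rng.choice(len(model.nodes), size=n_flips, replace=False).tolist()) \
        if n_flips else set()
    values = {
        name: (1 - steady_state[i]) if i in flip_at else steady_state[i]
        for i, name in enumerate(model.node_names)
    }
    return ObservationVector(values=values,
                             provenance={k: "expression" for k in values})


# ---------------------------------------------------------------------------
# toy macrophage fixture
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ToyMacrophageFixture:
    model: BooleanModel
    observation: ObservationVector
    phenotype_constraint: Mapping[str, int]
    targets: tuple[str, ...]
    hub: str
    synergy_pair: tuple[str, str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "phenotype_constraint",
                           dict(self.phenotype_constraint))


def toy_macrophage_fixture() -> ToyMacrophageFixture:
    """Miniature pro-inflammatory macrophage model for end-to-end tests.

    Five environmental inputs (LPS, TNFa, IFNG, a growth factor and IL10)
    drive receptor -> kinase -> transcription-factor chains into four
    phenotype nodes.  The model is acyclic, so every one of the 2^5 input
    combinations has a unique steady state.  NFkB is the hub: its knockout
    turns apoptosis on (via loss of BCL2) and proliferation off.  JAK1/JAK2
    redundantly relay IFNG to STAT1, so only their *double* knockout
    silences the TNF-release signal — the fixture's synergy pair.
    """
    V = Var
    rules: dict[str, BoolExpr] = {
        "TLR4": V("LPS"),
        "TNFR": V("TNFa"),
        "IFNGR": V("IFNG"),
        "GFR": V("GF"),
        "IL10R": V("IL10"),
        "NFkB": V("TLR4") | V("TNFR"),
        "JAK1": V("IFNGR"),
        "JAK2": V("IFNGR"),
        "STAT1": V("JAK1") | V("JAK2"),
        "ERK": V("GFR"),
        "MYC": V("ERK"),
        "STAT3": V("IL10R"),
        "BCL2": V("NFkB"),
        "CASP3": ~V("BCL2"),
        "Apoptosis_M1_macrophage": V("CASP3"),
        "Proliferation_M1_macrophage": and_all([V("NFkB"), V("MYC"),
                                                ~V("STAT3")]),
        "TNF_release_signal": V("STAT1"),
        "Inflammation_signal": V("NFkB") | V("STAT1"),
    }
    input_names = ("GF", "IFNG", "IL10", "LPS", "TNFa")
    order = input_names + tuple(rules)
    nodes = tuple(Node(name=n, kind="input" if n in input_names else "internal")
                  for n in order)
    model = BooleanModel(nodes=nodes, rules=rules, name="toy_macrophage_m1")
    model = classify_nodes(model, cell_suffixes=["_M1_macrophage"],
                           signal_suffix="_signal")

    observation = ObservationVector(
        values={"NFkB": 1, "TNFR": 1, "STAT1": 1, "MYC": 1, "CASP3": 0},
        provenance={"NFkB": "literature", "STAT1": "literature",
                    "TNFR": "expression", "MYC": "expression",
                    "CASP3": "expression"},
    )
    constraint = {"Apoptosis_M1_macrophage": 0, "Proliferation_M1_macrophage": 1}
    targets = ("NFkB", "JAK1", "JAK2", "ERK", "BCL2")
    return ToyMacrophageFixture(model=model, observation=observation,
                                phenotype_constraint=constraint,
                                targets=targets, hub="NFkB",
                                synergy_pair=("JAK1", "JAK2"))


def verify_against_oracle(model: BooleanModel, inputs: Mapping[str, int],
                          search_budget: int = 1 << 16) -> bool:
    """Does the stability prover agree exactly with brute-force enumeration?

    Agreement means: same stable/not-stable verdict, identical fixed-point
    set, matching steady state when stable, and a cycle witness exactly when
    the functional graph has a cycle.  Inconclusive never counts as agreeing.
    """
    from .dynamics import STATUS_NOT_STABLE, STATUS_STABLE, prove_stability

    fixed, cycles = brute_force_attractors(model, inputs)
    result = prove_stability(model, inputs, search_budget=search_budget)
    oracle_stable = len(fixed) == 1 and not cycles
    if result.status == STATUS_STABLE:
        return oracle_stable and result.steady_state == fixed[0]
    if result.status == STATUS_NOT_STABLE:
        if oracle_stable:
            return False
        if (result.witness_cycle is not None) != bool(cycles):
            return False
        return result.witness_cycle is not None or \
            set(result.fixed_points) == set(fixed)
    return False  # inconclusive


def oracle_agreement(n_models: int = 100, base_seed: int = 0,
                     n_inputs: int = 2) -> tuple[int, int]:
    """(agreeing, total) input conditions over a seeded family of models.

    Model sizes cycle over 4..12 internal nodes and alternate between acyclic
    and feedback-rich wiring; every input combination of every model is
    checked against the brute-force oracle.
    """
    agree = total = 0
    for i in range(n_models):
        spec = FixtureSpec(n_internal=4 + (i % 9), n_inputs=n_inputs,
                           max_in_degree=3, acyclic=(i % 2 == 0),
                           seed=base_seed + i)
        model = random_boolean_model(spec)
        for bits in product((0, 1), repeat=n_inputs):
            inputs = dict(zip(model.input_names, bits))
            total += 1
            agree += verify_against_oracle(model, inputs)
    return agree, total


def dag_steady_state(model: BooleanModel, inputs: Mapping[str, int]) -> State:
    """Closed-form steady state of an acyclic model: topological evaluation."""
    import networkx as nx

    if not model.is_acyclic():
        raise ValueError("model has feedback; no topological closed form")
    env = {n: int(inputs[n]) for n in model.input_names}
    for name in nx.topological_sort(model.dependency_graph()):
        if name in model.rules:
            env[name] = model.rules[name].evaluate(env)
    return tuple(env[n] for n in model.node_names)
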