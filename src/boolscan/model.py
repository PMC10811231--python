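"""Domain types for granularity-1 logical models.

A :class:`BooleanModel` is an ordered set of nodes plus one update rule per
non-input node.  Input nodes (no regulators) carry the environmental
condition; phenotype nodes are readout nodes named by convention with a
cell-specific suffix (e.g. ``_M1_macrophage``) or a tissue-level ``_signal``
suffix, mirroring how curated signalling maps label their outcome nodes.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .errors import (
    AmbiguousPhenotypeError,
    ConflictError,
    DanglingReferenceError,
    ModelLookupError,
)
from .expr import BoolExpr, Const, Not, Var, and_all, or_all

#: A model state: 0/1 values aligned to the model's node order.
State = tuple[int, ...]

NODE_KINDS = ("input", "internal", "phenotype")
PHENOTYPE_CLASSES = ("cell_specific", "signal", "none")


@dataclass(frozen=True, slots=True)
class Node:
    name: str
    kind: str = "internal"
    phenotype_class: str = "none"
    annotations: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("node name must be non-empty")
        if self.kind not in NODE_KINDS:
            raise ValueError(f"unknown node kind {self.kind!r}")
        if self.phenotype_class not in PHENOTYPE_CLASSES:
            raise ValueError(f"unknown phenotype class {self.phenotype_class!r}")
        if self.phenotype_class != "none" and self.kind != "phenotype":
            raise ValueError(
                f"{self.name}: phenotype_class={self.phenotype_class} on kind={self.kind}"
            )

    def annotation(self, key: str) -> str | None:
        for k, v in self.annotations:
            if k == key:
                return v
        return None


@dataclass(frozen=True)
class BooleanModel:
    """Nodes, rules and metadata of a Boolean (granularity-1) network."""

    nodes: tuple[Node, ...]
    rules: Mapping[str, BoolExpr]
    name: str = "model"
    granularity: int = 1

    def __post_init__(self) -> None:
        if self.granularity != 1:
            raise ValueError("only granularity-1 (Boolean) models are supported")
        names = [n.name for n in self.nodes]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate node names: {dup}")
        name_set = set(names)
        for target, expr in self.rules.items():
            if target not in name_set:
                raise DanglingReferenceError(f"rule target {target!r} is not a node")
            missing = expr.refs() - name_set
            if missing:
                raise DanglingReferenceError(
                    f"rule for {target!r} references missing nodes {sorted(missing)}"
                )
        ruled = set(self.rules)
        for n in self.nodes:
            if (n.kind == "input") and (n.name in ruled):
                raise ValueError(f"input node {n.name!r} must not have a rule")
            if (n.kind != "input") and (n.name not in ruled):
                raise ValueError(f"non-input node {n.name!r} has no rule")
        object.__setattr__(self, "rules", dict(self.rules))

    # -- lookups ----------------------------------------------------------
    @property
    def node_names(self) -> tuple[str, ...]:
        return tuple(n.name for n in self.nodes)

    @property
    def index(self) -> dict[str, int]:
        return {n.name: i for i, n in enumerate(self.nodes)}

    @property
    def input_names(self) -> tuple[str, ...]:
        return tuple(n.name for n in self.nodes if n.kind == "input")

    @property
    def phenotype_names(self) -> tuple[str, ...]:
        return tuple(n.name for n in self.nodes if n.kind == "phenotype")

    def node(self, name: str) -> Node:
        for n in self.nodes:
            if n.name == name:
                return n
        raise ModelLookupError(f"no node named {name!r}")

    def regulators(self, name: str) -> frozenset[str]:
        expr = self.rules.get(name)
        return expr.refs() if expr is not None else frozenset()

    def dependency_graph(self) -> nx.DiGraph:
        """Directed regulator -> target graph over all nodes."""
        g = nx.DiGraph()
        g.add_nodes_from(self.node_names)
        for target, expr in self.rules.items():
            for src in expr.refs():
                g.add_edge(src, target)
        return g

    def is_acyclic(self) -> bool:
        return nx.is_directed_acyclic_graph(self.dependency_graph())

    def content_hash(self) -> str:
        """Stable hash of names, kinds and rule reprs; keys scan checkpoints."""
        h = hashlib.sha256()
        for n in self.nodes:
            h.update(f"{n.name}\x00{n.kind}\x00".encode())
        for target in sorted(self.rules):
            h.update(f"{target}\x01{self.rules[target]!r}\x00".encode())
        return h.hexdigest()[:16]

    # -- state helpers ----------------------------------------------------
    def state_from_dict(self, values: Mapping[str, int]) -> State:
        missing = set(self.node_names) - set(values)
        if missing:
            raise ModelLookupError(f"state missing values for {sorted(missing)}")
        return tuple(int(values[n]) for n in self.node_names)

    def state_to_dict(self, state: State) -> dict[str, int]:
        return dict(zip(self.node_names, state))


@dataclass(frozen=True)
class InputAssignment:
    """Partition of a model's inputs into clamped (``fixed``) and free."""

    fixed: Mapping[str, int]
    free: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "fixed", dict(self.fixed))
        overlap = set(self.fixed) & set(self.free)
        if overlap:
            raise ValueError(f"inputs both fixed and free: {sorted(overlap)}")
        bad = {k: v for k, v in self.fixed.items() if v not in (0, 1)}
        if bad:
            raise ValueError(f"non-Boolean fixed values: {bad}")

    @classmethod
    def for_model(cls, model: BooleanModel, fixed: Mapping[str, int]) -> "InputAssignment":
        from .errors import AssignmentError

        inputs = set(model.input_names)
        bad = set(fixed) - inputs
        if bad:
            raise AssignmentError(f"fixed keys are not input nodes: {sorted(bad)}")
        free = tuple(sorted(inputs - set(fixed)))
        return cls(fixed=dict(fixed), free=free)

    @property
    def all_inputs(self) -> frozenset[str]:
        return frozenset(self.fixed) | frozenset(self.free)


# ---------------------------------------------------------------------------
# node classification and model surgery
# ---------------------------------------------------------------------------

def classify_nodes(model: BooleanModel, cell_suffixes: Sequence[str],
                   signal_suffix: str = "_signal") -> BooleanModel:
    """Re-derive every node's kind from the model structure and name suffixes.

    Nodes whose names end with a cell-specific suffix become cell-specific
    phenotypes; the signal suffix marks tissue-level signal phenotypes; nodes
    with no regulators are inputs; everything else is internal.
    """
    if not cell_suffixes or not signal_suffix:
        raise ValueError("suffix lists must be non-empty")
    new_nodes = []
    for n in model.nodes:
        is_cell = any(n.name.endswith(s) for s in cell_suffixes)
        is_signal = n.name.endswith(signal_suffix)
        if is_cell and is_signal:
            raise AmbiguousPhenotypeError(
                f"{n.name!r} matches both a cell suffix and the signal suffix"
            )
        if is_cell:
            kind, pc = "phenotype", "cell_specific"
        elif is_signal:
            kind, pc = "phenotype", "signal"
        elif n.name not in model.rules:
            kind, pc = "input", "none"
        else:
            kind, pc = "internal", "none"
        new_nodes.append(replace(n, kind=kind, phenotype_class=pc))
    return BooleanModel(nodes=tuple(new_nodes), rules=model.rules,
                        name=model.name, granularity=model.granularity)


@dataclass(frozen=True)
class RemovalReport:
    removed_nodes: tuple[str, ...]
    removed_inputs: tuple[str, ...]

    @property
    def n_removed(self) -> int:
        return len(self.removed_nodes)

    @property
    def n_removed_inputs(self) -> int:
        return len(self.removed_inputs)


def restrict_to_upstream(model: BooleanModel,
                         phenotype_names: Sequence[str]) -> tuple[BooleanModel, RemovalReport]:
    """Induced sub-model on the ancestor closure of the given phenotypes.

    Keeps exactly the phenotypes and every node with a directed path to one of
    them, so every retained rule is closed over the retained node set.  Inputs
    that fed only removed nodes are removed with them and itemised in the
    report (they cannot influence the retained dynamics).
    """
    name_set = set(model.node_names)
    unknown = set(phenotype_names) - name_set
    if unknown:
        raise ModelLookupError(f"unknown phenotype names: {sorted(unknown)}")
    g = model.dependency_graph()
    keep: set[str] = set(phenotype_names)
    for p in phenotype_names:
        keep |= nx.ancestors(g, p)
    kept_nodes = tuple(n for n in model.nodes if n.name in keep)
    kept_rules = {t: e for t, e in model.rules.items() if t in keep}
    removed = tuple(n.name for n in model.nodes if n.name not in keep)
    removed_inputs = tuple(n.name for n in model.nodes
                           if n.name not in keep and n.kind == "input")
    sub = BooleanModel(nodes=kept_nodes, rules=kept_rules,
                       name=model.name, granularity=model.granularity)
    return sub, RemovalReport(removed_nodes=removed, removed_inputs=removed_inputs)


def infer_default_rules(signed_graph: Iterable[tuple[str, str, str]],
                        name: str = "model") -> BooleanModel:
    """Build a model from a signed interaction list with default logic.

    Each regulated node gets ``(OR of activators) AND NOT (OR of inhibitors)``;
    a node with only inhibitors gets ``NOT (OR of inhibitors)``; unregulated
    nodes are inputs.  This mirrors the default-rule convention of automatic
    map-to-model converters and is meant for fixture generation — curated
    models may use other logic for co-regulated nodes.
    """
    activators: dict[str, list[str]] = {}
    inhibitors: dict[str, list[str]] = {}
    names: dict[str, None] = {}  # insertion-ordered set
    seen: dict[tuple[str, str], str] = {}
    for src, dst, sign in signed_graph:
        if sign not in ("activator", "inhibitor"):
            raise ValueError(f"edge sign must be activator/inhibitor, got {sign!r}")
        prev = seen.get((src, dst))
        if prev is not None and prev != sign:
            raise ConflictError(f"edge {src}->{dst} listed as both {prev} and {sign}")
        seen[(src, dst)] = sign
        names.setdefault(src)
        names.setdefault(dst)
        if prev is None:
            (activators if sign == "activator" else inhibitors).setdefault(dst, []).append(src)

    rules: dict[str, BoolExpr] = {}
    for target in names:
        acts = activators.get(target, [])
        inhs = inhibitors.get(target, [])
        if not acts and not inhs:
            continue
        act_expr = or_all([Var(a) for a in acts])
        if acts and inhs:
            rules[target] = and_all([act_expr, Not(or_all([Var(i) for i in inhs]))])
        elif acts:
            rules[target] = act_expr
        else:
            rules[target] = Not(or_all([Var(i) for i in inhs]))
    nodes = tuple(
        Node(name=n, kind="internal" if n in rules else "input") for n in names
    )
    return BooleanModel(nodes=nodes, rules=rules, name=name)


def model_summary_rows(model: BooleanModel) -> list[tuple[str, str, int]]:
    """(node, kind, in-degree) rows for the model-summary TSV."""
    return [(n.name, n.kind, len(model.regulators(n.name))) for n in model.nodes]


def constant_rule(value: int) -> BoolExpr:
    return Const(value)
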