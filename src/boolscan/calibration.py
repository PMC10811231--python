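"""Model calibration against discretized expression evidence.

Differential-expression evidence (up in disease -> 1, down -> 0) and curated
literature observations are merged into a Boolean observation vector over a
subset of nodes.  Steady states surviving the phenotype filter are scored
against this vector with the simple matching coefficient

    S = (N00 + N11) / (N00 + N11 + N10 + N01)

where N00/N11 count agreeing zeros/ones and N10/N01 count disagreements,
over the observed nodes resolvable to model nodes.  The per-node mean over
the top-scoring states is the calibrated state; nodes constant across those
states are "fixed", the rest carry intermediate means.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ConflictError, EmptyComparisonError, ModelLookupError
from .model import BooleanModel, State

PROVENANCES = ("literature", "expression", "both")


@dataclass(frozen=True, slots=True)
class DEGRecord:
    """One differential-expression row: gene, log2 fold-change, adjusted p."""

    gene: str
    logFC: float
    adjP: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.adjP <= 1.0:
            raise ValueError(f"{self.gene}: adjusted p-value {self.adjP} outside [0, 1]")


@dataclass(frozen=True)
class ObservationVector:
    """Boolean observed values for a node subset, with per-entry provenance."""

    values: Mapping[str, int]
    provenance: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        values = {k: int(v) for k, v in self.values.items()}
        bad = {k: v for k, v in values.items() if v not in (0, 1)}
        if bad:
            raise ValueError(f"non-Boolean observed values: {bad}")
        prov = {k: self.provenance.get(k, "literature") for k in values}
        unknown = sorted(set(prov.values()) - set(PROVENANCES))
        if unknown:
            raise ValueError(f"unknown provenance labels: {unknown}")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "provenance", prov)

    def __len__(self) -> int:
        return len(self.values)

    def resolve(self, model: BooleanModel,
                name_map: Mapping[str, str] | None = None
                ) -> tuple[dict[str, int], list[str]]:
        """Map observation keys onto model nodes; quarantine the unresolvable.

        ``name_map`` translates observation names (e.g. gene symbols) to model
        node names before matching.
        """
        known = set(model.node_names)
        resolved: dict[str, int] = {}
        quarantined: list[str] = []
        for key, value in self.values.items():
            node = (name_map or {}).get(key, key)
            if node in known:
                resolved[node] = value
            else:
                quarantined.append(key)
        return resolved, quarantined


def discretize_deg_table(records: Iterable[DEGRecord], p_threshold: float = 0.05,
                         strict: bool = True) -> ObservationVector:
    """Discretize differential expression: significant up -> 1, down -> 0.

    Genes failing the adjusted-p threshold, or with logFC exactly 0, are
    excluded.  The threshold comparison is strict (<) by default; pass
    ``strict=False`` for <=.
    """
    if not 0.0 < p_threshold < 1.0:
        raise ValueError("p_threshold must lie in (0, 1)")
    values: dict[str, int] = {}
    conflicts: set[str] = set()
    for rec in records:
        passes = rec.adjP < p_threshold if strict else rec.adjP <= p_threshold
        if not passes or rec.logFC == 0.0:
            continue
        value = 1 if rec.logFC > 0 else 0
        if rec.gene in values and values[rec.gene] != value:
            conflicts.add(rec.gene)
        values[rec.gene] = value
    if conflicts:
        raise ConflictError(
            f"genes with conflicting discretized values: {sorted(conflicts)}"
        )
    return ObservationVector(values=values,
                             provenance={g: "expression" for g in values})


MERGE_POLICIES = ("error", "literature_wins", "expression_wins")


def merge_observations(literature: ObservationVector, expression: ObservationVector,
                       policy: str = "error") -> ObservationVector:
    """Union the two evidence sources; agreeing duplicates get provenance 'both'."""
    if policy not in MERGE_POLICIES:
        raise ValueError(f"unknown merge policy {policy!r}")
    values = dict(literature.values)
    prov = {k: "literature" for k in values}
    disagreements = []
    for key, value in expression.values.items():
        if key not in values:
            values[key] = value
            prov[key] = "expression"
        elif values[key] == value:
            prov[key] = "both"
        else:
            disagreements.append(key)
            if policy == "expression_wins":
                values[key] = value
                prov[key] = "expression"
            # literature_wins keeps the existing entry
    if disagreements and policy == "error":
        raise ConflictError(
            f"literature and expression disagree on: {sorted(disagreements)}"
        )
    return ObservationVector(values=values, provenance=prov)


def filter_by_phenotype(states: Sequence[State], model: BooleanModel,
                        constraint: Mapping[str, int]) -> list[State]:
    """Keep the states whose constrained phenotype nodes all match."""
    index = model.index
    unknown = set(constraint) - set(index)
    if unknown:
        raise ModelLookupError(f"unknown phenotype nodes: {sorted(unknown)}")
    positions = [(index[name], int(value)) for name, value in constraint.items()]
    return [s for s in states if all(s[pos] == v for pos, v in positions)]


@dataclass(frozen=True, slots=True)
class SimilarityScore:
    S: float
    N00: int
    N01: int
    N10: int
    N11: int

    @property
    def n_compared(self) -> int:
        return self.N00 + self.N01 + self.N10 + self.N11


def similarity(state: State, observation: ObservationVector, model: BooleanModel,
               name_map: Mapping[str, str] | None = None) -> SimilarityScore:
    """Simple matching coefficient between a steady state and the observations."""
    resolved, _ = observation.resolve(model, name_map)
    if not resolved:
        raise EmptyComparisonError("no observation key resolves to a model node")
    index = model.index
    n00 = n01 = n10 = n11 = 0
    for node, observed in resolved.items():
        actual = state[index[node]]
        if actual == 0 and observed == 0:
            n00 += 1
        elif actual == 1 and observed == 1:
            n11 += 1
        elif actual == 1 and observed == 0:
            n10 += 1
        else:
            n01 += 1
    return SimilarityScore(S=(n00 + n11) / (n00 + n01 + n10 + n11),
                           N00=n00, N01=n01, N10=n10, N11=n11)


def select_top(states: Sequence[State], observation: ObservationVector,
               model: BooleanModel, name_map: Mapping[str, str] | None = None
               ) -> tuple[float, list[State]]:
    """All states achieving the maximum similarity score (ties kept)."""
    if not states:
        raise ValueError("select_top needs at least one state")
    scores = [similarity(s, observation, model, name_map).S for s in states]
    best = max(scores)
    return best, [s for s, sc in zip(states, scores) if sc == best]


@dataclass(frozen=True)
class CalibratedState:
    """Per-node mean over the selected steady states."""

    means: Mapping[str, float]
    node_names: tuple[str, ...]
    n_states: int
    achieved_score: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "means", dict(self.means))

    @property
    def fixed(self) -> tuple[str, ...]:
        return tuple(n for n in self.node_names if self.means[n] in (0.0, 1.0))

    @property
    def unfixed(self) -> tuple[str, ...]:
        return tuple(n for n in self.node_names if self.means[n] not in (0.0, 1.0))

    def fixed_value(self, name: str) -> int:
        mean = self.means[name]
        if mean not in (0.0, 1.0):
            raise ValueError(f"{name} is not fixed (mean {mean})")
        return int(mean)


def mean_state(states: Sequence[State], model: BooleanModel,
               achieved_score: float | None = None) -> CalibratedState:
    """Arithmetic per-node mean; a node is fixed iff constant across states."""
    if not states:
        raise ValueError("mean_state needs at least one state")
    n = len(states)
    names = model.node_names
    means = {name: sum(s[i] for s in states) / n for i, name in enumerate(names)}
    return CalibratedState(means=means, node_names=names, n_states=n,
                           achieved_score=achieved_score)


@dataclass(frozen=True)
class MatchReport:
    matches: tuple[str, ...]
    mismatches: tuple[str, ...]
    unfixed_overlap: tuple[str, ...]
    quarantined: tuple[str, ...]
    percentage: float  # matches / observed-and-resolved, half-up to 1 decimal

    @property
    def n_observed(self) -> int:
        return len(self.matches) + len(self.mismatches) + len(self.unfixed_overlap)


def _round_half_up(x: float, digits: int = 1) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("1." + "0" * digits),
                                           rounding=ROUND_HALF_UP))


def match_report(calibrated: CalibratedState, observation: ObservationVector,
                 model: BooleanModel,
                 name_map: Mapping[str, str] | None = None) -> MatchReport:
    """Compare the calibrated state with the observations, node by node.

    Observed nodes fixed at the observed value are matches; fixed at the
    complement are mismatches; unfixed nodes are reported separately rather
    than counted either way.
    """
    resolved, quarantined = observation.resolve(model, name_map)
    fixed = set(calibrated.fixed)
    matches, mismatches, unfixed = [], [], []
    for node in resolved:  # observation insertion order
        if node not in fixed:
            unfixed.append(node)
        elif calibrated.fixed_value(node) == resolved[node]:
            matches.append(node)
        else:
            mismatches.append(node)
    total = len(resolved)
    pct = _round_half_up(100.0 * len(matches) / total) if total else 0.0
    return MatchReport(matches=tuple(matches), mismatches=tuple(mismatches),
                       unfixed_overlap=tuple(unfixed),
                       quarantined=tuple(quarantined), percentage=pct)


# ---------------------------------------------------------------------------
# tabular IO (TSV conventions: obs.tsv, deg.tsv, phenotypes.tsv, calibrated)
# ---------------------------------------------------------------------------

def read_deg_tsv(path: str) -> list[DEGRecord]:
    df = pd.read_csv(path, sep="\t")
    return [DEGRecord(gene=str(r.gene), logFC=float(r.logFC), adjP=float(r.adjP))
            for r in df.itertuples(index=False)]


def read_observation_tsv(path: str) -> ObservationVector:
    df = pd.read_csv(path, sep="\t")
    prov = ({str(r.node): str(r.provenance) for r in df.itertuples(index=False)}
            if "provenance" in df.columns else {})
    return ObservationVector(
        values={str(r.node): int(r.value) for r in df.itertuples(index=False)},
        provenance=prov)


def read_phenotype_tsv(path: str) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t")
    return {str(r.node): int(r.required_value) for r in df.itertuples(index=False)}


def write_calibrated_tsv(calibrated: CalibratedState, path: str) -> None:
    fixed = set(calibrated.fixed)
    with open(path, "w") as fh:
        fh.write("node\tmean\tfixed_flag\n")
        for name in calibrated.node_names:
            fh.write(f"{name}\t{calibrated.means[name]:g}\t{int(name in fixed)}\n")


def read_calibrated_tsv(path: str) -> CalibratedState:
    df = pd.read_csv(path, sep="\t")
    means = {str(r.node): float(r.mean) for r in df.itertuples(index=False)}
    return CalibratedState(means=means, node_names=tuple(means), n_states=0)
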