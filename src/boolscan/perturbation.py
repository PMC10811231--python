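"""In-silico knockout screens on a calibrated model.

A knockout clamps the targeted nodes at 0 (mimicking pharmacological
inhibition); over-expression clamping at 1 is exposed for completeness but
unused by the default screens.  Simulations start from the calibrated state,
with any unfixed node resolved by an explicit, recorded policy.  Each
phenotype's post-knockout value is compared against its calibrated value:
0 -> 1 is *induced*, 1 -> 0 is *suppressed*.  In a double screen, a pair is
*synergistic* when it produces a phenotype change that neither of its single
knockouts produces alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import combinations
from typing import Mapping, Sequence

from .calibration import CalibratedState
from .dynamics import Attractor, simulate
from .errors import ModelLookupError
from .expr import Const
from .model import BooleanModel, State

INDUCED = "induced"
SUPPRESSED = "suppressed"
UNCHANGED = "unchanged"

RESOLVE_POLICIES = ("zeros", "ones", "as_is_threshold")


def pair_count(n_targets: int) -> int:
    """Number of unordered knockout pairs, C(n, 2), without materialising."""
    if n_targets < 0:
        raise ValueError("target count must be non-negative")
    return n_targets * (n_targets - 1) // 2


@dataclass(frozen=True)
class KnockoutSpec:
    """Non-empty set of node names to clamp (at 0 by default)."""

    nodes: frozenset[str]
    clamp_value: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "nodes", frozenset(self.nodes))
        if not self.nodes:
            raise ValueError("knockout spec must name at least one node")
        if self.clamp_value not in (0, 1):
            raise ValueError("clamp value must be 0 or 1")

    @property
    def label(self) -> str:
        return "+".join(sorted(self.nodes))


def apply_knockout(model: BooleanModel, spec: KnockoutSpec) -> BooleanModel:
    """Replace each targeted node's rule by the clamp constant.

    Targeted input nodes become constant internal nodes, so the returned
    model's input set excludes them; all other rules are untouched.
    """
    unknown = spec.nodes - set(model.node_names)
    if unknown:
        raise ModelLookupError(f"knockout targets not in model: {sorted(unknown)}")
    nodes = []
    rules = dict(model.rules)
    for n in model.nodes:
        if n.name in spec.nodes:
            rules[n.name] = Const(spec.clamp_value)
            if n.kind == "input":
                n = replace(n, kind="internal")
        nodes.append(n)
    return BooleanModel(nodes=tuple(nodes), rules=rules,
                        name=f"{model.name}__ko_{spec.label}",
                        granularity=model.granularity)


def resolve_initial_state(calibrated: CalibratedState, policy: str = "zeros") -> State:
    """Concrete 0/1 state from a calibrated mean vector.

    Fixed nodes keep their value; unfixed nodes take 0 (``zeros``), 1
    (``ones``) or their rounded mean (``as_is_threshold``, rejecting the
    unresolvable mean 0.5).
    """
    if policy not in RESOLVE_POLICIES:
        raise ValueError(f"unknown policy {policy!r}; choose from {RESOLVE_POLICIES}")
    out = []
    for name in calibrated.node_names:
        mean = calibrated.means[name]
        if mean in (0.0, 1.0):
            out.append(int(mean))
        elif policy == "zeros":
            out.append(0)
        elif policy == "ones":
            out.append(1)
        else:
            if mean == 0.5:
                raise ValueError(
                    f"{name}: mean 0.5 cannot be thresholded; "
                    "use the zeros or ones policy"
                )
            out.append(int(mean > 0.5))
    return tuple(out)


@dataclass(frozen=True)
class PerturbationResult:
    knockout: KnockoutSpec
    status: str  # "steady" | "oscillatory"
    attractor: Attractor
    deltas: Mapping[str, str]  # phenotype -> induced/suppressed/unchanged
    calibrated_values: Mapping[str, int]
    perturbed_values: Mapping[str, object]  # int, or frozenset over a cycle
    initial_policy: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "deltas", dict(self.deltas))
        object.__setattr__(self, "calibrated_values", dict(self.calibrated_values))
        object.__setattr__(self, "perturbed_values", dict(self.perturbed_values))

    @property
    def changed_phenotypes(self) -> tuple[str, ...]:
        return tuple(p for p, d in self.deltas.items() if d != UNCHANGED)


def perturb_and_classify(model: BooleanModel, calibrated: CalibratedState,
                         spec: KnockoutSpec,
                         phenotypes: Sequence[str] | None = None,
                         policy: str = "zeros",
                         max_steps: int | None = None) -> PerturbationResult:
    """Simulate the knockout from the calibrated state and classify deltas."""
    if phenotypes is None:
        phenotypes = model.phenotype_names
    unknown = set(phenotypes) - set(model.node_names)
    if unknown:
        raise ModelLookupError(f"unknown phenotype nodes: {sorted(unknown)}")

    ko_model = apply_knockout(model, spec)
    initial = resolve_initial_state(calibrated, policy)
    init_env = dict(zip(model.node_names, initial))
    inputs = {name: init_env[name] for name in ko_model.input_names}
    _, attractor = simulate(ko_model, initial, inputs, max_steps=max_steps)

    index = model.index
    calibrated_values = {
        p: (calibrated.fixed_value(p)
            if calibrated.means[p] in (0.0, 1.0) else initial[index[p]])
        for p in phenotypes
    }
    deltas: dict[str, str] = {}
    perturbed: dict[str, object] = {}
    if attractor.kind == "steady":
        final = attractor.states[0]
        for p in phenotypes:
            before, after = calibrated_values[p], final[index[p]]
            perturbed[p] = after
            if before == after:
                deltas[p] = UNCHANGED
            else:
                deltas[p] = INDUCED if after == 1 else SUPPRESSED
        status = "steady"
    else:
        for p in phenotypes:
            values = frozenset(s[index[p]] for s in attractor.states)
            perturbed[p] = values
            deltas[p] = ("oscillatory" if len(values) > 1 else
                         (UNCHANGED if calibrated_values[p] in values else
                          (INDUCED if 1 in values else SUPPRESSED)))
        status = "oscillatory"
    return PerturbationResult(knockout=spec, status=status, attractor=attractor,
                              deltas=deltas, calibrated_values=calibrated_values,
                              perturbed_values=perturbed, initial_policy=policy)


@dataclass(frozen=True)
class ScreenResult:
    results: tuple[PerturbationResult, ...]
    unresolved_targets: tuple[str, ...]

    @property
    def hits(self) -> tuple[PerturbationResult, ...]:
        """Results with at least one phenotype change."""
        return tuple(r for r in self.results if r.changed_phenotypes)


def single_ko_screen(model: BooleanModel, calibrated: CalibratedState,
                     targets: Sequence[str],
                     phenotypes: Sequence[str] | None = None,
                     policy: str = "zeros") -> ScreenResult:
    """One knockout per target, in the given order; bad names are collected."""
    known = set(model.node_names)
    unresolved = tuple(t for t in targets if t not in known)
    results = tuple(
        perturb_and_classify(model, calibrated, KnockoutSpec(frozenset((t,))),
                             phenotypes, policy)
        for t in targets if t in known
    )
    return ScreenResult(results=results, unresolved_targets=unresolved)


@dataclass(frozen=True)
class PairResult:
    pair: tuple[str, str]
    result: PerturbationResult
    synergy: bool


def _produces(result: PerturbationResult | None, phenotype: str, label: str) -> bool:
    return result is not None and result.deltas.get(phenotype) == label


def double_ko_screen(model: BooleanModel, calibrated: CalibratedState,
                     targets: Sequence[str],
                     phenotypes: Sequence[str] | None = None,
                     policy: str = "zeros"
                     ) -> tuple[tuple[PairResult, ...], tuple[str, ...]]:
    """All C(n, 2) unordered pairs of targets, with synergy flags.

    A pair is flagged synergistic when, for some phenotype, it produces an
    induced/suppressed change that neither constituent single knockout
    produces for that phenotype.
    """
    known = set(model.node_names)
    unresolved = tuple(t for t in targets if t not in known)
    resolved = sorted({t for t in targets if t in known})
    if len(resolved) < 2:
        raise ValueError("double screen needs at least two resolvable targets")
    singles = {
        t: perturb_and_classify(model, calibrated, KnockoutSpec(frozenset((t,))),
                                phenotypes, policy)
        for t in resolved
    }
    pheno_list = (tuple(phenotypes) if phenotypes is not None
                  else model.phenotype_names)
    out = []
    for a, b in combinations(resolved, 2):
        result = perturb_and_classify(
            model, calibrated, KnockoutSpec(frozenset((a, b))), pheno_list, policy)
        synergy = any(
            result.deltas.get(p) == label
            and not _produces(singles[a], p, label)
            and not _produces(singles[b], p, label)
            for p in pheno_list
            for label in (INDUCED, SUPPRESSED)
        )
        out.append(PairResult(pair=(a, b), result=result, synergy=synergy))
    return tuple(out), unresolved


def sensitivity_screen(model: BooleanModel, calibrated: CalibratedState,
                       targets: Sequence[str],
                       phenotypes: Sequence[str] | None = None
                       ) -> dict[str, dict[str, tuple[str, str]]]:
    """Re-run the single screen under both unfixed-node policies.

    Returns, per target, the phenotypes whose delta label differs between the
    ``zeros`` and ``ones`` resolutions (empty everywhere when the unfixed
    nodes do not matter).
    """
    zeros = single_ko_screen(model, calibrated, targets, phenotypes, "zeros")
    ones = single_ko_screen(model, calibrated, targets, phenotypes, "ones")
    diffs: dict[str, dict[str, tuple[str, str]]] = {}
    for rz, ro in zip(zeros.results, ones.results):
        delta = {p: (rz.deltas[p], ro.deltas[p])
                 for p in rz.deltas if rz.deltas[p] != ro.deltas[p]}
        if delta:
            diffs[rz.knockout.label] = delta
    return diffs


def screen_rows(results: Sequence[PerturbationResult | PairResult]
                ) -> list[dict[str, object]]:
    """Flat rows (target(s), status, one column per phenotype) for TSV output."""
    rows = []
    for item in results:
        if isinstance(item, PairResult):
            result, label = item.result, "+".join(item.pair)
            extra: dict[str, object] = {"synergy": int(item.synergy)}
        else:
            result, label, extra = item, item.knockout.label, {}
        row: dict[str, object] = {"target": label, "status": result.status}
        row.update(result.deltas)
        row.update(extra)
        rows.append(row)
    return rows
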