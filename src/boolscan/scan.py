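"""Exhaustive steady-state scan over free-input combinations.

The number of conditions to analyse is ``2^n`` for ``n`` free inputs, so
inputs with known experimental values are clamped beforehand to shrink the
scan.  Combination ``i`` encodes an input valuation little-endian over the
name-sorted free inputs (bit ``j`` of ``i`` drives the ``j``-th free input);
the encoding is stable across versions so scan rows can be referenced by
index.  Because every record is a pure function of its index, the aggregate
result is identical for any worker count, and an interrupted scan can resume
from chunk checkpoints with a bit-identical final serialization.
"""

from __future__ import annotations

import gzip
import io
import json
import os
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

from joblib import Parallel, delayed

from .dynamics import (
    STATUS_INCONCLUSIVE,
    STATUS_NOT_STABLE,
    STATUS_STABLE,
    StabilityResult,
    prove_stability,
)
from .errors import ResumeError, ScanGuardError
from .model import BooleanModel, InputAssignment, State

#: Scans larger than this many combinations need an explicit override.
DEFAULT_COMBINATION_GUARD = 1 << 24

#: Detailed record statuses written to scan TSVs.
REC_STABLE = "stable"
REC_CYCLIC = "cyclic"
REC_MULTISTABLE = "multistable"
REC_INCONCLUSIVE = "inconclusive"


def count_input_combinations(n_inputs: int, n_fixed: int) -> int:
    """``2^(n_inputs - n_fixed)`` without materialising anything."""
    if not 0 <= n_fixed <= n_inputs:
        raise ValueError("need 0 <= n_fixed <= n_inputs")
    return 1 << (n_inputs - n_fixed)


def enumerate_input_combinations(model: BooleanModel, fixed: Mapping[str, int]
                                 ) -> Iterator[dict[str, int]]:
    """Yield all full input valuations completing ``fixed``, in index order."""
    assignment = InputAssignment.for_model(model, fixed)
    free = assignment.free
    for i in range(1 << len(free)):
        yield combination_valuation(assignment, i)


def combination_valuation(assignment: InputAssignment, index: int) -> dict[str, int]:
    """Decode combination ``index`` (little-endian over sorted free inputs)."""
    free = assignment.free
    if not 0 <= index < (1 << len(free)):
        raise ValueError(f"combination index {index} out of range")
    valuation = dict(assignment.fixed)
    for j, name in enumerate(free):
        valuation[name] = (index >> j) & 1
    return valuation


@dataclass(frozen=True)
class ScanRecord:
    index: int
    status: str  # one of REC_*
    steady_state: State | None

    @classmethod
    def from_stability(cls, index: int, result: StabilityResult) -> "ScanRecord":
        if result.status == STATUS_STABLE:
            return cls(index, REC_STABLE, result.steady_state)
        if result.status == STATUS_NOT_STABLE:
            status = REC_CYCLIC if result.witness_cycle is not None else REC_MULTISTABLE
            return cls(index, status, None)
        return cls(index, REC_INCONCLUSIVE, None)


@dataclass(frozen=True)
class ScanResult:
    model_name: str
    model_hash: str
    node_names: tuple[str, ...]
    fixed: Mapping[str, int]
    free: tuple[str, ...]
    records: tuple[ScanRecord, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "fixed", dict(self.fixed))
        if len(self.records) != 1 << len(self.free):
            raise ValueError("record count must be 2^(free inputs)")

    @property
    def counters(self) -> dict[str, int]:
        counts = {REC_STABLE: 0, REC_CYCLIC: 0, REC_MULTISTABLE: 0,
                  REC_INCONCLUSIVE: 0}
        for r in self.records:
            counts[r.status] += 1
        return counts

    def valuation(self, index: int) -> dict[str, int]:
        return combination_valuation(
            InputAssignment(fixed=self.fixed, free=self.free), index)


@dataclass(frozen=True)
class DiscardReport:
    n_cyclic: int
    n_multistable: int
    n_inconclusive: int

    @property
    def total(self) -> int:
        return self.n_cyclic + self.n_multistable + self.n_inconclusive


def _compute_chunk(model: BooleanModel, fixed: Mapping[str, int],
                   indices: Sequence[int], search_budget: int) -> list[ScanRecord]:
    assignment = InputAssignment.for_model(model, fixed)
    out = []
    for i in indices:
        valuation = combination_valuation(assignment, i)
        result = prove_stability(model, valuation, search_budget=search_budget)
        out.append(ScanRecord.from_stability(i, result))
    return out


def scan(model: BooleanModel, fixed: Mapping[str, int] | None = None,
         workers: int = 1, checkpoint_dir: str | None = None,
         checkpoint_every: int = 256, search_budget: int = 1 << 16,
         guard: int = DEFAULT_COMBINATION_GUARD,
         allow_large: bool = False) -> ScanResult:
    """Prove stability for every free-input combination.

    ``checkpoint_dir`` makes the scan resumable: finished chunks are written
    as TSV shards keyed by the model hash, and a re-run recomputes only the
    missing ones, producing a result identical to an uninterrupted scan.
    """
    fixed = dict(fixed or {})
    if workers < 1:
        raise ValueError("workers must be >= 1")
    assignment = InputAssignment.for_model(model, fixed)
    total = 1 << len(assignment.free)
    if total > guard and not allow_large:
        raise ScanGuardError(
            f"{total} combinations exceed the guard ({guard}); "
            "pass allow_large=True to run anyway"
        )

    chunk_starts = list(range(0, total, checkpoint_every))
    done: dict[int, list[ScanRecord]] = {}
    if checkpoint_dir is not None:
        done = _load_checkpoints(checkpoint_dir, model, fixed, assignment.free,
                                 checkpoint_every, len(model.nodes))

    todo = [s for s in chunk_starts if s not in done]
    ranges = [range(s, min(s + checkpoint_every, total)) for s in todo]
    if workers == 1 or len(ranges) <= 1:
        computed = [_compute_chunk(model, fixed, r, search_budget) for r in ranges]
    else:
        computed = Parallel(n_jobs=workers)(
            delayed(_compute_chunk)(model, fixed, r, search_budget) for r in ranges
        )
    for start, records in zip(todo, computed):
        done[start] = records
        if checkpoint_dir is not None:
            _write_chunk(checkpoint_dir, start, records, len(model.nodes))

    records = tuple(rec for start in chunk_starts for rec in done[start])
    return ScanResult(model_name=model.name, model_hash=model.content_hash(),
                      node_names=model.node_names, fixed=fixed,
                      free=assignment.free, records=records)


def filter_steady(scan_result: ScanResult) -> tuple[list[State], DiscardReport]:
    """Steady states in combination order, plus counts of what was discarded."""
    states = [r.steady_state for r in scan_result.records if r.status == REC_STABLE]
    c = scan_result.counters
    return states, DiscardReport(n_cyclic=c[REC_CYCLIC],
                                 n_multistable=c[REC_MULTISTABLE],
                                 n_inconclusive=c[REC_INCONCLUSIVE])


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def serialize_scan(scan_result: ScanResult) -> str:
    """Canonical TSV text: header comments, then one row per combination."""
    buf = io.StringIO()
    buf.write(f"# model\t{scan_result.model_name}\n")
    buf.write(f"# model_hash\t{scan_result.model_hash}\n")
    fixed_txt = ",".join(f"{k}={v}" for k, v in sorted(scan_result.fixed.items()))
    buf.write(f"# fixed\t{fixed_txt}\n")
    buf.write(f"# free\t{','.join(scan_result.free)}\n")
    buf.write("combination_index\tstatus\t" + "\t".join(scan_result.node_names) + "\n")
    for r in scan_result.records:
        cells = [str(v) for v in r.steady_state] if r.steady_state is not None \
            else ["" for _ in scan_result.node_names]
        buf.write(f"{r.index}\t{r.status}\t" + "\t".join(cells) + "\n")
    return buf.getvalue()


def write_scan_tsv(scan_result: ScanResult, path: str) -> None:
    text = serialize_scan(scan_result)
    if path.endswith(".gz"):
        with gzip.open(path, "wt") as fh:
            fh.write(text)
    else:
        with open(path, "w") as fh:
            fh.write(text)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def _meta_path(checkpoint_dir: str) -> str:
    return os.path.join(checkpoint_dir, "meta.json")


def _chunk_path(checkpoint_dir: str, start: int) -> str:
    return os.path.join(checkpoint_dir, f"chunk_{start:010d}.tsv")


def _load_checkpoints(checkpoint_dir: str, model: BooleanModel,
                      fixed: Mapping[str, int], free: tuple[str, ...],
                      checkpoint_every: int, n_nodes: int
                      ) -> dict[int, list[ScanRecord]]:
    os.makedirs(checkpoint_dir, exist_ok=True)
    meta = {
        "model_hash": model.content_hash(),
        "fixed": {k: int(v) for k, v in sorted(fixed.items())},
        "free": list(free),
        "checkpoint_every": checkpoint_every,
    }
    meta_file = _meta_path(checkpoint_dir)
    if os.path.exists(meta_file):
        with open(meta_file) as fh:
            existing = json.load(fh)
        if existing != meta:
            raise ResumeError(
                "checkpoint directory was written for a different model/scan "
                f"({meta_file})"
            )
    else:
        with open(meta_file, "w") as fh:
            json.dump(meta, fh, indent=1)

    done: dict[int, list[ScanRecord]] = {}
    total = 1 << len(free)
    for start in range(0, total, checkpoint_every):
        path = _chunk_path(checkpoint_dir, start)
        if not os.path.exists(path):
            continue
        expected = min(start + checkpoint_every, total) - start
        records = _read_chunk(path, n_nodes)
        if records is not None and len(records) == expected:
            done[start] = records
    return done


def _write_chunk(checkpoint_dir: str, start: int,
                 records: list[ScanRecord], n_nodes: int) -> None:
    path = _chunk_path(checkpoint_dir, start)
    tmp = path + ".tmp"
    with open(tmp, "w") as fh:
        for r in records:
            state_txt = "".join(map(str, r.steady_state)) if r.steady_state else "-"
            fh.write(f"{r.index}\t{r.status}\t{state_txt}\n")
    os.replace(tmp, path)  # atomic so a killed scan never leaves torn chunks


def _read_chunk(path: str, n_nodes: int) -> list[ScanRecord] | None:
    records = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 3:
                return None
            index, status, state_txt = parts
            if status == REC_STABLE:
                if len(state_txt) != n_nodes or set(state_txt) - {"0", "1"}:
                    return None
                state: State | None = tuple(int(c) for c in state_txt)
            else:
                state = None
            records.append(ScanRecord(int(index), status, state))
    return records
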