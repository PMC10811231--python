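# Methods

## Model semantics

A model is a granularity-1 qualitative network: each node holds 0 or 1 and
each non-input node has an update rule over {AND, OR, NOT}, node references
and constants. Inputs (nodes with no regulators) are clamped externally and
define the environmental condition. Updates are synchronous: the successor
of state `s` evaluates every rule on `s` simultaneously. Attractors are
fixed points (`F(s) = s`) or simple cycles of the deterministic successor
map; because the map is functional, every trajectory ends in exactly one of
them. Asynchronous schemes, multi-valued logic and SAT-based analysis are
out of scope.

Node kinds are derived, not declared: no regulators → input; a name ending
in a cell-specific suffix (default `_M1_macrophage` / `_M2_macrophage`) →
cell-specific phenotype; the `_signal` suffix → tissue-level signal
phenotype; everything else internal. A name carrying both suffix types is an
error rather than a silent choice.

## Formats

* **SBML-qual (read).** Plain XML; parsed with `lxml`. Only Boolean species
  (`maxLevel` 1) are accepted. Function terms are combined as: value 1 iff a
  level-1 term fires, or the default level is 1 and no level-0 term fires —
  this assumes the terms are disjoint, which the standard requires.
  Supported MathML: `and/or/not`, species-vs-constant comparisons
  (`eq/geq/leq/gt/lt` at levels 0/1), bare `ci`, `cn`, `true/false`.
* **BMA-style JSON (read/write).** `variables[{id, name, rangeFrom,
  rangeTo, formula}]` + `relationships[{fromVariable, toVariable, type}]`.
  The formula grammar is deliberately the Boolean-exact subset: `var(id)`,
  n-ary `min` (AND) and `max` (OR), constants 0/1, and the complement
  `1 - expr` (NOT). `avg/ceil/floor` are rejected with a clear error — they
  cannot arise in a Boolean-valued formula over Boolean operands, and
  rejecting them keeps every accepted formula exactly Boolean. A variable
  with an empty formula takes the default rule implied by its relationships,
  `(OR of activators) AND NOT (OR of inhibitors)`; with no relationships it
  is an input. Node identity across formats is the whitespace-trimmed
  display name (observation tables are keyed by biological names);
  numeric ids are preserved in node annotations. The writer emits formulas
  for all ruled nodes and syntactically derived relationship signs, so a
  write→parse round trip is semantically identity (equal truth tables),
  which the tests check exhaustively.

## Upstream restriction

`restrict_to_upstream` keeps the ancestor closure of the chosen phenotype
nodes in the regulator→target graph. Closure guarantees every retained rule
references only retained nodes. Inputs feeding only removed nodes are
removed with them — they cannot influence the retained dynamics — and are
itemised in the removal report so a user who prefers to clamp them at a
default instead can see exactly which they were.

## Stability proof

Phase 1, *range reduction*: starting from clamped input singletons and
`{0,1}` elsewhere, each node's set is replaced by the image of its rule over
its regulators' sets until a fixpoint. The sequence is monotone decreasing,
so it terminates; by induction every attractor state lies in every iterate,
so the result contains all attractors and is closed under the update map.
All-singleton sets therefore prove a unique steady state outright (always
the case for acyclic models, where the proof reduces to topological
evaluation).

The per-rule image is computed exactly (enumerating the product of
referenced-node sets) for rules referencing ≤ 12 nodes; wider rules use a
compositional set evaluation that is a sound superset (it ignores
correlations between repeated references, e.g. `A AND NOT A` abstracts to
`{0,1}`). Either way the conservativeness invariant holds; the cutoff of 12
keeps the exact image at ≤ 4096 evaluations per rule.

Phase 2, *cycle search*: with `u` unresolved nodes and `2^u` within the
search budget (default `2^16`), the reduced space is enumerated and the
functional graph decomposed: stable iff exactly one fixed point and no
cycle of length ≥ 2; otherwise the witness (a cycle, or the multiple fixed
points) is returned, distinguishing "cyclic" from "multistable" verdicts.
Beyond the budget, seeded simulations (a fixed documented seed,
`dynamics.FALLBACK_SEED`) can still disprove stability by exhibiting a
cycle or two distinct fixed points; if they cannot, the verdict is
`inconclusive` — a first-class status, never a silent guess. The published
analysis pipeline this mirrors used satisfiability queries for phase 2; the
guarantee (find any cycle or extra fixed point) is what matters here, not
the mechanism, and exhaustive search over the reduced space provides it
exactly at test scale.

Every steady state returned is re-checked against `F(s) = s` before being
reported.

## Scans

Free inputs are the model inputs not clamped by the fixed-input table.
Combination `i` assigns bit `j` of `i` (little-endian) to the `j`-th
name-sorted free input; the encoding is documented and stable so scan rows
can be cited by index. Records are pure functions of their index, which
gives two invariants the tests enforce byte-for-byte: worker-count
invariance (joblib parallelism over chunks, aggregation by index) and
kill-and-resume equivalence (atomic per-chunk TSV checkpoints keyed by a
model content hash; resuming with a different model is refused). Scans
above `2^24` combinations require an explicit override: full published-scale
scans (`2^21` conditions) are cluster work, and the guard prevents
accidental desk runs.

## Calibration

Differential expression is discretized as: adjusted p below threshold
(default 0.05, strict `<`; inclusivity is configurable since conventions
differ) and positive log fold-change → 1, negative → 0; everything else
excluded. Literature and expression evidence merge with provenance
tracking; disagreements fail loudly by default (`literature_wins` /
`expression_wins` are explicit opt-ins) because a silent resolution would
bias the score.

Steady states are filtered on required phenotype values, then scored with
the simple matching coefficient over the observed nodes resolvable to model
nodes; unresolvable observation keys are quarantined and logged rather than
fatal, and an optional name map (gene symbol → node) handles naming drift.
All argmax states are kept on ties — the calibrated state is defined as a
mean over a *set* of best states. The match report classifies each observed
node as match / mismatch / unfixed; unfixed nodes are reported separately
rather than counted as matches, and percentages are rounded half-up to one
decimal.

## Knockouts

A knockout replaces each target's rule by the constant 0 (clamped inputs
become constant internal nodes); clamping at 1 exists for over-expression
experiments but the screens default to inhibition, mirroring screens of
inhibitor-druggable targets. Simulations start from the calibrated state;
unfixed nodes are resolved by an explicit recorded policy (default `zeros`;
`ones` and a thresholding policy that refuses the ambiguous mean 0.5 are
available, and `sensitivity_screen` reports any delta labels that differ
between the zeros and ones resolutions). Trajectories are capped at
`2 × nodes + 10` steps, matching the fast convergence of granularity-1
models while staying bounded; the scan path uses the stability proof, not
simulation. If the knockout model oscillates from the calibrated state, the
result is labelled oscillatory, with per-phenotype value sets over the
cycle instead of delta labels.

Synergy: a pair is flagged when some phenotype acquires an
induced/suppressed label that neither constituent single knockout produces
for that phenotype. Receptor screens are the pair screen restricted to a
user-supplied receptor list; no automatic receptor detection is attempted.

## Synthetic fixtures and what they do (not) show

The random-model generator draws signed regulator sets from a seeded stream
and applies the default-rule construction; the `acyclic` flag restricts
regulators to earlier nodes, forcing a DAG. All outputs are pure functions
of the spec, so fixtures are reproducible by construction. The brute-force
oracle enumerates the full `2^n` synchronous transition graph (guarded at
20 non-input nodes, ~10^6 states) and finds fixed points and cycles of any
length exactly — that, rather than sampled simulation, is why it can serve
as ground truth for the prover.

The toy macrophage fixture is a hand-built 23-node acyclic model that
mimics curated inflammation-map conventions: five environmental inputs
(LPS, TNFα, IFNγ, growth factor, IL-10), receptor→kinase→transcription
factor chains, an NF-κB hub whose loss flips apoptosis on and proliferation
off, a redundant JAK1/JAK2 relay whose double knockout is the unique
synergy pair, and suffix-named phenotype nodes. Its committed golden
outputs (scan, calibrated state, both screens) were generated by this
package and are compared byte-for-byte in the end-to-end test.

These fixtures exercise every pipeline stage, but they are not transcriptome
emulators: observation tables are small typed rows, not expression matrices
with realistic noise, and the toy model is acyclic where real models have
feedback. Passing tests therefore demonstrate correctness of the machinery
(proof, scan, scoring, screens), not biological validity of any particular
model.

## Problem sizes used in the shipped checks

Oracle-agreement runs use 100 seeded models of 4–12 internal nodes with 2
inputs each (400 input conditions), sized so that exhaustive enumeration
stays trivially cheap while covering both acyclic and feedback-rich wiring.
Calibration-recovery runs plant `k` flips with `2k` strictly below the
minimal Hamming distance between steady states, the regime where unique
recovery is guaranteed by the margin argument. The acceptance script
reports cardinalities at the published model sizes (64 inputs / 43 fixed,
71 and 60 targets) by counting, never by materialising.

## Known limitations

* Synchronous semantics only; oscillatory biology that depends on update
  asynchrony is invisible here.
* The `inconclusive` verdict is reachable only above the phase-2 budget;
  callers doing large-scale scans should either raise the budget or treat
  inconclusive counts as a signal to re-run harder.
* SBML-qual writing is not implemented (the JSON dialect is the exchange
  format for writing).
* Multi-valued (granularity > 1) models are rejected, not approximated.
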