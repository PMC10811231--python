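# boolscan

Steady-state scanning, expression-based calibration and in-silico knockout
screening for large Boolean models of cell signalling.

## What problem this solves

Curated molecular interaction maps of disease processes (for example the
pro- and anti-inflammatory macrophage maps used in rheumatoid-arthritis
research) can be converted automatically into executable Boolean models with
hundreds of nodes. Analysing such models is hard for two reasons: the
synchronous state space has `2^n` states, and the models carry dozens of
*input* nodes (nodes with no regulators, representing the cellular
environment), so even the space of environmental conditions is `2^k` for `k`
free inputs. `boolscan` is a toolkit for modellers who need to

1. load such models (SBML-qual or a BMA-style JSON dialect), classify their
   nodes and restrict them to the regulators upstream of the phenotypes of
   interest;
2. prove, per input combination, whether the synchronous dynamics reach a
   single steady state — without enumerating `2^n` states;
3. calibrate the model against discretized differential-expression evidence;
4. screen single and paired knockouts for phenotype-selective interventions.

## The method

**Stability proof.** For one input valuation, every node's value set is
narrowed iteratively from `{0,1}` to the image of its update rule over its
regulators' current sets (*range reduction*). If all sets collapse to
singletons, that vector is the unique attractor. Otherwise the reduced
space — which provably contains every attractor state and is closed under
the update map — is enumerated: the condition is stable iff the functional
graph has exactly one fixed point and no cycle. A scan repeats this for all
`2^k` free-input combinations, in parallel, with resumable checkpoints and
worker-count-independent output.

**Calibration.** Steady states surviving a phenotype-value filter are scored
against the observation vector `o` (genes up in disease → 1, down → 0) with
the simple matching coefficient

    S = (N00 + N11) / (N00 + N11 + N10 + N01)

where `Nxy` counts observed nodes with state `x` and observation `y`. The
per-node mean over the top-scoring states is the **calibrated state**; nodes
constant across those states are *fixed*, the rest retain fractional means.

**Knockout screens.** Knockouts clamp targets at 0 (pharmacological
inhibition); simulations start from the calibrated state and each phenotype
is classified as *induced* (0→1), *suppressed* (1→0) or *unchanged* against
its calibrated value. A target pair is *synergistic* when it produces a
phenotype change neither single knockout produces alone.

## Worked example

The shipped toy macrophage model (23 nodes, 5 environmental inputs, an
NF-κB hub and suffix-named phenotype nodes) runs end to end in seconds:

```python
from boolscan import *
from boolscan.scan import filter_steady

fx = toy_macrophage_fixture()
result = scan(fx.model, {})                      # all 2^5 input conditions
states, _ = filter_steady(result)                # -> 32 steady states
survivors = filter_by_phenotype(states, fx.model, fx.phenotype_constraint)
best, top = select_top(survivors, fx.observation, fx.model)
cal = mean_state(top, fx.model, achieved_score=best)
print(len(survivors), best, len(top), len(cal.fixed), cal.unfixed)
# 6 1.0 2 21 ('LPS', 'TLR4')

screen = single_ko_screen(fx.model, cal, fx.targets)
for r in screen.hits:
    print(r.knockout.label, dict(d for d in r.deltas.items() if d[1] != "unchanged"))
# NFkB {'Apoptosis_M1_macrophage': 'induced', 'Proliferation_M1_macrophage': 'suppressed'}
# ERK {'Proliferation_M1_macrophage': 'suppressed'}
# BCL2 {'Apoptosis_M1_macrophage': 'induced'}

pairs, _ = double_ko_screen(fx.model, cal, fx.targets)
print([p.pair for p in pairs if p.synergy])
# [('JAK1', 'JAK2')]
```

Reading: of the 32 steady states, 6 satisfy the disease phenotype
constraint (apoptosis OFF, proliferation ON); 2 of them match all 5
observed node values (`S = 1.0`), and their mean fixes 21 of 23 nodes.
Knocking out the NF-κB hub flips both cell phenotypes — the selective
"kill the inflammatory cell" intervention — while only the JAK1+JAK2 pair
silences the TNF-release signal that neither single knockout touches.

The same pipeline is scriptable from the shell (`boolscan summary / scan /
calibrate / ko`); see `boolscan --help`.

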