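"""Synchronous update, simulation, range reduction and the stability proof."""

from itertools import product

import pytest

from boolscan.dynamics import (
    STATUS_NOT_STABLE,
    STATUS_STABLE,
    prove_stability,
    range_reduction,
    simulate,
    sync_step,
    trajectory_rows,
)
from boolscan.errors import IncompleteAssignmentError, NonterminationError
from boolscan.expr import Const, Var
from boolscan.fixtures import (
    FixtureSpec,
    brute_force_attractors,
    dag_steady_state,
    random_boolean_model,
)
from boolscan.model import BooleanModel, Node


class TestSyncStep:
    def test_all_rules_read_the_previous_state(self, two_node_loop):
        # A=NOT B, B=A at (0,0): both rules see the old state simultaneously
        assert sync_step(two_node_loop, (0, 0), {}) == (1, 0)

    def test_constant_rules_give_the_constant_vector(self):
        m = BooleanModel(nodes=(Node("A"), Node("B")),
                         rules={"A": Const(1), "B": Const(0)})
        for state in product((0, 1), repeat=2):
            assert sync_step(m, state, {}) == (1, 0)

    def test_inputs_keep_their_clamped_values(self, chain_model):
        nxt = sync_step(chain_model, (0, 0, 0, 0), {"I": 1, "J": 0})
        assert nxt[0] == 1 and nxt[3] == 0

    def test_missing_input_value_errors(self, chain_model):
        with pytest.raises(IncompleteAssignmentError):
            sync_step(chain_model, (0, 0, 0, 0), {"I": 1})


class TestSimulate:
    def test_four_cycle(self, two_node_loop):
        traj, att = simulate(two_node_loop, (0, 0), {})
        assert att.kind == "cyclic" and len(att.states) == 4
        assert traj == [(0, 0), (1, 0), (1, 1), (0, 1), (0, 0)]

    def test_dag_converges_within_depth_steps(self, chain_model):
        for start in product((0, 1), repeat=4):
            traj, att = simulate(chain_model, start, {"I": 1, "J": 0})
            assert att.kind == "steady"
            assert att.states[0] == (1, 1, 1, 0)
            assert len(traj) <= 5

    def test_fixed_point_start_gives_length_two_trajectory(self, chain_model):
        traj, att = simulate(chain_model, (1, 1, 1, 0), {"I": 1, "J": 0})
        assert att.kind == "steady" and len(traj) == 2

    def test_step_budget_guard(self, two_node_loop):
        with pytest.raises(NonterminationError):
            simulate(two_node_loop, (0, 0), {}, max_steps=2)

    def test_trajectory_rows_for_export(self, two_node_loop):
        traj, _ = simulate(two_node_loop, (0, 0), {})
        rows = trajectory_rows(two_node_loop, traj)
        assert rows[:2] == [(0, "A", 0), (0, "B", 0)]
        assert len(rows) == 2 * len(traj)


class TestRangeReduction:
    def test_dag_collapses_to_singletons(self, chain_model):
        sets = range_reduction(chain_model, {"I": 1, "J": 0})
        assert all(len(s) == 1 for s in sets.values())
        assert sets["P"] == frozenset((1,))

    def test_feedback_loop_stays_unresolved(self, two_node_loop):
        sets = range_reduction(two_node_loop, {})
        assert sets["A"] == sets["B"] == frozenset((0, 1))

    def test_constant_rule_reduces_immediately(self):
        m = BooleanModel(nodes=(Node("A"), Node("B")),
                         rules={"A": Const(0), "B": Var("A")})
        sets = range_reduction(m, {})
        assert sets == {"A": frozenset((0,)), "B": frozenset((0,))}

    def test_reduction_is_conservative_on_random_models(self):
        for seed in range(10):
            m = random_boolean_model(FixtureSpec(n_internal=6, n_inputs=2,
                                                 seed=seed))
            for bits in product((0, 1), repeat=2):
                inputs = dict(zip(m.input_names, bits))
                sets = range_reduction(m, inputs)
                fixed, cycles = brute_force_attractors(m, inputs)
                recurrent = list(fixed) + [s for c in cycles for s in c]
                idx = m.index
                for state in recurrent:
                    for name, allowed in sets.items():
                        assert state[idx[name]] in allowed


class TestProveStability:
    def test_dag_is_stable_at_the_topological_evaluation(self, chain_model):
        r = prove_stability(chain_model, {"I": 1, "J": 0})
        assert r.status == STATUS_STABLE
        assert r.steady_state == dag_steady_state(chain_model, {"I": 1, "J": 0})

    def test_two_node_loop_yields_a_cycle_witness(self, two_node_loop):
        r = prove_stability(two_node_loop, {})
        assert r.status == STATUS_NOT_STABLE
        assert r.witness_cycle is not None and len(r.witness_cycle.states) == 4
        # the witness really is a cycle of the dynamics
        states = r.witness_cycle.states
        for a, b in zip(states, states[1:] + states[:1]):
            assert sync_step(two_node_loop, a, {}) == b

    def test_self_sustaining_or_stabilises_by_range_reduction(self):
        # A = A OR B with B clamped 1: reduction forces A to 1
        m = BooleanModel(nodes=(Node("B", kind="input"), Node("A")),
                         rules={"A": Var("A") | Var("B")})
        r = prove_stability(m, {"B": 1})
        assert r.status == STATUS_STABLE and r.steady_state == (1, 1)
        assert r.reduced_ranges["A"] == frozenset((1,))

    def test_multiple_fixed_points_detected(self):
        # A = A: both 0 and 1 are fixed points under any input-free dynamics
        m = BooleanModel(nodes=(Node("A"),), rules={"A": Var("A")})
        r = prove_stability(m, {})
        assert r.status == STATUS_NOT_STABLE
        assert r.multiple_fixed_points and len(r.fixed_points) == 2

    def test_steady_states_satisfy_the_fixed_point_equation(self):
        for seed in range(15):
            m = random_boolean_model(FixtureSpec(n_internal=7, n_inputs=2,
                                                 seed=seed))
            for bits in product((0, 1), repeat=2):
                inputs = dict(zip(m.input_names, bits))
                r = prove_stability(m, inputs)
                if r.status == STATUS_STABLE:
                    assert sync_step(m, r.steady_state, inputs) == r.steady_state
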