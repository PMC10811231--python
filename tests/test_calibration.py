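"""Discretization, similarity scoring (simple matching coefficient) and the
calibrated mean state."""

import pytest
from hypothesis import given, settings, strategies as st

from boolscan.calibration import (
    DEGRecord,
    ObservationVector,
    discretize_deg_table,
    filter_by_phenotype,
    match_report,
    mean_state,
    merge_observations,
    select_top,
    similarity,
)
from boolscan.errors import ConflictError, EmptyComparisonError, ModelLookupError
from boolscan.expr import Var
from boolscan.model import BooleanModel, Node


@pytest.fixture()
def abp_model():
    return BooleanModel(
        nodes=(Node("A", kind="input"), Node("B", kind="input"), Node("P")),
        rules={"P": Var("A") | Var("B")})


class TestDiscretize:
    def test_signs_map_to_boolean_values(self):
        obs = discretize_deg_table([
            DEGRecord("geneX", +2.3, 0.001),
            DEGRecord("geneY", -1.2, 0.01),
            DEGRecord("geneZ", +3.0, 0.20),  # fails threshold
        ])
        assert obs.values == {"geneX": 1, "geneY": 0}
        assert obs.provenance["geneX"] == "expression"

    def test_threshold_strictness_is_configurable(self):
        recs = [DEGRecord("g", 1.0, 0.05)]
        assert len(discretize_deg_table(recs)) == 0
        assert discretize_deg_table(recs, strict=False).values == {"g": 1}

    def test_conflicting_duplicates_fail_loudly(self):
        with pytest.raises(ConflictError, match="g1"):
            discretize_deg_table([DEGRecord("g1", 2.0, 0.01),
                                  DEGRecord("g1", -2.0, 0.01)])

    def test_zero_logfc_excluded(self):
        assert len(discretize_deg_table([DEGRecord("g", 0.0, 0.001)])) == 0


class TestMergeObservations:
    lit = ObservationVector({"A": 1, "B": 0})
    expr = ObservationVector({"B": 0, "C": 1},
                             provenance={"B": "expression", "C": "expression"})

    def test_union_with_agreement_marks_both(self):
        merged = merge_observations(self.lit, self.expr)
        assert merged.values == {"A": 1, "B": 0, "C": 1}
        assert merged.provenance == {"A": "literature", "B": "both",
                                     "C": "expression"}

    def test_default_policy_errors_on_disagreement(self):
        conflicting = ObservationVector({"B": 1})
        with pytest.raises(ConflictError, match="B"):
            merge_observations(self.lit, conflicting)

    @pytest.mark.parametrize("policy,expected", [("literature_wins", 0),
                                                 ("expression_wins", 1)])
    def test_resolution_policies(self, policy, expected):
        merged = merge_observations(self.lit, ObservationVector({"B": 1}),
                                    policy=policy)
        assert merged.values["B"] == expected


class TestPhenotypeFilter:
    states = [(0, 0, 0), (1, 0, 1), (0, 1, 1), (1, 1, 1)]

    def test_empty_constraint_keeps_everything(self, abp_model):
        assert filter_by_phenotype(self.states, abp_model, {}) == self.states

    def test_filter_matches_hand_selection(self, abp_model):
        kept = filter_by_phenotype(self.states, abp_model, {"P": 1, "A": 1})
        assert kept == [(1, 0, 1), (1, 1, 1)]

    def test_adding_a_constraint_never_enlarges_the_survivor_set(self, abp_model):
        base = filter_by_phenotype(self.states, abp_model, {"P": 1})
        tighter = filter_by_phenotype(self.states, abp_model, {"P": 1, "B": 0})
        assert set(tighter) <= set(base)

    def test_unknown_phenotype_errors(self, abp_model):
        with pytest.raises(ModelLookupError):
            filter_by_phenotype(self.states, abp_model, {"Q": 1})


class TestSimilarity:
    def test_hand_counted_example(self, abp_model):
        obs = ObservationVector({"A": 1, "B": 0, "P": 1})
        score = similarity((1, 1, 1), obs, abp_model)
        assert (score.N11, score.N00, score.N10, score.N01) == (2, 0, 1, 0)
        assert score.S == pytest.approx(2 / 3)

    def test_perfect_and_zero_matches(self, abp_model):
        obs = ObservationVector({"A": 1, "B": 0, "P": 1})
        assert similarity((1, 0, 1), obs, abp_model).S == 1.0
        assert similarity((0, 1, 0), obs, abp_model).S == 0.0

    def test_unresolvable_names_are_quarantined_not_counted(self, abp_model):
        obs = ObservationVector({"A": 1, "GHOST": 1})
        score = similarity((1, 0, 0), obs, abp_model)
        assert score.n_compared == 1 and score.S == 1.0

    def test_name_map_resolves_gene_symbols(self, abp_model):
        obs = ObservationVector({"geneA": 1})
        score = similarity((1, 0, 0), obs, abp_model, name_map={"geneA": "A"})
        assert score.S == 1.0

    def test_no_resolvable_observation_is_an_error(self, abp_model):
        with pytest.raises(EmptyComparisonError):
            similarity((1, 0, 0), ObservationVector({"GHOST": 1}), abp_model)

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(st.tuples(*[st.integers(0, 1)] * 3), st.tuples(*[st.integers(0, 1)] * 3))
    def test_score_bounds_and_symmetry(self, state, observed, ):
        model = BooleanModel(
            nodes=(Node("A", kind="input"), Node("B", kind="input"),
                   Node("P", kind="input")), rules={})
        obs = ObservationVector(dict(zip("ABP", observed)))
        swapped = ObservationVector(dict(zip("ABP", state)))
        s1 = similarity(state, obs, model)
        s2 = similarity(tuple(observed), swapped, model)
        assert 0.0 <= s1.S <= 1.0
        assert s1.S == s2.S  # simple matching is symmetric


class TestSelectTopAndMeanState:
    def test_single_state_is_its_own_argmax(self, abp_model):
        obs = ObservationVector({"A": 1})
        best, top = select_top([(1, 0, 1)], obs, abp_model)
        assert best == 1.0 and top == [(1, 0, 1)]

    def test_ties_keep_all_argmax_states(self, abp_model):
        obs = ObservationVector({"P": 1})
        best, top = select_top([(1, 0, 1), (0, 1, 1), (0, 0, 0)], obs, abp_model)
        assert best == 1.0 and len(top) == 2

    def test_mean_state_arithmetic_and_fixed_classification(self, abp_model):
        cs = mean_state([(1, 0, 1), (1, 1, 1)], abp_model)
        assert cs.means == {"A": 1.0, "B": 0.5, "P": 1.0}
        assert cs.fixed == ("A", "P") and cs.unfixed == ("B",)
        assert cs.fixed_value("A") == 1

    def test_identical_copies_fix_every_node(self, abp_model):
        cs = mean_state([(1, 0, 1)] * 3, abp_model)
        assert cs.unfixed == ()


class TestMatchReport:
    def test_perfect_calibration(self, abp_model):
        cs = mean_state([(1, 0, 1)], abp_model)
        report = match_report(cs, ObservationVector({"A": 1, "B": 0}), abp_model)
        assert report.percentage == 100.0 and report.mismatches == ()

    def test_one_flip_out_of_twenty_reports_95_percent(self):
        names = [f"n{i:02d}" for i in range(20)]
        model = BooleanModel(nodes=tuple(Node(n, kind="input") for n in names),
                             rules={})
        state = tuple([1] * 20)
        cs = mean_state([state], model)
        observed = {n: 1 for n in names}
        observed["n07"] = 0  # the planted flip
        report = match_report(cs, ObservationVector(observed), model)
        assert report.percentage == 95.0
        assert report.mismatches == ("n07",)

    def test_unfixed_nodes_reported_separately(self, abp_model):
        cs = mean_state([(1, 0, 1), (0, 1, 1)], abp_model)  # A, B unfixed
        report = match_report(cs, ObservationVector({"A": 1, "B": 0}), abp_model)
        assert report.matches == () and set(report.unfixed_overlap) == {"A", "B"}

    def test_rounding_is_half_up_to_one_decimal(self):
        # 28/29 observed = 96.551...% -> 96.6; 27/28 = 96.428...% -> 96.4
        names = [f"n{i}" for i in range(29)]
        model = BooleanModel(nodes=tuple(Node(n, kind="input") for n in names),
                             rules={})
        cs = mean_state([tuple([1] * 29)], model)
        obs = {n: 1 for n in names}
        obs["n0"] = 0
        assert match_report(cs, ObservationVector(obs), model).percentage == 96.6
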