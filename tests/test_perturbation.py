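"""Knockout construction, classification and single/double screens."""

import pytest

from boolscan.calibration import mean_state, select_top
from boolscan.errors import ModelLookupError
from boolscan.fixtures import dag_steady_state
from boolscan.model import State
from boolscan.perturbation import (
    INDUCED,
    SUPPRESSED,
    UNCHANGED,
    KnockoutSpec,
    apply_knockout,
    double_ko_screen,
    pair_count,
    perturb_and_classify,
    resolve_initial_state,
    sensitivity_screen,
    single_ko_screen,
)


@pytest.fixture()
def toy_calibrated(toy):
    from boolscan.calibration import filter_by_phenotype
    from boolscan.scan import filter_steady, scan

    states, _ = filter_steady(scan(toy.model, {}))
    survivors = filter_by_phenotype(states, toy.model, toy.phenotype_constraint)
    best, top = select_top(survivors, toy.observation, toy.model)
    return mean_state(top, toy.model, achieved_score=best)


class TestApplyKnockout:
    def test_input_knockout_propagates_through_a_chain(self, chain_model):
        ko = apply_knockout(chain_model, KnockoutSpec(frozenset(("I",))))
        assert "I" not in ko.input_names  # clamped inputs become constants
        steady = dag_steady_state(ko, {"J": 1})
        as_dict = ko.state_to_dict(steady)
        assert (as_dict["I"], as_dict["A"], as_dict["P"]) == (0, 0, 0)

    def test_other_rules_are_untouched(self, toy):
        ko = apply_knockout(toy.model, KnockoutSpec(frozenset(("NFkB",))))
        for name, expr in toy.model.rules.items():
            if name != "NFkB":
                assert ko.rules[name] is expr

    def test_empty_spec_rejected(self):
        with pytest.raises(ValueError):
            KnockoutSpec(frozenset())

    def test_unknown_target_errors(self, toy):
        with pytest.raises(ModelLookupError):
            apply_knockout(toy.model, KnockoutSpec(frozenset(("GHOST",))))


class TestResolveInitialState:
    def test_all_fixed_state_ignores_the_policy(self, chain_model):
        cs = mean_state([(1, 1, 1, 0)], chain_model)
        for policy in ("zeros", "ones", "as_is_threshold"):
            assert resolve_initial_state(cs, policy) == (1, 1, 1, 0)

    def test_unfixed_nodes_follow_the_policy(self, chain_model):
        cs = mean_state([(1, 1, 1, 0), (0, 1, 1, 0)], chain_model)  # I unfixed
        assert resolve_initial_state(cs, "zeros")[0] == 0
        assert resolve_initial_state(cs, "ones")[0] == 1

    def test_threshold_policy_rejects_exact_half(self, chain_model):
        cs = mean_state([(1, 1, 1, 0), (0, 1, 1, 0)], chain_model)
        with pytest.raises(ValueError, match="0.5"):
            resolve_initial_state(cs, "as_is_threshold")


class TestPerturbAndClassify:
    def test_hub_knockout_flips_both_cell_phenotypes(self, toy, toy_calibrated):
        result = perturb_and_classify(toy.model, toy_calibrated,
                                      KnockoutSpec(frozenset((toy.hub,))))
        assert result.deltas["Apoptosis_M1_macrophage"] == INDUCED
        assert result.deltas["Proliferation_M1_macrophage"] == SUPPRESSED

    def test_knockout_without_a_path_to_phenotypes_changes_nothing(
            self, toy, toy_calibrated):
        # Inflammation_signal is a sink: no phenotype is downstream of it
        result = perturb_and_classify(
            toy.model, toy_calibrated,
            KnockoutSpec(frozenset(("Inflammation_signal",))),
            phenotypes=["Apoptosis_M1_macrophage",
                        "Proliferation_M1_macrophage"])
        assert set(result.deltas.values()) == {UNCHANGED}

    def test_classification_labels_match_the_stored_values(self, toy,
                                                           toy_calibrated):
        result = perturb_and_classify(toy.model, toy_calibrated,
                                      KnockoutSpec(frozenset((toy.hub,))))
        for p, delta in result.deltas.items():
            before = result.calibrated_values[p]
            after = result.perturbed_values[p]
            expected = (UNCHANGED if before == after
                        else (INDUCED if after == 1 else SUPPRESSED))
            assert delta == expected

    def test_already_zero_constant_knockout_is_a_no_op(self, toy,
                                                       toy_calibrated):
        # IL10 is 0 in the calibrated state and clamping it at 0 changes nothing
        result = perturb_and_classify(toy.model, toy_calibrated,
                                      KnockoutSpec(frozenset(("IL10",))))
        assert set(result.deltas.values()) == {UNCHANGED}


class TestScreens:
    def test_single_screen_row_per_target(self, toy, toy_calibrated):
        screen = single_ko_screen(toy.model, toy_calibrated, toy.targets)
        assert len(screen.results) == len(toy.targets)
        hit_labels = {r.knockout.label for r in screen.hits}
        assert hit_labels == {"NFkB", "ERK", "BCL2"}

    def test_unresolvable_targets_collected_and_screen_continues(
            self, toy, toy_calibrated):
        screen = single_ko_screen(toy.model, toy_calibrated,
                                  ["NFkB", "GHOST1", "GHOST2"])
        assert screen.unresolved_targets == ("GHOST1", "GHOST2")
        assert len(screen.results) == 1

    def test_pair_count_law(self):
        assert pair_count(4) == 6
        assert pair_count(71) == 2485
        assert pair_count(60) == 1770

    def test_double_screen_enumerates_all_pairs(self, toy, toy_calibrated):
        pairs, _ = double_ko_screen(toy.model, toy_calibrated, toy.targets)
        assert len(pairs) == pair_count(len(toy.targets))

    def test_synergy_flag_set_for_exactly_the_redundant_pair(self, toy,
                                                             toy_calibrated):
        pairs, _ = double_ko_screen(toy.model, toy_calibrated, toy.targets)
        synergistic = [p.pair for p in pairs if p.synergy]
        assert synergistic == [toy.synergy_pair]
        # the pair silences the signal phenotype that neither single touches
        flagged = next(p for p in pairs if p.synergy)
        assert flagged.result.deltas["TNF_release_signal"] == SUPPRESSED

    def test_pair_order_invariance(self, toy, toy_calibrated):
        a = perturb_and_classify(toy.model, toy_calibrated,
                                 KnockoutSpec(frozenset(("JAK1", "JAK2"))))
        b = perturb_and_classify(toy.model, toy_calibrated,
                                 KnockoutSpec(frozenset(("JAK2", "JAK1"))))
        assert a.deltas == b.deltas
        assert a.attractor.states == b.attractor.states

    def test_sensitivity_screen_reports_policy_differences(self, toy,
                                                           toy_calibrated):
        # the toy's unfixed nodes (LPS/TLR4) are redundant with TNFR for NFkB,
        # except when TNFR itself is knocked out
        diffs = sensitivity_screen(toy.model, toy_calibrated,
                                   ["NFkB", "ERK", "TNFR"])
        assert "NFkB" not in diffs and "ERK" not in diffs
        assert "TNFR" in diffs
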