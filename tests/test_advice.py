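"""Advice engine: per-source rules, ranking hierarchy, script, choices."""

import itertools

import numpy as np
import pytest

from modadvice.advice import (
    BA,
    EPA,
    EXPOSURE,
    HUB_NODES,
    NETWORK_TRIGGERS,
    OPTIONAL_MODULES,
    SLEEP,
    WELLNESS,
    AdviceError,
    DiagnosticHistory,
    ModuleId,
    advise_from_interview,
    advise_from_network,
    enumerate_combinations,
    merge_advice,
    rank_combinations,
    record_choice,
    render_script,
)
from modadvice.network import Edge, SymptomNetwork
from modadvice.templates import TemplateError, render_observation


def network_with_edges(*pairs: tuple[str, str, float]) -> SymptomNetwork:
    nodes = sorted({n for a, b, _ in pairs for n in (a, b)})
    return SymptomNetwork(
        "p",
        True,
        retained_nodes=tuple(nodes),
        edges=tuple(Edge(a, b, w) for a, b, w in pairs),
        n_obs=84,
    )


def brute_force_best_key(
    primary: frozenset, network: frozenset
) -> tuple[int, int]:
    """Independent scorer: max lexicographic key over all 9 candidates."""
    net_only = network - primary
    best = (-1, -1)
    for c in itertools.combinations(sorted(OPTIONAL_MODULES, key=lambda m: m.value), 3):
        s = frozenset(c)
        if not s & {BA, EXPOSURE}:
            continue
        key = (len(s & primary), len(s & net_only))
        best = max(best, key)
    return best


class TestInterviewAdvice:
    @pytest.mark.parametrize(
        "dep, anx, expected",
        [
            (True, False, {BA}),
            (False, True, {EXPOSURE}),
            (True, True, {BA, EXPOSURE}),
        ],
    )
    def test_remission_rules(self, dep, anx, expected):
        dx = DiagnosticHistory("p", remitted_depressive=dep, remitted_anxiety=anx)
        assert advise_from_interview(dx) == expected

    def test_no_remitted_disorder_violates_inclusion(self):
        with pytest.raises(AdviceError, match="inclusion"):
            DiagnosticHistory("p", remitted_depressive=False, remitted_anxiety=False)


class TestNetworkAdvice:
    @pytest.mark.parametrize("hub", sorted(HUB_NODES))
    @pytest.mark.parametrize(
        "trigger", sorted({n for s in NETWORK_TRIGGERS.values() for n in s})
    )
    def test_every_single_edge_advises_its_modules(self, hub, trigger):
        net = network_with_edges((hub, trigger, 0.4))
        expected = {m for m, s in NETWORK_TRIGGERS.items() if trigger in s}
        assert advise_from_network(net) == expected

    def test_worked_example_edges(self):
        net = network_with_edges(
            ("anxious", "positive_affect", -0.45), ("sad", "fatigue", 0.38)
        )
        assert advise_from_network(net) == {EPA, SLEEP}

    def test_social_company_advises_both_modules(self):
        net = network_with_edges(("sad", "social_company", 0.33))
        assert advise_from_network(net) == {EXPOSURE, BA}

    def test_hub_hub_and_peripheral_edges_advise_nothing(self):
        net = network_with_edges(
            ("anxious", "sad", 0.5), ("fatigue", "loneliness", 0.6)
        )
        assert advise_from_network(net) == set()

    def test_infeasible_network_is_silent(self):
        net = SymptomNetwork("p", False, infeasible_reason="compliance")
        assert advise_from_network(net) == set()


class TestMergeAdvice:
    def test_union_and_provenance(self):
        b = merge_advice(
            "p",
            frozenset({BA, EXPOSURE}),
            frozenset({SLEEP, WELLNESS, EPA}),
            frozenset({EPA}),
        )
        assert b.union_advice == OPTIONAL_MODULES
        assert {p.source for p in b.provenance_for(EPA)} == {"questionnaires", "network"}
        assert len(b.provenance_for(BA)) == 1

    def test_idempotent_union(self):
        b = merge_advice("p", frozenset({EXPOSURE}), frozenset(), frozenset({EXPOSURE}))
        assert b.union_advice == {EXPOSURE}
        assert {p.source for p in b.provenance_for(EXPOSURE)} == {"interview", "network"}

    def test_source_universe_enforced(self):
        with pytest.raises(AdviceError):
            merge_advice("p", frozenset({SLEEP}), frozenset(), frozenset())
        with pytest.raises(AdviceError):
            merge_advice("p", frozenset({BA}), frozenset({BA}), frozenset())


class TestEnumerateCombinations:
    def test_nine_candidates_missing_only_the_coreless_triple(self):
        combos = enumerate_combinations()
        assert len(combos) == 9
        sets = {c.modules for c in combos}
        all_triples = {
            frozenset(c)
            for c in itertools.combinations(sorted(OPTIONAL_MODULES, key=lambda m: m.value), 3)
        }
        assert all_triples - sets == {frozenset({EPA, SLEEP, WELLNESS})}
        assert all(c.modules & {BA, EXPOSURE} for c in combos)

    def test_time_consuming_flags_exactly_the_dual_core_sets(self):
        combos = enumerate_combinations()
        flagged = {c.modules for c in combos if c.time_consuming}
        assert flagged == {s.modules for s in combos if {BA, EXPOSURE} <= s.modules}
        assert len(flagged) == 3

    def test_option_indices_stable(self):
        assert [c.option_index for c in enumerate_combinations()] == list(range(1, 10))


class TestRankCombinations:
    def test_hierarchy_worked_example(self):
        # questionnaires advise {BA, Wellness, Sleep}; network adds {EPA}:
        # the fully questionnaire-covered triple outranks EPA-covering ones
        bundle = merge_advice(
            "p", frozenset({BA}), frozenset({WELLNESS, SLEEP}), frozenset({EPA})
        )
        plan = rank_combinations(bundle)
        assert [c.modules for c in plan.tier_1] == [frozenset({BA, WELLNESS, SLEEP})]
        assert plan.tier_1[0].rank_key == (3, 0)
        assert {c.modules for c in plan.tier_2} == {
            frozenset({BA, WELLNESS, EPA}),
            frozenset({BA, SLEEP, EPA}),
        }
        assert all(c.rank_key == (2, 1) for c in plan.tier_2)

    def test_single_module_advice_ties_all_containing_candidates(self):
        bundle = merge_advice("p", frozenset({BA}), frozenset(), frozenset())
        plan = rank_combinations(bundle)
        assert all(BA in c.modules for c in plan.tier_1)
        assert len(plan.tier_1) == 6  # every BA-containing candidate scores (1, 0)
        assert plan.tier_2 == ()  # fewer than 3 modules advised: no second tier

    def test_exhaustive_source_states_match_brute_force(self):
        interview_states = [
            frozenset(s)
            for r in range(3)
            for s in itertools.combinations({BA, EXPOSURE}, r)
        ]
        q_states = [
            frozenset(s)
            for r in range(4)
            for s in itertools.combinations({SLEEP, EPA, WELLNESS}, r)
        ]
        net_states = [
            frozenset(s)
            for r in range(6)
            for s in itertools.combinations(sorted(OPTIONAL_MODULES, key=lambda m: m.value), r)
        ]
        assert (len(interview_states), len(q_states), len(net_states)) == (4, 8, 32)
        for iv in interview_states:
            for q in q_states:
                for nv in net_states:
                    bundle = merge_advice("p", iv, q, nv)
                    plan = rank_combinations(bundle)
                    best = brute_force_best_key(bundle.primary_advice, nv)
                    assert plan.tier_1, (iv, q, nv)
                    assert all(c.rank_key == best for c in plan.tier_1)
                    assert all(
                        c.rank_key < best
                        for c in plan.candidates
                        if c.modules not in {t.modules for t in plan.tier_1}
                    )

    def test_source_hierarchy_strict(self):
        # equal total coverage, different primary coverage: primary wins
        bundle = merge_advice("p", frozenset({BA}), frozenset({SLEEP}), frozenset({EPA, WELLNESS}))
        plan = rank_combinations(bundle)
        ranked = {c.modules: i for i, c in enumerate(plan.candidates)}
        two_primary = frozenset({BA, SLEEP, WELLNESS})   # (2, 1)
        one_primary = frozenset({BA, EPA, WELLNESS})     # (1, 2): same total
        assert ranked[two_primary] < ranked[one_primary]


class TestScriptAndChoice:
    def make_plan(self):
        net = network_with_edges(
            ("anxious", "positive_affect", -0.45), ("sad", "fatigue", 0.38)
        )
        bundle = merge_advice(
            "p", frozenset({BA}), frozenset(), advise_from_network(net)
        )
        return bundle, rank_combinations(bundle), net

    def test_script_contains_observation_and_rationale_sentences(self):
        bundle, plan, net = self.make_plan()
        plan = render_script(bundle, plan, net)
        assert (
            "At moments you feel anxious, you also experience fewer positive feelings."
            in plan.script_text
        )
        assert "At moments you feel sad, you also feel more tired." in plan.script_text
        assert "Enhancing Positive Affect" in plan.script_text
        assert "Sleep" in plan.script_text

    def test_no_edges_means_no_observation_sentences(self):
        bundle = merge_advice("p", frozenset({BA}), frozenset(), frozenset())
        plan = render_script(bundle, rank_combinations(bundle), None)
        assert "At moments you feel" not in plan.script_text
        assert "Behavioral Activation" in plan.script_text

    def test_missing_template_is_a_configuration_error(self):
        with pytest.raises(TemplateError):
            render_observation("anxious", "fatigue", 0.4, templates={"observations": {}})

    def test_choice_annotations(self):
        bundle, plan, net = self.make_plan()
        plan = render_script(bundle, plan, net)
        top = sorted(plan.tier_1[0].modules, key=lambda m: m.value)
        chosen_plan = record_choice(plan, tuple(top))
        assert all(
            status == "advised_and_chosen"
            for m, status in chosen_plan.congruence
            if m in chosen_plan.chosen
        )
        assert chosen_plan.delivered_sequence[0] is ModuleId.PSYCHO_EDUCATION
        assert chosen_plan.delivered_sequence[1] is ModuleId.COGNITIVE_RESTRUCTURING
        assert chosen_plan.delivered_sequence[-1] is ModuleId.STAYFINE_PLAN

    def test_deviation_by_one_module(self):
        bundle, plan, _ = self.make_plan()
        # advised union is {BA, EPA, SLEEP}; swap SLEEP for WELLNESS
        chosen_plan = record_choice(plan, (BA, EPA, WELLNESS))
        statuses = dict(chosen_plan.congruence)
        assert statuses[WELLNESS] == "chosen_not_advised"
        assert statuses[SLEEP] == "advised_not_chosen"
        assert sum(1 for s in statuses.values() if s == "chosen_not_advised") == 1

    def test_coreless_choice_accepted_with_warning(self):
        bundle, plan, _ = self.make_plan()
        chosen_plan = record_choice(plan, (EPA, SLEEP, WELLNESS))
        assert chosen_plan.no_core_module_warning is True

    @pytest.mark.parametrize("bad", [(BA, EPA), (BA, BA, EPA), (BA, EPA, SLEEP, WELLNESS)])
    def test_invalid_choices_rejected(self, bad):
        _, plan, _ = self.make_plan()
        with pytest.raises(AdviceError):
            record_choice(plan, bad)
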