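"""Rule-based module advice, combination ranking, and the feedback script.

The intervention delivers six modules: three fixed (Psycho-Education,
Cognitive Restructuring, and the closing relapse-prevention plan) and
three chosen from five optional modules. Three data sources each advise
optional modules:

* diagnostic interview — Behavioral Activation for a remitted depressive
  disorder, Exposure for a remitted anxiety disorder, both for both;
* questionnaires — Sleep / Enhancing Positive Affect / Wellness via the
  scoring cutoffs (:mod:`modadvice.scoring`);
* symptom network — a retained edge between the anxious or sad node and a
  module's trigger nodes advises that module.

Candidate 3-module combinations always contain Behavioral Activation or
Exposure (the core components for depression and anxiety relapse), giving
9 of the 10 possible triples. Candidates are ranked lexicographically by
(number of interview/questionnaire-advised modules covered, number of
network-advised modules covered): interview- and questionnaire-based
advice outranks network-based advice.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from enum import Enum

from .network import SymptomNetwork
from .scoring import QuestionnaireScores
from .templates import render_module_rationale, render_observation


class ModuleId(str, Enum):
    # optional modules
    BEHAVIORAL_ACTIVATION = "BEHAVIORAL_ACTIVATION"
    EXPOSURE = "EXPOSURE"
    ENHANCING_POSITIVE_AFFECT = "ENHANCING_POSITIVE_AFFECT"
    SLEEP = "SLEEP"
    WELLNESS = "WELLNESS"
    # fixed modules
    PSYCHO_EDUCATION = "PSYCHO_EDUCATION"
    COGNITIVE_RESTRUCTURING = "COGNITIVE_RESTRUCTURING"
    STAYFINE_PLAN = "STAYFINE_PLAN"


BA = ModuleId.BEHAVIORAL_ACTIVATION
EXPOSURE = ModuleId.EXPOSURE
EPA = ModuleId.ENHANCING_POSITIVE_AFFECT
SLEEP = ModuleId.SLEEP
WELLNESS = ModuleId.WELLNESS

OPTIONAL_MODULES: frozenset[ModuleId] = frozenset({BA, EXPOSURE, EPA, SLEEP, WELLNESS})
FIXED_MODULES: tuple[ModuleId, ...] = (
    ModuleId.PSYCHO_EDUCATION,
    ModuleId.COGNITIVE_RESTRUCTURING,
    ModuleId.STAYFINE_PLAN,
)
INTERVIEW_UNIVERSE: frozenset[ModuleId] = frozenset({BA, EXPOSURE})
QUESTIONNAIRE_UNIVERSE: frozenset[ModuleId] = frozenset({SLEEP, EPA, WELLNESS})

#: Hub nodes: advice flows only from edges touching anxiety or sadness.
HUB_NODES: frozenset[str] = frozenset({"anxious", "sad"})

#: Trigger nodes per module: an edge between a hub and a trigger node
#: advises every module listing that trigger (social company is listed for
#: both Exposure and Behavioral Activation).
NETWORK_TRIGGERS: dict[ModuleId, frozenset[str]] = {
    EXPOSURE: frozenset(
        {"experiential_avoidance", "behavioral_avoidance", "social_company"}
    ),
    BA: frozenset({"social_company", "activity_investment"}),
    EPA: frozenset({"positive_affect", "angry", "loneliness"}),
    WELLNESS: frozenset({"stressed"}),
    SLEEP: frozenset({"fatigue"}),
}


class AdviceError(ValueError):
    pass


@dataclass(frozen=True)
class DiagnosticHistory:
    """Boolean remission history from the diagnostic interview."""

    participant_id: str
    remitted_depressive: bool
    remitted_anxiety: bool
    disorder_list: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not (self.remitted_depressive or self.remitted_anxiety):
            raise AdviceError(
                f"participant {self.participant_id}: at least one remitted "
                "anxiety or depressive disorder is required (inclusion criterion)"
            )


@dataclass(frozen=True)
class Provenance:
    source: str  # "interview" | "questionnaires" | "network"
    evidence: str


@dataclass(frozen=True)
class AdviceBundle:
    """Per-source advised-module sets for one participant, with provenance."""

    participant_id: str
    interview_advice: frozenset[ModuleId]
    questionnaire_advice: frozenset[ModuleId]
    network_advice: frozenset[ModuleId]
    provenance: tuple[tuple[ModuleId, Provenance], ...] = ()

    @property
    def union_advice(self) -> frozenset[ModuleId]:
        return self.interview_advice | self.questionnaire_advice | self.network_advice

    @property
    def primary_advice(self) -> frozenset[ModuleId]:
        """Interview + questionnaire advice (outranks network advice)."""
        return self.interview_advice | self.questionnaire_advice

    def provenance_for(self, module: ModuleId) -> tuple[Provenance, ...]:
        return tuple(p for m, p in self.provenance if m == module)


@dataclass(frozen=True)
class Candidate:
    option_index: int
    modules: frozenset[ModuleId]
    covered_primary: int = 0
    covered_network: int = 0
    time_consuming: bool = False

    @property
    def rank_key(self) -> tuple[int, int]:
        return (self.covered_primary, self.covered_network)


@dataclass(frozen=True)
class RankedPlan:
    participant_id: str
    candidates: tuple[Candidate, ...]  # ranked best-first
    tier_1: tuple[Candidate, ...]
    tier_2: tuple[Candidate, ...]
    advised_union: frozenset[ModuleId] = frozenset()
    script_text: str = ""
    chosen: frozenset[ModuleId] | None = None
    chosen_order: tuple[ModuleId, ...] = ()
    congruence: tuple[tuple[ModuleId, str], ...] = ()
    no_core_module_warning: bool = False

    @property
    def delivered_sequence(self) -> tuple[ModuleId, ...]:
        """Full module sequence: fixed openers, chosen order, closing plan."""
        if self.chosen is None:
            raise AdviceError("no choice recorded yet")
        return (FIXED_MODULES[0], FIXED_MODULES[1]) + self.chosen_order + (
            FIXED_MODULES[2],
        )


def advise_from_interview(dx: DiagnosticHistory) -> frozenset[ModuleId]:
    """Behavioral Activation for remitted depression, Exposure for anxiety."""
    advised = set()
    if dx.remitted_depressive:
        advised.add(BA)
    if dx.remitted_anxiety:
        advised.add(EXPOSURE)
    return frozenset(advised)


def advise_from_questionnaires(scores: QuestionnaireScores) -> frozenset[ModuleId]:
    advised = set()
    if scores.advise_sleep:
        advised.add(SLEEP)
    if scores.advise_epa:
        advised.add(EPA)
    if scores.advise_wellness:
        advised.add(WELLNESS)
    return frozenset(advised)


def advise_from_network(net: SymptomNetwork) -> frozenset[ModuleId]:
    """Modules whose trigger nodes share a retained edge with anxious/sad.

    An infeasible network yields the empty set; an anxious-sad edge by
    itself advises nothing; an edge to social company advises both
    Exposure and Behavioral Activation.
    """
    if not net.feasible:
        return frozenset()
    advised = set()
    for e in net.edges:
        pair = {e.node_a, e.node_b}
        hubs = pair & HUB_NODES
        others = pair - HUB_NODES
        if not hubs or not others:
            continue
        (other,) = others
        for module, triggers in NETWORK_TRIGGERS.items():
            if other in triggers:
                advised.add(module)
    return frozenset(advised)


def merge_advice(
    participant_id: str,
    interview: frozenset[ModuleId],
    questionnaires: frozenset[ModuleId],
    network: frozenset[ModuleId],
    *,
    evidence: dict[str, dict[ModuleId, str]] | None = None,
) -> AdviceBundle:
    """Combine the three sources into a bundle with per-module provenance."""
    if not interview <= INTERVIEW_UNIVERSE:
        raise AdviceError(f"interview advice outside its universe: {interview}")
    if not questionnaires <= QUESTIONNAIRE_UNIVERSE:
        raise AdviceError(f"questionnaire advice outside its universe: {questionnaires}")
    if not network <= OPTIONAL_MODULES:
        raise AdviceError(f"network advice outside the optional modules: {network}")
    evidence = evidence or {}
    prov = []
    for source, modules in (
        ("interview", interview),
        ("questionnaires", questionnaires),
        ("network", network),
    ):
        for m in sorted(modules, key=lambda x: x.value):
            note = evidence.get(source, {}).get(m, source)
            prov.append((m, Provenance(source, note)))
    return AdviceBundle(
        participant_id=participant_id,
        interview_advice=interview,
        questionnaire_advice=questionnaires,
        network_advice=network,
        provenance=tuple(prov),
    )


def enumerate_combinations() -> tuple[Candidate, ...]:
    """The 9 valid 3-module combinations, in canonical option order.

    Of the C(5,3)=10 triples, only those containing Behavioral Activation
    or Exposure are valid; the excluded one is {EPA, Sleep, Wellness}.
    Option indices are assigned canonically: BA-without-Exposure sets
    first, then Exposure-without-BA, then the three BA+Exposure sets
    (the time-consuming ones).
    """
    order = (BA, EXPOSURE, EPA, SLEEP, WELLNESS)
    triples = [frozenset(c) for c in itertools.combinations(order, 3)]
    valid = [t for t in triples if BA in t or EXPOSURE in t]

    def sort_key(t: frozenset[ModuleId]) -> tuple:
        group = 0 if (BA in t and EXPOSURE not in t) else (1 if BA not in t else 2)
        return (group, tuple(order.index(m) for m in sorted(t, key=order.index)))

    valid.sort(key=sort_key)
    return tuple(
        Candidate(
            option_index=i + 1,
            modules=t,
            time_consuming=(BA in t and EXPOSURE in t),
        )
        for i, t in enumerate(valid)
    )


def rank_combinations(bundle: AdviceBundle) -> RankedPlan:
    """Score and rank every candidate combination for one participant.

    Each candidate is scored (covered_primary, covered_network) and ranked
    lexicographically, ties broken by option index. ``tier_1`` holds every
    candidate attaining the maximal key; ``tier_2`` holds the next-best key
    when more than three modules were advised overall (the case in which a
    second recommendation was shown).
    """
    primary = bundle.primary_advice
    network_only = bundle.network_advice - primary
    scored = [
        replace(
            c,
            covered_primary=len(c.modules & primary),
            covered_network=len(c.modules & network_only),
        )
        for c in enumerate_combinations()
    ]
    scored.sort(key=lambda c: (-c.covered_primary, -c.covered_network, c.option_index))
    best_key = scored[0].rank_key
    tier_1 = tuple(c for c in scored if c.rank_key == best_key)
    tier_2: tuple[Candidate, ...] = ()
    if len(bundle.union_advice) > 3:
        next_keys = sorted({c.rank_key for c in scored if c.rank_key != best_key}, reverse=True)
        if next_keys:
            tier_2 = tuple(c for c in scored if c.rank_key == next_keys[0])
    return RankedPlan(
        participant_id=bundle.participant_id,
        candidates=tuple(scored),
        tier_1=tier_1,
        tier_2=tier_2,
        advised_union=bundle.union_advice,
    )


def render_script(
    bundle: AdviceBundle,
    plan: RankedPlan,
    net: SymptomNetwork | None = None,
    *,
    templates: dict | None = None,
) -> RankedPlan:
    """Render the shared-decision-making feedback script.

    One observation sentence per advice-triggering network edge (keyed by
    hub node, partner node, and weight sign), then one rationale sentence
    per advised module, then the recommended combinations.
    """
    lines: list[str] = []
    if net is not None and net.feasible:
        for e in net.edges:
            pair = {e.node_a, e.node_b}
            hubs = pair & HUB_NODES
            others = pair - HUB_NODES
            if not hubs or not others:
                continue
            lines.append(
                render_observation(
                    next(iter(hubs)), next(iter(others)), e.weight, templates=templates
                )
            )
    for m in sorted(bundle.union_advice, key=lambda x: x.value):
        lines.append(render_module_rationale(m.value, templates=templates))
    if plan.tier_1:
        rec = "; ".join(
            " + ".join(sorted(x.value for x in c.modules)) for c in plan.tier_1
        )
        lines.append(f"Recommended combination(s): {rec}.")
    if plan.tier_2:
        rec = "; ".join(
            " + ".join(sorted(x.value for x in c.modules)) for c in plan.tier_2
        )
        lines.append(f"Second recommendation(s): {rec}.")
    if any(c.time_consuming for c in plan.tier_1 + plan.tier_2):
        lines.append(
            "Note: combinations with both Behavioral Activation and Exposure "
            "are more time-consuming."
        )
    return replace(plan, script_text="\n".join(lines))


def record_choice(
    plan: RankedPlan, chosen_order: tuple[ModuleId, ...] | list[ModuleId]
) -> RankedPlan:
    """Record the shared-decision-making choice and annotate congruence.

    Any 3 distinct optional modules are accepted — the recommendations are
    guidance, not a rule — but a choice without Behavioral Activation or
    Exposure is flagged.
    """
    chosen_order = tuple(chosen_order)
    chosen = frozenset(chosen_order)
    if len(chosen_order) != 3 or len(chosen) != 3:
        raise AdviceError("exactly 3 distinct modules must be chosen")
    if not chosen <= OPTIONAL_MODULES:
        raise AdviceError(f"chosen modules must be optional modules, got {chosen}")
    congruence = []
    for m in sorted(OPTIONAL_MODULES, key=lambda x: x.value):
        if m in chosen and m in plan.advised_union:
            congruence.append((m, "advised_and_chosen"))
        elif m in plan.advised_union:
            congruence.append((m, "advised_not_chosen"))
        elif m in chosen:
            congruence.append((m, "chosen_not_advised"))
    return replace(
        plan,
        chosen=chosen,
        chosen_order=chosen_order,
        congruence=tuple(congruence),
        no_core_module_warning=not (chosen & {BA, EXPOSURE}),
    )
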