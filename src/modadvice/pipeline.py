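"""End-to-end orchestration: score -> network -> advise -> evaluate.

Per-participant failures are isolated: a participant whose data cannot be
processed is logged and skipped, and the run continues. Only systemic
problems (unreadable files, schema violations) abort a run.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path

from . import io
from .advice import (
    AdviceBundle,
    DiagnosticHistory,
    ModuleId,
    RankedPlan,
    advise_from_interview,
    advise_from_network,
    advise_from_questionnaires,
    merge_advice,
    rank_combinations,
    record_choice,
    render_script,
)
from .config import DEFAULT_CONFIG, RunConfig
from .congruency import ParticipantRecord, evaluation_report
from .network import EmaMatrix, SymptomNetwork, build_network
from .scoring import QuestionnaireScores, score_participant

log = logging.getLogger("modadvice")


@dataclass(frozen=True)
class ParticipantResult:
    participant_id: str
    scores: QuestionnaireScores
    network: SymptomNetwork
    bundle: AdviceBundle
    plan: RankedPlan


def personalize_participant(
    dx: DiagnosticHistory,
    srsq: tuple[int, ...],
    panas: tuple[int, ...],
    mhcsf: tuple[int, ...],
    ema: EmaMatrix | None,
    config: RunConfig = DEFAULT_CONFIG,
) -> ParticipantResult:
    """Run the full data-driven advice procedure for one participant."""
    scores = score_participant(dx.participant_id, srsq, panas, mhcsf, config=config)
    interview = advise_from_interview(dx)
    questionnaires = advise_from_questionnaires(scores)
    if ema is None:
        net = SymptomNetwork(
            dx.participant_id, False, infeasible_reason="no_ema_data"
        )
    else:
        net = build_network(ema, config)
    network_advice = advise_from_network(net)
    evidence = {
        "interview": {
            m: f"remitted {'depressive' if m.value.startswith('BEHAV') else 'anxiety'} disorder"
            for m in interview
        },
        "questionnaires": _questionnaire_evidence(scores, config),
        "network": {
            m: "; ".join(
                f"{e.node_a}-{e.node_b} ({e.weight:+.2f})" for e in net.edges
            )
            or (net.infeasible_reason or "network")
            for m in network_advice
        },
    }
    bundle = merge_advice(
        dx.participant_id, interview, questionnaires, network_advice, evidence=evidence
    )
    plan = render_script(bundle, rank_combinations(bundle), net)
    return ParticipantResult(dx.participant_id, scores, net, bundle, plan)


def _questionnaire_evidence(
    scores: QuestionnaireScores, config: RunConfig
) -> dict[ModuleId, str]:
    ev = {}
    if scores.advise_sleep:
        ev[ModuleId.SLEEP] = f"SRSQ total {scores.srsq_total} > {config.srsq_cutoff}"
    if scores.advise_epa:
        ev[ModuleId.ENHANCING_POSITIVE_AFFECT] = (
            f"PANAS PA {scores.panas_pa} / NA {scores.panas_na} "
            f"(cutoffs <{config.panas_pa_cutoff:g} / >{config.panas_na_cutoff:g})"
        )
    if scores.advise_wellness:
        ev[ModuleId.WELLNESS] = (
            "legacy rule: always advised"
            if config.legacy_wellness
            else "not flourishing"
        )
    return ev


def read_choices_csv(path: str | Path) -> dict[str, tuple[ModuleId, ...]]:
    """Chosen-module file: columns participant_id, chosen (semicolon list, in order)."""
    out: dict[str, tuple[ModuleId, ...]] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"participant_id", "chosen"} <= set(
            reader.fieldnames
        ):
            raise io.CsvFormatError(f"{path}: header must include participant_id,chosen")
        for row in reader:
            out[row["participant_id"]] = tuple(
                ModuleId(s) for s in row["chosen"].split(";") if s
            )
    return out


def run_pipeline(
    questionnaires_path: str | Path,
    diagnoses_path: str | Path,
    ema_path: str | Path,
    out_dir: str | Path,
    config: RunConfig = DEFAULT_CONFIG,
    choices_path: str | Path | None = None,
) -> int:
    """Process a whole cohort from files; returns a process exit status.

    Writes one plan JSON and one network JSON per participant plus, when a
    choices file is given, the cohort CSV and the congruency report.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log.info("thresholds in force: %s", config.model_dump())
    questionnaires = io.read_questionnaire_csv(questionnaires_path, config)
    diagnoses = {d.participant_id: d for d in io.read_diagnoses_csv(diagnoses_path)}
    emas = {e.participant_id: e for e in io.read_ema_csv(ema_path)}
    choices = read_choices_csv(choices_path) if choices_path else None

    results: list[ParticipantResult] = []
    failures = 0
    for pid, srsq, panas, mhc in questionnaires:
        try:
            dx = diagnoses.get(pid)
            if dx is None:
                raise ValueError(f"participant {pid} missing from diagnoses file")
            res = personalize_participant(
                dx, srsq, panas, mhc, emas.get(pid), config
            )
            if choices is not None and pid in choices:
                res = ParticipantResult(
                    res.participant_id,
                    res.scores,
                    res.network,
                    res.bundle,
                    record_choice(res.plan, choices[pid]),
                )
            results.append(res)
        except Exception:
            failures += 1
            log.exception("participant %s failed; continuing", pid)
    for res in results:
        io.write_plan_json(res.plan, out_dir / f"plan_{res.participant_id}.json")
        io.write_network_json(res.network, out_dir / f"network_{res.participant_id}.json")
    if choices is not None:
        records = tuple(
            ParticipantRecord(
                participant_id=r.participant_id,
                interview_advice=r.bundle.interview_advice,
                questionnaire_advice=r.bundle.questionnaire_advice,
                network_advice=r.bundle.network_advice,
                chosen=r.plan.chosen,
            )
            for r in results
            if r.plan.chosen is not None
        )
        io.write_cohort_csv(records, out_dir / "cohort.csv")
        if records:
            io.write_report(evaluation_report(records, config), out_dir)
    if not results:
        log.error("no participant processed successfully")
        return 1
    return 0
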