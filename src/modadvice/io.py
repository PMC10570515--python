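"""Readers and writers for the plain-text interchange formats.

Everything is CSV/TSV/JSON/Markdown. The EMA diary travels in long format
(one row per answered beep) with 14 slider columns plus the yes/no
social-company item; a configurable item->node mapping collapses these to
the 11 network nodes (default: the ten slider-backed node names map to
themselves, ``social_company_yesno`` maps to ``social_company`` recoded
0/100, and the four remaining diary items are ignored).
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Iterable

import numpy as np

from .advice import DiagnosticHistory, ModuleId, RankedPlan
from .config import DEFAULT_CONFIG, RunConfig
from .congruency import ParticipantRecord
from .network import NODE_NAMES, EmaMatrix, SymptomNetwork
from .scoring import QuestionnaireScores

#: Diary slider items that do not feed a network node under the default map.
FILLER_ITEMS: tuple[str, ...] = ("restless", "worrying", "relaxed", "physically_active")

SLIDER_NODE_ITEMS: tuple[str, ...] = tuple(n for n in NODE_NAMES if n != "social_company")
EMA_SLIDER_COLUMNS: tuple[str, ...] = SLIDER_NODE_ITEMS + FILLER_ITEMS
EMA_COLUMNS: tuple[str, ...] = (
    ("participant_id", "day", "beep") + EMA_SLIDER_COLUMNS + ("social_company_yesno",)
)

#: Default item->node mapping (column name -> node name).
DEFAULT_ITEM_MAP: dict[str, str] = {
    **{n: n for n in SLIDER_NODE_ITEMS},
    "social_company_yesno": "social_company",
}

QUESTIONNAIRE_COLUMNS: tuple[str, ...] = (
    ("participant_id",)
    + tuple(f"srsq_{i}" for i in range(1, 10))
    + tuple(f"panas_{i}" for i in range(1, 21))
    + tuple(f"mhc_{i}" for i in range(1, 15))
)


class CsvFormatError(ValueError):
    """Malformed input file; the message lists the offending lines."""


# ---------------------------------------------------------------------------
# questionnaires

def write_questionnaire_csv(
    rows: Iterable[tuple[str, tuple[int, ...], tuple[int, ...], tuple[int, ...]]],
    path: str | Path,
) -> None:
    """Rows of (participant_id, srsq 9 items, panas 20 items, mhc 14 items)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(QUESTIONNAIRE_COLUMNS)
        for pid, srsq, panas, mhc in rows:
            w.writerow([pid, *srsq, *panas, *mhc])


def read_questionnaire_csv(
    path: str | Path, config: RunConfig = DEFAULT_CONFIG
) -> list[tuple[str, tuple[int, ...], tuple[int, ...], tuple[int, ...]]]:
    """Parse and validate the one-row-per-participant questionnaire file.

    Missing cells are rejected unless ``config.allow_prorated_totals``,
    in which case they are mean-imputed within the instrument (rounded to
    the nearest coded value).
    """
    ranges = [("srsq", 9, 1, 3), ("panas", 20, 1, 5), ("mhc", 14, 0, 5)]
    out = []
    errors = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or tuple(reader.fieldnames) != QUESTIONNAIRE_COLUMNS:
            raise CsvFormatError(
                f"{path}: header must be exactly {','.join(QUESTIONNAIRE_COLUMNS)}"
            )
        for lineno, row in enumerate(reader, start=2):
            pid = row["participant_id"]
            instruments = []
            for prefix, n, lo, hi in ranges:
                vals: list[int | None] = []
                for i in range(1, n + 1):
                    cell = (row.get(f"{prefix}_{i}") or "").strip()
                    if cell == "":
                        vals.append(None)
                        continue
                    try:
                        v = int(cell)
                    except ValueError:
                        errors.append(f"line {lineno}: {prefix}_{i} not an integer: {cell!r}")
                        v = None
                    if v is not None and not lo <= v <= hi:
                        errors.append(f"line {lineno}: {prefix}_{i}={v} outside {lo}-{hi}")
                        v = None
                    vals.append(v)
                if any(v is None for v in vals):
                    present = [v for v in vals if v is not None]
                    if config.allow_prorated_totals and present:
                        fill = int(round(float(np.mean(present))))
                        fill = min(max(fill, lo), hi)
                        vals = [fill if v is None else v for v in vals]
                    else:
                        errors.append(
                            f"line {lineno}: participant {pid} has missing {prefix} items"
                        )
                        vals = [lo] * n  # placeholder; run fails below anyway
                instruments.append(tuple(vals))
            out.append((pid, *instruments))
    if errors:
        raise CsvFormatError(f"{path}: " + "; ".join(errors))
    return out


# ---------------------------------------------------------------------------
# diagnoses

def write_diagnoses_csv(dx: Iterable[DiagnosticHistory], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["participant_id", "remitted_depressive", "remitted_anxiety", "disorders"])
        for d in dx:
            w.writerow(
                [
                    d.participant_id,
                    "yes" if d.remitted_depressive else "no",
                    "yes" if d.remitted_anxiety else "no",
                    ";".join(d.disorder_list),
                ]
            )


def _parse_yesno(cell: str, where: str) -> bool:
    v = cell.strip().lower()
    if v in ("yes", "true", "1"):
        return True
    if v in ("no", "false", "0"):
        return False
    raise CsvFormatError(f"{where}: expected yes/no, got {cell!r}")


def read_diagnoses_csv(path: str | Path) -> list[DiagnosticHistory]:
    out = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        required = {"participant_id", "remitted_depressive", "remitted_anxiety"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise CsvFormatError(f"{path}: header must include {sorted(required)}")
        for lineno, row in enumerate(reader, start=2):
            out.append(
                DiagnosticHistory(
                    participant_id=row["participant_id"],
                    remitted_depressive=_parse_yesno(
                        row["remitted_depressive"], f"{path} line {lineno}"
                    ),
                    remitted_anxiety=_parse_yesno(
                        row["remitted_anxiety"], f"{path} line {lineno}"
                    ),
                    disorder_list=tuple(
                        s for s in (row.get("disorders") or "").split(";") if s
                    ),
                )
            )
    return out


# ---------------------------------------------------------------------------
# EMA diary

def write_ema_csv(emas: Iterable[EmaMatrix], path: str | Path) -> None:
    """Write answered beeps in long format (unanswered beeps are omitted).

    Filler diary items (which no node maps to) are written as the neutral
    midpoint 50 so files stay schema-complete.
    """
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(EMA_COLUMNS)
        for ema in emas:
            idx = ema.beep_index or tuple(range(1, ema.completed_count + 1))
            for row_i, beep in enumerate(idx):
                day, within = (beep - 1) // 6 + 1, (beep - 1) % 6 + 1
                vals = {
                    n: ema.values[row_i, ema.node_names.index(n)]
                    for n in SLIDER_NODE_ITEMS
                }
                social = ema.values[row_i, ema.node_names.index("social_company")]
                w.writerow(
                    [ema.participant_id, day, within]
                    + [f"{vals[n]:g}" for n in SLIDER_NODE_ITEMS]
                    + ["50"] * len(FILLER_ITEMS)
                    + ["yes" if social >= 50 else "no"]
                )


def read_ema_csv(
    path: str | Path, item_map: dict[str, str] | None = None
) -> list[EmaMatrix]:
    """Parse the long-format diary into one validated EmaMatrix per person.

    A beep is completed only if every mapped item is present and valid;
    incomplete beeps are dropped (listwise deletion). Duplicate
    (participant, day, beep) rows and out-of-range values are rejected
    with their line numbers.
    """
    item_map = dict(item_map or DEFAULT_ITEM_MAP)
    if set(item_map.values()) != set(NODE_NAMES):
        raise CsvFormatError("item map must cover exactly the 11 network nodes")
    per_pid: dict[str, dict[int, list[float]]] = {}
    order: list[str] = []
    errors: list[str] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise CsvFormatError(f"{path}: empty file")
        missing_cols = set(item_map) - set(reader.fieldnames)
        if missing_cols or not {"participant_id", "day", "beep"} <= set(reader.fieldnames):
            raise CsvFormatError(f"{path}: missing columns {sorted(missing_cols)}")
        for lineno, row in enumerate(reader, start=2):
            pid = row["participant_id"]
            try:
                day, beep = int(row["day"]), int(row["beep"])
            except (TypeError, ValueError):
                errors.append(f"line {lineno}: non-integer day/beep")
                continue
            if not (1 <= day <= 14 and 1 <= beep <= 6):
                errors.append(f"line {lineno}: day {day}/beep {beep} outside 1-14/1-6")
                continue
            beep_idx = (day - 1) * 6 + beep
            if pid not in per_pid:
                per_pid[pid] = {}
                order.append(pid)
            if beep_idx in per_pid[pid]:
                errors.append(
                    f"line {lineno}: duplicate beep (participant {pid}, day {day}, beep {beep})"
                )
                continue
            node_vals: dict[str, float] = {}
            complete = True
            for col, node in item_map.items():
                cell = (row.get(col) or "").strip()
                if cell == "":
                    complete = False
                    continue
                if col.endswith("_yesno"):
                    try:
                        node_vals[node] = 100.0 if _parse_yesno(cell, "") else 0.0
                    except CsvFormatError:
                        errors.append(f"line {lineno}: {col} expected yes/no, got {cell!r}")
                    continue
                try:
                    v = float(cell)
                except ValueError:
                    errors.append(f"line {lineno}: {col} not numeric: {cell!r}")
                    continue
                if not 0 <= v <= 100:
                    errors.append(f"line {lineno}: {col}={v:g} outside 0-100")
                    continue
                node_vals[node] = v
            if errors and errors[-1].startswith(f"line {lineno}"):
                continue
            if complete and len(node_vals) == len(NODE_NAMES):
                per_pid[pid][beep_idx] = [node_vals[n] for n in NODE_NAMES]
    if errors:
        raise CsvFormatError(f"{path}: " + "; ".join(errors))
    out = []
    for pid in order:
        beeps = sorted(per_pid[pid])
        values = np.array([per_pid[pid][b] for b in beeps], dtype=float).reshape(
            len(beeps), len(NODE_NAMES)
        )
        out.append(EmaMatrix(pid, values, beep_index=tuple(beeps)))
    return out


# ---------------------------------------------------------------------------
# network / plan / report serialization

def write_network_json(net: SymptomNetwork, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(net.to_dict(), indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )


def write_network_tsv(net: SymptomNetwork, path: str | Path) -> None:
    lines = ["node_a\tnode_b\tweight\tp_value"]
    for e in net.edges:
        pv = "" if e.p_value is None else f"{e.p_value:.6g}"
        lines.append(f"{e.node_a}\t{e.node_b}\t{e.weight:.6g}\t{pv}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_network_dot(net: SymptomNetwork, path: str | Path) -> None:
    lines = [f'graph "{net.participant_id}" {{']
    for n in net.retained_nodes:
        lines.append(f"  {n};")
    for e in net.edges:
        style = "solid" if e.weight >= 0 else "dashed"
        lines.append(
            f'  {e.node_a} -- {e.node_b} [label="{e.weight:.2f}", style={style}];'
        )
    lines.append("}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def plan_to_dict(plan: RankedPlan) -> dict:
    return {
        "participant_id": plan.participant_id,
        "advised_union": sorted(m.value for m in plan.advised_union),
        "candidates": [
            {
                "option_index": c.option_index,
                "modules": sorted(m.value for m in c.modules),
                "covered_primary": c.covered_primary,
                "covered_network": c.covered_network,
                "time_consuming": c.time_consuming,
            }
            for c in plan.candidates
        ],
        "tier_1": [sorted(m.value for m in c.modules) for c in plan.tier_1],
        "tier_2": [sorted(m.value for m in c.modules) for c in plan.tier_2],
        "chosen": None if plan.chosen is None else sorted(m.value for m in plan.chosen),
        "chosen_order": [m.value for m in plan.chosen_order],
        "congruence": [[m.value, s] for m, s in plan.congruence],
        "no_core_module_warning": plan.no_core_module_warning,
        "script_text": plan.script_text,
    }


def write_plan_json(plan: RankedPlan, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(plan_to_dict(plan), indent=2, sort_keys=True) + "\n",
        encoding="utf-8",
    )


def write_cohort_csv(records: Iterable[ParticipantRecord], path: str | Path) -> None:
    """Per-participant advice and choice sets (semicolon-delimited cells)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(
            ["participant_id", "interview_advice", "questionnaire_advice",
             "network_advice", "chosen"]
        )
        for r in records:
            w.writerow(
                [
                    r.participant_id,
                    _set_cell(r.interview_advice),
                    _set_cell(r.questionnaire_advice),
                    _set_cell(r.network_advice),
                    _set_cell(r.chosen),
                ]
            )


def read_cohort_csv(path: str | Path) -> tuple[ParticipantRecord, ...]:
    out = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        required = {
            "participant_id", "interview_advice", "questionnaire_advice",
            "network_advice", "chosen",
        }
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise CsvFormatError(f"{path}: header must include {sorted(required)}")
        for lineno, row in enumerate(reader, start=2):
            try:
                out.append(
                    ParticipantRecord(
                        participant_id=row["participant_id"],
                        interview_advice=_parse_set(row["interview_advice"]),
                        questionnaire_advice=_parse_set(row["questionnaire_advice"]),
                        network_advice=_parse_set(row["network_advice"]),
                        chosen=_parse_set(row["chosen"]),
                    )
                )
            except (KeyError, ValueError) as err:
                raise CsvFormatError(f"{path} line {lineno}: {err}") from err
    return tuple(out)


def _set_cell(modules: frozenset[ModuleId]) -> str:
    return ";".join(sorted(m.value for m in modules))


def _parse_set(cell: str) -> frozenset[ModuleId]:
    return frozenset(ModuleId(s) for s in (cell or "").split(";") if s)


def write_report(report: dict, out_dir: str | Path) -> tuple[Path, Path]:
    """Emit report.json and report.md with deterministic content ordering."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    json_path = out_dir / "report.json"
    md_path = out_dir / "report.md"
    json_path.write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    md_path.write_text(report_markdown(report), encoding="utf-8")
    return json_path, md_path


def report_markdown(report: dict) -> str:
    """Human-readable Markdown rendering of an evaluation report."""
    lines = [
        "# Congruency evaluation report",
        "",
        f"Participants: {report['n_participants']}",
        "",
        "## Frequency of advised and chosen modules",
        "",
        "| Module | Interview | Questionnaires | Network | Chosen |",
        "|---|---|---|---|---|",
    ]
    freq = report["frequencies"]
    modules = sorted(
        {m for axis in freq.values() for m in axis}
    )
    for m in modules:
        cells = []
        for axis in ("interview", "questionnaires", "network", "chosen"):
            e = freq[axis].get(m)
            cells.append("-" if e is None else f"{e['count']} ({e['percent']:.2f}%)")
        lines.append(f"| {m} | " + " | ".join(cells) + " |")
    card = report["advice_cardinality"]
    lines += [
        "",
        "## Advised-module cardinality",
        "",
        f"- fewer than 3 advised: {card['below_3']['count']} ({card['below_3']['percent']:.2f}%)",
        f"- exactly 3 advised: {card['exactly_3']['count']} ({card['exactly_3']['percent']:.2f}%)",
        f"- more than 3 advised: {card['above_3']['count']} ({card['above_3']['percent']:.2f}%)",
        "",
        "## Advice-source congruency (vs. network model)",
        "",
        "| Module | Source | nn | ny | yn | yy | chi-square (df=1) | p |",
        "|---|---|---|---|---|---|---|---|",
    ]
    for e in report["source_vs_network"]:
        cs = e["chi_square"]
        if cs["performed"]:
            stat, p = f"{cs['statistic']:.3f}", f"{cs['p_value']:.2f}"
        else:
            stat, p = f"not performed ({cs['skip_reason']})", "-"
        c = e["cells"]
        lines.append(
            f"| {e['module']} | {e['axis_a']} | {c['nn']['count']} | {c['ny']['count']} "
            f"| {c['yn']['count']} | {c['yy']['count']} | {stat} | {p} |"
        )
    lines += [
        "",
        "## Chosen modules vs. data-driven advice",
        "",
        "| Module | Advice axis | nn | ny | yn | yy |",
        "|---|---|---|---|---|---|",
    ]
    for e in report["chosen_vs_sources"]:
        c = e["cells"]
        lines.append(
            f"| {e['module']} | {e['axis_a']} | {c['nn']['count']} | {c['ny']['count']} "
            f"| {c['yn']['count']} | {c['yy']['count']} |"
        )
    for note in report.get("footnotes", []):
        lines += ["", f"*{note}*"]
    return "\n".join(lines) + "\n"
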