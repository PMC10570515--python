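"""Cohort-level congruency evaluation of advice sources and choices.

Given per-participant advice sets (interview / questionnaires / network)
and the modules chosen through shared decision-making, this module builds
frequency tables, 2x2 contingency tables between any two axes, and
Yates-corrected Pearson chi-square tests with explicit skip rules for
tables with very low cell counts (the evaluation reports such tables
descriptively instead of testing them).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy.stats import chi2

from .advice import (
    BA,
    EPA,
    EXPOSURE,
    INTERVIEW_UNIVERSE,
    OPTIONAL_MODULES,
    QUESTIONNAIRE_UNIVERSE,
    SLEEP,
    WELLNESS,
    ModuleId,
)
from .config import DEFAULT_CONFIG, RunConfig

REPORT_SCHEMA_VERSION = "1.0"

#: Which modules can appear on each contingency axis (a dash in the
#: published tables: e.g. Behavioral Activation has no questionnaire axis).
AXIS_UNIVERSES: dict[str, frozenset[ModuleId]] = {
    "interview": INTERVIEW_UNIVERSE,
    "questionnaires": QUESTIONNAIRE_UNIVERSE,
    "network": OPTIONAL_MODULES,
    "chosen": OPTIONAL_MODULES,
}


class EvaluationError(ValueError):
    pass


@dataclass(frozen=True)
class ParticipantRecord:
    participant_id: str
    interview_advice: frozenset[ModuleId]
    questionnaire_advice: frozenset[ModuleId]
    network_advice: frozenset[ModuleId]
    chosen: frozenset[ModuleId]

    def __post_init__(self) -> None:
        if len(self.chosen) != 3:
            raise EvaluationError(
                f"participant {self.participant_id}: chosen set must have 3 modules"
            )
        for name, universe in (
            ("interview", INTERVIEW_UNIVERSE),
            ("questionnaires", QUESTIONNAIRE_UNIVERSE),
            ("network", OPTIONAL_MODULES),
            ("chosen", OPTIONAL_MODULES),
        ):
            if not self.advice_for(name) <= universe:
                raise EvaluationError(
                    f"participant {self.participant_id}: {name} set outside universe"
                )

    def advice_for(self, axis: str) -> frozenset[ModuleId]:
        return {
            "interview": self.interview_advice,
            "questionnaires": self.questionnaire_advice,
            "network": self.network_advice,
            "chosen": self.chosen,
        }[axis]

    def union_advice(self, *, exclude_wellness: bool = False) -> frozenset[ModuleId]:
        union = self.interview_advice | self.questionnaire_advice | self.network_advice
        return union - {WELLNESS} if exclude_wellness else union


CohortTable = tuple[ParticipantRecord, ...]


def percentage(count: int, total: int) -> float:
    """Percentage rounded half-up to 2 decimals (display convention)."""
    if total <= 0:
        raise EvaluationError("total must be positive")
    pct = Decimal(count) / Decimal(total) * 100
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ContingencyTable2x2:
    """2x2 cross-tabulation: rows = axis_a membership, cols = axis_b."""

    module: ModuleId
    axis_a: str
    axis_b: str
    n_nn: int
    n_ny: int
    n_yn: int
    n_yy: int

    @property
    def total(self) -> int:
        return self.n_nn + self.n_ny + self.n_yn + self.n_yy

    @property
    def cells(self) -> tuple[int, int, int, int]:
        return (self.n_nn, self.n_ny, self.n_yn, self.n_yy)

    def as_array(self) -> np.ndarray:
        return np.array([[self.n_nn, self.n_ny], [self.n_yn, self.n_yy]], dtype=float)


@dataclass(frozen=True)
class ChiSquareResult:
    performed: bool
    statistic: float | None = None
    df: int = 1
    p_value: float | None = None
    skip_reason: str | None = None
    expected_below_5: bool = False


def frequency_table(
    cohort: CohortTable,
) -> dict[str, dict[str, dict[str, float | int]]]:
    """Per-module counts and percentages per advice source and for choices."""
    if not cohort:
        raise EvaluationError("empty cohort")
    n = len(cohort)
    out: dict[str, dict[str, dict[str, float | int]]] = {}
    for axis in ("interview", "questionnaires", "network", "chosen"):
        universe = AXIS_UNIVERSES[axis]
        table = {}
        for m in sorted(OPTIONAL_MODULES, key=lambda x: x.value):
            if m not in universe:
                continue
            count = sum(1 for r in cohort if m in r.advice_for(axis))
            table[m.value] = {"count": count, "percent": percentage(count, n)}
        out[axis] = table
    return out


def advice_cardinality_summary(
    cohort: CohortTable, *, exclude_wellness: bool = False
) -> dict[str, dict[str, float | int]]:
    """How many participants were advised fewer / exactly / more than the
    three modules they must choose."""
    if not cohort:
        raise EvaluationError("empty cohort")
    n = len(cohort)
    below = sum(
        1 for r in cohort if len(r.union_advice(exclude_wellness=exclude_wellness)) < 3
    )
    above = sum(
        1 for r in cohort if len(r.union_advice(exclude_wellness=exclude_wellness)) > 3
    )
    exact = n - below - above
    return {
        "below_3": {"count": below, "percent": percentage(below, n)},
        "exactly_3": {"count": exact, "percent": percentage(exact, n)},
        "above_3": {"count": above, "percent": percentage(above, n)},
    }


def cross_tabulate(
    cohort: CohortTable, module: ModuleId, axis_a: str, axis_b: str
) -> ContingencyTable2x2:
    """Count participants by (module in axis_a set, module in axis_b set)."""
    if not cohort:
        raise EvaluationError("empty cohort")
    for axis in (axis_a, axis_b):
        if axis not in AXIS_UNIVERSES:
            raise EvaluationError(f"unknown axis {axis!r}")
        if module not in AXIS_UNIVERSES[axis]:
            raise EvaluationError(
                f"module {module.value} has no {axis} axis (dash in the table)"
            )
    cells = {"nn": 0, "ny": 0, "yn": 0, "yy": 0}
    for r in cohort:
        a = "y" if module in r.advice_for(axis_a) else "n"
        b = "y" if module in r.advice_for(axis_b) else "n"
        cells[a + b] += 1
    return ContingencyTable2x2(
        module, axis_a, axis_b, cells["nn"], cells["ny"], cells["yn"], cells["yy"]
    )


def yates_chi_square(
    table: ContingencyTable2x2 | tuple[int, int, int, int],
    min_cell: int = 2,
) -> ChiSquareResult:
    """Pearson chi-square with Yates' continuity correction on a 2x2 table.

    The test is skipped (``performed=False``) when any observed cell is
    below ``min_cell`` or a margin is zero; the evaluation reported such
    tables descriptively only. The correction term |O-E|-0.5 is floored at
    zero so near-perfect fits are not inflated. Expected counts below 5 do
    not skip the test but set ``expected_below_5``, flagging results to be
    interpreted with caution.
    """
    if isinstance(table, ContingencyTable2x2):
        obs = table.as_array()
    else:
        obs = np.array(table, dtype=float).reshape(2, 2)
    if (obs < 0).any() or (obs != np.floor(obs)).any():
        raise EvaluationError("cells must be non-negative integers")
    low = obs.min()
    if low < min_cell:
        return ChiSquareResult(
            performed=False,
            skip_reason=f"cell count {int(low)} below minimum {min_cell}",
        )
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    n = obs.sum()
    if (row == 0).any() or (col == 0).any():
        return ChiSquareResult(performed=False, skip_reason="zero margin")
    expected = np.outer(row, col) / n
    corrected = np.maximum(np.abs(obs - expected) - 0.5, 0.0)
    stat = float((corrected**2 / expected).sum())
    return ChiSquareResult(
        performed=True,
        statistic=stat,
        df=1,
        p_value=float(chi2.sf(stat, 1)),
        expected_below_5=bool((expected < 5).any()),
    )


#: The advised-vs-advised comparisons of the evaluation: interview sources
#: for the interview-advisable modules, questionnaires for the rest.
SOURCE_PAIRINGS: tuple[tuple[ModuleId, str], ...] = (
    (BA, "interview"),
    (EXPOSURE, "interview"),
    (EPA, "questionnaires"),
    (SLEEP, "questionnaires"),
    (WELLNESS, "questionnaires"),
)


def evaluation_report(
    cohort: CohortTable, config: RunConfig = DEFAULT_CONFIG
) -> dict:
    """Assemble the full congruency report (frequency + contingency tables).

    With ``config.exclude_wellness`` the Wellness rows are dropped from the
    contingency analyses (but kept, footnoted, in the frequency table),
    mirroring how the deployed-rule error was handled in the evaluation.
    """
    if not cohort:
        raise EvaluationError("empty cohort")
    modules_tested = [
        (m, src)
        for m, src in SOURCE_PAIRINGS
        if not (config.exclude_wellness and m is WELLNESS)
    ]
    source_vs_network = []
    for m, src in modules_tested:
        tab = cross_tabulate(cohort, m, src, "network")
        res = yates_chi_square(tab, config.min_cell)
        source_vs_network.append(_table_entry(tab, res))
    chosen_vs_sources = []
    for m, src in modules_tested:
        for axis in (src, "network"):
            tab = cross_tabulate(cohort, m, axis, "chosen")
            chosen_vs_sources.append(_table_entry(tab, None))
    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "n_participants": len(cohort),
        "config": {
            "min_cell": config.min_cell,
            "exclude_wellness": config.exclude_wellness,
            "legacy_wellness": config.legacy_wellness,
        },
        "frequencies": frequency_table(cohort),
        "advice_cardinality": advice_cardinality_summary(
            cohort, exclude_wellness=config.exclude_wellness
        ),
        "source_vs_network": source_vs_network,
        "chosen_vs_sources": chosen_vs_sources,
    }
    if config.exclude_wellness:
        report["footnotes"] = [
            "Wellness excluded from contingency analyses (advice rule error)."
        ]
    return report


def _table_entry(tab: ContingencyTable2x2, res: ChiSquareResult | None) -> dict:
    n = tab.total
    entry = {
        "module": tab.module.value,
        "axis_a": tab.axis_a,
        "axis_b": tab.axis_b,
        "cells": {
            "nn": {"count": tab.n_nn, "percent": percentage(tab.n_nn, n)},
            "ny": {"count": tab.n_ny, "percent": percentage(tab.n_ny, n)},
            "yn": {"count": tab.n_yn, "percent": percentage(tab.n_yn, n)},
            "yy": {"count": tab.n_yy, "percent": percentage(tab.n_yy, n)},
        },
    }
    if res is not None:
        entry["chi_square"] = {
            "performed": res.performed,
            "statistic": None if res.statistic is None else round(res.statistic, 3),
            "df": res.df,
            "p_value": None if res.p_value is None else round(res.p_value, 4),
            "skip_reason": res.skip_reason,
            "expected_below_5": res.expected_below_5,
        }
    return entry
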