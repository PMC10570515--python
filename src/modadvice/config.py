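"""Run configuration: every threshold the personalization procedure uses.

All cutoffs default to the values of the deployed procedure so a default run
reproduces its behavior; they are deliberately centralized because the choice
of thresholds is an open research question in this kind of data-driven
module selection.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal

from pydantic import BaseModel, Field


class RunConfig(BaseModel):
    """Thresholds, flags, and run parameters for the personalization engine.

    Parameters
    ----------
    srsq_cutoff : float
        Sleep Reduction Screening Questionnaire clinical cutoff; the Sleep
        module is advised when the total (range 9-27) is strictly greater.
    panas_pa_cutoff, panas_na_cutoff : float
        Suboptimal-affect cutoffs: PA strictly below ``panas_pa_cutoff`` or
        NA strictly above ``panas_na_cutoff`` advises Enhancing Positive
        Affect (midpoint of the 10-50 subscale range).
    panas_rule : {"or", "and"}
        Whether one or both affect conditions must hold.
    mhc_hedonic_min_items : int
        Minimum number of items 1-3 scored 4 or 5 for the hedonic part of
        the flourishing criterion.
    mhc_functioning_min_items : int
        Minimum number of items 4-14 scored 4 or 5 ("more than 6" -> 7).
    sd_min : float
        EMA nodes with sample standard deviation below this are pruned
        before network estimation (slider units, 0-100 scale).
    edge_min : float
        Partial correlations with absolute value below this are excluded
        from the network.
    min_beeps : int
        Minimum number of fully answered beeps (out of 84) required to
        estimate a network.
    min_cell : int
        Chi-square tests are skipped when any observed 2x2 cell is below
        this count.
    signed_edges : bool
        If True the edge threshold applies to the signed value (negative
        partial correlations are always excluded) instead of the absolute
        value.
    legacy_wellness : bool
        Reproduce the deployed (erroneous) Wellness rule: the questionnaire
        step always advises Wellness regardless of flourishing.
    exclude_wellness : bool
        Drop Wellness from congruency analyses (as the published evaluation
        did, because of the legacy rule).
    allow_prorated_totals : bool
        Mean-impute missing questionnaire items instead of rejecting
        partial forms (exploratory use only).
    """

    srsq_cutoff: float = Field(default=17.3, gt=0)
    panas_pa_cutoff: float = Field(default=30.0, gt=0)
    panas_na_cutoff: float = Field(default=30.0, gt=0)
    panas_rule: Literal["or", "and"] = "or"
    mhc_hedonic_min_items: int = Field(default=1, ge=0)
    mhc_functioning_min_items: int = Field(default=7, ge=0)

    sd_min: float = Field(default=10.0, gt=0)
    edge_min: float = Field(default=0.3, gt=0)
    min_beeps: int = Field(default=50, gt=0)
    condition_max: float = Field(default=1e8, gt=0)

    min_cell: int = Field(default=2, ge=0)

    signed_edges: bool = False
    legacy_wellness: bool = False
    exclude_wellness: bool = False
    allow_prorated_totals: bool = False

    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.model_validate(json.load(fh))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(self.model_dump(), indent=2, sort_keys=True) + "\n",
            encoding="utf-8",
        )


DEFAULT_CONFIG = RunConfig()
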