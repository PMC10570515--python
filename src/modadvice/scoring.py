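"""Questionnaire scoring and per-questionnaire module advice flags.

Three self-report instruments feed the questionnaire step of the
personalization procedure:

* SRSQ (Sleep Reduction Screening Questionnaire): 9 items on a 3-point
  scale (1-3); higher totals mean more sleep reduction, i.e. worse sleep.
  Totals strictly above the clinical cutoff (17.3) advise the Sleep module.
* PANAS (Positive and Negative Affect Schedule): 20 items on a 5-point
  scale (1-5), ten per subscale in the standard alternating assignment.
  Suboptimal affect (PA < 30 or NA > 30, subscale range 10-50) advises
  Enhancing Positive Affect.
* MHC-SF (Mental Health Continuum - Short Form): 14 items on a 6-point
  scale (0-5). Flourishing requires at least one of items 1-3 scored 4 or
  5 (hedonic wellbeing) and more than 6 of items 4-14 scored 4 or 5
  (positive functioning); its absence advises Wellness.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

from .config import DEFAULT_CONFIG, RunConfig


class Instrument(str, Enum):
    SRSQ = "SRSQ"
    PANAS = "PANAS"
    MHC_SF = "MHC_SF"


#: (number of items, minimum item score, maximum item score)
INSTRUMENT_SPECS: dict[Instrument, tuple[int, int, int]] = {
    Instrument.SRSQ: (9, 1, 3),
    Instrument.PANAS: (20, 1, 5),
    Instrument.MHC_SF: (14, 0, 5),
}

#: Standard PANAS positive-affect item positions (1-based); the other ten
#: items form the negative-affect subscale.
PANAS_PA_ITEMS: frozenset[int] = frozenset({1, 3, 5, 9, 10, 12, 14, 16, 17, 19})

#: SRSQ keying vector: +1 keeps an item as coded, -1 reverse-keys it
#: (score -> 4 - score). The instrument's exact keying is not public; the
#: default applies no reversal, which is consistent with the 9-27 total range.
DEFAULT_SRSQ_KEYING: tuple[int, ...] = (1,) * 9


class ScoringError(ValueError):
    """Invalid item responses (wrong count or out-of-range score)."""


@dataclass(frozen=True)
class ItemResponseSet:
    """One participant's complete responses to one instrument."""

    participant_id: str
    instrument: Instrument
    responses: tuple[int, ...]

    def __post_init__(self) -> None:
        n, lo, hi = INSTRUMENT_SPECS[self.instrument]
        if len(self.responses) != n:
            raise ScoringError(
                f"{self.instrument.value} expects {n} items, "
                f"got {len(self.responses)} (participant {self.participant_id})"
            )
        for i, r in enumerate(self.responses, start=1):
            if not isinstance(r, int) or isinstance(r, bool) or not lo <= r <= hi:
                raise ScoringError(
                    f"{self.instrument.value} item {i} score {r!r} outside "
                    f"coded range {lo}-{hi} (participant {self.participant_id})"
                )


@dataclass(frozen=True)
class QuestionnaireScores:
    """Subscale totals and the derived module-advice flags for one participant."""

    participant_id: str
    srsq_total: int
    panas_pa: int
    panas_na: int
    mhc_item1to3_max_met: bool
    mhc_item4to14_count: int
    flourishing: bool
    advise_sleep: bool
    advise_epa: bool
    advise_wellness: bool


def _check(responses: Sequence[int], instrument: Instrument) -> tuple[int, ...]:
    return ItemResponseSet("_", instrument, tuple(responses)).responses


def score_srsq(
    responses: Sequence[int],
    *,
    keying: Sequence[int] = DEFAULT_SRSQ_KEYING,
    config: RunConfig = DEFAULT_CONFIG,
) -> tuple[int, bool]:
    """Score the SRSQ; return ``(total, advise_sleep)``.

    The total is the sum of the keyed 9 items (range 9-27); the Sleep module
    is advised for totals strictly greater than ``config.srsq_cutoff``, so
    with the default cutoff of 17.3 integer totals of 18 and above trigger
    the advice.
    """
    resp = _check(responses, Instrument.SRSQ)
    if len(keying) != 9 or any(k not in (-1, 1) for k in keying):
        raise ScoringError("SRSQ keying vector must be nine entries of +1/-1")
    keyed = tuple(r if k == 1 else 4 - r for r, k in zip(resp, keying))
    total = sum(keyed)
    return total, total > config.srsq_cutoff


def score_panas(
    responses: Sequence[int],
    *,
    pa_items: frozenset[int] = PANAS_PA_ITEMS,
    config: RunConfig = DEFAULT_CONFIG,
) -> tuple[int, int, bool]:
    """Score the PANAS; return ``(pa, na, advise_epa)``.

    ``pa_items`` holds the 1-based positions of the ten positive-affect
    items. Suboptimal affect (PA strictly below the PA cutoff, NA strictly
    above the NA cutoff, combined by ``config.panas_rule``) advises the
    Enhancing Positive Affect module.
    """
    resp = _check(responses, Instrument.PANAS)
    if len(pa_items) != 10 or not all(1 <= i <= 20 for i in pa_items):
        raise ScoringError("PANAS subscale map must assign exactly 10 of items 1-20 to PA")
    pa = sum(r for i, r in enumerate(resp, start=1) if i in pa_items)
    na = sum(r for i, r in enumerate(resp, start=1) if i not in pa_items)
    low_pa = pa < config.panas_pa_cutoff
    high_na = na > config.panas_na_cutoff
    advise = (low_pa or high_na) if config.panas_rule == "or" else (low_pa and high_na)
    return pa, na, advise


def score_mhcsf(
    responses: Sequence[int], *, config: RunConfig = DEFAULT_CONFIG
) -> tuple[bool, bool]:
    """Score the MHC-SF flourishing criterion; return ``(flourishing, advise_wellness)``.

    Flourishing requires at least ``config.mhc_hedonic_min_items`` of items
    1-3 scored 4 or 5 and at least ``config.mhc_functioning_min_items`` of
    items 4-14 scored 4 or 5. Wellness is advised when the participant does
    not flourish (unless the legacy flag forces the advice, see
    :func:`score_participant`).
    """
    resp = _check(responses, Instrument.MHC_SF)
    hedonic = sum(1 for r in resp[:3] if r >= 4)
    functioning = sum(1 for r in resp[3:] if r >= 4)
    flourishing = (
        hedonic >= config.mhc_hedonic_min_items
        and functioning >= config.mhc_functioning_min_items
    )
    advise = True if config.legacy_wellness else not flourishing
    return flourishing, advise


def score_participant(
    participant_id: str,
    srsq: Sequence[int],
    panas: Sequence[int],
    mhcsf: Sequence[int],
    *,
    config: RunConfig = DEFAULT_CONFIG,
) -> QuestionnaireScores:
    """Score all three instruments for one participant."""
    total, advise_sleep = score_srsq(srsq, config=config)
    pa, na, advise_epa = score_panas(panas, config=config)
    resp = _check(mhcsf, Instrument.MHC_SF)
    flourishing, advise_wellness = score_mhcsf(resp, config=config)
    return QuestionnaireScores(
        participant_id=participant_id,
        srsq_total=total,
        panas_pa=pa,
        panas_na=na,
        mhc_item1to3_max_met=any(r >= 4 for r in resp[:3]),
        mhc_item4to14_count=sum(1 for r in resp[3:] if r >= 4),
        flourishing=flourishing,
        advise_sleep=advise_sleep,
        advise_epa=advise_epa,
        advise_wellness=advise_wellness,
    )
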