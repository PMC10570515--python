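"""Feedback-script sentence templates, externalized for translation.

Observation sentences are keyed by ``"<hub>|<partner>|<sign>"`` (hub node,
partner node, ``pos``/``neg`` for the edge weight sign); module rationales
by module id. A custom template table (e.g. loaded from JSON with
:func:`load_templates`) overlays the built-in defaults; a node pair or
module without a template raises :class:`TemplateError` so configuration
gaps surface before a script reaches a participant.
"""

from __future__ import annotations

import json
from pathlib import Path


class TemplateError(KeyError):
    pass


_PARTNER_PHRASES: dict[tuple[str, str], str] = {
    ("positive_affect", "neg"): "experience fewer positive feelings",
    ("positive_affect", "pos"): "experience more positive feelings",
    ("fatigue", "pos"): "feel more tired",
    ("fatigue", "neg"): "feel less tired",
    ("angry", "pos"): "feel more angry",
    ("angry", "neg"): "feel less angry",
    ("stressed", "pos"): "feel more stressed",
    ("stressed", "neg"): "feel less stressed",
    ("experiential_avoidance", "pos"): "push away your feelings more",
    ("experiential_avoidance", "neg"): "push away your feelings less",
    ("behavioral_avoidance", "pos"): "avoid doing things more often",
    ("behavioral_avoidance", "neg"): "avoid doing things less often",
    ("loneliness", "pos"): "feel more lonely",
    ("loneliness", "neg"): "feel less lonely",
    ("activity_investment", "pos"): "undertake more activities",
    ("activity_investment", "neg"): "undertake fewer activities",
    ("social_company", "pos"): "are more often in the company of others",
    ("social_company", "neg"): "are more often alone",
    ("anxious", "pos"): "feel more anxious",
    ("anxious", "neg"): "feel less anxious",
    ("sad", "pos"): "feel more sad",
    ("sad", "neg"): "feel less sad",
}

_HUB_PHRASES: dict[str, str] = {"anxious": "anxious", "sad": "sad"}

DEFAULT_TEMPLATES: dict[str, dict[str, str]] = {
    "observations": {
        f"{hub}|{node}|{sign}": f"At moments you feel {hub_phrase}, you also {phrase}."
        for hub, hub_phrase in _HUB_PHRASES.items()
        for (node, sign), phrase in _PARTNER_PHRASES.items()
        if node not in _HUB_PHRASES
    },
    "rationales": {
        "BEHAVIORAL_ACTIVATION": (
            "In the module Behavioral Activation you practice undertaking "
            "simple pleasurable activities and evaluate how they influence "
            "your mood."
        ),
        "EXPOSURE": (
            "In the module Exposure you practice facing situations you tend "
            "to avoid and test your anxious expectations."
        ),
        "ENHANCING_POSITIVE_AFFECT": (
            "In the module Enhancing Positive Affect you train detailed "
            "remembrance and recollection of positive events, which can "
            "strengthen positive feelings."
        ),
        "SLEEP": (
            "In the module Sleep you learn how sleep affects how you feel "
            "and how to ensure you sleep long and well enough."
        ),
        "WELLNESS": (
            "In the module Wellness you work on the different dimensions of "
            "wellbeing with psycho-education and exercises."
        ),
    },
}


def load_templates(path: str | Path) -> dict[str, dict[str, str]]:
    """Load a template table from JSON, overlaying the built-in defaults."""
    with open(path, encoding="utf-8") as fh:
        custom = json.load(fh)
    merged = {k: dict(v) for k, v in DEFAULT_TEMPLATES.items()}
    for section in ("observations", "rationales"):
        merged.setdefault(section, {}).update(custom.get(section, {}))
    return merged


def render_observation(
    hub: str, partner: str, weight: float, *, templates: dict | None = None
) -> str:
    sign = "pos" if weight >= 0 else "neg"
    table = (templates or DEFAULT_TEMPLATES)["observations"]
    key = f"{hub}|{partner}|{sign}"
    if key not in table:
        raise TemplateError(f"no observation template for {key}")
    return table[key]


def render_module_rationale(module_id: str, *, templates: dict | None = None) -> str:
    table = (templates or DEFAULT_TEMPLATES)["rationales"]
    if module_id not in table:
        raise TemplateError(f"no rationale template for module {module_id}")
    return table[module_id]
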