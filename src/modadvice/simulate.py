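"""Synthetic cohort generator with known ground truth.

The study's raw data are not shareable, so every input stream is emulated:
diagnostic history drawn from the cohort's prior-disorder mix,
questionnaire item responses from a discretized latent-Gaussian scheme
calibrated to the published total-score means/SDs, and EMA diaries from a
multivariate Gaussian whose precision matrix realizes a known
partial-correlation structure. The item-generation scheme is a test
harness, not a claim about the study's data-generating process; it exists
so that scoring, network recovery, and the full advice pipeline can be
exercised end to end with a verifiable ground truth.

All randomness flows from ``SimSpec.seed`` through per-operation
``numpy`` generator streams, so identical specs give identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from pydantic import BaseModel, Field, field_validator, model_validator
from scipy import optimize, stats

from .advice import (
    DiagnosticHistory,
    ModuleId,
    OPTIONAL_MODULES,
    RankedPlan,
    record_choice,
)
from .network import N_BEEPS, NODE_NAMES, EmaMatrix
from .scoring import PANAS_PA_ITEMS

_SOCIAL = NODE_NAMES.index("social_company")

# per-operation rng stream ids (combined with the spec seed)
_STREAM_DX, _STREAM_ITEMS, _STREAM_EMA, _STREAM_CHOICE = 1, 2, 3, 4


class InstrumentTarget(BaseModel):
    """Target mean/SD of a (sub)scale total for item simulation."""

    n_items: int
    item_min: int
    item_max: int
    mean: float
    sd: float = Field(gt=0)

    @model_validator(mode="after")
    def _feasible(self) -> "InstrumentTarget":
        lo, hi = self.n_items * self.item_min, self.n_items * self.item_max
        if not lo <= self.mean <= hi:
            raise ValueError(
                f"target mean {self.mean} outside attainable total range {lo}-{hi}"
            )
        return self


def default_true_pcor() -> list[list[float]]:
    """A sparse, plausible ground-truth partial-correlation structure.

    Anxiety and sadness co-fluctuate and connect to stress, positive
    affect (negatively), fatigue, and avoidance; weak enough off-diagonals
    keep the implied precision matrix diagonally dominant, hence positive
    definite.
    """
    k = len(NODE_NAMES)
    r = np.eye(k)
    edges = {
        ("anxious", "sad"): 0.30,
        ("anxious", "stressed"): 0.25,
        ("anxious", "experiential_avoidance"): 0.20,
        ("sad", "positive_affect"): -0.30,
        ("sad", "fatigue"): 0.30,
        ("positive_affect", "activity_investment"): 0.20,
        ("loneliness", "social_company"): -0.15,
    }
    for (a, b), w in edges.items():
        i, j = NODE_NAMES.index(a), NODE_NAMES.index(b)
        r[i, j] = r[j, i] = w
    return r.tolist()


class SimSpec(BaseModel):
    """Full specification of a synthetic cohort.

    Defaults reproduce the study conditions: the prior-disorder mix
    (20/74 depressive-only, 7/74 anxiety-only, 47/74 both), the published
    questionnaire total means/SDs, 84 beeps, and an 85% beep-completion
    rate (roughly 71 of 84 beeps on average, comfortably above the
    50-beep network requirement).
    """

    n_participants: int = Field(default=74, gt=0)
    seed: int = 0
    dx_probs: tuple[float, float, float] = (20 / 74, 7 / 74, 47 / 74)
    srsq: InstrumentTarget = InstrumentTarget(
        n_items=9, item_min=1, item_max=3, mean=15.76, sd=3.34
    )
    panas_pa: InstrumentTarget = InstrumentTarget(
        n_items=10, item_min=1, item_max=5, mean=33.32, sd=5.19
    )
    panas_na: InstrumentTarget = InstrumentTarget(
        n_items=10, item_min=1, item_max=5, mean=18.54, sd=6.00
    )
    mhc_sf: InstrumentTarget = InstrumentTarget(
        n_items=14, item_min=0, item_max=5, mean=47.96, sd=10.61
    )
    true_pcor: list[list[float]] = Field(default_factory=default_true_pcor)
    beeps: int = N_BEEPS
    compliance_rate: float = Field(default=0.85, ge=0.0, le=1.0)
    node_mean: float = 50.0
    node_sd: float = 15.0
    clip: bool = True
    dichotomize_social: bool = True

    @field_validator("dx_probs")
    @classmethod
    def _probs_sum(cls, v: tuple[float, float, float]) -> tuple[float, float, float]:
        if abs(sum(v) - 1.0) > 1e-9:
            raise ValueError("dx_probs must sum to 1")
        return v

    def precision_matrix(self) -> np.ndarray:
        """Unit-diagonal precision matrix realizing ``true_pcor``."""
        r = np.asarray(self.true_pcor, dtype=float)
        k = len(NODE_NAMES)
        if r.shape != (k, k) or not np.allclose(r, r.T) or not np.allclose(np.diag(r), 1):
            raise ValueError("true_pcor must be a symmetric 11x11 matrix with unit diagonal")
        prec = -r.copy()
        np.fill_diagonal(prec, 1.0)
        try:
            np.linalg.cholesky(prec)
        except np.linalg.LinAlgError:
            raise ValueError("implied precision matrix is not positive definite")
        return prec

    def latent_correlation(self) -> np.ndarray:
        """Correlation matrix of the generating Gaussian."""
        cov = np.linalg.inv(self.precision_matrix())
        d = np.sqrt(np.diag(cov))
        return cov / np.outer(d, d)


@dataclass(frozen=True)
class SyntheticParticipant:
    participant_id: str
    diagnoses: DiagnosticHistory
    srsq: tuple[int, ...]
    panas: tuple[int, ...]
    mhc_sf: tuple[int, ...]
    ema: EmaMatrix


def _rng(spec: SimSpec, stream: int, sub: int = 0) -> np.random.Generator:
    return np.random.default_rng([spec.seed % (2**31), stream, sub])


def simulate_diagnoses(spec: SimSpec) -> list[DiagnosticHistory]:
    """Draw prior-disorder categories i.i.d. from the three-way mix."""
    rng = _rng(spec, _STREAM_DX)
    cats = rng.choice(3, size=spec.n_participants, p=list(spec.dx_probs))
    out = []
    for i, c in enumerate(cats):
        out.append(
            DiagnosticHistory(
                participant_id=f"P{i + 1:04d}",
                remitted_depressive=c in (0, 2),
                remitted_anxiety=c in (1, 2),
            )
        )
    return out


def _discretized_mean(m: float, s: float, lo: int, hi: int) -> float:
    """Expected value of round-and-clip of N(m, s^2) onto the integers lo..hi."""
    vs = np.arange(lo, hi + 1, dtype=float)
    upper = np.where(vs == hi, np.inf, vs + 0.5)
    lower = np.where(vs == lo, -np.inf, vs - 0.5)
    probs = stats.norm.cdf((upper - m) / s) - stats.norm.cdf((lower - m) / s)
    return float((vs * probs).sum())


def _simulate_scale(
    target: InstrumentTarget, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Item matrix (n x n_items) whose totals approximate the target.

    A shared per-participant latent plus independent per-item noise is
    discretized (rounded, clipped to the item range). The within-item
    noise SD is at most 35% of the item range (shrinking for near-
    degenerate targets); the between-person component absorbs the
    remaining total-score variance, and the latent item mean is calibrated
    so the *discretized* per-item mean hits the target despite the bias
    that rounding and clipping introduce near the scale ends.
    """
    k = target.n_items
    lo, hi = target.item_min, target.item_max
    item_mean = target.mean / k
    w = min(0.35 * (hi - lo), target.sd / np.sqrt(k))
    b = np.sqrt(max(target.sd**2 - k * w**2, 0.0)) / k
    s_marginal = float(np.hypot(b, w))
    if s_marginal < 1e-6:
        m = item_mean
    else:
        m = optimize.brentq(
            lambda mm: _discretized_mean(mm, s_marginal, lo, hi) - item_mean,
            lo - 6 * s_marginal - 1,
            hi + 6 * s_marginal + 1,
            xtol=1e-10,
        )
    z = rng.standard_normal((n, 1))
    eps = rng.standard_normal((n, k))
    latent = m + b * z + w * eps
    return np.clip(np.rint(latent), lo, hi).astype(int)


def simulate_items(
    spec: SimSpec,
) -> list[dict[str, tuple[int, ...]]]:
    """Questionnaire item responses per participant.

    Returns dicts with keys ``srsq`` (9 items), ``panas`` (20 items, PA/NA
    interleaved per the standard subscale map), and ``mhc_sf`` (14 items).
    """
    rng = _rng(spec, _STREAM_ITEMS)
    n = spec.n_participants
    srsq = _simulate_scale(spec.srsq, n, rng)
    pa = _simulate_scale(spec.panas_pa, n, rng)
    na = _simulate_scale(spec.panas_na, n, rng)
    mhc = _simulate_scale(spec.mhc_sf, n, rng)
    panas = np.empty((n, 20), dtype=int)
    pa_pos = sorted(PANAS_PA_ITEMS)
    na_pos = sorted(set(range(1, 21)) - PANAS_PA_ITEMS)
    for j, pos in enumerate(pa_pos):
        panas[:, pos - 1] = pa[:, j]
    for j, pos in enumerate(na_pos):
        panas[:, pos - 1] = na[:, j]
    return [
        {
            "srsq": tuple(int(x) for x in srsq[i]),
            "panas": tuple(int(x) for x in panas[i]),
            "mhc_sf": tuple(int(x) for x in mhc[i]),
        }
        for i in range(n)
    ]


def simulate_observations(
    spec: SimSpec, participant_index: int, n_obs: int | None = None
) -> np.ndarray:
    """Raw beep-by-node draws from the ground-truth network (no missingness).

    Observations are i.i.d. from the Gaussian whose precision matrix
    realizes ``spec.true_pcor``, mapped to the 0-100 slider scale. With
    ``spec.clip``/``spec.dichotomize_social`` disabled this is the exact
    Gaussian pathway used by parameter-recovery oracle tests, which may
    request far more observations than a 14-day diary holds.
    """
    n = spec.beeps if n_obs is None else n_obs
    rng = _rng(spec, _STREAM_EMA, participant_index)
    corr = spec.latent_correlation()
    chol = np.linalg.cholesky(corr)
    z = rng.standard_normal((n, len(NODE_NAMES))) @ chol.T
    values = spec.node_mean + spec.node_sd * z
    if spec.dichotomize_social:
        med = np.median(values[:, _SOCIAL])
        values[:, _SOCIAL] = np.where(values[:, _SOCIAL] > med, 100.0, 0.0)
    if spec.clip:
        values = np.clip(values, 0.0, 100.0)
    return values


def simulate_ema(
    spec: SimSpec, participant_index: int, participant_id: str | None = None
) -> EmaMatrix:
    """One participant's EMA diary from the ground-truth network.

    Draws ``spec.beeps`` observations via :func:`simulate_observations`,
    then marks each beep independently completed with probability
    ``compliance_rate`` (beep-level MCAR); only completed beeps enter the
    matrix. The social-company node is dichotomized at its median and
    recoded 0/100 (it is a yes/no item).
    """
    values = simulate_observations(spec, participant_index)
    rng = _rng(spec, _STREAM_EMA, 10_000_000 + participant_index)
    completed = rng.random(spec.beeps) < spec.compliance_rate
    beep_index = tuple(int(i + 1) for i in np.flatnonzero(completed))
    pid = participant_id or f"P{participant_index + 1:04d}"
    return EmaMatrix(pid, values[completed], beep_index=beep_index)


def simulate_cohort(spec: SimSpec) -> list[SyntheticParticipant]:
    """Full synthetic cohort: diagnoses + items + EMA per participant."""
    dx = simulate_diagnoses(spec)
    items = simulate_items(spec)
    return [
        SyntheticParticipant(
            participant_id=d.participant_id,
            diagnoses=d,
            srsq=it["srsq"],
            panas=it["panas"],
            mhc_sf=it["mhc_sf"],
            ema=simulate_ema(spec, i, d.participant_id),
        )
        for i, (d, it) in enumerate(zip(dx, items))
    ]


BEHAVIOR_MODELS = ("adherent", "positivity_biased", "random")

#: modules framed as "improving positives" vs "combating negatives"
_POSITIVE = (ModuleId.ENHANCING_POSITIVE_AFFECT, ModuleId.WELLNESS)
_NEGATIVE = (ModuleId.SLEEP, ModuleId.EXPOSURE)


def simulate_choices(
    plans: list[RankedPlan],
    behavior_model: str = "adherent",
    *,
    spec: SimSpec | None = None,
    seed: int | None = None,
    bias_prob: float = 0.5,
) -> list[RankedPlan]:
    """Attach a simulated shared-decision-making choice to each plan.

    ``adherent`` picks the top-ranked combination; ``positivity_biased``
    starts from it and swaps negatively framed modules (Sleep, Exposure)
    for positively framed ones (Enhancing Positive Affect, Wellness) with
    probability ``bias_prob`` per swappable module; ``random`` picks a
    uniform 3-subset of the five optional modules.
    """
    if behavior_model not in BEHAVIOR_MODELS:
        raise ValueError(
            f"unknown behavior model {behavior_model!r}; expected one of {BEHAVIOR_MODELS}"
        )
    base_seed = spec.seed if spec is not None else (seed or 0)
    rng = np.random.default_rng([base_seed % (2**31), _STREAM_CHOICE])
    optional = sorted(OPTIONAL_MODULES, key=lambda m: m.value)
    out = []
    for plan in plans:
        if behavior_model == "random":
            # index-based draw keeps the enum members intact
            chosen = [optional[i] for i in rng.choice(len(optional), size=3, replace=False)]
        else:
            chosen = sorted(plan.tier_1[0].modules, key=lambda m: m.value)
            if behavior_model == "positivity_biased":
                for neg in _NEGATIVE:
                    if neg in chosen and rng.random() < bias_prob:
                        pool = [m for m in _POSITIVE if m not in chosen]
                        if pool:
                            chosen[chosen.index(neg)] = pool[0]
        order = list(rng.permutation(len(chosen)))
        out.append(record_choice(plan, tuple(chosen[i] for i in order)))
    return out
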