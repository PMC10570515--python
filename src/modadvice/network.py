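"""Per-participant contemporaneous symptom networks from EMA diary data.

One participant answers up to 84 beeps (6/day for 14 days) on 0-100 slider
scales; the network step pools the completed beeps into a single Gaussian
graphical model over 11 fixed nodes. Estimation follows the deployed
pipeline exactly:

1. compliance: at least ``min_beeps`` (default 50) fully answered beeps;
2. variance pruning: nodes whose sample standard deviation is below
   ``sd_min`` (default 10 slider units) are removed — a network needs
   fluctuation, a near-constant item carries no contemporaneous signal;
3. partial correlations from the standardized inverse of the Pearson
   correlation matrix of the retained columns;
4. edge thresholding: only partial correlations with |r| >= ``edge_min``
   (default 0.3) are kept as edges.

Infeasibility (non-compliance, too few nodes, collinearity) is data, not
an exception: :func:`build_network` always returns a ``SymptomNetwork``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .config import DEFAULT_CONFIG, RunConfig

#: Canonical node order; every EmaMatrix column layout follows this list.
NODE_NAMES: tuple[str, ...] = (
    "anxious",
    "sad",
    "angry",
    "stressed",
    "positive_affect",
    "fatigue",
    "experiential_avoidance",
    "behavioral_avoidance",
    "loneliness",
    "activity_investment",
    "social_company",
)

N_BEEPS = 84  # 6 beeps/day x 14 days


class EmaValidationError(ValueError):
    pass


@dataclass(frozen=True)
class EmaMatrix:
    """One participant's beep-by-node EMA matrix.

    ``values`` has one row per *answered* beep (at most 84) and one column
    per node in :data:`NODE_NAMES`, on the common 0-100 scale (the yes/no
    social-company item is recoded 0/100 upstream). Rows with any missing
    item are dropped before construction; ``completed_count`` is the number
    of fully answered beeps and therefore equals ``values.shape[0]``.
    """

    participant_id: str
    values: np.ndarray
    beep_index: tuple[int, ...] = ()
    node_names: tuple[str, ...] = NODE_NAMES

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 2 or v.shape[1] != len(self.node_names):
            raise EmaValidationError(
                f"EMA matrix must be observations x {len(self.node_names)} nodes, "
                f"got shape {v.shape}"
            )
        if self.node_names != NODE_NAMES:
            raise EmaValidationError(
                f"node_names must be the canonical 11 nodes in order, got {self.node_names}"
            )
        if v.shape[0] > N_BEEPS:
            raise EmaValidationError(f"more than {N_BEEPS} beeps ({v.shape[0]})")
        if v.size and (np.isnan(v).any() or v.min() < 0 or v.max() > 100):
            raise EmaValidationError("EMA values must be complete and within 0-100")
        if self.beep_index and len(self.beep_index) != v.shape[0]:
            raise EmaValidationError("beep_index length must match the row count")

    @property
    def completed_count(self) -> int:
        return int(self.values.shape[0])


@dataclass(frozen=True)
class Edge:
    node_a: str
    node_b: str
    weight: float
    p_value: float | None = None


@dataclass(frozen=True)
class SymptomNetwork:
    """Thresholded partial-correlation network (or an explicit infeasibility)."""

    participant_id: str
    feasible: bool
    retained_nodes: tuple[str, ...] = ()
    pruned_nodes: tuple[tuple[str, str], ...] = ()  # (node, reason)
    pcor: np.ndarray | None = None
    p_values: np.ndarray | None = None
    edges: tuple[Edge, ...] = ()
    n_obs: int = 0
    infeasible_reason: str | None = None

    def edge_set(self) -> frozenset[frozenset[str]]:
        return frozenset(frozenset((e.node_a, e.node_b)) for e in self.edges)

    def to_dict(self) -> dict:
        return {
            "participant_id": self.participant_id,
            "feasible": self.feasible,
            "retained_nodes": list(self.retained_nodes),
            "pruned_nodes": [list(p) for p in self.pruned_nodes],
            "pcor": None if self.pcor is None else np.round(self.pcor, 10).tolist(),
            "edges": [
                {
                    "node_a": e.node_a,
                    "node_b": e.node_b,
                    "weight": round(e.weight, 10),
                    "p_value": None if e.p_value is None else round(e.p_value, 10),
                }
                for e in self.edges
            ],
            "n_obs": self.n_obs,
            "infeasible_reason": self.infeasible_reason,
        }


def check_compliance(ema: EmaMatrix, min_beeps: int = 50) -> bool:
    """True iff the participant completed at least ``min_beeps`` beeps."""
    return ema.completed_count >= min_beeps


def prune_low_variance(
    ema: EmaMatrix, sd_min: float = 10.0
) -> tuple[tuple[str, ...], tuple[tuple[str, str], ...]]:
    """Split nodes into (retained, pruned-with-reason) by sample sd.

    The sd uses the n-1 denominator over completed beeps; a node is pruned
    iff sd < ``sd_min`` (constant columns have sd 0 and are always pruned).
    """
    if ema.completed_count < 2:
        raise EmaValidationError("need at least 2 observations to compute an sd")
    sds = ema.values.std(axis=0, ddof=1)
    retained = tuple(n for n, s in zip(ema.node_names, sds) if s >= sd_min)
    pruned = tuple(
        (n, "sd_below_threshold") for n, s in zip(ema.node_names, sds) if s < sd_min
    )
    return retained, pruned


class IllConditionedError(ValueError):
    """Correlation matrix too close to singular for inversion."""

    def __init__(self, pair: tuple[str, str], cond: float):
        self.pair = pair
        self.cond = cond
        super().__init__(
            f"correlation matrix ill-conditioned (cond={cond:.3g}); "
            f"most collinear pair: {pair[0]}-{pair[1]}"
        )


def partial_correlations(
    values: np.ndarray,
    node_names: Sequence[str] | None = None,
    *,
    condition_max: float = 1e8,
) -> np.ndarray:
    """Partial correlations of each column pair given all remaining columns.

    Computed as ``-P[i,j]/sqrt(P[i,i]*P[j,j])`` with ``P`` the inverse of
    the Pearson correlation matrix; the diagonal is set to 1. With exactly
    two columns this reduces to the plain Pearson correlation.
    """
    x = np.asarray(values, dtype=float)
    n, k = x.shape
    if k < 2:
        raise ValueError("need at least 2 variables")
    if n < k + 3:
        raise ValueError(f"need more than k+2={k + 2} observations, got {n}")
    r = np.corrcoef(x, rowvar=False)
    cond = np.linalg.cond(r)
    if not np.isfinite(cond) or cond > condition_max:
        off = np.abs(r - np.eye(k))
        i, j = np.unravel_index(np.argmax(off), off.shape)
        names = tuple(node_names) if node_names else tuple(f"x{m}" for m in range(k))
        raise IllConditionedError((names[min(i, j)], names[max(i, j)]), cond)
    p = np.linalg.inv(r)
    d = np.sqrt(np.outer(np.diag(p), np.diag(p)))
    pcor = -p / d
    np.fill_diagonal(pcor, 1.0)
    return (pcor + pcor.T) / 2.0  # symmetrize within numerical tolerance


def partial_correlation_pvalues(pcor: np.ndarray, n_obs: int) -> np.ndarray:
    """Two-sided p-values via the t transform, df = n - k (k nodes).

    Conditioning on the k-2 remaining variables costs k-2 degrees of
    freedom on top of the usual 2. Reported as metadata only: the operative
    edge filter is the magnitude threshold.
    """
    k = pcor.shape[0]
    df = n_obs - k
    if df <= 0:
        return np.full_like(pcor, np.nan)
    r = np.clip(pcor, -0.9999999999, 0.9999999999)
    with np.errstate(divide="ignore"):
        t = r * np.sqrt(df / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    np.fill_diagonal(p, 0.0)
    return p


def threshold_edges(
    pcor: np.ndarray,
    node_names: Sequence[str],
    edge_min: float = 0.3,
    *,
    p_values: np.ndarray | None = None,
    signed: bool = False,
) -> tuple[Edge, ...]:
    """Keep the unordered pairs with |pcor| >= ``edge_min`` (inclusive).

    In ``signed`` mode the raw value must be >= ``edge_min``, so negative
    partial correlations never form edges.
    """
    k = pcor.shape[0]
    edges = []
    for i in range(k):
        for j in range(i + 1, k):
            w = float(pcor[i, j])
            keep = w >= edge_min if signed else abs(w) >= edge_min
            if keep:
                pv = None if p_values is None else float(p_values[i, j])
                edges.append(Edge(node_names[i], node_names[j], w, pv))
    return tuple(edges)


def build_network(ema: EmaMatrix, config: RunConfig = DEFAULT_CONFIG) -> SymptomNetwork:
    """Run compliance check, variance pruning, estimation, and thresholding.

    Never raises for data-dependent failure: non-compliance, fewer than
    three retained nodes, too few observations, or collinearity yield
    ``feasible=False`` with a reason, mirroring how the procedure simply
    produced no network-based advice for such participants.
    """
    pid = ema.participant_id
    if not check_compliance(ema, config.min_beeps):
        return SymptomNetwork(
            pid, False, n_obs=ema.completed_count, infeasible_reason="compliance"
        )
    retained, pruned = prune_low_variance(ema, config.sd_min)
    if len(retained) < 3:
        return SymptomNetwork(
            pid,
            False,
            retained_nodes=retained,
            pruned_nodes=pruned,
            n_obs=ema.completed_count,
            infeasible_reason="fewer_than_3_retained_nodes",
        )
    cols = [ema.node_names.index(n) for n in retained]
    sub = ema.values[:, cols]
    n = sub.shape[0]
    if n < len(retained) + 3:
        return SymptomNetwork(
            pid,
            False,
            retained_nodes=retained,
            pruned_nodes=pruned,
            n_obs=n,
            infeasible_reason="too_few_observations",
        )
    try:
        pcor = partial_correlations(sub, retained, condition_max=config.condition_max)
    except IllConditionedError as err:
        return SymptomNetwork(
            pid,
            False,
            retained_nodes=retained,
            pruned_nodes=pruned,
            n_obs=n,
            infeasible_reason=f"ill_conditioned:{err.pair[0]}-{err.pair[1]}",
        )
    pvals = partial_correlation_pvalues(pcor, n)
    edges = threshold_edges(
        pcor, retained, config.edge_min, p_values=pvals, signed=config.signed_edges
    )
    return SymptomNetwork(
        pid,
        True,
        retained_nodes=retained,
        pruned_nodes=pruned,
        pcor=pcor,
        p_values=pvals,
        edges=edges,
        n_obs=n,
    )
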