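"""Member-gene calling by iterative outlier removal under the K² statistic.

Within one robust component most gene weights sit in a near-Gaussian bulk
around zero; the member genes are the heavy-tailed outliers.  Membership is
called by repeatedly removing the gene with the largest absolute weight and
recomputing the D'Agostino-Pearson K² omnibus normality statistic on what
remains: every gene removed before K² first drops to or below the cutoff is
a member, signed by its weight.  If the full vector already looks Gaussian
(K² <= cutoff) the module has zero members — a legitimate outcome that is
kept and flagged rather than erroring.

The default cutoff of 550 follows the convention of ICA-based module
workflows on transcriptomic compendia; it is deliberately conservative
(K² is asymptotically chi-square with 2 df under normality, so 550 is far
beyond any plausible null fluctuation for thousands of genes) and is
exposed for calibration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .matrix import ModuleSet

__all__ = [
    "ModuleMembership",
    "CutoffCalibration",
    "dagostino_k2",
    "call_members",
    "call_all",
    "removal_trace",
    "calibrate_cutoff",
    "DEFAULT_K2_CUTOFF",
    "MIN_K2_SAMPLE",
]

DEFAULT_K2_CUTOFF = 550.0
MIN_K2_SAMPLE = 20  # skewness/kurtosis Z-transforms are unstable below this


@dataclass
class ModuleMembership:
    """Called members of one component, with the removal trace.

    ``members`` is sorted by descending absolute weight; ``k2_trace``
    records (removed_gene, K² after that removal).  ``n_members`` may be 0.
    """

    module_id: str
    members: list[tuple[str, float, int]]  # (gene_id, weight, sign)
    k2_trace: list[tuple[str, float]]
    cutoff: float
    initial_k2: float
    is_empty: bool = field(init=False)

    def __post_init__(self) -> None:
        self.is_empty = len(self.members) == 0

    @property
    def n_members(self) -> int:
        return len(self.members)

    @property
    def gene_set(self) -> set[str]:
        return {g for g, _, _ in self.members}


def dagostino_k2(values: np.ndarray) -> float:
    """D'Agostino-Pearson K² = Z₁(skew)² + Z₂(kurtosis)².

    Chi-square(2) under normality, asymptotically.  Requires >= 20
    observations with nonzero variance.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or values.size < MIN_K2_SAMPLE:
        raise ValueError(
            f"K² needs a 1-D sample of >= {MIN_K2_SAMPLE} values, got "
            f"{values.size}"
        )
    if np.ptp(values) == 0:
        raise ValueError("K² undefined for a zero-variance sample")
    stat, _ = stats.normaltest(values)
    return float(stat)


def call_members(
    gene_ids: list[str],
    weights: np.ndarray,
    cutoff: float = DEFAULT_K2_CUTOFF,
    module_id: str = "module",
) -> ModuleMembership:
    """Iteratively strip the largest-|weight| gene until K² <= cutoff.

    Ties in |weight| are broken by gene id (lexicographic), so the member
    set does not depend on input order.  Runs out of evaluable genes (< 20
    remaining before K² drops) -> hard error.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    weights = np.asarray(weights, dtype=float)
    if len(gene_ids) != weights.size:
        raise ValueError("gene_ids and weights length mismatch")

    # removal order: descending |weight|, gene id breaks ties
    order = sorted(
        range(weights.size), key=lambda i: (-abs(weights[i]), gene_ids[i])
    )
    remaining = list(order)

    k2 = dagostino_k2(weights[remaining])
    initial_k2 = k2
    members: list[tuple[str, float, int]] = []
    trace: list[tuple[str, float]] = []
    while k2 > cutoff:
        if len(remaining) - 1 < MIN_K2_SAMPLE:
            raise ValueError(
                f"{module_id}: K² never dropped below cutoff {cutoff} before "
                f"fewer than {MIN_K2_SAMPLE} genes remained; the weight "
                "vector is too short or the cutoff too small"
            )
        i = remaining.pop(0)
        w = float(weights[i])
        members.append((gene_ids[i], w, 1 if w >= 0 else -1))
        k2 = dagostino_k2(weights[remaining])
        trace.append((gene_ids[i], k2))
    return ModuleMembership(
        module_id=module_id,
        members=members,
        k2_trace=trace,
        cutoff=cutoff,
        initial_k2=initial_k2,
    )


def removal_trace(
    gene_ids: list[str],
    weights: np.ndarray,
    floor: float,
) -> tuple[float, list[tuple[str, float]]]:
    """K² trace along the fixed removal order, down to ``floor``.

    The removal order (descending |weight|, gene id on ties) does not
    depend on any cutoff, so one trace resolves membership for every
    cutoff >= ``floor``: the member count at cutoff c is the number of
    removals before the statistic first drops to <= c.  The trace stops
    once K² <= floor or fewer than 20 evaluable genes would remain.
    """
    weights = np.asarray(weights, dtype=float)
    order = sorted(
        range(weights.size), key=lambda i: (-abs(weights[i]), gene_ids[i])
    )
    remaining = list(order)
    initial = dagostino_k2(weights[remaining])
    trace: list[tuple[str, float]] = []
    k2 = initial
    while k2 > floor and len(remaining) - 1 >= MIN_K2_SAMPLE:
        i = remaining.pop(0)
        k2 = dagostino_k2(weights[remaining])
        trace.append((gene_ids[i], k2))
    return initial, trace


def _members_at(initial: float, trace_k2: np.ndarray, cutoff: float) -> int:
    """Member count implied by a removal trace at a given cutoff."""
    if initial <= cutoff:
        return 0
    below = np.flatnonzero(trace_k2 <= cutoff)
    return int(below[0] + 1) if below.size else len(trace_k2)


@dataclass
class CutoffCalibration:
    """Membership-stability sweep over candidate K² cutoffs.

    ``member_counts[i, k]`` is the member count of component k at
    ``cutoffs[i]``.  ``recommended`` is the geometric midpoint of the
    longest log-spaced plateau on which every component's count is
    constant and not all counts are zero — the regime where membership is
    insensitive to the exact cutoff choice.
    """

    cutoffs: np.ndarray
    member_counts: np.ndarray
    recommended: float
    plateau: tuple[float, float]


def calibrate_cutoff(
    M: np.ndarray,
    gene_ids: list[str],
    cutoffs: np.ndarray | None = None,
) -> CutoffCalibration:
    """Sweep cutoffs and pick one inside the widest stable plateau.

    K² magnitudes grow with vector length and outlier fraction, so a fixed
    convention (e.g. 550 for ~4,700-gene compendia) does not transfer
    across scales; this helper re-derives a scale-appropriate cutoff from
    the data.  Raising the cutoff can never add members, so counts are
    non-increasing along the sweep.
    """
    if cutoffs is None:
        cutoffs = np.geomspace(10.0, 5000.0, 80)
    cutoffs = np.sort(np.asarray(cutoffs, dtype=float))
    M = np.asarray(M, dtype=float)
    floor = float(cutoffs[0])

    traces = []
    for k in range(M.shape[1]):
        initial, trace = removal_trace(gene_ids, M[:, k], floor=floor)
        traces.append((initial, np.array([v for _, v in trace])))

    counts = np.zeros((cutoffs.size, M.shape[1]), dtype=int)
    for i, c in enumerate(cutoffs):
        for k, (initial, tk2) in enumerate(traces):
            counts[i, k] = _members_at(initial, tk2, c)

    # plateaus: maximal runs of identical count vectors, skipping all-zero
    best_span, best = -1.0, None
    i = 0
    while i < cutoffs.size:
        j = i
        while j + 1 < cutoffs.size and np.array_equal(
            counts[j + 1], counts[i]
        ):
            j += 1
        if counts[i].any():
            span = float(np.log(cutoffs[j] / cutoffs[i]))
            if span > best_span:
                best_span, best = span, (i, j)
        i = j + 1

    if best is None:  # every cutoff yields empty modules
        return CutoffCalibration(
            cutoffs=cutoffs,
            member_counts=counts,
            recommended=float(cutoffs[0]),
            plateau=(float(cutoffs[0]), float(cutoffs[0])),
        )
    lo, hi = float(cutoffs[best[0]]), float(cutoffs[best[1]])
    return CutoffCalibration(
        cutoffs=cutoffs,
        member_counts=counts,
        recommended=float(np.sqrt(lo * hi)),
        plateau=(lo, hi),
    )


def call_all(
    M: np.ndarray,
    gene_ids: list[str],
    cutoff: float | str = DEFAULT_K2_CUTOFF,
    module_prefix: str = "fModule",
) -> tuple[ModuleSet, list[ModuleMembership]]:
    """Apply :func:`call_members` to every column of a gene-weight matrix.

    ``cutoff="auto"`` calibrates a scale-appropriate cutoff first (see
    :func:`calibrate_cutoff`).  Zero-member modules stay in both outputs
    (flagged ``is_empty``); the returned :class:`ModuleSet` keeps their
    empty gene sets so module counts match the decomposition.
    """
    M = np.asarray(M, dtype=float)
    if isinstance(cutoff, str):
        if cutoff != "auto":
            raise ValueError(f"unknown cutoff mode {cutoff!r}")
        cutoff = calibrate_cutoff(M, gene_ids).recommended
    memberships = []
    modules: dict[str, set[str]] = {}
    weights: dict[str, dict[str, float]] = {}
    for k in range(M.shape[1]):
        mid = f"{module_prefix}_{k}"
        mm = call_members(gene_ids, M[:, k], cutoff=cutoff, module_id=mid)
        memberships.append(mm)
        modules[mid] = mm.gene_set
        weights[mid] = {g: w for g, w, _ in mm.members}
    return ModuleSet(modules=modules, weights=weights), memberships
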