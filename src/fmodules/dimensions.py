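"""ICA dimensionality scan and optimal-dimension selection.

The number of requested components changes what ICA finds: too few and
distinct modules fuse, too many and real modules shatter into single-gene
components.  The scan runs the full robust decomposition + membership
pipeline over a grid of dimensions and, at each k, counts

* ``n_robust`` — robust components found,
* ``n_single`` — components whose called membership is exactly one gene,
* ``n_zero``   — degenerate components with no called members,
* ``n_multi``  — components with two or more members
  (``n_robust - n_single - n_zero``),
* ``n_final``  — components that match (absolute Pearson R above a
  threshold, default 0.7) a robust component at the largest scanned
  dimension, i.e. components that persist at full resolution.

The optimal dimension is the scanned k with ``n_final > n_multi`` that
minimises ``n_single`` (smallest k on ties); if no k satisfies the
inequality, the k minimising ``n_single`` is returned with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ica import decompose
from .matrix import FitnessMatrix
from .membership import DEFAULT_K2_CUTOFF, call_all

__all__ = ["DimensionScan", "scan_dimensions", "select_optimal"]


@dataclass
class DimensionScan:
    """Per-dimension robust/single/multi/final component counts."""

    dimensions: list[int]
    n_robust: dict[int, int]
    n_single: dict[int, int]
    n_zero: dict[int, int]
    n_final: dict[int, int]
    r_threshold: float
    k2_cutoff: float
    decompositions: dict = field(default_factory=dict, repr=False)

    def n_multi(self, k: int) -> int:
        return self.n_robust[k] - self.n_single[k] - self.n_zero[k]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "dimension": k,
                "n_robust": self.n_robust[k],
                "n_single": self.n_single[k],
                "n_zero": self.n_zero[k],
                "n_multi": self.n_multi(k),
                "n_final": self.n_final[k],
            }
            for k in self.dimensions
        ]
        return pd.DataFrame(rows)


def scan_dimensions(
    F: FitnessMatrix,
    dims: list[int],
    n_runs: int = 100,
    tol: float = 1e-7,
    base_seed: int = 0,
    eps: float = 0.1,
    min_size: int | None = None,
    sign_mode: str = "absolute",
    k2_cutoff: float = DEFAULT_K2_CUTOFF,
    r_threshold: float = 0.7,
    keep_decompositions: bool = False,
) -> DimensionScan:
    """Run the robust pipeline at every dimension in ``dims``.

    ``dims`` must be ascending and within the sample count; matching for
    ``n_final`` is against the robust components at max(dims) using
    absolute Pearson correlation.
    """
    if not dims:
        raise ValueError("empty dimension grid")
    if sorted(dims) != list(dims):
        raise ValueError("dims must be sorted ascending")
    bad = [k for k in dims if k > F.n_samples]
    if bad:
        raise ValueError(
            f"dimensions {bad} exceed the sample count {F.n_samples}"
        )

    results = {}
    for k in dims:
        dec = decompose(
            F,
            k,
            n_runs=n_runs,
            tol=tol,
            base_seed=base_seed,
            eps=eps,
            min_size=min_size,
            sign_mode=sign_mode,
        )
        _, memberships = (
            call_all(dec.M, dec.gene_ids, cutoff=k2_cutoff)
            if dec.n_components
            else (None, [])
        )
        results[k] = (dec, memberships)

    k_max = dims[-1]
    M_ref = results[k_max][0].M
    n_robust, n_single, n_zero, n_final = {}, {}, {}, {}
    for k in dims:
        dec, memberships = results[k]
        n_robust[k] = dec.n_components
        n_single[k] = sum(1 for mm in memberships if mm.n_members == 1)
        n_zero[k] = sum(1 for mm in memberships if mm.n_members == 0)
        n_final[k] = _count_matched(dec.M, M_ref, r_threshold)
    scan = DimensionScan(
        dimensions=list(dims),
        n_robust=n_robust,
        n_single=n_single,
        n_zero=n_zero,
        n_final=n_final,
        r_threshold=r_threshold,
        k2_cutoff=k2_cutoff,
    )
    if keep_decompositions:
        scan.decompositions = {k: results[k][0] for k in dims}
    return scan


def _count_matched(M: np.ndarray, M_ref: np.ndarray, r_threshold: float) -> int:
    """Components of M with |Pearson R| > threshold vs any reference column."""
    if M.shape[1] == 0 or M_ref.shape[1] == 0:
        return 0
    A = M - M.mean(axis=0, keepdims=True)
    B = M_ref - M_ref.mean(axis=0, keepdims=True)
    A = A / np.linalg.norm(A, axis=0, keepdims=True)
    B = B / np.linalg.norm(B, axis=0, keepdims=True)
    R = np.abs(A.T @ B)  # m x m_ref
    return int((R.max(axis=1) > r_threshold).sum())


def select_optimal(scan: DimensionScan) -> int:
    """Pick the dimension per the persistence criterion.

    Among dimensions where the number of persistent components exceeds the
    number of multi-gene (>= 2 member) components, return the one with the fewest
    single-gene components (smallest dimension on ties).  With no
    satisfying dimension, fall back to minimising single-gene components
    and warn.
    """
    if not scan.dimensions:
        raise ValueError("empty scan")
    satisfying = [
        k for k in scan.dimensions if scan.n_final[k] > scan.n_multi(k)
    ]
    pool = satisfying
    if not pool:
        warnings.warn(
            "no scanned dimension had more persistent components than "
            "multi-gene components; falling back to minimal single-gene count",
            stacklevel=2,
        )
        pool = list(scan.dimensions)
    return min(pool, key=lambda k: (scan.n_single[k], k))
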