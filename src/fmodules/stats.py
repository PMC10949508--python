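"""Explained-variance accounting and membership multiplicity summaries.

Explained variance uses the residual-reduction definition on the
column-centred matrix (the centring convention of the decomposition):

* per module:  ev_k  = 1 - ||F - M_k A_k||²_F / ||F||²_F, with A_k the
  least-squares activity for component k alone;
* total:       ev_all = 1 - ||F - M A||²_F / ||F||²_F, with the joint
  least-squares A.

Components are not orthogonal, so per-module values need not sum to the
total.  An alternative energy-ratio definition ||M_k A_k||²_F / ||F||²_F is
available for sensitivity checks; every report carries a formula tag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ica import centered_values
from .matrix import FitnessMatrix, ModuleSet

__all__ = [
    "VarianceReport",
    "MultiplicityReport",
    "explained_variance",
    "multiplicity",
]


@dataclass
class VarianceReport:
    per_module: dict[str, float]  # fractions in [0, 1]
    total: float
    formula: str

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "module_id": list(self.per_module),
                "explained_variance_pct": [
                    100 * v for v in self.per_module.values()
                ],
            }
        )
        df.attrs["formula"] = self.formula
        return df


@dataclass
class MultiplicityReport:
    histogram: dict[int, int]  # modules-per-gene -> gene count
    median_module_size: float
    n_empty_modules: int
    n_unique_member_genes: int
    include_empty_in_median: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "n_modules_per_gene": list(self.histogram),
                "n_genes": list(self.histogram.values()),
            }
        )


def explained_variance(
    F: FitnessMatrix,
    M: np.ndarray,
    module_ids: list[str] | None = None,
    which: str = "each",
    formula: str = "residual_reduction",
    center: bool = True,
) -> VarianceReport:
    """Explained-variance fractions for single components and the full set.

    ``which`` selects 'each' (per module + total), 'all' (total only) or a
    list-like subset of column indices.  Activities are re-fit by least
    squares for whichever column set is being scored.
    """
    M = np.asarray(M, dtype=float)
    X = centered_values(F) if center else F.values
    total_ss = float(np.linalg.norm(X) ** 2)
    if total_ss == 0:
        raise ValueError("fitness matrix has zero variance")
    if module_ids is None:
        module_ids = [f"fModule_{k}" for k in range(M.shape[1])]

    def ev_for(cols: np.ndarray) -> float:
        Msub = M[:, cols]
        if formula == "residual_reduction":
            A = np.linalg.lstsq(Msub, X, rcond=None)[0]
            return 1.0 - float(np.linalg.norm(X - Msub @ A) ** 2) / total_ss
        if formula == "energy_ratio":
            A = np.linalg.lstsq(Msub, X, rcond=None)[0]
            return float(np.linalg.norm(Msub @ A) ** 2) / total_ss
        raise ValueError(f"unknown formula {formula!r}")

    all_cols = np.arange(M.shape[1])
    total = ev_for(all_cols) if M.shape[1] else 0.0
    per_module: dict[str, float] = {}
    if which == "each":
        for k in range(M.shape[1]):
            per_module[module_ids[k]] = ev_for(np.array([k]))
    elif which == "all":
        pass
    else:
        for k in np.asarray(which, dtype=int):
            per_module[module_ids[k]] = ev_for(np.array([k]))
    return VarianceReport(per_module=per_module, total=total, formula=formula)


def multiplicity(
    modules: ModuleSet, include_empty_in_median: bool = False
) -> MultiplicityReport:
    """Per-gene module counts and module-size summaries.

    The histogram maps modules-per-gene (>= 1) to the number of genes with
    that multiplicity; its counts sum to the union of member genes.  Median
    module size excludes zero-member modules unless requested otherwise.
    """
    counts: dict[str, int] = {}
    for _, genes in modules:
        for g in genes:
            counts[g] = counts.get(g, 0) + 1
    histogram: dict[int, int] = {}
    for c in counts.values():
        histogram[c] = histogram.get(c, 0) + 1
    histogram = dict(sorted(histogram.items()))

    sizes = [len(genes) for _, genes in modules]
    if not include_empty_in_median:
        sizes = [s for s in sizes if s > 0]
    median = float(np.median(sizes)) if sizes else float("nan")
    return MultiplicityReport(
        histogram=histogram,
        median_module_size=median,
        n_empty_modules=len(modules.empty_modules()),
        n_unique_member_genes=len(counts),
        include_empty_in_median=include_empty_in_median,
    )
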