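"""Core containers for gene-fitness data.

A fitness compendium is a dense genes x samples matrix of fitness
log-ratios from pooled mutant screens (negative = disruption of the gene
is harmful in that condition).  Missingness is tracked with an explicit
boolean mask and never imputed; downstream decomposition requires
complete-case genes only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["FitnessMatrix", "SampleMetadata", "ModuleSet"]


@dataclass
class FitnessMatrix:
    """Dense genes x samples matrix of fitness log-ratios.

    Parameters
    ----------
    gene_ids
        Ordered, unique locus tags (rows).
    sample_ids
        Ordered, unique experiment labels (columns).
    values
        Float matrix, ``(n_genes, n_samples)``.  Entries where
        ``missing_mask`` is True carry no information (stored as NaN).
    missing_mask
        Boolean matrix of the same shape; True marks a missing cell.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    missing_mask: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.gene_ids = [str(g).strip() for g in self.gene_ids]
        self.sample_ids = [str(s).strip() for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if self.missing_mask is None:
            self.missing_mask = ~np.isfinite(self.values)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        n_g, n_s = self.values.shape
        if len(self.gene_ids) != n_g:
            raise ValueError(
                f"{len(self.gene_ids)} gene ids for {n_g} rows"
            )
        if len(self.sample_ids) != n_s:
            raise ValueError(
                f"{len(self.sample_ids)} sample ids for {n_s} columns"
            )
        if self.missing_mask.shape != self.values.shape:
            raise ValueError("missing_mask shape differs from values")
        dup_g = _duplicates(self.gene_ids)
        if dup_g:
            raise ValueError(f"duplicate gene ids: {sorted(dup_g)}")
        dup_s = _duplicates(self.sample_ids)
        if dup_s:
            raise ValueError(f"duplicate sample ids: {sorted(dup_s)}")
        observed = ~self.missing_mask
        if not np.all(np.isfinite(self.values[observed])):
            raise ValueError("non-finite value present outside missing_mask")
        # canonical storage: masked cells are NaN
        self.values = self.values.copy()
        self.values[self.missing_mask] = np.nan

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def is_complete(self) -> bool:
        return not self.missing_mask.any()

    def to_frame(self) -> pd.DataFrame:
        """Genes x samples DataFrame; missing cells are NaN."""
        return pd.DataFrame(
            self.values, index=self.gene_ids, columns=self.sample_ids
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FitnessMatrix":
        return cls(
            gene_ids=list(df.index.astype(str)),
            sample_ids=list(df.columns.astype(str)),
            values=df.to_numpy(dtype=float),
        )

    def select_genes(self, keep: np.ndarray) -> "FitnessMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = keep
        return FitnessMatrix(
            gene_ids=[self.gene_ids[i] for i in idx],
            sample_ids=list(self.sample_ids),
            values=self.values[idx, :],
            missing_mask=self.missing_mask[idx, :],
        )


@dataclass
class SampleMetadata:
    """Per-sample annotations: condition description and replicate group.

    ``condition_label`` is the free-text description as published;
    ``condition_key`` is a user-supplied deduplicated identifier (replicates
    of the same growth condition share a key).  Both are kept because
    condition deduplication rules vary between sources.
    """

    table: pd.DataFrame

    REQUIRED = ("sample_id", "condition_label")

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.table).copy()
        for col in self.REQUIRED:
            if col not in df.columns:
                raise ValueError(f"metadata missing required column {col!r}")
        if "condition_key" not in df.columns:
            df["condition_key"] = df["condition_label"]
        if "replicate_index" not in df.columns:
            df["replicate_index"] = (
                df.groupby("condition_key").cumcount() + 1
            )
        if "source" not in df.columns:
            df["source"] = ""
        df["sample_id"] = df["sample_id"].astype(str).str.strip()
        if df["sample_id"].duplicated().any():
            dups = df.loc[df["sample_id"].duplicated(), "sample_id"]
            raise ValueError(f"duplicate sample ids: {sorted(set(dups))}")
        if (df["replicate_index"].astype(int) < 1).any():
            raise ValueError("replicate_index must be >= 1")
        self.table = df

    def validate_against(self, fm: FitnessMatrix) -> None:
        """Every matrix sample must appear exactly once in the metadata."""
        meta_ids = set(self.table["sample_id"])
        missing = [s for s in fm.sample_ids if s not in meta_ids]
        if missing:
            raise ValueError(f"samples without metadata: {missing}")

    @property
    def n_conditions(self) -> int:
        return self.table["condition_key"].nunique()


@dataclass
class ModuleSet:
    """A collection of gene modules: module id -> set of member gene ids.

    Holds either functional modules called from a fitness decomposition or
    an external regulatory module collection (e.g. iModulon gene sets), so
    the two can be compared on a shared gene namespace.  Optional signed
    weights and an annotation label may accompany each module.
    """

    modules: dict[str, set[str]]
    weights: dict[str, dict[str, float]] = field(default_factory=dict)
    labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.modules = {
            str(m): {str(g).strip() for g in genes}
            for m, genes in self.modules.items()
        }

    @property
    def module_ids(self) -> list[str]:
        return list(self.modules)

    @property
    def gene_universe(self) -> set[str]:
        out: set[str] = set()
        for genes in self.modules.values():
            out |= genes
        return out

    def size(self, module_id: str) -> int:
        return len(self.modules[module_id])

    def empty_modules(self) -> list[str]:
        return [m for m, genes in self.modules.items() if not genes]

    def __len__(self) -> int:
        return len(self.modules)

    def __iter__(self):
        return iter(self.modules.items())


def _duplicates(items: list[str]) -> set[str]:
    seen: set[str] = set()
    dups: set[str] = set()
    for x in items:
        if x in seen:
            dups.add(x)
        seen.add(x)
    return dups
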