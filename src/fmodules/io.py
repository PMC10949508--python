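"""Reading, merging and filtering fitness tables and module definitions.

Fitness tables arrive as tab-separated genes x experiments matrices.  Two
dialects are supported:

* ``plain_matrix`` — first column is the gene id, every other column is an
  experiment.
* ``fitness_browser`` — the layout used by the LBL Fitness Browser exports:
  one or more leading identifier/description columns (locus tag, systematic
  name, description) followed by experiment columns.  Identifier columns
  are everything before the first header matching ``experiment_pattern``;
  with no pattern, only the first column is treated as the identifier.

Merging takes the union of gene universes and concatenates samples;
replicates are deliberately never averaged or rescaled.  Genes lacking a
value in any sample are removed by complete-case filtering before
decomposition.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import FitnessMatrix, ModuleSet, SampleMetadata, _duplicates

__all__ = [
    "read_fitness_table",
    "write_fitness_table",
    "merge_tables",
    "filter_complete_genes",
    "read_module_set",
    "write_module_set",
    "read_sample_metadata",
]

DIALECTS = ("fitness_browser", "plain_matrix")


def read_fitness_table(
    path: str | Path,
    dialect: str = "plain_matrix",
    experiment_pattern: str | None = None,
) -> FitnessMatrix:
    """Read a TSV fitness table into a :class:`FitnessMatrix`.

    Unparseable or empty cells become missing (mask True).  Duplicate gene
    ids and tables without experiment columns are hard errors.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected {DIALECTS}")
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: no experiment columns found")

    headers = list(df.columns)
    if dialect == "fitness_browser" and experiment_pattern is not None:
        rx = re.compile(experiment_pattern)
        first_exp = next(
            (i for i, h in enumerate(headers) if rx.search(h)), None
        )
        if first_exp is None or first_exp == 0:
            raise ValueError(
                f"{path}: experiment pattern {experiment_pattern!r} matched "
                "no column after the identifier block"
            )
        n_id = first_exp
    else:
        n_id = 1  # default: first column is the gene identifier

    gene_ids = [g.strip() for g in df.iloc[:, 0]]
    dups = _duplicates(gene_ids)
    if dups:
        raise ValueError(f"{path}: duplicate gene id(s): {sorted(dups)}")
    exp_cols = headers[n_id:]
    if not exp_cols:
        raise ValueError(f"{path}: zero experiment columns")

    values = df[exp_cols].apply(pd.to_numeric, errors="coerce").to_numpy()
    return FitnessMatrix(
        gene_ids=gene_ids, sample_ids=exp_cols, values=values
    )


def write_fitness_table(fm: FitnessMatrix, path: str | Path) -> None:
    """Write a plain-matrix TSV (gene id column + experiment columns)."""
    df = fm.to_frame()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", float_format="%.17g")


def merge_tables(tables: list[FitnessMatrix]) -> FitnessMatrix:
    """Union of gene universes, concatenation of samples.

    A gene absent from a source table is missing for that table's samples.
    Replicates are not averaged; values pass through unchanged.  Sample ids
    must be disjoint across tables.
    """
    if not tables:
        raise ValueError("need at least one table to merge")
    all_samples: list[str] = []
    for t in tables:
        all_samples.extend(t.sample_ids)
    dups = _duplicates(all_samples)
    if dups:
        raise ValueError(f"colliding sample ids across tables: {sorted(dups)}")

    gene_order: list[str] = []
    seen: set[str] = set()
    for t in tables:
        for g in t.gene_ids:
            if g not in seen:
                seen.add(g)
                gene_order.append(g)
    gene_pos = {g: i for i, g in enumerate(gene_order)}

    values = np.full((len(gene_order), len(all_samples)), np.nan)
    mask = np.ones_like(values, dtype=bool)
    col = 0
    for t in tables:
        rows = [gene_pos[g] for g in t.gene_ids]
        values[rows, col : col + t.n_samples] = t.values
        mask[rows, col : col + t.n_samples] = t.missing_mask
        col += t.n_samples
    return FitnessMatrix(
        gene_ids=gene_order,
        sample_ids=all_samples,
        values=values,
        missing_mask=mask,
    )


def filter_complete_genes(fm: FitnessMatrix) -> FitnessMatrix:
    """Keep only genes observed in every sample (complete-case rule)."""
    keep = ~fm.missing_mask.any(axis=1)
    if not keep.any():
        raise ValueError(
            "complete-case filtering removed every gene; inspect the inputs "
            "for samples with pervasive missingness"
        )
    return fm.select_genes(keep)


def read_module_set(path: str | Path) -> ModuleSet:
    """Read module definitions from JSON or two-column TSV.

    JSON: ``{"module_id": ["gene", ...], ...}`` or
    ``{"module_id": {"genes": [...], "label": "..."}}``.
    TSV: two columns (module_id, gene_id), header optional.  Duplicate
    (module, gene) pairs are deduplicated.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json" or text.lstrip().startswith("{"):
        raw = json.loads(text)
        modules: dict[str, set[str]] = {}
        labels: dict[str, str] = {}
        for mod, entry in raw.items():
            if isinstance(entry, dict):
                modules[str(mod)] = {str(g) for g in entry.get("genes", [])}
                if "label" in entry:
                    labels[str(mod)] = str(entry["label"])
            else:
                modules[str(mod)] = {str(g) for g in entry}
        return ModuleSet(modules=modules, labels=labels)

    modules = {}
    lines = text.splitlines()
    start = 0
    if lines and lines[0].lower().replace(" ", "").startswith(
        ("module_id\t", "module\t")
    ):
        start = 1
    for lineno, line in enumerate(lines[start:], start=start + 1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 2 or not parts[0].strip() or not parts[1].strip():
            raise ValueError(
                f"{path}: malformed module row at line {lineno}: {line!r}"
            )
        modules.setdefault(parts[0].strip(), set()).add(parts[1].strip())
    return ModuleSet(modules=modules)


def write_module_set(ms: ModuleSet, path: str | Path) -> None:
    """Write module membership as two-column TSV (module_id, gene_id)."""
    with open(path, "w") as fh:
        fh.write("module_id\tgene_id\n")
        for mod in ms.module_ids:
            for gene in sorted(ms.modules[mod]):
                fh.write(f"{mod}\t{gene}\n")


def read_sample_metadata(path: str | Path) -> SampleMetadata:
    """Read the sample metadata TSV (sample_id, condition_label, ...)."""
    return SampleMetadata(pd.read_csv(path, sep="\t", dtype=str))
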