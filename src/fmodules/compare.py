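"""Overlap between two module collections (functional vs regulatory).

Modules called from fitness data group genes by shared function; modules
called from expression data (e.g. iModulon sets) group genes by shared
regulation.  This module enumerates the gene-sharing links between the two
collections, the unique-gene overlap count, and flat link records suitable
for Sankey plotting, plus annotation-transfer suggestions for modules left
uncharacterised on one side.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .matrix import ModuleSet

__all__ = ["OverlapTable", "overlap", "sankey_links", "cross_annotate"]


@dataclass
class OverlapTable:
    """Pairwise gene-sharing links between module collections A and B."""

    links: list[tuple[str, str, set[str], int]]
    genes_a_only: int
    genes_b_only: int
    genes_both: int
    coverage_a: dict[str, float]  # fraction of each A module shared with B
    coverage_b: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "module_a": a,
                    "module_b": b,
                    "n_shared": n,
                    "shared_genes": ",".join(sorted(genes)),
                }
                for a, b, genes, n in self.links
            ],
            columns=["module_a", "module_b", "n_shared", "shared_genes"],
        )


def overlap(set_a: ModuleSet, set_b: ModuleSet) -> OverlapTable:
    """All module pairs sharing >= 1 gene, plus unique-gene totals.

    ``genes_both`` counts genes present in at least one module on each side
    once, regardless of how many pairs they connect; the per-link counts
    double-count such genes by design (each link is an independent ribbon).
    Empty collections yield an empty table with zero totals.
    """
    universe_a = set_a.gene_universe
    universe_b = set_b.gene_universe
    links = []
    for aid, agenes in set_a:
        for bid, bgenes in set_b:
            shared = agenes & bgenes
            if shared:
                links.append((aid, bid, shared, len(shared)))
    links.sort(key=lambda t: (-t[3], t[0], t[1]))
    coverage_a = {
        aid: (len(agenes & universe_b) / len(agenes) if agenes else 0.0)
        for aid, agenes in set_a
    }
    coverage_b = {
        bid: (len(bgenes & universe_a) / len(bgenes) if bgenes else 0.0)
        for bid, bgenes in set_b
    }
    both = universe_a & universe_b
    return OverlapTable(
        links=links,
        genes_a_only=len(universe_a - universe_b),
        genes_b_only=len(universe_b - universe_a),
        genes_both=len(both),
        coverage_a=coverage_a,
        coverage_b=coverage_b,
    )


def sankey_links(table: OverlapTable) -> pd.DataFrame:
    """Flat (left_label, right_label, weight) records, heaviest first.

    Ordering is deterministic: descending weight, then labels.
    """
    rows = [
        {"left_label": a, "right_label": b, "weight": n}
        for a, b, _, n in table.links
    ]
    df = pd.DataFrame(rows, columns=["left_label", "right_label", "weight"])
    if len(df):
        df = df.sort_values(
            ["weight", "left_label", "right_label"],
            ascending=[False, True, True],
        ).reset_index(drop=True)
    return df


def cross_annotate(
    table: OverlapTable,
    annotations_a: dict[str, str],
    annotations_b: dict[str, str],
    uncharacterized_label: str = "Uncharacterized",
) -> list[dict]:
    """Suggest annotations for uncharacterised modules from the other side.

    For each module labelled uncharacterised, lists the annotated
    counterpart modules it shares genes with, ranked by shared-gene count.
    """
    suggestions = []

    def is_unchar(label: str | None) -> bool:
        return label is None or label.strip().lower() == (
            uncharacterized_label.lower()
        )

    for a, b, genes, n in table.links:
        lab_a = annotations_a.get(a)
        lab_b = annotations_b.get(b)
        if is_unchar(lab_a) and not is_unchar(lab_b):
            suggestions.append(
                {
                    "module": a,
                    "suggested_from": b,
                    "suggested_label": lab_b,
                    "n_shared": n,
                }
            )
        if is_unchar(lab_b) and not is_unchar(lab_a):
            suggestions.append(
                {
                    "module": b,
                    "suggested_from": a,
                    "suggested_label": lab_a,
                    "n_shared": n,
                }
            )
    suggestions.sort(
        key=lambda s: (s["module"], -s["n_shared"], s["suggested_from"])
    )
    return suggestions
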