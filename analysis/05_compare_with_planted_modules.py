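"""Score the recovered modules against the planted truth.

Treats the planted member sets as an external module collection and
computes the gene-sharing overlap links (Sankey export) plus the greedy
Jaccard matching used for recovery scoring.  With real data the second
collection would be an independently derived module set (e.g. regulatory
modules from expression data); here the planted truth doubles as that
collection, giving a known-answer check of the comparison stage.
"""

import json
from pathlib import Path

import pandas as pd

from fmodules import ModuleSet, overlap, read_module_set, sankey_links, truth_match

OUT = Path("results/comparison")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    members = pd.read_csv("results/modules/members.tsv", sep="\t")
    recovered = ModuleSet(
        {
            mid: set(grp["gene_id"])
            for mid, grp in members.groupby("module_id")
        }
    )
    truth = json.loads(Path("results/synthetic/truth.json").read_text())
    planted = ModuleSet(
        {m: set(g) for m, g in truth["member_sets"].items()}
    )

    table = overlap(recovered, planted)
    table.to_frame().to_csv(OUT / "overlap.tsv", sep="\t", index=False)
    sankey_links(table).to_csv(OUT / "sankey.tsv", sep="\t", index=False)

    rep = truth_match(recovered, planted)
    pd.DataFrame(rep["matches"]).to_csv(
        OUT / "matching.tsv", sep="\t", index=False
    )
    jaccards = [m["jaccard"] for m in rep["matches"]]
    print(
        f"{len(table.links)} overlap links; {table.genes_both} genes in "
        f"both collections; {len(rep['matches'])} matched module pairs "
        f"(min Jaccard {min(jaccards):.2f}); "
        f"{len(rep['unmatched_planted'])} planted modules unmatched"
    )


if __name__ == "__main__":
    main()
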