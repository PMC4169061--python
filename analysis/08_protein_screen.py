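"""Robust protein-phenotype association and two-branch clustering.

Huber regression of each protein's log2 abundance on the PCA phenotype,
BH across the panel (q < 0.1), then average-linkage clustering of the
significant set on correlation distance; the two top-level dendrogram
branches are summarized with their plasma/membrane annotation fractions.
"""

import pandas as pd
from _lib import load_config

from micronet import io as mio
from micronet.proteins import protein_screen

C = load_config()


def main() -> None:
    scores = pd.read_csv(C.RESULTS / "met_pc_scores.csv", index_col=0)["PC1"]
    panel = mio.read_proteins(C.INPUTS / "proteins.csv")
    annotation = pd.read_csv(C.INPUTS / "protein_annotation.csv")
    results, clustering = protein_screen(panel, scores, annotation=annotation)
    results.to_csv(C.RESULTS / "protein_results.tsv", sep="\t", float_format="%.6g")
    n_sig = int(results["significant"].sum())
    print(f"{n_sig} of {len(results)} proteins associated at q < 0.1")
    if "branches" in clustering:
        (C.RESULTS / "protein_cluster_order.txt").write_text(
            "\n".join(clustering["order"]) + "\n"
        )
        for i, b in enumerate(clustering["branches"], 1):
            frac = b.plasma_fraction
            print(f"branch {i}: {len(b.members)} proteins, "
                  f"{b.n_plasma_membrane}/{b.n_annotated} plasma/membrane "
                  f"({100 * frac:.1f} %)")


if __name__ == "__main__":
    main()
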