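"""Average the repeated metabolite assessments and build the PCA phenotype.

The first principal component of the averaged, z-scored panel is the
latent quantitative phenotype for every downstream association; its sign
is anchored so that vitamin E loads positively.
"""

from _lib import load_config

from micronet import io as mio
from micronet.metabolites import average_assessments, cluster_heatmap_order, compute_met_pc

C = load_config()


def main() -> None:
    panel = mio.read_metabolites(C.INPUTS / "metabolites.csv")
    averaged = average_assessments(panel)
    pcs = compute_met_pc(averaged)
    pcs.scores.round(6).to_csv(C.RESULTS / "met_pc_scores.csv")
    pcs.loadings.round(6).to_csv(C.RESULTS / "met_pc_loadings.csv")
    pcs.variance_frac.round(6).to_csv(C.RESULTS / "met_pc_variance.csv")
    row_order, col_order, _, _ = cluster_heatmap_order(averaged)
    (C.RESULTS / "heatmap_order.txt").write_text(
        "rows\t" + "\t".join(map(str, row_order)) + "\n"
        "cols\t" + "\t".join(map(str, col_order)) + "\n"
    )
    print(f"averaged panel: {averaged.shape[0]} subjects x "
          f"{averaged.shape[1]} metabolites")
    for i in range(2):
        print(f"PC{i + 1} explains {100 * pcs.variance_frac.iloc[i]:.1f} % "
              f"of the variance")
    top = pcs.loadings["PC1"].abs().sort_values(ascending=False).head(3)
    print(f"strongest PC1 loadings: {', '.join(top.index)}")


if __name__ == "__main__":
    main()
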