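"""Module, neighborhood and QTL-window enrichment.

Hypergeometric tests of (a) the statistical hit genes and (b) the
micronutrient-neighborhood genes in each topological module (BH over
modules, q < 0.1), the dual "micronutrient system" flag for modules
significant in both, and enrichment of hit genes in per-phenotype QTL
1-Mbp window sets (BH over phenotypes, q < 0.15).
"""

import pandas as pd
from _lib import load_config

from micronet import io as mio
from micronet.enrich import (
    micronutrient_system_flag,
    module_enrichment,
    qtl_enrichment,
    qtl_gene_sets,
)

C = load_config()


def main() -> None:
    part = pd.read_csv(C.RESULTS / "modules.tsv", sep="\t")
    assignment = dict(zip(part["gene_id"], part["module"]))
    universe = set(assignment)
    hits = set(mio.read_gene_list(C.RESULTS / "significant_genes.txt"))
    neighborhood = set(mio.read_gene_list(C.INPUTS / "neighborhood_genes.txt"))

    enr_hits = module_enrichment(assignment, hits, universe)
    enr_nb = module_enrichment(assignment, neighborhood, universe)
    enr_hits.to_csv(C.RESULTS / "module_enrichment_hits.tsv", sep="\t", float_format="%.8g")
    enr_nb.to_csv(C.RESULTS / "module_enrichment_neighborhood.tsv",
                  sep="\t", float_format="%.8g")
    systems = micronutrient_system_flag(enr_hits, enr_nb)
    print(f"modules enriched in hit genes (q<0.1): "
          f"{sorted(enr_hits.index[enr_hits.significant])}")
    print(f"modules enriched in neighborhood genes (q<0.1): "
          f"{sorted(enr_nb.index[enr_nb.significant])}")
    print(f"micronutrient system module(s) (enriched in both): {systems}")

    gene_table = mio.read_gene_bed(C.INPUTS / "genes.bed")
    qtl = mio.read_qtl_bed(C.INPUTS / "qtl.bed")
    sets = qtl_gene_sets(gene_table, qtl)
    enr_qtl = qtl_enrichment(hits, sets, set(gene_table["gene_id"]))
    enr_qtl.to_csv(C.RESULTS / "qtl_enrichment.tsv", sep="\t", float_format="%.8g")
    print(f"QTL phenotypes enriched (q<0.15): "
          f"{sorted(enr_qtl.index[enr_qtl.significant])}")


if __name__ == "__main__":
    main()
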