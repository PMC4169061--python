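"""Generate the reference synthetic cohort and write all study inputs.

Emits genotypes with per-call quality, SNP map and gene annotation,
covariates with sibling clusters, repeated metabolite assessments loading
on a planted latent factor, a protein panel, the planted-module
interaction network, the neighborhood gene list and the QTL table.
"""

from _lib import load_config

from micronet.simulate import simulate_study, write_study

C = load_config()


def main() -> None:
    study = simulate_study(C.STUDY_CONFIG)
    paths = write_study(study, C.INPUTS)
    print(f"cohort: {len(study.subjects)} subjects in "
          f"{study.covariates['family_id'].nunique()} families")
    print(f"genotypes: {study.calls.shape[1]} SNPs over "
          f"{len(study.gene_table)} genes")
    print(f"network: {study.network.number_of_nodes()} genes, "
          f"{study.network.number_of_edges()} interactions")
    print(f"planted: {len(study.truth['causal_genes'])} causal genes in "
          f"module {study.truth['causal_modules']}, "
          f"{len(study.neighborhood_genes)} neighborhood genes")
    print(f"wrote {len(paths)} input files to {C.INPUTS}")


if __name__ == "__main__":
    main()
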