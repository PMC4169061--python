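"""End-to-end orchestration: simulate -> metpc -> qc -> scan -> genes ->
modules -> enrich -> proteins, with a provenance manifest.

``run_pipeline`` can start from a :class:`~micronet.simulate.SyntheticStudy`
(in-memory) or from a directory of input files. Stages run in dependency
order; each writes a plain-text table to the output directory and records
its SHA-256 in the manifest, so a rerun with the same config and seed
reproduces identical checksums for every deterministic stage and identical
results for the seeded stochastic stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

from micronet import io as mio
from micronet.enrich import (
    micronutrient_system_flag,
    module_enrichment,
    qtl_enrichment,
    qtl_gene_sets,
)
from micronet.genes import build_gene_models, run_gene_scan
from micronet.metabolites import average_assessments, compute_met_pc
from micronet.network import (
    largest_connected_component,
    partition_summary,
    spinglass_partition,
)
from micronet.proteins import protein_screen
from micronet.qc import run_qc
from micronet.association import run_genome_scan
from micronet.simulate import SimConfig, SyntheticStudy, simulate_study, write_study

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All stage parameters plus the root seed.

    Thresholds mirror the study design: call-quality 0.7, MAF 0.1, exact
    HWE alpha 0.001; SNP significance at adjusted p < 0.05, gene and
    module significance at q < 0.1, QTL phenotypes at q < 0.15.
    """

    outdir: str = "pipeline_out"
    seed: int = 0
    sim: SimConfig | None = None  # simulate when set; else read input_dir
    input_dir: str | None = None
    anchor: str = "vitamin_E"
    quality_threshold: float = 0.7
    quality_mode: str = "any"
    maf_threshold: float = 0.1
    hwe_alpha: float = 0.001
    snp_alpha_bh: float = 0.05
    gene_q: float = 0.1
    module_q: float = 0.1
    qtl_q: float = 0.15
    flank: int = 50_000
    gene_stages: tuple[int, ...] = (1_000, 10_000, 100_000)
    spins: int = 25
    gamma: float = 1.0
    restarts: int = 3
    max_sweeps: int = 1500
    log2_proteins: bool = True

    def config_hash(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""
        d = dataclasses.asdict(self)
        d.pop("outdir", None)
        if self.sim is not None:
            d["sim"] = dataclasses.asdict(self.sim)
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    checksums: dict[str, str] = field(default_factory=dict)
    timings: dict[str, float] = field(default_factory=dict)
    stats: dict = field(default_factory=dict)
    timestamp: str = ""

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def validate_inputs(study: SyntheticStudy) -> list[str]:
    """Cross-file consistency report; empty list means clean."""
    failures = []
    subj = set(study.calls.index)
    if subj - set(study.covariates.index):
        failures.append("genotyped subject(s) missing from covariates")
    if subj - set(study.metabolites["subject_id"]):
        failures.append("genotyped subject(s) missing from metabolite panel")
    if set(study.snp_map["snp_id"]) != set(study.calls.columns):
        failures.append("SNP map and genotype columns disagree")
    net_genes = set(study.network.nodes())
    ann_genes = set(study.gene_table["gene_id"])
    missing_nb = [g for g in study.neighborhood_genes if g not in net_genes]
    if missing_nb:
        failures.append(
            f"{len(missing_nb)} neighborhood gene(s) absent from network"
        )
    if net_genes - ann_genes:
        failures.append("network gene(s) missing from annotation")
    if (study.gene_table["start"] > study.gene_table["end"]).any():
        failures.append("gene interval with start > end")
    return failures


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute every stage; returns the manifest (also written to disk)."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_hash=config.config_hash(), seed=config.seed,
                           timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"))

    def _record(name: str, path: Path, t0: float) -> None:
        manifest.checksums[name] = _sha256(path)
        manifest.timings[name] = round(time.time() - t0, 3)

    # --- stage: inputs -----------------------------------------------------
    t0 = time.time()
    if config.sim is not None:
        study = simulate_study(config.sim)
        paths = write_study(study, out / "inputs")
        for name, p in paths.items():
            manifest.checksums[f"input/{name}"] = _sha256(p)
    elif config.input_dir is not None:
        study = load_study(config.input_dir)
    else:
        raise ValueError("config needs either sim or input_dir")
    manifest.timings["inputs"] = round(time.time() - t0, 3)
    failures = validate_inputs(study)
    if failures:
        log.warning("input validation: %s", failures)
    manifest.stats["validation_failures"] = failures

    # --- metabolite phenotype ---------------------------------------------
    t0 = time.time()
    averaged = average_assessments(study.metabolites)
    metpc = compute_met_pc(averaged, anchor=config.anchor)
    scores_path = out / "met_pc_scores.csv"
    metpc.scores.round(6).to_csv(scores_path)
    manifest.stats["pc1_variance_frac"] = float(metpc.variance_frac.iloc[0])
    _record("met_pc_scores", scores_path, t0)

    # --- genotype QC -------------------------------------------------------
    t0 = time.time()
    qc_calls, qc_report = run_qc(
        study.calls, study.quality,
        quality_threshold=config.quality_threshold,
        quality_mode=config.quality_mode,
        maf_threshold=config.maf_threshold,
        hwe_alpha=config.hwe_alpha,
    )
    qc_path = out / "qc_report.json"
    qc_path.write_text(json.dumps(qc_report.to_dict(), indent=1))
    manifest.stats["qc"] = qc_report.to_dict()
    _record("qc_report", qc_path, t0)

    # --- SNP scan ----------------------------------------------------------
    t0 = time.time()
    scan = run_genome_scan(metpc.pc1, qc_calls, study.covariates)
    scan_path = out / "snp_scan.tsv"
    scan.to_csv(scan_path, sep="\t", float_format="%.6g")
    n_sig_snps = int((scan["p_bh"] < config.snp_alpha_bh).sum())
    manifest.stats["n_significant_snps"] = n_sig_snps
    _record("snp_scan", scan_path, t0)

    # --- gene aggregation --------------------------------------------------
    t0 = time.time()
    models, gene_report = build_gene_models(
        study.snp_map, study.gene_table, qc_calls, flank=config.flank
    )
    genes = run_gene_scan(scan, models, stages=config.gene_stages,
                          seed=config.seed)
    genes_path = out / "gene_results.tsv"
    genes.to_csv(genes_path, sep="\t", float_format="%.8g")
    sig_genes = set(genes.index[genes["q"] < config.gene_q])
    manifest.stats["gene_models"] = gene_report
    manifest.stats["n_significant_genes"] = len(sig_genes)
    _record("gene_results", genes_path, t0)

    # --- network modules ---------------------------------------------------
    t0 = time.time()
    lcc = largest_connected_component(study.network)
    partition = spinglass_partition(
        lcc, q=config.spins, gamma=config.gamma,
        restarts=config.restarts, max_sweeps=config.max_sweeps,
        seed=config.seed,
    )
    part_path = out / "modules.tsv"
    partition.to_frame().to_csv(part_path, sep="\t", index=False)
    manifest.stats["modules"] = partition_summary(partition)
    manifest.stats["modularity"] = partition.modularity
    _record("modules", part_path, t0)

    # --- enrichment --------------------------------------------------------
    t0 = time.time()
    universe = set(lcc.nodes())
    enr_hits = module_enrichment(partition, sig_genes, universe,
                                 q_threshold=config.module_q)
    enr_nb = module_enrichment(partition, set(study.neighborhood_genes),
                               universe, q_threshold=config.module_q)
    systems = micronutrient_system_flag(enr_hits, enr_nb)
    qtl_sets = qtl_gene_sets(study.gene_table, study.qtl_table)
    enr_qtl = qtl_enrichment(sig_genes, qtl_sets,
                             set(study.gene_table["gene_id"]),
                             q_threshold=config.qtl_q)
    enr_path = out / "module_enrichment.tsv"
    enr_hits.to_csv(enr_path, sep="\t", float_format="%.8g")
    enr_nb.to_csv(out / "neighborhood_enrichment.tsv", sep="\t", float_format="%.8g")
    enr_qtl.to_csv(out / "qtl_enrichment.tsv", sep="\t", float_format="%.8g")
    manifest.stats["micronutrient_systems"] = [int(m) for m in systems]
    manifest.stats["n_enriched_modules_hits"] = int(enr_hits["significant"].sum())
    manifest.stats["n_enriched_modules_neighborhood"] = int(enr_nb["significant"].sum())
    manifest.stats["n_enriched_qtl_phenotypes"] = int(enr_qtl["significant"].sum())
    manifest.checksums["neighborhood_enrichment"] = _sha256(
        out / "neighborhood_enrichment.tsv")
    manifest.checksums["qtl_enrichment"] = _sha256(out / "qtl_enrichment.tsv")
    _record("module_enrichment", enr_path, t0)

    # --- proteins ----------------------------------------------------------
    t0 = time.time()
    prot_results, clustering = protein_screen(
        study.proteins, metpc.pc1,
        annotation=study.protein_annotation,
        log2_transform=config.log2_proteins,
    )
    prot_path = out / "protein_results.tsv"
    prot_results.to_csv(prot_path, sep="\t", float_format="%.6g")
    manifest.stats["n_significant_proteins"] = int(prot_results["significant"].sum())
    if "branches" in clustering:
        manifest.stats["branch_plasma_fractions"] = [
            round(b.plasma_fraction, 4) if b.n_annotated else None
            for b in clustering["branches"]
        ]
    _record("protein_results", prot_path, t0)

    manifest_path = out / "manifest.json"
    manifest_path.write_text(manifest.to_json())
    return manifest


def load_study(input_dir: str | Path) -> SyntheticStudy:
    """Reassemble a study from the files ``write_study`` produces."""
    import networkx as nx
    import pandas as pd

    d = Path(input_dir)
    truth = {}
    truth_path = d / "truth.json"
    if truth_path.exists():
        truth = json.loads(truth_path.read_text())
    calls = mio.read_genotypes(d / "genotypes.tsv")
    network = nx.read_edgelist(d / "network_edges.tsv", delimiter="\t")
    return SyntheticStudy(
        config=SimConfig(),
        calls=calls,
        quality=mio.read_quality(d / "quality.tsv"),
        snp_map=mio.read_snp_map(d / "snp_map.tsv"),
        gene_table=mio.read_gene_bed(d / "genes.bed"),
        covariates=mio.read_covariates(d / "covariates.csv"),
        metabolites=mio.read_metabolites(d / "metabolites.csv"),
        proteins=mio.read_proteins(d / "proteins.csv"),
        protein_annotation=pd.read_csv(d / "protein_annotation.csv"),
        network=network,
        neighborhood_genes=mio.read_gene_list(d / "neighborhood_genes.txt"),
        qtl_table=mio.read_qtl_bed(d / "qtl.bed"),
        truth=truth,
    )
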