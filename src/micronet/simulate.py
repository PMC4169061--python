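"""Synthetic study generator.

Emulates the statistical structure the downstream analysis assumes:

* genotypes in LD blocks, drawn from a block-level latent Gaussian copula,
  with sibling clusters that share parental haplotypes per block;
* per-call quality scores and missing calls, so QC has something to remove;
* a planted latent metabolite factor (the stand-in for the met_PC1
  phenotype) driven by causal SNPs plus age/sex confounding;
* repeated metabolite assessments loading on the factor;
* a protein panel with a signal subset tied to the factor under
  heavy-tailed noise;
* a stochastic-block-model interaction network with planted modules, a
  micronutrient-neighborhood gene list overlapping one block, and a QTL
  interval table covering a configurable fraction of causal genes.

All randomness flows from one root seed through named
``numpy.random.SeedSequence`` child streams, so every output is
bit-reproducible for a fixed seed and individual stages are decoupled
(changing the protein stream does not disturb the genotypes).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

METABOLITES = (
    "vitamin_A",
    "vitamin_D",
    "vitamin_E",
    "riboflavin",
    "thiamine",
    "pyridoxal",
    "homocysteine",
    "SAM_SAH",
)

#: default factor loadings: six metabolites load strongly on the latent
#: factor, vitamin D and riboflavin only weakly (they belong to a second,
#: unmodelled axis of variation).
DEFAULT_LOADINGS = {
    "vitamin_A": 1.0,
    "vitamin_D": 0.2,
    "vitamin_E": 1.0,
    "riboflavin": 0.2,
    "thiamine": 1.0,
    "pyridoxal": 1.0,
    "homocysteine": 1.0,
    "SAM_SAH": 1.0,
}

# seed-stream names; one child stream per independent source of randomness
_STREAMS = (
    "families",
    "maf",
    "haplotypes",
    "quality",
    "missing",
    "covariates",
    "latent",
    "metabolites",
    "proteins",
    "network",
    "neighborhood",
    "qtl",
    "causal",
)


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters for one synthetic cohort.

    Defaults describe the reference synthetic condition used throughout:
    200 children in up-to-three-sibling families, 5,000 SNPs in 5-SNP LD
    blocks over 1,000 genes, a 10-block interaction network with 8 causal
    genes planted in one block (each carrying roughly a tenth of the latent
    factor's variance), and a neighborhood gene list overlapping the same
    block.
    """

    n_subjects: int = 200
    n_families: int = 130
    n_genes: int = 1000
    snps_per_gene: int | tuple[int, int] = 5
    n_snps: int | None = None  # derived from genes when None
    ld_block_size: int = 5
    within_block_r: float = 0.8
    maf_range: tuple[float, float] = (0.15, 0.5)
    n_modules: int = 10
    sbm_p_in: float = 0.2
    sbm_p_out: float = 0.01
    n_causal_genes: int = 8
    causal_module_ids: tuple[int, ...] = (3,)
    beta_snp: float = 0.45
    gamma_age: float = 0.05
    gamma_sex: float = 0.2
    latent_noise_sd: float = 1.7
    metabolite_loadings: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LOADINGS)
    )
    noise_sd: float = 1.0
    assessment_noise_frac: float = 0.3  # assessment SD = frac * noise_sd
    n_assessments: int = 3
    n_proteins: int = 200
    n_signal_proteins: int = 20
    protein_beta: float = 0.5
    protein_noise_df: int = 3
    missing_call_rate: float = 0.001
    low_quality_rate: float = 0.0005
    n_neighborhood: int = 80
    neighborhood_overlap: float = 0.7
    neighborhood_block: int | None = None  # default: first causal module
    n_qtl_phenotypes: int = 8
    qtl_frac_causal_covered: float = 0.8
    qtl_per_phenotype: int = 3
    n_chromosomes: int = 2
    gene_length: int = 20_000
    gene_spacing: int = 300_000
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_subjects, self.n_families, self.n_genes, self.ld_block_size) <= 0:
            raise ValueError("dimensions must be positive")
        if not self.n_families <= self.n_subjects <= 3 * self.n_families:
            raise ValueError(
                "n_subjects must fit in n_families sibling clusters of size 1-3"
            )
        if not (0.0 <= self.within_block_r < 1.0):
            raise ValueError("within_block_r must be in [0, 1)")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie in (0, 0.5]")
        for name in ("sbm_p_in", "sbm_p_out", "missing_call_rate", "low_quality_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be a probability")
        if self.sbm_p_in <= self.sbm_p_out:
            raise ValueError("sbm_p_in must exceed sbm_p_out (planted modules)")
        bad = set(self.causal_module_ids) - set(range(1, self.n_modules + 1))
        if bad:
            raise ValueError(f"causal_module_ids not in 1..n_modules: {sorted(bad)}")
        if self.n_snps is not None and isinstance(self.snps_per_gene, int):
            if self.n_snps != self.n_genes * self.snps_per_gene:
                raise ValueError("n_snps inconsistent with n_genes * snps_per_gene")
        if not (0.0 <= self.neighborhood_overlap <= 1.0):
            raise ValueError("neighborhood_overlap must be in [0, 1]")

    def streams(self) -> dict[str, np.random.Generator]:
        """One independent generator per randomness source, all from `seed`."""
        root = np.random.SeedSequence(self.seed)
        children = root.spawn(len(_STREAMS))
        return {name: np.random.default_rng(c) for name, c in zip(_STREAMS, children)}


@dataclass
class SyntheticStudy:
    """Everything one cohort analysis consumes, plus the planted truth."""

    config: SimConfig
    calls: pd.DataFrame  # subjects x SNPs, int8; -1 = missing
    quality: pd.DataFrame  # subjects x SNPs, float; NaN where call missing
    snp_map: pd.DataFrame  # snp_id, chrom, pos, ref, alt, gene_id
    gene_table: pd.DataFrame  # gene_id, chrom, start, end (1-based inclusive)
    covariates: pd.DataFrame  # subject_id, age, sex, hei, family_id
    metabolites: pd.DataFrame  # long: subject_id, assessment, metabolite, value
    proteins: pd.DataFrame  # subjects x proteins (linear-scale abundance)
    protein_annotation: pd.DataFrame  # protein_id, location
    network: nx.Graph
    neighborhood_genes: list[str]
    qtl_table: pd.DataFrame  # phenotype, chrom, start, end, source_id
    truth: dict

    @property
    def subjects(self) -> list[str]:
        return list(self.calls.index)


# ---------------------------------------------------------------------------
# gene / SNP layout


def _gene_layout(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Tile genes along chromosomes with wide spacing (no overlap at 50 kb
    flanks under the default spacing)."""
    gene_ids = [f"g{i:04d}" for i in range(1, cfg.n_genes + 1)]
    per_chrom = int(np.ceil(cfg.n_genes / cfg.n_chromosomes))
    rows = []
    for i, gid in enumerate(gene_ids):
        chrom = f"chr{i // per_chrom + 1}"
        j = i % per_chrom
        start = 10_001 + j * cfg.gene_spacing
        rows.append((gid, chrom, start, start + cfg.gene_length - 1))
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"])


def _snp_counts(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    if isinstance(cfg.snps_per_gene, int):
        return np.full(cfg.n_genes, cfg.snps_per_gene, dtype=int)
    lo, hi = cfg.snps_per_gene
    return rng.integers(lo, hi + 1, size=cfg.n_genes)


def _snp_map(cfg: SimConfig, gene_table: pd.DataFrame, counts: np.ndarray) -> pd.DataFrame:
    rows = []
    k = 0
    for (_, g), c in zip(gene_table.iterrows(), counts):
        # evenly spaced positions inside the gene body
        pos = np.linspace(g.start + 10, g.end - 10, c).astype(int)
        for p in pos:
            k += 1
            rows.append((f"rs{k:06d}", g.chrom, int(p), "A", "B", g.gene_id))
    return pd.DataFrame(
        rows, columns=["snp_id", "chrom", "pos", "ref", "alt", "gene_id"]
    )


# ---------------------------------------------------------------------------
# genotypes


def _family_sizes(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    sizes = np.ones(cfg.n_families, dtype=int)
    extra = cfg.n_subjects - cfg.n_families
    while extra > 0:
        open_idx = np.flatnonzero(sizes < 3)
        pick = rng.choice(open_idx)
        sizes[pick] += 1
        extra -= 1
    return sizes


def _block_slices(n_snps: int, block: int) -> list[slice]:
    return [slice(s, min(s + block, n_snps)) for s in range(0, n_snps, block)]


def _draw_haplotype_block(
    rng: np.random.Generator, thresholds: np.ndarray, r: float, size: int
) -> np.ndarray:
    """`size` haplotypes over one LD block via an equicorrelated Gaussian
    copula: z = sqrt(r) * shared + sqrt(1-r) * own, allele = 1{z < Phi^-1(f)}."""
    m = thresholds.shape[0]
    shared = rng.standard_normal((size, 1))
    own = rng.standard_normal((size, m))
    z = np.sqrt(r) * shared + np.sqrt(1.0 - r) * own
    return (z < thresholds).astype(np.int8)


def simulate_genotypes(
    cfg: SimConfig, *, streams: dict[str, np.random.Generator] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame, dict]:
    """Draw genotypes, quality scores and the SNP map.

    Returns ``(calls, quality, snp_map, gene_table, meta)`` where ``meta``
    carries the family assignment and per-SNP population allele
    frequencies. Calls count the minor allele after orientation; -1 marks
    a missing call.
    """
    streams = streams or cfg.streams()
    gene_table = _gene_layout(cfg, streams["maf"])
    counts = _snp_counts(cfg, streams["maf"])
    snp_map = _snp_map(cfg, gene_table, counts)
    n_snps = len(snp_map)

    lo, hi = cfg.maf_range
    freqs = streams["maf"].uniform(lo, hi, size=n_snps)
    thresholds = stats.norm.ppf(freqs)

    sizes = _family_sizes(cfg, streams["families"])
    family_of = np.repeat(np.arange(cfg.n_families), sizes)
    subjects = [f"s{i:03d}" for i in range(1, cfg.n_subjects + 1)]

    hap_rng = streams["haplotypes"]
    geno = np.empty((cfg.n_subjects, n_snps), dtype=np.int8)
    for sl in _block_slices(n_snps, cfg.ld_block_size):
        th = thresholds[sl]
        row = 0
        for fam_size in sizes:
            # four parental haplotypes per family per block
            par = _draw_haplotype_block(hap_rng, th, cfg.within_block_r, 4)
            mat, pat = par[:2], par[2:]
            mi = hap_rng.integers(0, 2, size=fam_size)
            pi = hap_rng.integers(0, 2, size=fam_size)
            geno[row : row + fam_size, sl] = mat[mi] + pat[pi]
            row += fam_size

    # orient to minor allele: flip columns whose sample frequency exceeds 1/2
    f_hat = geno.mean(axis=0) / 2.0
    flip = f_hat > 0.5
    geno[:, flip] = 2 - geno[:, flip]
    snp_map = snp_map.copy()
    snp_map["flipped"] = flip

    qual = streams["quality"].uniform(0.7, 1.0, size=geno.shape)
    low = streams["quality"].random(geno.shape) < cfg.low_quality_rate
    qual[low] = streams["quality"].uniform(0.0, 0.7, size=int(low.sum()))

    miss = streams["missing"].random(geno.shape) < cfg.missing_call_rate
    geno[miss] = -1
    qual[miss] = np.nan

    snp_ids = snp_map["snp_id"].tolist()
    calls = pd.DataFrame(geno, index=subjects, columns=snp_ids)
    quality = pd.DataFrame(qual, index=subjects, columns=snp_ids)
    calls.index.name = quality.index.name = "subject_id"
    meta = {
        "family_of": family_of,
        "family_ids": [f"fam{f:03d}" for f in family_of],
        "freqs": freqs,
    }
    return calls, quality, snp_map, gene_table, meta


# ---------------------------------------------------------------------------
# phenotypes


def simulate_phenotypes(
    cfg: SimConfig,
    calls: pd.DataFrame,
    snp_map: pd.DataFrame,
    gene_models: dict[str, list[str]],
    causal_genes: list[str],
    family_ids: list[str],
    *,
    streams: dict[str, np.random.Generator] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame, dict]:
    """Covariates, metabolite assessments, protein panel and planted truth.

    The latent factor is ``standardize(sum_j beta * minor_count_j +
    gamma_age * age + gamma_sex * sex + eps)`` over all causal SNPs; each
    metabolite is ``loading * L + N(0, noise_sd)`` observed as repeated
    assessments with extra assessment noise; signal proteins are
    ``protein_beta * L`` plus Student-t (df=3) noise, null proteins pure
    t noise.
    """
    streams = streams or cfg.streams()
    causal_snps = [s for g in causal_genes for s in gene_models[g]]
    if not causal_snps and cfg.beta_snp != 0.0:
        raise ValueError("no causal SNPs resolvable but beta_snp != 0")

    n = len(calls)
    rng_cov = streams["covariates"]
    age = rng_cov.uniform(6.0, 14.0, size=n)
    sex = rng_cov.integers(0, 2, size=n)
    hei = np.clip(rng_cov.normal(55.0, 10.0, size=n), 20.0, 95.0)
    covariates = pd.DataFrame(
        {
            "subject_id": calls.index,
            "age": np.round(age, 2),
            "sex": sex,
            "hei": np.round(hei, 2),
            "family_id": family_ids,
        }
    ).set_index("subject_id")

    # dosage with missing calls imputed at the SNP mean: the latent factor is
    # a population property, not subject to the QC path
    if causal_snps:
        dose = calls[causal_snps].to_numpy(dtype=float)
        dose[dose < 0] = np.nan
        col_mean = np.nanmean(dose, axis=0)
        dose = np.where(np.isnan(dose), col_mean, dose)
        genetic = cfg.beta_snp * dose.sum(axis=1)
    else:
        genetic = np.zeros(n)

    eps = streams["latent"].normal(0.0, cfg.latent_noise_sd, size=n)
    raw = genetic + cfg.gamma_age * age + cfg.gamma_sex * sex + eps
    sd_raw = float(raw.std(ddof=0))
    if sd_raw == 0.0:
        raise ValueError("latent factor degenerate (zero variance)")
    latent = (raw - raw.mean()) / sd_raw

    loadings = cfg.metabolite_loadings
    rng_met = streams["metabolites"]
    rows = []
    assess_sd = cfg.assessment_noise_frac * cfg.noise_sd
    for met, lam in loadings.items():
        base = lam * latent + rng_met.normal(0.0, cfg.noise_sd, size=n)
        for a in range(1, cfg.n_assessments + 1):
            vals = base + rng_met.normal(0.0, assess_sd, size=n)
            rows.append(
                pd.DataFrame(
                    {
                        "subject_id": calls.index,
                        "assessment": a,
                        "metabolite": met,
                        "value": vals,
                    }
                )
            )
    metabolites = pd.concat(rows, ignore_index=True)

    rng_prot = streams["proteins"]
    prot_ids = [f"P{i:04d}" for i in range(1, cfg.n_proteins + 1)]
    signal_ids = prot_ids[: cfg.n_signal_proteins]
    noise = rng_prot.standard_t(cfg.protein_noise_df, size=(n, cfg.n_proteins))
    signal = np.zeros((n, cfg.n_proteins))
    signal[:, : cfg.n_signal_proteins] = cfg.protein_beta * latent[:, None]
    # log2-scale construction; written on the (right-skewed) linear scale
    proteins = pd.DataFrame(
        np.exp2(10.0 + signal + noise), index=calls.index, columns=prot_ids
    )
    loc = np.where(
        rng_prot.random(cfg.n_proteins)
        < np.where(np.isin(prot_ids, signal_ids), 0.7, 0.4),
        "plasma_membrane",
        "cytosolic",
    )
    protein_annotation = pd.DataFrame({"protein_id": prot_ids, "location": loc})

    truth = {
        "latent": pd.Series(latent, index=calls.index, name="latent"),
        "causal_snps": causal_snps,
        "causal_genes": list(causal_genes),
        "signal_proteins": signal_ids,
        "sd_raw": sd_raw,
        # marginal standardized per-allele effect; exact when causal SNPs are
        # mutually uncorrelated (no shared LD blocks)
        "effective_beta": cfg.beta_snp / sd_raw,
        "metabolite_base_noise_sd": cfg.noise_sd,
    }
    return covariates, metabolites, proteins, protein_annotation, truth


# ---------------------------------------------------------------------------
# network, neighborhood, QTL


def simulate_network(
    cfg: SimConfig,
    gene_table: pd.DataFrame,
    causal_genes: list[str],
    *,
    streams: dict[str, np.random.Generator] | None = None,
) -> tuple[nx.Graph, dict[str, int], list[str], pd.DataFrame]:
    """Planted-partition interaction network + neighborhood list + QTL table.

    Genes are split into ``n_modules`` contiguous blocks; edges are drawn
    with probability ``sbm_p_in`` inside a block and ``sbm_p_out`` between
    blocks. The neighborhood gene list overlaps the designated block by
    ``neighborhood_overlap``; QTL intervals for the first phenotype are
    placed within 1 Mbp of a ``qtl_frac_causal_covered`` fraction of the
    causal genes.
    """
    streams = streams or cfg.streams()
    genes = gene_table["gene_id"].tolist()
    sizes = np.full(cfg.n_modules, len(genes) // cfg.n_modules, dtype=int)
    sizes[: len(genes) % cfg.n_modules] += 1
    bounds = np.concatenate([[0], np.cumsum(sizes)])
    block_of = {}
    for b in range(cfg.n_modules):
        for gid in genes[bounds[b] : bounds[b + 1]]:
            block_of[gid] = b + 1

    rng = streams["network"]
    sbm_seed = int(rng.integers(0, 2**31 - 1))
    g_int = nx.stochastic_block_model(
        sizes.tolist(),
        np.full((cfg.n_modules, cfg.n_modules), cfg.sbm_p_out)
        + np.eye(cfg.n_modules) * (cfg.sbm_p_in - cfg.sbm_p_out),
        seed=sbm_seed,
    )
    network = nx.relabel_nodes(nx.Graph(g_int.edges()), dict(enumerate(genes)))
    network.add_nodes_from(genes)

    nb_block = cfg.neighborhood_block or cfg.causal_module_ids[0]
    in_block = [g for g in genes if block_of[g] == nb_block]
    out_block = [g for g in genes if block_of[g] != nb_block]
    k_in = min(round(cfg.n_neighborhood * cfg.neighborhood_overlap), len(in_block))
    k_out = min(cfg.n_neighborhood - k_in, len(out_block))
    rng_nb = streams["neighborhood"]
    neighborhood = sorted(
        list(rng_nb.choice(in_block, size=k_in, replace=False))
        + list(rng_nb.choice(out_block, size=k_out, replace=False))
    )

    rng_qtl = streams["qtl"]
    gt = gene_table.set_index("gene_id")
    rows: list[tuple] = []
    phenos = [f"pheno_{i:02d}" for i in range(1, cfg.n_qtl_phenotypes + 1)]
    n_cov = round(cfg.qtl_frac_causal_covered * len(causal_genes))
    covered = rng_qtl.choice(causal_genes, size=n_cov, replace=False)
    for i, gid in enumerate(covered):
        g = gt.loc[gid]
        offset = int(rng_qtl.uniform(0, 900_000))
        start = max(1, int(g.start) - offset)
        rows.append((phenos[0], g.chrom, start, start + 1_000, f"qtl_c{i:02d}"))
    chrom_max = gene_table.groupby("chrom")["end"].max()
    for pheno in phenos[1:]:
        for j in range(cfg.qtl_per_phenotype):
            chrom = rng_qtl.choice(chrom_max.index)
            start = int(rng_qtl.uniform(1, chrom_max[chrom]))
            rows.append((pheno, chrom, start, start + 1_000, f"qtl_{pheno}_{j}"))
    qtl_table = pd.DataFrame(
        rows, columns=["phenotype", "chrom", "start", "end", "source_id"]
    )
    return network, block_of, neighborhood, qtl_table


# ---------------------------------------------------------------------------
# orchestration


def simulate_study(cfg: SimConfig) -> SyntheticStudy:
    """Generate one complete synthetic cohort from a single seed."""
    streams = cfg.streams()
    calls, quality, snp_map, gene_table, meta = simulate_genotypes(
        cfg, streams=streams
    )
    gene_models = {
        gid: grp["snp_id"].tolist() for gid, grp in snp_map.groupby("gene_id")
    }

    # causal genes concentrated in the designated network blocks (blocks are
    # contiguous index ranges; see simulate_network)
    genes = gene_table["gene_id"].tolist()
    sizes = np.full(cfg.n_modules, len(genes) // cfg.n_modules, dtype=int)
    sizes[: len(genes) % cfg.n_modules] += 1
    bounds = np.concatenate([[0], np.cumsum(sizes)])
    pool = [
        g
        for b in cfg.causal_module_ids
        for g in genes[bounds[b - 1] : bounds[b]]
    ]
    causal_genes = sorted(
        streams["causal"].choice(pool, size=cfg.n_causal_genes, replace=False)
    )

    covariates, metabolites, proteins, protein_annotation, truth = simulate_phenotypes(
        cfg,
        calls,
        snp_map,
        gene_models,
        causal_genes,
        meta["family_ids"],
        streams=streams,
    )
    network, block_of, neighborhood, qtl_table = simulate_network(
        cfg, gene_table, causal_genes, streams=streams
    )
    truth.update(
        {
            "causal_modules": list(cfg.causal_module_ids),
            "block_of": block_of,
            "neighborhood_block": cfg.neighborhood_block or cfg.causal_module_ids[0],
            "qtl_signal_phenotype": "pheno_01",
        }
    )
    return SyntheticStudy(
        config=cfg,
        calls=calls,
        quality=quality,
        snp_map=snp_map,
        gene_table=gene_table,
        covariates=covariates,
        metabolites=metabolites,
        proteins=proteins,
        protein_annotation=protein_annotation,
        network=network,
        neighborhood_genes=neighborhood,
        qtl_table=qtl_table,
        truth=truth,
    )


def write_study(study: SyntheticStudy, outdir: str | Path) -> dict[str, Path]:
    """Write every downstream input file; returns the path map."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "genotypes": out / "genotypes.tsv",
        "quality": out / "quality.tsv",
        "snp_map": out / "snp_map.tsv",
        "genes_bed": out / "genes.bed",
        "covariates": out / "covariates.csv",
        "metabolites": out / "metabolites.csv",
        "proteins": out / "proteins.csv",
        "protein_annotation": out / "protein_annotation.csv",
        "edges": out / "network_edges.tsv",
        "neighborhood": out / "neighborhood_genes.txt",
        "qtl_bed": out / "qtl.bed",
        "truth": out / "truth.json",
    }
    study.calls.to_csv(paths["genotypes"], sep="\t")
    study.quality.to_csv(paths["quality"], sep="\t", float_format="%.4f")
    study.snp_map.to_csv(paths["snp_map"], sep="\t", index=False)
    bed = study.gene_table.copy()  # files use BED 0-based half-open
    bed["start"] = bed["start"] - 1
    bed[["chrom", "start", "end", "gene_id"]].to_csv(
        paths["genes_bed"], sep="\t", index=False, header=False
    )
    study.covariates.to_csv(paths["covariates"])
    study.metabolites.to_csv(paths["metabolites"], index=False, float_format="%.6g")
    study.proteins.to_csv(paths["proteins"], float_format="%.6g")
    study.protein_annotation.to_csv(paths["protein_annotation"], index=False)
    nx.write_edgelist(study.network, paths["edges"], delimiter="\t", data=False)
    paths["neighborhood"].write_text("\n".join(study.neighborhood_genes) + "\n")
    qtl = study.qtl_table.copy()
    qtl["start"] = qtl["start"] - 1
    qtl[["chrom", "start", "end", "phenotype", "source_id"]].to_csv(
        paths["qtl_bed"], sep="\t", index=False, header=False
    )
    truth = {
        k: (v.to_dict() if isinstance(v, pd.Series) else v)
        for k, v in study.truth.items()
    }
    truth["config"] = dataclasses.asdict(study.config)
    truth["config"]["snps_per_gene"] = (
        list(study.config.snps_per_gene)
        if isinstance(study.config.snps_per_gene, tuple)
        else study.config.snps_per_gene
    )
    paths["truth"].write_text(json.dumps(truth, indent=1, default=str))
    return paths
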