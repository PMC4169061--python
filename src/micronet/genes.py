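"""LD-aware gene-level aggregation of SNP association p-values.

Each gene's statistic is the sum of 1-df chi-square quantiles of its
member SNPs' nominal p-values, T = sum_i F^-1_{chi2(1)}(1 - p_i). The
null distribution of T depends on the local LD structure: under the null
the per-SNP z-scores are approximately multivariate normal with the
genotype correlation matrix R, so null draws of T are simulated as
sum(Z^2) with Z ~ MVN(0, R). The Monte-Carlo p-value uses the add-one
estimator p = (1 + #{null >= T}) / (1 + n_sims) and an adaptive schedule
that escalates the simulation count only for genes that look significant
at the current stage.

LD is estimated from the study genotypes themselves (Pearson correlation
of minor-allele counts); the correlation matrix is repaired to the nearest
positive semidefinite matrix by eigenvalue clipping before Cholesky.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from micronet.association import bh_adjust

log = logging.getLogger(__name__)

DEFAULT_STAGES = (1_000, 10_000, 1_000_000)
DEFAULT_FLANK = 50_000
_TINY_P = float(np.nextafter(0, 1))


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    start: int  # half-open internal coordinates [start, end)
    end: int
    snp_ids: list[str]
    ld: np.ndarray  # pairwise genotype correlation, unit diagonal

    def __post_init__(self) -> None:
        k = len(self.snp_ids)
        if self.ld.shape != (k, k):
            raise ValueError(f"{self.gene_id}: LD matrix shape mismatch")


@dataclass
class GeneResult:
    gene_id: str
    n_snps: int
    statistic: float
    n_sims: int
    p: float
    q: float = np.nan


def build_gene_models(
    snp_map: pd.DataFrame,
    gene_table: pd.DataFrame,
    calls: pd.DataFrame,
    *,
    flank: int = DEFAULT_FLANK,
) -> tuple[dict[str, GeneModel], dict]:
    """Assign SNPs to flanked gene intervals and estimate per-gene LD.

    ``gene_table`` has 1-based inclusive start/end columns (converted
    internally to half-open); a SNP joins every gene whose flanked interval
    contains its position. Genes without SNPs are omitted and counted in
    the returned report. Duplicate gene ids are an error.
    """
    if gene_table["gene_id"].duplicated().any():
        dup = gene_table.loc[gene_table["gene_id"].duplicated(), "gene_id"].tolist()
        raise ValueError(f"duplicate gene ids in annotation: {dup[:5]}")
    usable = snp_map[snp_map["snp_id"].isin(calls.columns)]
    models: dict[str, GeneModel] = {}
    n_empty = 0
    for row in gene_table.itertuples(index=False):
        start = row.start - 1  # to half-open
        end = row.end
        sel = usable[
            (usable["chrom"] == row.chrom)
            & (usable["pos"] - 1 >= start - flank)
            & (usable["pos"] - 1 < end + flank)
        ]
        if sel.empty:
            n_empty += 1
            continue
        snp_ids = sel["snp_id"].tolist()
        g = calls[snp_ids].to_numpy(float)
        g[g < 0] = np.nan
        ld = pd.DataFrame(g).corr().to_numpy()
        # SNPs constant in-sample yield NaN correlations; treat as unlinked
        np.fill_diagonal(ld, 1.0)
        ld = np.nan_to_num(ld, nan=0.0)
        models[row.gene_id] = GeneModel(
            row.gene_id, row.chrom, start, end, snp_ids, ld
        )
    report = {"n_genes": len(gene_table), "n_with_snps": len(models),
              "n_without_snps": n_empty}
    return models, report


def gene_statistic(pvals: np.ndarray | list) -> float:
    """T = sum of upper-tail chi-square(1) quantiles of the SNP p-values."""
    p = np.asarray(pvals, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    if (p == 0).any():
        log.warning("p=0 input clamped to smallest positive float")
        p = np.where(p == 0, _TINY_P, p)
    return float(stats.chi2.isf(p, df=1).sum())


def _psd_repair(r: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    """Nearest-PSD style repair: clip eigenvalues at eps, rescale diag to 1."""
    if np.isnan(r).any():
        raise ValueError("LD matrix contains NaN")
    r = (r + r.T) / 2.0
    w, v = np.linalg.eigh(r)
    if w.min() >= eps:
        return r
    w = np.clip(w, eps, None)
    fixed = (v * w) @ v.T
    d = np.sqrt(np.diag(fixed))
    return fixed / np.outer(d, d)


def gene_pvalue(
    statistic: float,
    ld: np.ndarray,
    *,
    stages: tuple[int, ...] = DEFAULT_STAGES,
    seed: int | np.random.SeedSequence = 0,
    gene_id: str = "?",
) -> tuple[float, int]:
    """Monte-Carlo gene p-value under the MVN(0, R) null.

    Runs the stage sizes in order, escalating while the current estimate
    satisfies p < 10 / n_sims (i.e. fewer than ~10 exceedances observed);
    returns (p, n_sims_used). Simulation is chunked so the largest stage
    stays memory-bounded.
    """
    try:
        r = _psd_repair(np.atleast_2d(np.asarray(ld, dtype=float)))
    except ValueError as exc:
        raise ValueError(f"gene {gene_id}: unusable LD matrix ({exc})") from exc
    chol = np.linalg.cholesky(r)
    k = r.shape[0]
    rng = np.random.default_rng(seed)

    p = 1.0
    used = 0
    for n_sims in stages:
        exceed = 0
        done = 0
        while done < n_sims:
            chunk = min(n_sims - done, 200_000)
            z = rng.standard_normal((chunk, k)) @ chol.T
            null = np.einsum("ij,ij->i", z, z)
            exceed += int((null >= statistic).sum())
            done += chunk
        p = (1 + exceed) / (1 + n_sims)
        used = n_sims
        if p >= 10.0 / n_sims:
            break
    return float(p), used


def run_gene_scan(
    snp_results: pd.DataFrame,
    models: dict[str, GeneModel],
    *,
    stages: tuple[int, ...] = DEFAULT_STAGES,
    seed: int = 0,
) -> pd.DataFrame:
    """Gene p-values for every model with >=1 tested SNP, BH-adjusted.

    ``snp_results`` is the genome-scan table indexed by SNP id with a
    nominal ``p`` column. Each gene gets an independent child seed so
    results do not depend on gene iteration order.
    """
    root = np.random.SeedSequence(seed)
    gene_ids = sorted(models)
    children = dict(zip(gene_ids, root.spawn(len(gene_ids))))
    rows = []
    pv = snp_results["p"]
    for gid in gene_ids:
        model = models[gid]
        keep = [i for i, s in enumerate(model.snp_ids)
                if s in pv.index and np.isfinite(pv[s])]
        if not keep:
            continue
        snp_p = pv[[model.snp_ids[i] for i in keep]].to_numpy()
        ld = model.ld[np.ix_(keep, keep)]
        t = gene_statistic(snp_p)
        p, used = gene_pvalue(t, ld, stages=stages, seed=children[gid], gene_id=gid)
        rows.append((gid, len(keep), t, used, p))
    out = pd.DataFrame(
        rows, columns=["gene_id", "n_snps", "statistic", "n_sims", "p"]
    ).set_index("gene_id")
    out["q"] = bh_adjust(out["p"])
    return out
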