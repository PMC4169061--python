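"""Hypergeometric overrepresentation analyses.

Three families of tests share one primitive, the exact hypergeometric
upper tail P(X >= k):

* module enrichment — are phenotype-associated genes (or any gene set)
  overrepresented in a topological module? One test per module, BH over
  the modules, significance at q < 0.1.
* the dual "micronutrient system" criterion — modules significant in both
  the statistical-hit analysis and the micronutrient-neighborhood
  analysis.
* QTL-window enrichment — per QTL phenotype, the genes within 1 Mbp of
  its intervals form a set; are the study's significant genes
  overrepresented there? BH over phenotypes, significance at q < 0.15.

BH families are always per-analysis, never pooled across analyses. The
universe for module tests defaults to the genes of the network's largest
connected component, since the modules partition exactly that set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import gammaln

from micronet.association import bh_adjust

log = logging.getLogger(__name__)

MODULE_Q_THRESHOLD = 0.1
QTL_Q_THRESHOLD = 0.15
QTL_WINDOW = 1_000_000


@dataclass
class GeneSet:
    name: str
    members: frozenset
    provenance: str = "gmt"  # met_pc1 | neighborhood | gmt | qtl_phenotype

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.name!r} is empty")


def hypergeom_upper(N: int, K: int, n: int, k: int) -> float:
    """Exact upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    N: universe size, K: marked genes, n: sample (unit) size, k: observed
    marked in the sample. Summation is done in log space over the
    admissible support, so small tails keep full relative precision.
    """
    if not (0 <= k <= min(n, K) <= N) or n > N or K > N or min(N, K, n, k) < 0:
        raise ValueError(f"invalid hypergeometric bounds N={N} K={K} n={n} k={k}")
    if k == 0:
        return 1.0
    hi = min(n, K)
    j = np.arange(k, hi + 1)
    log_terms = (
        gammaln(K + 1) - gammaln(j + 1) - gammaln(K - j + 1)
        + gammaln(N - K + 1) - gammaln(n - j + 1) - gammaln(N - K - n + j + 1)
        - (gammaln(N + 1) - gammaln(n + 1) - gammaln(N - n + 1))
    )
    top = log_terms.max()
    return float(min(1.0, np.exp(top) * np.exp(log_terms - top).sum()))


def module_enrichment(
    partition,
    gene_set: GeneSet | set,
    universe: set,
    *,
    q_threshold: float = MODULE_Q_THRESHOLD,
) -> pd.DataFrame:
    """One hypergeometric test per module against the given universe.

    Gene-set members outside the universe are dropped (and counted in the
    log); returns a per-module table with expected/observed hits, p, q and
    the significance flag at the stated q threshold.
    """
    members = gene_set.members if isinstance(gene_set, GeneSet) else frozenset(gene_set)
    hits = members & universe
    dropped = len(members) - len(hits)
    if dropped:
        log.info("%d gene-set member(s) outside the universe dropped", dropped)
    if not hits:
        log.warning("gene set has empty intersection with the universe; all p=1")
    N = len(universe)
    K = len(hits)
    rows = []
    assignment = partition.assignment if hasattr(partition, "assignment") else partition
    module_ids = sorted(set(assignment.values()))
    for mid in module_ids:
        module_genes = {g for g, m in assignment.items() if m == mid} & universe
        n = len(module_genes)
        k = len(module_genes & hits)
        p = hypergeom_upper(N, K, n, k) if n else 1.0
        rows.append((mid, n, n * K / N if N else 0.0, k, p))
    out = pd.DataFrame(
        rows, columns=["module", "size", "expected", "observed", "p"]
    ).set_index("module")
    out["q"] = bh_adjust(out["p"])
    out["significant"] = out["q"] < q_threshold
    return out


def micronutrient_system_flag(
    results_hits: pd.DataFrame, results_neighborhood: pd.DataFrame
) -> list:
    """Modules significant (q < threshold) in BOTH enrichment analyses.

    Both tables must come from the same partition (identical module index).
    """
    if not results_hits.index.equals(results_neighborhood.index):
        raise ValueError("enrichment results use different module partitions")
    both = results_hits["significant"] & results_neighborhood["significant"]
    return sorted(results_hits.index[both])


def qtl_gene_sets(
    gene_table: pd.DataFrame,
    qtl_table: pd.DataFrame,
    *,
    window: int = QTL_WINDOW,
) -> dict[str, GeneSet]:
    """Per-phenotype sets of genes within `window` bp of any QTL interval.

    Both tables carry 1-based inclusive coordinates in memory; a gene is
    in the set iff its interval intersects the QTL interval expanded by
    the window on both sides. Phenotypes whose expanded intervals catch no
    gene are dropped with a warning.
    """
    sets: dict[str, GeneSet] = {}
    for pheno, grp in qtl_table.groupby("phenotype"):
        members = set()
        for q in grp.itertuples(index=False):
            lo = q.start - window
            hi = q.end + window
            sel = gene_table[
                (gene_table["chrom"] == q.chrom)
                & (gene_table["end"] >= lo)
                & (gene_table["start"] <= hi)
            ]
            members.update(sel["gene_id"])
        if not members:
            log.warning("QTL phenotype %r catches no genes; dropped", pheno)
            continue
        sets[pheno] = GeneSet(pheno, frozenset(members), provenance="qtl_phenotype")
    return sets


def qtl_enrichment(
    significant_genes: set,
    qtl_sets: dict[str, GeneSet],
    universe: set,
    *,
    q_threshold: float = QTL_Q_THRESHOLD,
) -> pd.DataFrame:
    """Hypergeometric enrichment of the significant genes in each QTL
    phenotype's window set; BH over phenotypes, flag at q < 0.15."""
    hits = set(significant_genes) & universe
    N = len(universe)
    K = len(hits)
    rows = []
    for pheno in sorted(qtl_sets):
        unit = set(qtl_sets[pheno].members) & universe
        n = len(unit)
        k = len(unit & hits)
        p = hypergeom_upper(N, K, n, k) if n else 1.0
        rows.append((pheno, n, n * K / N if N else 0.0, k, p))
    out = pd.DataFrame(
        rows, columns=["phenotype", "size", "expected", "observed", "p"]
    ).set_index("phenotype")
    out["q"] = bh_adjust(out["p"])
    out["significant"] = out["q"] < q_threshold
    return out


def read_gmt(path: str | Path) -> dict[str, GeneSet]:
    """GMT gene-set file: name <tab> description <tab> member genes..."""
    sets = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        name, _desc, *genes = fields
        sets[name] = GeneSet(name, frozenset(g for g in genes if g), provenance="gmt")
    return sets
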