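"""Readers for the pipeline's plain-text input formats.

Files use field conventions: BED-like gene/QTL files are 0-based
half-open; in memory all coordinates are 1-based inclusive (converted
here, once). Genotype calls are a subjects x SNPs TSV with -1 for
missing; per-call quality scores travel in a parallel TSV.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd


def read_genotypes(path: str | Path) -> pd.DataFrame:
    calls = pd.read_csv(path, sep="\t", index_col=0)
    calls.index.name = "subject_id"
    bad = ~calls.isin([-1, 0, 1, 2]).all(axis=0)
    if bad.any():
        raise ValueError(f"non {{0,1,2,-1}} calls in columns: "
                         f"{list(calls.columns[bad])[:5]}")
    return calls.astype(np.int8)


def read_quality(path: str | Path) -> pd.DataFrame:
    q = pd.read_csv(path, sep="\t", index_col=0)
    q.index.name = "subject_id"
    return q.astype(float)


def read_snp_map(path: str | Path) -> pd.DataFrame:
    m = pd.read_csv(path, sep="\t")
    required = {"snp_id", "chrom", "pos"}
    if not required <= set(m.columns):
        raise ValueError(f"SNP map needs columns {sorted(required)}")
    if m["snp_id"].duplicated().any():
        raise ValueError("duplicate SNP ids in map")
    if (m["pos"] <= 0).any():
        raise ValueError("SNP positions must be positive (1-based)")
    return m


def read_gene_bed(path: str | Path) -> pd.DataFrame:
    bed = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "gene_id"],
        usecols=range(4),
    )
    bed["start"] = bed["start"] + 1  # BED 0-based half-open -> 1-based inclusive
    return bed[["gene_id", "chrom", "start", "end"]]


def read_qtl_bed(path: str | Path) -> pd.DataFrame:
    bed = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "phenotype", "source_id"],
    )
    bed["start"] = bed["start"] + 1
    return bed[["phenotype", "chrom", "start", "end", "source_id"]]


def read_covariates(path: str | Path) -> pd.DataFrame:
    cov = pd.read_csv(path).set_index("subject_id")
    required = {"age", "sex", "hei", "family_id"}
    if not required <= set(cov.columns):
        raise ValueError(f"covariates need columns {sorted(required)}")
    return cov


def read_metabolites(path: str | Path) -> pd.DataFrame:
    """Long (subject_id, assessment, metabolite, value) or wide
    (subject_id + one column per metabolite); dialect by header."""
    df = pd.read_csv(path)
    if {"metabolite", "value"} <= set(df.columns):
        return df
    long = df.melt(id_vars="subject_id", var_name="metabolite", value_name="value")
    long["assessment"] = 1
    return long


def read_proteins(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)


def read_gene_list(path: str | Path) -> list[str]:
    return [
        line.strip()
        for line in Path(path).read_text().splitlines()
        if line.strip() and not line.startswith("#")
    ]
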