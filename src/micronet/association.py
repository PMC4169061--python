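"""Per-SNP association of the latent phenotype with genotype.

The model is a Gaussian GEE with identity link and an independence working
correlation over sibling (family) clusters. Under that working correlation
the point estimates coincide with ordinary least squares; inference uses
the cluster-robust (sandwich) covariance aggregated over families, with a
Wald z test of the genotype coefficient against the standard normal (the
usual GEE convention — a documented small-sample liberality).

The genome scan evaluates all SNPs in one vectorised pass (shared
covariates are residualised once; per-SNP bread/meat matrices are built as
batched arrays), which makes Monte-Carlo calibration and permutation
oracles cheap. ``fit_gee_snp`` exposes the same estimator for a single SNP.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)


@dataclass
class SnpAssocResult:
    snp_id: str
    coding: str
    beta: float
    se: float
    z: float
    p: float
    n: int
    se_type: str = "sandwich"


def bh_adjust(p: np.ndarray | pd.Series | list) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    q_(i) = min_{j>=i} m * p_(j) / j, capped at 1, mapped back to input
    order. NaNs propagate and are excluded from the family size m.
    """
    arr = np.asarray(p, dtype=float)
    out = np.full(arr.shape, np.nan)
    ok = ~np.isnan(arr)
    pv = arr[ok]
    if ((pv < 0) | (pv > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(adj, 1.0)
    out[ok] = q
    return out


def _design(covariates: pd.DataFrame) -> np.ndarray:
    """Intercept + age + sex + diet-quality score, in fixed column order."""
    return np.column_stack(
        [
            np.ones(len(covariates)),
            covariates["age"].to_numpy(float),
            covariates["sex"].to_numpy(float),
            covariates["hei"].to_numpy(float),
        ]
    )


def _cluster_codes(covariates: pd.DataFrame) -> np.ndarray:
    return pd.factorize(covariates["family_id"])[0]


def fit_gee_snp(
    phenotype: pd.Series,
    genotype: pd.Series,
    covariates: pd.DataFrame,
    *,
    coding: str = "additive",
) -> SnpAssocResult:
    """Fit one SNP; complete cases across phenotype/genotype/covariates.

    coding="additive" tests the minor-allele count; coding="categorical"
    fits genotype-class indicators and reports a 2-df Wald chi-square p
    (beta/se/z refer to the heterozygote contrast).
    """
    df = pd.concat(
        [phenotype.rename("y"), genotype.rename("g"), covariates], axis=1, join="inner"
    ).dropna()
    df = df[df["g"] >= 0]
    y = df["y"].to_numpy(float)
    x0 = _design(df)
    clusters = _cluster_codes(df)
    g = df["g"].to_numpy(float)

    if np.ptp(g) == 0:
        log.warning("SNP %s constant after QC; association undefined", genotype.name)
        return SnpAssocResult(str(genotype.name), coding, np.nan, np.nan, np.nan,
                              np.nan, len(df))

    if coding == "additive":
        gx = g[:, None]
    elif coding == "categorical":
        cols = [np.where(g == lvl, 1.0, 0.0) for lvl in (1, 2) if (g == lvl).any()]
        gx = np.column_stack(cols)
    else:
        raise ValueError(f"unknown coding {coding!r}")

    x = np.hstack([x0, gx])
    beta_hat, cov, se_type = _ols_sandwich(y, x, clusters)
    k = gx.shape[1]
    b = beta_hat[-k:]
    v = cov[-k:, -k:]
    if coding == "additive" or k == 1:
        se = float(np.sqrt(v[0, 0]))
        z = float(b[0] / se)
        p = float(2 * stats.norm.sf(abs(z)))
        return SnpAssocResult(str(genotype.name), coding, float(b[0]), se, z, p,
                              len(df), se_type)
    w = float(b @ np.linalg.solve(v, b))
    p = float(stats.chi2.sf(w, df=k))
    se = float(np.sqrt(v[0, 0]))
    return SnpAssocResult(str(genotype.name), coding, float(b[0]), se,
                          float(b[0] / se), p, len(df), se_type)


def _ols_sandwich(y: np.ndarray, x: np.ndarray, clusters: np.ndarray):
    """OLS point estimate with cluster-robust covariance.

    With fewer than 2 clusters the sandwich is undefined; fall back to the
    classical model-based covariance with a warning.
    """
    xtx_inv = np.linalg.inv(x.T @ x)
    beta = xtx_inv @ (x.T @ y)
    resid = y - x @ beta
    n_clusters = len(np.unique(clusters))
    if n_clusters < 2:
        log.warning("fewer than 2 clusters; using classical (model-based) SE")
        sigma2 = resid @ resid / (len(y) - x.shape[1])
        return beta, sigma2 * xtx_inv, "classical"
    meat = np.zeros((x.shape[1], x.shape[1]))
    for c in np.unique(clusters):
        s = x[clusters == c].T @ resid[clusters == c]
        meat += np.outer(s, s)
    return beta, xtx_inv @ meat @ xtx_inv, "sandwich"


def run_genome_scan(
    phenotype: pd.Series,
    calls: pd.DataFrame,
    covariates: pd.DataFrame,
    *,
    coding: str = "additive",
) -> pd.DataFrame:
    """Additive GEE scan over every SNP column, BH-adjusted.

    Output is indexed by SNP id with columns beta, se, z, p, p_bh, n;
    results do not depend on SNP or subject ordering. The categorical
    coding falls back to the per-SNP fit.
    """
    common = phenotype.dropna().index.intersection(covariates.dropna().index)
    common = common.intersection(calls.index).sort_values()
    if calls.shape[1] == 0:
        return pd.DataFrame(
            columns=["beta", "se", "z", "p", "p_bh", "n"], index=pd.Index([], name="snp_id")
        )
    if coding != "additive":
        res = [
            fit_gee_snp(phenotype, calls[c], covariates, coding=coding)
            for c in calls.columns
        ]
        out = pd.DataFrame(
            {
                "beta": [r.beta for r in res],
                "se": [r.se for r in res],
                "z": [r.z for r in res],
                "p": [r.p for r in res],
                "n": [r.n for r in res],
            },
            index=pd.Index(calls.columns, name="snp_id"),
        )
        out["p_bh"] = bh_adjust(out["p"])
        return out[["beta", "se", "z", "p", "p_bh", "n"]]

    y = phenotype.loc[common].to_numpy(float)
    cov = covariates.loc[common]
    x0 = _design(cov)
    clusters = _cluster_codes(cov)
    g = calls.loc[common].to_numpy(float)
    g[g < 0] = np.nan  # missing calls: scans run on QC'd data, but be safe
    if np.isnan(g).any():
        col_mean = np.nanmean(g, axis=0)
        g = np.where(np.isnan(g), col_mean, g)

    beta, se, z, p, se_type = _scan_sandwich(y, x0, g, clusters)
    out = pd.DataFrame(
        {"beta": beta, "se": se, "z": z, "p": p, "p_bh": bh_adjust(p), "n": len(y)},
        index=pd.Index(calls.columns, name="snp_id"),
    )
    return out


def _scan_sandwich(y, x0, g, clusters):
    """Vectorised OLS + cluster sandwich for many single-SNP models sharing
    the covariate block x0. Returns per-SNP beta, se, z, p for the genotype
    coefficient."""
    n, p0 = x0.shape
    m = g.shape[1]
    const = np.ptp(g, axis=0) == 0

    xtx0 = x0.T @ x0
    xtx0_inv = np.linalg.inv(xtx0)
    x0g = x0.T @ g  # p0 x m
    gg = np.einsum("ij,ij->j", g, g)

    # full-model coefficients via block inversion:
    # beta_g = (g'M0 g)^-1 g'M0 y with M0 the covariate annihilator
    g_r = g - x0 @ (xtx0_inv @ x0g)
    y_r = y - x0 @ (xtx0_inv @ (x0.T @ y))
    grg = np.einsum("ij,ij->j", g_r, g_r)
    grg_safe = np.where(const, 1.0, grg)
    beta_g = (g_r.T @ y_r) / grg_safe
    beta_cov = xtx0_inv @ (x0.T @ y)[:, None] - (xtx0_inv @ x0g) * beta_g[None, :]

    resid = (y[:, None] - x0 @ beta_cov) - g * beta_g[None, :]  # n x m

    codes, uniq = pd.factorize(clusters)
    n_clusters = len(uniq)
    p = p0 + 1
    order = np.argsort(codes, kind="stable")
    starts = np.searchsorted(codes[order], np.arange(n_clusters))

    # per-cluster score vectors s_cj = [x0_c' e_cj ; g_cj' e_cj]
    s0 = np.stack(
        [
            np.add.reduceat((x0[:, a][:, None] * resid)[order], starts, axis=0)
            for a in range(p0)
        ],
        axis=1,
    )  # n_clusters x p0 x m
    sg = np.add.reduceat((g * resid)[order], starts, axis=0)  # n_clusters x m

    s = np.concatenate([s0, sg[:, None, :]], axis=1)  # n_clusters x p x m
    meat = np.einsum("cam,cbm->mab", s, s)  # m x p x p

    # bread: inv of [[xtx0, x0g_j], [x0g_j', gg_j]] per SNP, batched; constant
    # SNPs get a placeholder identity-like block (results are NaN'd below)
    x0g_safe = np.where(const[None, :], 0.0, x0g)
    bread = np.empty((m, p, p))
    bread[:, :p0, :p0] = xtx0
    bread[:, :p0, p0] = x0g_safe.T
    bread[:, p0, :p0] = x0g_safe.T
    bread[:, p0, p0] = np.where(const, 1.0, gg)
    if n_clusters < 2:
        dof = n - p
        sigma2 = np.einsum("ij,ij->j", resid, resid) / dof
        binv = np.linalg.inv(bread)
        var_g = sigma2 * binv[:, p0, p0]
        se_type = "classical"
    else:
        binv = np.linalg.inv(bread)
        cov_full = binv @ meat @ binv
        var_g = cov_full[:, p0, p0]
        se_type = "sandwich"

    se = np.sqrt(np.maximum(var_g, 0.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        z = beta_g / se
    pvals = 2 * stats.norm.sf(np.abs(z))
    beta_g = np.where(const, np.nan, beta_g)
    se = np.where(const, np.nan, se)
    z = np.where(const, np.nan, z)
    pvals = np.where(const, np.nan, pvals)
    if const.any():
        log.warning("%d constant SNP(s) in scan; p set to NaN", int(const.sum()))
    return beta_g, se, z, pvals, se_type
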