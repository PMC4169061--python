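"""Metabolite averaging, PCA phenotype (met_PC1/met_PC2), heatmap ordering.

Repeated blood assessments are averaged per subject before any modelling;
principal components of the (column-standardized) averaged panel provide
the latent quantitative phenotypes. Component 1 ("met_PC1") is
sign-anchored on a named metabolite so its direction is stable across
runs and column orders.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

log = logging.getLogger(__name__)

DEFAULT_ANCHOR = "vitamin_E"


@dataclass
class MetPC:
    """PCA decomposition of the averaged metabolite panel.

    scores:        subjects x components (centered)
    loadings:      metabolites x components, each column unit-norm
    variance_frac: fraction of total variance per component (sums to 1)
    anchor:        metabolite whose loading on component 1 is kept >= 0
    """

    scores: pd.DataFrame
    loadings: pd.DataFrame
    variance_frac: pd.Series
    anchor: str

    @property
    def pc1(self) -> pd.Series:
        return self.scores["PC1"]


def average_assessments(panel: pd.DataFrame) -> pd.DataFrame:
    """Per-subject mean over available assessments -> subjects x metabolites.

    `panel` is long format with columns subject_id, assessment, metabolite,
    value. Missing values are ignored in the mean; a subject missing a
    metabolite in every assessment gets NaN there. Subjects with no data at
    all are dropped with a warning.
    """
    required = {"subject_id", "metabolite", "value"}
    if not required <= set(panel.columns):
        raise ValueError(f"panel must have columns {sorted(required)}")
    wide = panel.pivot_table(
        index="subject_id", columns="metabolite", values="value", aggfunc="mean"
    ).reindex(pd.unique(panel["subject_id"])).sort_index()
    empty = wide.index[wide.isna().all(axis=1)]
    if len(empty):
        log.warning("dropping %d subject(s) with no assessments: %s",
                    len(empty), list(empty))
        wide = wide.drop(index=empty)
    wide.columns.name = None
    return wide


def compute_met_pc(
    matrix: pd.DataFrame,
    *,
    standardize: bool = True,
    anchor: str = DEFAULT_ANCHOR,
) -> MetPC:
    """PCA of the averaged panel; complete-case over subjects.

    Metabolites are on incommensurable assay units, so columns are z-scored
    by default (PCA of the correlation matrix). Subjects with any missing
    metabolite are excluded rather than imputed — with cohorts this small,
    imputation would inject untracked structure.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 metabolite columns")
    data = matrix.dropna(axis=0, how="any")
    if data.shape[0] < 2:
        raise ValueError("fewer than 2 complete-case subjects")
    x = data.to_numpy(dtype=float)
    x = x - x.mean(axis=0)
    if standardize:
        sd = x.std(axis=0, ddof=1)
        dead = data.columns[sd == 0]
        if len(dead):
            raise ValueError(
                f"constant metabolite column(s) under standardization: {list(dead)}"
            )
        x = x / sd

    # SVD of the centered/scaled matrix == eigendecomposition of covariance
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    n_comp = len(s)
    names = [f"PC{i + 1}" for i in range(n_comp)]
    var = s**2
    variance_frac = pd.Series(var / var.sum(), index=names, name="variance_frac")
    loadings = pd.DataFrame(vt.T, index=data.columns, columns=names)
    scores = pd.DataFrame(u * s, index=data.index, columns=names)

    # deterministic orientation: anchor metabolite loads >= 0 on PC1; the
    # remaining components are signed by their largest-magnitude loading
    if anchor not in loadings.index:
        raise ValueError(f"anchor metabolite {anchor!r} not in panel")
    for j, name in enumerate(names):
        if name == "PC1":
            sign = 1.0 if loadings.loc[anchor, name] >= 0 else -1.0
        else:
            lead = loadings[name].abs().idxmax()
            sign = 1.0 if loadings.loc[lead, name] >= 0 else -1.0
        loadings[name] *= sign
        scores[name] *= sign
    return MetPC(scores=scores, loadings=loadings,
                 variance_frac=variance_frac, anchor=anchor)


def cluster_heatmap_order(
    matrix: pd.DataFrame,
) -> tuple[list, list, np.ndarray | None, np.ndarray | None]:
    """Average-linkage leaf orders for a subject x metabolite heatmap.

    Values are z-scored per column, distances are Euclidean. Returns
    (row_order, col_order, row_linkage, col_linkage); degenerate axes
    (fewer than 2 rows, or a single column) fall back to identity / value
    ordering with a None linkage.
    """
    data = matrix.dropna(axis=0, how="any")
    x = data.to_numpy(dtype=float)
    sd = x.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    z = (x - x.mean(axis=0)) / sd

    if data.shape[1] == 1:
        row_order = list(data.index[np.argsort(x[:, 0], kind="stable")])
        return row_order, list(data.columns), None, None
    if data.shape[0] < 2:
        return list(data.index), list(data.columns), None, None

    row_link = hierarchy.average(pdist(z))
    col_link = hierarchy.average(pdist(z.T))
    row_order = [data.index[i] for i in hierarchy.leaves_list(row_link)]
    col_order = [data.columns[i] for i in hierarchy.leaves_list(col_link)]
    return row_order, col_order, row_link, col_link
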