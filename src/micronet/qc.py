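"""Genotype quality control.

Four SNP filters applied in fixed order — call quality, completeness,
minor-allele frequency, exact Hardy-Weinberg — each SNP attributed to the
first filter that removes it, so the removal counts plus survivors always
partition the input.

The Hardy-Weinberg test is the exact conditional test: given the observed
allele counts, the probability of each admissible heterozygote count is
computed and the p-value sums the probabilities of outcomes no more likely
than the observed one (two-sided). An exact test is used because the
cohorts of interest are far too small for the chi-square approximation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

log = logging.getLogger(__name__)

FILTER_ORDER = ("quality", "completeness", "maf", "hwe")


@dataclass
class QcReport:
    n_input: int
    removed: dict[str, int] = field(default_factory=dict)
    n_surviving: int = 0
    snp_stats: pd.DataFrame | None = None  # per surviving SNP: maf, hwe_p

    def check_partition(self) -> bool:
        return sum(self.removed.values()) + self.n_surviving == self.n_input

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "removed": dict(self.removed),
            "n_surviving": self.n_surviving,
        }


# ---------------------------------------------------------------------------
# individual filters


def filter_quality(
    calls: pd.DataFrame,
    quality: pd.DataFrame,
    threshold: float = 0.7,
    *,
    mode: str = "any",
) -> pd.DataFrame:
    """Drop SNPs with low per-call quality (GC-score style, in [0,1]).

    mode="any" (default) removes a SNP if any present call falls below the
    threshold — the strictest reading; mode="mean" keys on the mean score
    over present calls.
    """
    q = quality.reindex(index=calls.index, columns=calls.columns)
    if mode == "any":
        bad = (q < threshold).any(axis=0)
    elif mode == "mean":
        bad = q.mean(axis=0, skipna=True) < threshold
    else:
        raise ValueError(f"unknown quality mode {mode!r}")
    return calls.loc[:, ~bad.to_numpy()]


def filter_completeness(calls: pd.DataFrame) -> pd.DataFrame:
    """Keep only SNPs genotyped in every subject (no missing calls)."""
    missing_subjects = calls.index[(calls < 0).all(axis=1)]
    if len(missing_subjects):
        log.warning(
            "subject(s) with no calls at any SNP: %s — every SNP will fail "
            "completeness", list(missing_subjects)
        )
    complete = (calls >= 0).all(axis=0)
    return calls.loc[:, complete.to_numpy()]


def compute_maf(calls: np.ndarray | pd.Series) -> float:
    """Minor allele frequency from complete 0/1/2 calls."""
    c = np.asarray(calls)
    if c.size == 0:
        raise ValueError("no calls")
    if (c < 0).any():
        raise ValueError("missing calls present; run completeness filter first")
    f = c.sum() / (2 * c.size)
    return float(min(f, 1.0 - f))


def filter_maf(calls: pd.DataFrame, threshold: float = 0.1) -> tuple[pd.DataFrame, pd.Series]:
    c = calls.to_numpy()
    f = c.sum(axis=0) / (2 * c.shape[0])
    maf = np.minimum(f, 1.0 - f)
    keep = maf >= threshold
    return calls.loc[:, keep], pd.Series(maf, index=calls.columns, name="maf")


def _hwe_het_probs(n: int, n_minor: int):
    """Probabilities of every admissible heterozygote count given allele
    counts (Levene/Haldane conditional distribution), in log space."""
    n_major = 2 * n - n_minor
    hets = np.arange(n_minor % 2, min(n_minor, n_major) + 1, 2)
    n_aa = (n_minor - hets) // 2
    n_AA = n - n_aa - hets
    logp = (
        gammaln(n + 1)
        - gammaln(n_AA + 1)
        - gammaln(hets + 1)
        - gammaln(n_aa + 1)
        + hets * np.log(2)
        + gammaln(n_minor + 1)
        + gammaln(n_major + 1)
        - gammaln(2 * n + 1)
    )
    return hets, np.exp(logp - logp.max()), logp


def hwe_exact_test(n_hom_major: int, n_het: int, n_hom_minor: int) -> float:
    """Exact two-sided Hardy-Weinberg p-value for one SNP.

    Conditions on the observed allele counts and sums the conditional
    probabilities of all heterozygote counts whose probability does not
    exceed the observed count's. Monomorphic SNPs return p=1.
    """
    if min(n_hom_major, n_het, n_hom_minor) < 0:
        raise ValueError("genotype counts must be nonnegative")
    n = n_hom_major + n_het + n_hom_minor
    if n == 0:
        raise ValueError("no genotypes")
    n_minor = 2 * n_hom_minor + n_het
    if n_minor == 0 or n_minor == 2 * n:
        return 1.0
    if n_minor > n:  # orient to the rarer allele
        n_minor = 2 * n - n_minor
    hets, rel, _ = _hwe_het_probs(n, n_minor)
    obs = rel[np.flatnonzero(hets == n_het)[0]]
    # tolerance guards ties against floating-point noise
    p = rel[rel <= obs * (1 + 1e-12)].sum() / rel.sum()
    return float(min(p, 1.0))


def filter_hwe(calls: pd.DataFrame, alpha: float = 0.001) -> tuple[pd.DataFrame, pd.Series]:
    c = calls.to_numpy()
    pvals = np.empty(c.shape[1])
    for j in range(c.shape[1]):
        col = c[:, j]
        pvals[j] = hwe_exact_test(
            int((col == 0).sum()), int((col == 1).sum()), int((col == 2).sum())
        )
    p = pd.Series(pvals, index=calls.columns, name="hwe_p")
    keep = p >= alpha
    return calls.loc[:, keep.to_numpy()], p


# ---------------------------------------------------------------------------
# pipeline


def run_qc(
    calls: pd.DataFrame,
    quality: pd.DataFrame,
    *,
    quality_threshold: float = 0.7,
    quality_mode: str = "any",
    maf_threshold: float = 0.1,
    hwe_alpha: float = 0.001,
) -> tuple[pd.DataFrame, QcReport]:
    """Apply the four filters in order; returns surviving calls + report."""
    report = QcReport(n_input=calls.shape[1])

    step = filter_quality(calls, quality, quality_threshold, mode=quality_mode)
    report.removed["quality"] = calls.shape[1] - step.shape[1]

    prev = step
    step = filter_completeness(prev)
    report.removed["completeness"] = prev.shape[1] - step.shape[1]

    prev = step
    step, maf = filter_maf(prev, maf_threshold)
    report.removed["maf"] = prev.shape[1] - step.shape[1]

    prev = step
    step, hwe_p = filter_hwe(prev, hwe_alpha)
    report.removed["hwe"] = prev.shape[1] - step.shape[1]

    report.n_surviving = step.shape[1]
    report.snp_stats = pd.DataFrame(
        {"maf": maf.reindex(step.columns), "hwe_p": hwe_p.reindex(step.columns)}
    )
    assert report.check_partition()
    return step, report
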