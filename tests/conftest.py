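"""Shared fixtures: one reference synthetic cohort per session, plus a
small fast cohort for pipeline-level tests."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from micronet.metabolites import average_assessments, compute_met_pc
from micronet.qc import run_qc
from micronet.simulate import SimConfig, simulate_study


@pytest.fixture(scope="session")
def study():
    """Reference cohort at the default study conditions (seed 7)."""
    return simulate_study(SimConfig(seed=7))


@pytest.fixture(scope="session")
def qc_calls(study):
    calls, _ = run_qc(study.calls, study.quality)
    return calls


@pytest.fixture(scope="session")
def met_pc(study):
    return compute_met_pc(average_assessments(study.metabolites))


@pytest.fixture(scope="session")
def small_config():
    """Reduced cohort for fast pipeline and oracle tests."""
    return SimConfig(
        n_subjects=100,
        n_families=65,
        n_genes=200,
        snps_per_gene=5,
        n_modules=5,
        n_causal_genes=6,
        causal_module_ids=(2,),
        n_neighborhood=40,
        n_proteins=60,
        n_signal_proteins=8,
        n_qtl_phenotypes=4,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return simulate_study(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def make_covariates(n: int, families: list[str] | None = None,
                    seed: int = 0) -> pd.DataFrame:
    """Minimal covariate table for hand-built association tests."""
    r = np.random.default_rng(seed)
    if families is None:
        families = [f"f{i}" for i in range(n)]  # singleton clusters
    return pd.DataFrame(
        {
            "age": r.uniform(6, 14, n),
            "sex": r.integers(0, 2, n),
            "hei": r.normal(55, 10, n),
            "family_id": families,
        },
        index=pd.Index([f"s{i:03d}" for i in range(n)], name="subject_id"),
    )
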