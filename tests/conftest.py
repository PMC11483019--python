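import logging

import numpy as np
import pandas as pd
import pytest

import bilestate as bs
from bilestate import qc

logging.getLogger("bilestate").setLevel(logging.WARNING)


def segment_for(n_genes: int, chrom_index: int, fold: float, length: int | None = None):
    """A CNV segment tuple covering (part of) one autosome for ``n_genes``."""
    sizes = [len(b) for b in np.array_split(np.arange(n_genes), 22)]
    start = int(sum(sizes[:chrom_index]))
    span = sizes[chrom_index] if length is None else min(length, sizes[chrom_index])
    return (f"chr{chrom_index + 1}", start, start + span, fold)


@pytest.fixture(scope="session")
def small_cohort():
    """A modest mixed cohort with planted CNVs, reused across read-only tests."""
    cfg = bs.CohortConfig(
        n_samples=6,
        n_patients=3,
        cells_per_sample=200,
        n_genes=600,
        n_programs=5,
        malignant_fraction=0.4,
        seed=42,
        cnv_segments=[segment_for(600, 0, 2.0), segment_for(600, 4, 0.5)],
    )
    adata, truth = bs.generate_cohort(cfg)
    return cfg, adata, truth


@pytest.fixture(scope="session")
def small_normalized(small_cohort):
    """Filtered + log-normalized view of the small cohort with truth aligned."""
    _, adata, truth = small_cohort
    filtered, _ = qc.filter_matrix(adata)
    norm = qc.normalize_log(filtered)
    return norm, truth


@pytest.fixture(scope="session")
def stromal_cohort():
    """Non-malignant-only cohort: five silhouette-separable lineages."""
    cfg = bs.CohortConfig(
        n_samples=4,
        n_patients=2,
        cells_per_sample=250,
        n_genes=500,
        n_programs=2,
        malignant_fraction=0.0,
        seed=7,
    )
    adata, truth = bs.generate_cohort(cfg)
    return cfg, adata, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def dense(adata):
    X = adata.X
    return np.asarray(X.todense()) if hasattr(X, "todense") else np.asarray(X)


def sample_meta_frame(obs: pd.DataFrame) -> pd.DataFrame:
    return obs[["sample", "patient", "timepoint"]].drop_duplicates().set_index("sample")
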