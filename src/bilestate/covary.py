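"""Cross-sample covariation of gene programs with a permutation null.

Program activity is aggregated per sample at an upper percentile (default
90th for display, 75th for significance), each program over its own cell
type only (tumor programs over tumor cells, T programs over T cells, ...).
Pairwise Pearson correlation of the sample x program matrix columns gives a
program x program correlation matrix, ordered by average-linkage
hierarchical clustering on Euclidean distance. Significance comes from
shuffling the cells' sample assignments (within cell-type strata),
recomputing percentiles and correlations, and counting how often the null
correlation exceeds the observed one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

logger = logging.getLogger(__name__)

PERCENTILES = (25, 50, 75, 90, 95)


@dataclass
class CovariationResult:
    correlation: dict[int, pd.DataFrame]  # percentile -> programs x programs
    linkage: np.ndarray | None
    dendrogram_order: list[str]
    pvalues: pd.DataFrame
    n_iterations: int
    significance_percentile: int
    seed: int


def percentile_matrix(
    scores: pd.DataFrame,
    sample_labels: pd.Series,
    cell_types: pd.Series,
    program_types: dict[str, str | None],
    percentile: float = 90,
    min_cells: int = 10,
) -> pd.DataFrame:
    """Per-sample upper-percentile program activity (linear interpolation).

    ``program_types`` maps each program column to the cell type its score is
    aggregated over (``None`` = all cells). Samples with fewer than
    ``min_cells`` cells of a program's type get a missing entry.
    """
    if not 0 < percentile < 100:
        raise ValueError(f"percentile must lie in (0, 100), got {percentile}")
    missing = [p for p in scores.columns if p not in program_types]
    if missing:
        raise ValueError(f"programs without a declared cell-type restriction: {missing}")
    labels = sample_labels.reindex(scores.index)
    ctypes = cell_types.reindex(scores.index)
    samples = pd.unique(labels.dropna())
    out = pd.DataFrame(index=pd.Index(samples, name="sample"), columns=scores.columns, dtype=float)
    for prog in scores.columns:
        restrict = program_types[prog]
        mask = np.ones(len(scores), dtype=bool) if restrict is None else (ctypes == restrict).to_numpy()
        vals = scores[prog].to_numpy()
        labs = labels.to_numpy()
        for s in samples:
            sel = mask & (labs == s)
            if sel.sum() < min_cells:
                continue
            out.loc[s, prog] = np.percentile(vals[sel], percentile, method="linear")
    return out


def program_correlations(
    matrix: pd.DataFrame, min_samples: int = 3
) -> tuple[pd.DataFrame, np.ndarray | None, list[str]]:
    """Pairwise-complete Pearson correlation + average-linkage ordering.

    Zero-variance columns get missing correlations and are excluded from
    the clustering. Pairs with fewer than ``min_samples`` complete samples
    are missing.
    """
    corr = matrix.corr(method="pearson", min_periods=min_samples)
    const = matrix.std(ddof=0) == 0
    if const.any():
        logger.warning(
            "programs %s have zero variance across samples; correlations missing",
            list(matrix.columns[const]),
        )
        corr.loc[const, :] = np.nan
        corr.loc[:, const] = np.nan
    usable = corr.index[corr.notna().sum(axis=1) > 1]
    linkage = None
    order = list(matrix.columns)
    if len(usable) >= 2:
        rows = corr.loc[usable, usable].fillna(0.0).to_numpy()
        linkage = hierarchy.linkage(rows, method="average", metric="euclidean")
        leaves = hierarchy.leaves_list(linkage)
        order = list(usable[leaves]) + [c for c in matrix.columns if c not in set(usable)]
    return corr, linkage, order


def _shuffle_labels(
    sample_labels: pd.Series, cell_types: pd.Series, rng: np.random.Generator, stratify: bool
) -> pd.Series:
    labs = sample_labels.to_numpy().copy()
    if stratify:
        for t in pd.unique(cell_types):
            idx = np.flatnonzero((cell_types == t).to_numpy())
            labs[idx] = labs[rng.permutation(idx)]
    else:
        labs = labs[rng.permutation(len(labs))]
    return pd.Series(labs, index=sample_labels.index)


def permutation_pvalues(
    scores: pd.DataFrame,
    sample_labels: pd.Series,
    cell_types: pd.Series,
    program_types: dict[str, str | None],
    n_iterations: int = 1000,
    percentile: float = 75,
    seed: int = 0,
    min_cells: int = 10,
    stratify: bool = True,
    add_one_smoothing: bool = False,
) -> pd.DataFrame:
    """One-sided permutation p-values for each program pair's correlation.

    ``p = #(null correlation > observed) / n_iterations`` — an estimator
    that can return exactly 0; ``add_one_smoothing`` switches to
    ``(count + 1) / (n + 1)``. Shuffles are exact permutations of the
    sample-label vector (within cell-type strata when ``stratify``), so
    per-sample cell counts are preserved.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    rng = np.random.default_rng(seed)
    observed = percentile_matrix(
        scores, sample_labels, cell_types, program_types, percentile, min_cells
    )
    obs_corr = observed.corr(method="pearson", min_periods=3)
    exceed = pd.DataFrame(0, index=obs_corr.index, columns=obs_corr.columns, dtype=float)
    for _ in range(n_iterations):
        perm = _shuffle_labels(sample_labels, cell_types, rng, stratify)
        pm = percentile_matrix(scores, perm, cell_types, program_types, percentile, min_cells)
        null_corr = pm.corr(method="pearson", min_periods=3)
        exceed += (null_corr > obs_corr).astype(float)
    if add_one_smoothing:
        pvals = (exceed + 1.0) / (n_iterations + 1.0)
    else:
        pvals = exceed / n_iterations
    pvals = pvals.where(obs_corr.notna())
    np_diag = np.arange(len(pvals))
    pvals.values[np_diag, np_diag] = np.nan
    return pvals


def run_covariation(
    scores: pd.DataFrame,
    sample_labels: pd.Series,
    cell_types: pd.Series,
    program_types: dict[str, str | None],
    percentiles: tuple[int, ...] = PERCENTILES,
    significance_percentile: int = 75,
    n_iterations: int = 1000,
    seed: int = 0,
    min_cells: int = 10,
) -> CovariationResult:
    """Percentile matrices at every display percentile + p-values at one."""
    corrs: dict[int, pd.DataFrame] = {}
    linkage = None
    order: list[str] = list(scores.columns)
    for q in percentiles:
        pm = percentile_matrix(scores, sample_labels, cell_types, program_types, q, min_cells)
        c, lk, od = program_correlations(pm)
        corrs[q] = c
        if q == significance_percentile:
            linkage, order = lk, od
    pvals = permutation_pvalues(
        scores, sample_labels, cell_types, program_types,
        n_iterations=n_iterations, percentile=significance_percentile,
        seed=seed, min_cells=min_cells,
    )
    return CovariationResult(
        correlation=corrs,
        linkage=linkage,
        dendrogram_order=order,
        pvalues=pvals,
        n_iterations=n_iterations,
        significance_percentile=significance_percentile,
        seed=seed,
    )
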