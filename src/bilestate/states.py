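"""Gene-set scoring and malignant cell-state classification.

Malignant biliary-tract-cancer cells are classified into five states —
classical (epithelial/adhesive: TSPAN8, TFF1, EPCAM, CDH1), basal
(keratin-high: KRT7/KRT19/KRT6A), mesenchymal (collagen-high:
COL3A1/COL6A2/COL1A1), neural-like (GLIS3, ZBTB20) and endothelial-like
(vessel-development genes, MMP7-high) — plus "intermediate" for cells with
co-activity of the mesenchymal and neural-like programs. State activity is
either a normalized cNMF usage or a binned-control gene-set score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse

from .exceptions import ConfigError

logger = logging.getLogger(__name__)

STATE_NAMES = ("classical", "basal", "mesenchymal", "neural-like", "endothelial-like")
INTERMEDIATE = "intermediate"


@dataclass
class StateDefinition:
    name: str
    gene_set: list[str]
    source: str = "cnmf_top_genes"  # or "external_gmt"


def _expr_frame(expression) -> pd.DataFrame:
    if isinstance(expression, ad.AnnData):
        X = expression.X
        X = np.asarray(X.todense()) if sparse.issparse(X) else np.asarray(X)
        return pd.DataFrame(X, index=expression.obs_names, columns=expression.var_names)
    return pd.DataFrame(expression)


def sample_bin_controls(
    gene_means: pd.Series,
    gene_set: list[str],
    n_control_bins: int = 25,
    n_control_per_gene: int = 50,
    seed: int = 0,
) -> list[str]:
    """Control genes matched to the set's expression levels.

    Genes are split into ``n_control_bins`` equal-frequency bins of mean
    expression; for every set gene, ``n_control_per_gene`` genes are drawn
    (with multiplicity) from its bin.
    """
    rng = np.random.default_rng(seed)
    ranks = gene_means.rank(method="first")
    bins = pd.qcut(ranks, q=min(n_control_bins, len(gene_means)), labels=False, duplicates="drop")
    controls: list[str] = []
    for g in gene_set:
        pool = gene_means.index[bins == bins.loc[g]]
        take = rng.choice(len(pool), size=n_control_per_gene, replace=len(pool) < n_control_per_gene)
        controls.extend(pool[take])
    return controls


def score_gene_set(
    expression,
    gene_set: list[str],
    n_control_bins: int = 25,
    n_control_per_gene: int = 50,
    seed: int = 0,
) -> pd.Series:
    """Mean set expression minus mean of expression-matched control genes."""
    E = _expr_frame(expression)
    present = [g for g in gene_set if g in E.columns]
    missing = [g for g in gene_set if g not in E.columns]
    if not present:
        raise KeyError(f"no gene of the set is measured; missing: {missing}")
    if missing:
        logger.warning("%d set genes not measured (e.g. %s)", len(missing), missing[0])
    controls = sample_bin_controls(
        E.mean(axis=0), present, n_control_bins, n_control_per_gene, seed
    )
    score = E[present].mean(axis=1) - E[controls].mean(axis=1)
    score.name = "score"
    return score


def top_program_genes(
    spectra: pd.DataFrame, n: int = 50
) -> dict[str, list[str]]:
    """The ``n`` highest-weight genes per program, ties broken by gene order."""
    if n > spectra.shape[1]:
        logger.warning("n=%d exceeds %d genes; returning all", n, spectra.shape[1])
        n = spectra.shape[1]
    out = {}
    for name, row in spectra.iterrows():
        order = np.argsort(-row.to_numpy(), kind="stable")[:n]
        out[name] = list(spectra.columns[order])
    return out


def assign_tumor_states(
    activities: pd.DataFrame,
    intermediate_rule: tuple[tuple[str, str], float] = (("mesenchymal", "neural-like"), 0.25),
    normalize: bool = True,
) -> pd.DataFrame:
    """Call one state per (malignant) cell from per-state activities.

    ``activities`` has one column per state in :data:`STATE_NAMES` (cNMF
    usages or gene-set scores). When ``normalize`` is set, activities are
    clipped at zero and row-normalized to sum 1. A cell whose two
    ``intermediate_rule`` states both reach the rule's threshold is called
    ``intermediate``; every other cell gets the argmax state with
    lexicographic tie-break. The margin (top minus second activity) is 0 on
    exact ties.
    """
    missing = [s for s in STATE_NAMES if s not in activities.columns]
    if missing:
        raise ConfigError(f"missing state activity columns: {missing}")
    act = activities[list(STATE_NAMES)].astype(float)
    if normalize:
        act = act.clip(lower=0.0)
        rowsum = act.sum(axis=1)
        act = act.div(rowsum.where(rowsum > 0, 1.0), axis=0)
    ordered = act[sorted(act.columns)]
    arr = ordered.to_numpy()
    top_idx = arr.argmax(axis=1)
    state = np.asarray(ordered.columns)[top_idx].astype(object)
    srt = np.sort(arr, axis=1)
    margin = srt[:, -1] - srt[:, -2]
    (pair, thr) = intermediate_rule
    a, b = pair
    if a not in act.columns or b not in act.columns:
        raise ConfigError(f"intermediate rule names unknown states: {pair}")
    inter = (act[a] >= thr) & (act[b] >= thr)
    state[inter.to_numpy()] = INTERMEDIATE
    out = act.copy()
    out.insert(0, "state", state)
    out["margin"] = margin
    return out


def map_programs_to_reference(
    discovered_scores: pd.DataFrame, reference_scores: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson correlation of discovered vs reference per-cell program scores.

    Both score sets must cover the same cells. Zero-variance score vectors
    yield missing correlations. Returns (correlation matrix, best-match
    table with the top reference program per discovered program).
    """
    if not discovered_scores.index.equals(reference_scores.index):
        raise ValueError("score sets must be computed on the same cells")
    D = discovered_scores.astype(float)
    R = reference_scores.astype(float)
    corr = pd.DataFrame(index=D.columns, columns=R.columns, dtype=float)
    for dc in D.columns:
        for rc in R.columns:
            x, y = D[dc], R[rc]
            if x.std(ddof=0) == 0 or y.std(ddof=0) == 0:
                corr.loc[dc, rc] = np.nan
            else:
                corr.loc[dc, rc] = x.corr(y)
    best = pd.DataFrame(index=corr.index, columns=["best_reference", "correlation"])
    valid = corr.notna().any(axis=1)
    if valid.any():
        best.loc[valid, "best_reference"] = corr.loc[valid].idxmax(axis=1)
        best.loc[valid, "correlation"] = corr.loc[valid].max(axis=1)
    return corr, best
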