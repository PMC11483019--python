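"""Consensus non-negative matrix factorization of gene expression programs.

Expression is modeled as a nonnegative combination of gene expression
programs: ``X ~ U @ S`` with usages ``U`` (cells x k) and spectra ``S``
(k x genes), both nonnegative. Single factorizations are unstable across
restarts, so the consensus procedure pools the spectra of many restarts,
filters outlier components by local density, clusters the survivors into k
groups, takes elementwise medians as consensus spectra, and refits usages
by nonnegative least squares. The mean silhouette of the component
clustering ("stability") and the refit Frobenius error, tabulated over a
grid of k, drive rank selection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment, nnls
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .exceptions import EmptyResultError, InvalidRankError

logger = logging.getLogger(__name__)


@dataclass
class PreparedMatrix:
    """Nonnegative HVG-subset matrix scaled to unit per-gene variance."""

    matrix: np.ndarray  # cells x genes, nonnegative
    genes: pd.Index
    cells: pd.Index
    gene_scale: np.ndarray  # the 1/std factors applied per gene


@dataclass
class FactorizationRun:
    k: int
    seed: int
    spectra: np.ndarray  # k x genes, rows L2-normalized
    usages: np.ndarray  # cells x k, rescaled to preserve the product
    reconstruction_error: float
    objective_history: list[float] = field(default_factory=list)


@dataclass
class ProgramDecomposition:
    k: int
    consensus_spectra: pd.DataFrame  # programs x genes, rows L2-normalized
    usages: pd.DataFrame  # cells x programs, unit row sums
    raw_usages: pd.DataFrame  # cells x programs, NNLS scale
    component_kept: np.ndarray  # bool per pooled run component
    component_labels: np.ndarray  # cluster label per kept component
    stability: float
    error: float


def prepare_matrix(expression, n_hvg: int = 2000) -> PreparedMatrix:
    """HVG subset of log-normalized expression, variance-scaled, no centering.

    Genes are ranked by binned normalized dispersion and the top ``n_hvg``
    kept; each retained gene is divided by its standard deviation so values
    stay nonnegative. Zero-variance genes are dropped.
    """
    import anndata as ad
    from scipy import sparse

    from .qc import binned_normalized_dispersion

    if isinstance(expression, ad.AnnData):
        X = expression.X
        genes = expression.var_names
        cells = expression.obs_names
    else:
        X = np.asarray(expression)
        genes = pd.RangeIndex(X.shape[1]).astype(str)
        cells = pd.RangeIndex(X.shape[0]).astype(str)
    X = np.asarray(X.todense()) if sparse.issparse(X) else np.asarray(X, dtype=float)
    disp = binned_normalized_dispersion(X)
    disp.index = pd.Index(genes)
    if n_hvg > len(genes):
        logger.warning("n_hvg=%d exceeds %d available genes; using all", n_hvg, len(genes))
        n_hvg = len(genes)
    ranked = disp["normalized_dispersion"].fillna(-np.inf).sort_values(
        ascending=False, kind="stable"
    )
    hvg = ranked.index[:n_hvg]
    mask = pd.Index(genes).isin(hvg)
    sub = X[:, mask]
    kept_genes = pd.Index(genes)[mask]
    std = sub.std(axis=0, ddof=1)
    nonzero = std > 0
    if (~nonzero).any():
        logger.info("dropping %d zero-variance genes before factorization", int((~nonzero).sum()))
    sub = sub[:, nonzero] / std[nonzero]
    return PreparedMatrix(
        matrix=sub,
        genes=kept_genes[nonzero],
        cells=pd.Index(cells),
        gene_scale=1.0 / std[nonzero],
    )


def factorize_once(
    matrix: np.ndarray,
    k: int,
    seed: int = 0,
    max_iter: int = 200,
    tol: float = 1e-4,
    check_every: int = 10,
) -> FactorizationRun:
    """One NMF restart by multiplicative updates with Frobenius loss.

    The objective ``||X - U S||_F`` is recorded every ``check_every``
    iterations and is non-increasing; iteration stops when the relative
    improvement between checks drops below ``tol`` or at ``max_iter``.
    """
    X = np.asarray(matrix, dtype=float)
    if k >= min(X.shape):
        raise InvalidRankError(f"k={k} must be below min(matrix shape)={min(X.shape)}")
    if (X < 0).any():
        raise ValueError("matrix must be nonnegative")
    rng = np.random.default_rng(seed)
    scale = np.sqrt(X.mean() / k) if X.mean() > 0 else 1.0
    U = rng.uniform(1e-3, 1.0, size=(X.shape[0], k)) * scale
    S = rng.uniform(1e-3, 1.0, size=(k, X.shape[1])) * scale
    eps = 1e-12
    history: list[float] = []
    prev = None
    for it in range(1, max_iter + 1):
        S *= (U.T @ X) / (U.T @ U @ S + eps)
        U *= (X @ S.T) / (U @ (S @ S.T) + eps)
        if it % check_every == 0 or it == max_iter:
            err = float(np.linalg.norm(X - U @ S))
            history.append(err)
            if prev is not None and prev - err < tol * max(prev, eps):
                break
            prev = err
    norms = np.linalg.norm(S, axis=1)
    norms[norms == 0] = 1.0
    return FactorizationRun(
        k=k,
        seed=seed,
        spectra=S / norms[:, None],
        usages=U * norms[None, :],
        reconstruction_error=history[-1],
        objective_history=history,
    )


def _refit_usages(X: np.ndarray, spectra: np.ndarray) -> np.ndarray:
    """Per-cell nonnegative least squares against fixed spectra."""
    ST = spectra.T
    out = np.empty((X.shape[0], spectra.shape[0]))
    for i in range(X.shape[0]):
        out[i], _ = nnls(ST, X[i])
    return out


def consensus_programs(
    matrix: np.ndarray,
    runs: list[FactorizationRun],
    density_threshold: float = 0.5,
    cells: pd.Index | None = None,
    genes: pd.Index | None = None,
) -> ProgramDecomposition:
    """Pool restart components into k consensus programs.

    Components are L2-normalized; each one's local density is its mean
    cosine distance to its ``n_runs - 1`` nearest neighbors, and components
    above ``density_threshold`` are discarded as outliers. Survivors are
    k-means clustered (k groups, seeded by the first run's seed); consensus
    spectra are per-cluster elementwise medians, renormalized; usages are
    refit by NNLS and row-normalized. Stability is the mean silhouette of
    the component clustering, error the Frobenius norm of the refit.
    """
    if len(runs) < 2:
        raise ValueError("consensus requires at least 2 factorization runs")
    ks = {r.k for r in runs}
    if len(ks) != 1:
        raise ValueError(f"all runs must share one k, got {sorted(ks)}")
    k = runs[0].k
    comps = np.vstack([r.spectra for r in runs])
    norms = np.linalg.norm(comps, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    comps = comps / norms
    # cosine distance matrix; mean distance to the (n_runs - 1) nearest others
    d = 1.0 - comps @ comps.T
    np.fill_diagonal(d, np.inf)
    n_neigh = len(runs) - 1
    part = np.partition(d, n_neigh - 1, axis=1)[:, :n_neigh]
    density = part.mean(axis=1)
    kept = density <= density_threshold
    if not kept.any():
        raise EmptyResultError(
            "density filter removed every component; raise density_threshold"
        )
    km = KMeans(n_clusters=k, n_init=10, random_state=runs[0].seed).fit(comps[kept])
    labels = km.labels_
    spectra = np.vstack(
        [np.median(comps[kept][labels == c], axis=0) for c in range(k)]
    )
    s_norm = np.linalg.norm(spectra, axis=1, keepdims=True)
    s_norm[s_norm == 0] = 1.0
    spectra /= s_norm
    if len(np.unique(labels)) > 1 and kept.sum() > k:
        stability = float(silhouette_score(comps[kept], labels, metric="euclidean"))
    else:
        stability = float("nan")
    X = np.asarray(matrix, dtype=float)
    raw_usages = _refit_usages(X, spectra)
    error = float(np.linalg.norm(X - raw_usages @ spectra))
    rowsum = raw_usages.sum(axis=1, keepdims=True)
    rowsum[rowsum == 0] = 1.0
    usages = raw_usages / rowsum
    cells = cells if cells is not None else pd.RangeIndex(X.shape[0]).astype(str)
    genes = genes if genes is not None else pd.RangeIndex(X.shape[1]).astype(str)
    prog_idx = pd.Index([f"usage_{i + 1}" for i in range(k)], name="program")
    return ProgramDecomposition(
        k=k,
        consensus_spectra=pd.DataFrame(spectra, index=prog_idx, columns=genes),
        usages=pd.DataFrame(usages, index=cells, columns=prog_idx),
        raw_usages=pd.DataFrame(raw_usages, index=cells, columns=prog_idx),
        component_kept=kept,
        component_labels=labels.copy(),
        stability=stability,
        error=error,
    )


def run_cnmf(
    matrix: np.ndarray,
    k: int,
    n_runs: int = 20,
    seed: int = 0,
    density_threshold: float = 0.5,
    max_iter: int = 200,
    tol: float = 1e-4,
    cells: pd.Index | None = None,
    genes: pd.Index | None = None,
) -> ProgramDecomposition:
    """``n_runs`` seeded restarts at rank ``k`` followed by the consensus step."""
    seeds = np.random.SeedSequence(seed).generate_state(n_runs) % (2**31)
    runs = [
        factorize_once(matrix, k, seed=int(s), max_iter=max_iter, tol=tol)
        for s in seeds
    ]
    return consensus_programs(
        matrix, runs, density_threshold=density_threshold, cells=cells, genes=genes
    )


def select_k(decompositions: list[ProgramDecomposition]) -> pd.DataFrame:
    """Stability/error diagnostics table over a grid of ranks.

    Rank choice stays with the user; :func:`suggest_k` applies the optional
    automatic rule (max stability with error within 10% of its minimum).
    """
    if len(decompositions) < 2:
        raise ValueError("k selection needs at least 2 evaluated ranks")
    rows = [
        {"k": d.k, "stability": d.stability, "error": d.error} for d in decompositions
    ]
    return pd.DataFrame(rows).sort_values("k").reset_index(drop=True)


def k_grid(k_min: int = 5, k_max: int = 101, k_step: int = 3) -> list[int]:
    """The rank grid used for program discovery (default 5..101 step 3)."""
    return list(range(k_min, k_max + 1, k_step))


def suggest_k(table: pd.DataFrame, error_slack: float = 0.10) -> int:
    """Max-stability rank among those with error within ``error_slack`` of min."""
    ok = table[table["error"] <= (1.0 + error_slack) * table["error"].min()]
    if ok.empty:
        ok = table
    return int(ok.loc[ok["stability"].idxmax(), "k"])


def plot_k_selection(table: pd.DataFrame, path: str) -> None:
    """Write the stability/error trade-off plot."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax1 = plt.subplots(figsize=(5, 3.5))
    ax1.plot(table["k"], table["stability"], "o-", color="tab:blue", label="stability")
    ax1.set_xlabel("k")
    ax1.set_ylabel("stability (silhouette)", color="tab:blue")
    ax2 = ax1.twinx()
    ax2.plot(table["k"], table["error"], "s--", color="tab:red", label="error")
    ax2.set_ylabel("reconstruction error", color="tab:red")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def match_programs(
    spectra_a: np.ndarray | pd.DataFrame, spectra_b: np.ndarray | pd.DataFrame
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Greedy-optimal 1:1 matching of two program sets by cosine similarity.

    Returns (rows of a, matched rows of b, cosine similarity per pair) from
    the assignment maximizing total cosine similarity.
    """
    A = np.asarray(spectra_a, dtype=float)
    B = np.asarray(spectra_b, dtype=float)
    An = A / np.maximum(np.linalg.norm(A, axis=1, keepdims=True), 1e-12)
    Bn = B / np.maximum(np.linalg.norm(B, axis=1, keepdims=True), 1e-12)
    sim = An @ Bn.T
    ri, ci = linear_sum_assignment(-sim)
    return ri, ci, sim[ri, ci]
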