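"""QC, normalization, feature selection, clustering and major-type annotation.

Default thresholds reproduce the study's processing: cells with fewer than
50 expressed genes, fewer than 200 total counts or more than 25%
mitochondrial counts are removed, then genes detected in fewer than 3
retained cells; counts are normalized to 1000 per cell and log1p
transformed; highly variable genes are selected by binned normalized
dispersion (mean in [0.0125, 3], normalized dispersion >= 0.5); the top 40
principal components feed a nearest-neighbor graph clustered with leiden at
resolution 0.5.
"""

from __future__ import annotations

import logging
import os
import warnings
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scanpy as sc
from scipy import io as spio
from scipy import sparse
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .exceptions import EmptyResultError, FormatError

logger = logging.getLogger(__name__)

MITO_PREFIX = "MT-"


@dataclass
class QCThresholds:
    min_genes_per_cell: int = 50
    min_counts_per_cell: int = 200
    max_mito_fraction: float = 0.25
    min_cells_per_gene: int = 3

    def __post_init__(self) -> None:
        for name in ("min_genes_per_cell", "min_counts_per_cell", "min_cells_per_gene"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.max_mito_fraction <= 1.0:
            raise ValueError("max_mito_fraction must lie in [0, 1]")


@dataclass
class FilterReport:
    """Cells/genes removed by each criterion (cells may fail several)."""

    n_cells_in: int
    n_genes_in: int
    cells_low_genes: int
    cells_low_counts: int
    cells_high_mito: int
    cells_removed: int
    genes_removed: int

    def as_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class EmbeddingResult:
    pca_coordinates: np.ndarray
    neighbor_graph: sparse.spmatrix
    cluster_labels: pd.Series
    umap_coordinates: np.ndarray | None = None


def _make_unique(symbols) -> pd.Index:
    seen: dict[str, int] = {}
    out = []
    for s in symbols:
        if s in seen:
            seen[s] += 1
            out.append(f"{s}-{seen[s]}")
        else:
            seen[s] = 0
            out.append(s)
    return pd.Index(out)


def read_counts(directory: str | os.PathLike, mito_prefix: str = MITO_PREFIX) -> ad.AnnData:
    """Read the 10x-style triplet layout written by ``synthetic.write_cohort``.

    ``matrix.mtx`` holds genes x cells; the result is cells x genes with the
    mitochondrial flag set from gene symbols starting with ``mito_prefix``.
    An optional ``cells.tsv`` sidecar is merged into ``obs``.
    """
    directory = os.fspath(directory)
    mtx = spio.mmread(os.path.join(directory, "matrix.mtx"))
    barcodes = pd.read_csv(
        os.path.join(directory, "barcodes.tsv"), sep="\t", header=None
    )[0].astype(str) if os.path.getsize(os.path.join(directory, "barcodes.tsv")) else pd.Series([], dtype=str)
    features = pd.read_csv(
        os.path.join(directory, "features.tsv"), sep="\t", header=None
    )
    feat_names = ["gene_id", "symbol", "chromosome", "start", "end"]
    if features.shape[1] < 2:
        raise FormatError("features.tsv needs at least gene id and symbol columns")
    features.columns = (feat_names + [f"extra_{i}" for i in range(features.shape[1])])[
        : features.shape[1]
    ]
    n_genes, n_cells = mtx.shape
    if len(features) != n_genes:
        raise FormatError(
            f"features.tsv has {len(features)} rows but matrix.mtx declares "
            f"{n_genes} genes"
        )
    if len(barcodes) != n_cells:
        raise FormatError(
            f"barcodes.tsv has {len(barcodes)} rows but matrix.mtx declares "
            f"{n_cells} cells"
        )
    symbols = features["symbol"].astype(str)
    if symbols.duplicated().any():
        dupes = symbols[symbols.duplicated()].unique()
        logger.warning(
            "features.tsv contains %d duplicated symbols (e.g. %s); "
            "disambiguating with numeric suffixes",
            len(dupes),
            dupes[0],
        )
        symbols = _make_unique(symbols)
    var = features.copy()
    var.index = pd.Index(symbols, name="gene")
    var["mito"] = var["symbol"].astype(str).str.startswith(mito_prefix)
    adata = ad.AnnData(
        X=sparse.csr_matrix(mtx.T.astype(np.int64)),
        obs=pd.DataFrame(index=pd.Index(barcodes, name="cell")),
        var=var,
    )
    cells_path = os.path.join(directory, "cells.tsv")
    if os.path.exists(cells_path):
        cells = pd.read_csv(cells_path, sep="\t", index_col=0)
        if not cells.index.astype(str).equals(pd.Index(barcodes).astype(str)):
            raise FormatError("cells.tsv barcodes do not match barcodes.tsv")
        for col in cells.columns:
            adata.obs[col] = cells[col].values
    return adata


def filter_matrix(
    counts: ad.AnnData, thresholds: QCThresholds | None = None
) -> tuple[ad.AnnData, FilterReport]:
    """Remove failing cells, then genes detected in too few retained cells."""
    thresholds = thresholds or QCThresholds()
    X = sparse.csr_matrix(counts.X)
    genes_per_cell = X.getnnz(axis=1)
    counts_per_cell = np.asarray(X.sum(axis=1)).ravel()
    mito = counts.var["mito"].to_numpy(dtype=bool)
    mito_counts = np.asarray(X[:, mito].sum(axis=1)).ravel() if mito.any() else np.zeros(X.shape[0])
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(counts_per_cell > 0, mito_counts / counts_per_cell, 0.0)

    low_genes = genes_per_cell < thresholds.min_genes_per_cell
    low_counts = counts_per_cell < thresholds.min_counts_per_cell
    high_mito = mito_frac > thresholds.max_mito_fraction
    keep_cells = ~(low_genes | low_counts | high_mito)
    if not keep_cells.any():
        raise EmptyResultError(
            "all cells fail the QC thresholds; review QCThresholds before rerunning"
        )
    retained = X[keep_cells]
    cells_per_gene = retained.getnnz(axis=0)
    keep_genes = cells_per_gene >= thresholds.min_cells_per_gene
    report = FilterReport(
        n_cells_in=X.shape[0],
        n_genes_in=X.shape[1],
        cells_low_genes=int(low_genes.sum()),
        cells_low_counts=int(low_counts.sum()),
        cells_high_mito=int(high_mito.sum()),
        cells_removed=int((~keep_cells).sum()),
        genes_removed=int((~keep_genes).sum()),
    )
    logger.info("QC filter: %s", report.as_dict())
    out = counts[keep_cells, keep_genes].copy()
    return out, report


def detect_doublets(
    counts: ad.AnnData,
    n_synthetic: int | None = None,
    k_neighbors: int = 30,
    threshold: float = 0.5,
    seed: int = 0,
    n_components: int = 30,
    sample_key: str = "sample",
) -> pd.Series:
    """Flag likely doublets per sample with a simulated-doublet kNN classifier.

    Within each sample, ``n_synthetic`` artificial doublets (sums of random
    cell pairs; default as many as there are cells) are embedded together
    with the real cells in PCA space of the log-normalized counts; a real
    cell is flagged when more than ``threshold`` of its ``k_neighbors``
    nearest neighbors are synthetic.
    """
    rng = np.random.default_rng(seed)
    flags = pd.Series(False, index=counts.obs_names, name="doublet")
    samples = (
        counts.obs[sample_key] if sample_key in counts.obs else pd.Series("all", index=counts.obs_names)
    )
    for s in pd.unique(samples):
        idx = np.flatnonzero((samples == s).to_numpy())
        n = idx.size
        if n < k_neighbors + 1:
            logger.warning("sample %s has %d cells < k_neighbors+1; flagging none", s, n)
            continue
        X = sparse.csr_matrix(counts.X)[idx].astype(float)
        n_syn = n if n_synthetic is None else int(n_synthetic)
        pairs = rng.integers(0, n, size=(n_syn, 2))
        synth = (X[pairs[:, 0]] + X[pairs[:, 1]]).tocsr()
        # thin each synthetic doublet to a real cell's depth so its sampling
        # noise matches the singlets it is compared against
        real_depth = np.asarray(X.sum(axis=1)).ravel()
        syn_depth = np.asarray(synth.sum(axis=1)).ravel()
        target = rng.choice(real_depth, size=n_syn)
        rate = np.minimum(1.0, target / np.maximum(syn_depth, 1.0))
        synth.data = rng.binomial(
            synth.data.astype(np.int64), np.repeat(rate, np.diff(synth.indptr))
        ).astype(float)
        combo = sparse.vstack([X, synth]).tocsr()
        totals = np.asarray(combo.sum(axis=1)).ravel()
        totals[totals == 0] = 1.0
        combo = combo.multiply(1000.0 / totals[:, None]).tocsr()
        combo.data = np.log1p(combo.data)
        n_comp = min(n_components, combo.shape[0] - 1, combo.shape[1] - 1)
        emb = PCA(n_components=n_comp, svd_solver="full", random_state=seed).fit_transform(
            np.asarray(combo.todense())
        )
        nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(emb)
        _, nbrs = nn.kneighbors(emb[:n])
        nbrs = nbrs[:, 1:]  # drop self
        synth_frac = (nbrs >= n).mean(axis=1)
        flags.iloc[idx] = synth_frac > threshold
    return flags


def normalize_log(counts: ad.AnnData, target_sum: float = 1000.0) -> ad.AnnData:
    """Scale each cell to ``target_sum`` total counts, then log1p.

    Raw counts are kept in ``layers['counts']``.
    """
    totals = np.asarray(sparse.csr_matrix(counts.X).sum(axis=1)).ravel()
    if (totals == 0).any():
        raise ValueError(
            f"{int((totals == 0).sum())} cells have zero total counts; "
            "filter before normalizing"
        )
    adata = counts.copy()
    adata.layers["counts"] = sparse.csr_matrix(adata.X).copy()
    adata.X = sparse.csr_matrix(adata.X, dtype=np.float64)
    sc.pp.normalize_total(adata, target_sum=target_sum)
    sc.pp.log1p(adata)
    return adata


def _dense(X) -> np.ndarray:
    return np.asarray(X.todense()) if sparse.issparse(X) else np.asarray(X)


def binned_normalized_dispersion(
    expression, n_bins: int = 20
) -> pd.DataFrame:
    """Per-gene mean / dispersion / normalized dispersion on log-normalized data.

    Means and dispersions (variance/mean) are computed on the de-logged
    values, means re-logged (log1p), and dispersions log-transformed; genes
    are then grouped into ``n_bins`` equal-frequency mean bins and each
    gene's dispersion standardized against its bin.
    """
    X = expression.X if isinstance(expression, ad.AnnData) else expression
    names = (
        expression.var_names
        if isinstance(expression, ad.AnnData)
        else pd.RangeIndex(X.shape[1])
    )
    E = np.expm1(_dense(X))
    mean = E.mean(axis=0)
    var = E.var(axis=0, ddof=1) if E.shape[0] > 1 else np.zeros(E.shape[1])
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / mean, np.nan)
    df = pd.DataFrame({"mean": np.log1p(mean)}, index=pd.Index(names, name="gene"))
    with np.errstate(divide="ignore"):
        df["dispersion"] = np.log(disp)
    finite = np.isfinite(df["dispersion"])
    try:
        bins = pd.qcut(df.loc[finite, "mean"], q=n_bins, duplicates="drop")
    except ValueError:  # too few distinct means for any binning
        bins = pd.Series("all", index=df.index[finite])
    grp = df.loc[finite, "dispersion"].groupby(bins, observed=True)
    bin_mean = grp.transform("mean")
    bin_std = grp.transform("std")
    small = grp.transform("size") < 2
    if small.any():
        logger.warning(
            "%d genes sit in dispersion bins with < 2 genes; their normalized "
            "dispersion is undefined and they are excluded",
            int(small.sum()),
        )
    norm = (df.loc[finite, "dispersion"] - bin_mean) / bin_std
    df["normalized_dispersion"] = norm
    return df


def select_hvg(
    expression,
    mean_min: float = 0.0125,
    mean_max: float = 3.0,
    min_dispersion: float = 0.5,
    n_bins: int = 20,
) -> pd.Index:
    """Highly variable genes by binned normalized dispersion."""
    df = binned_normalized_dispersion(expression, n_bins=n_bins)
    keep = (
        (df["mean"] >= mean_min)
        & (df["mean"] <= mean_max)
        & (df["normalized_dispersion"] >= min_dispersion)
    )
    return df.index[keep.fillna(False)]


def cluster_cells(
    expression: ad.AnnData,
    hvgs: pd.Index | list[str],
    n_components: int = 40,
    n_neighbors: int = 15,
    resolution: float = 0.5,
    seed: int = 0,
    compute_umap: bool = False,
    max_scale: float = 10.0,
) -> EmbeddingResult:
    """Scale-PCA-kNN-leiden on the HVG submatrix, deterministic under seed."""
    hvgs = pd.Index(hvgs)
    sub = expression[:, expression.var_names.isin(hvgs)].copy()
    cap = min(sub.n_obs - 1, sub.n_vars - 1)
    if n_components > cap:
        logger.warning("n_components=%d exceeds data rank; reduced to %d", n_components, cap)
        n_components = cap
    sc.pp.scale(sub, max_value=max_scale)
    sc.tl.pca(sub, n_comps=n_components, svd_solver="arpack", random_state=seed)
    sc.pp.neighbors(sub, n_neighbors=min(n_neighbors, sub.n_obs - 1), random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        sc.tl.leiden(sub, resolution=resolution, random_state=seed, key_added="leiden")
    umap = None
    if compute_umap:
        sc.tl.umap(sub, random_state=seed)
        umap = sub.obsm["X_umap"].copy()
    return EmbeddingResult(
        pca_coordinates=sub.obsm["X_pca"].copy(),
        neighbor_graph=sub.obsp["connectivities"].copy(),
        cluster_labels=pd.Series(
            sub.obs["leiden"].astype(str).values, index=expression.obs_names, name="cluster"
        ),
        umap_coordinates=umap,
    )


def annotate_major_types(
    expression: ad.AnnData,
    cluster_labels: pd.Series,
    marker_sets: dict[str, list[str]],
    seed: int = 0,
) -> pd.Series:
    """Assign each cluster the marker set with the highest mean cell score.

    Scores come from :func:`bilestate.states.score_gene_set`; ties between
    types break lexicographically. Cells inherit their cluster's label.
    """
    from .states import score_gene_set

    measured = set(expression.var_names)
    scores = {}
    for i, (name, genes) in enumerate(sorted(marker_sets.items())):
        present = [g for g in genes if g in measured]
        if not present:
            logger.warning("marker set %s has no measured genes; type excluded", name)
            continue
        scores[name] = score_gene_set(expression, present, seed=seed + i)
    if not scores:
        raise ValueError("no marker set overlaps the measured genes")
    score_df = pd.DataFrame(scores)  # columns already lexicographically sorted
    cluster_means = score_df.groupby(cluster_labels.values).mean()
    winner = cluster_means.idxmax(axis=1)  # first (lexicographic) max on ties
    ties = (cluster_means.eq(cluster_means.max(axis=1), axis=0)).sum(axis=1) > 1
    if ties.any():
        logger.warning(
            "clusters %s tie between types; broken lexicographically",
            list(cluster_means.index[ties]),
        )
    return pd.Series(
        winner.loc[cluster_labels.values].values, index=cluster_labels.index, name="cell_type"
    )
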