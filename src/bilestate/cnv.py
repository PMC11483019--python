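"""Expression-derived copy-number profiles and the malignancy score.

Copy-number state is inferred from expression alone: per-gene log-normalized
expression is centered against reference (non-malignant) cells, averaged in
genome-ordered windows within each chromosome, re-centered per cell and
clipped, giving a cells x regions profile. Per-cluster mean profiles are
discretized into states centered on neutral (0), and a cluster's malignancy
score is the sum of squared state values over regions — a flat (diploid-like)
cluster scores 0, and every aberrant region adds quadratically. Each cell
inherits its cluster's score, and malignant cells are called either by a
score threshold or from the upper component of a two-component mixture on
log1p scores.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse
from scipy.ndimage import median_filter
from sklearn.mixture import GaussianMixture

logger = logging.getLogger(__name__)

#: centered values of the default discrete state set (neutral = 0)
DEFAULT_STATE_VALUES = (-2.0, -1.0, -0.5, 0.0, 0.5, 1.0, 2.0)


def _chrom_key(chrom: str):
    m = re.match(r"chr(\d+)$", str(chrom))
    return (0, int(m.group(1))) if m else (1, str(chrom))


def genome_ordering(var: pd.DataFrame) -> pd.DataFrame:
    """Order genes by (chromosome, start) with 0-based half-open coordinates.

    ``var`` needs ``chromosome``, ``start`` and ``end`` columns; the index
    names the genes. Each gene appears exactly once.
    """
    if var.index.duplicated().any():
        raise ValueError("gene ordering requires unique gene names")
    order = sorted(
        range(len(var)),
        key=lambda i: (_chrom_key(var["chromosome"].iloc[i]), int(var["start"].iloc[i])),
    )
    out = var.iloc[order][["chromosome", "start", "end"]].copy()
    return out


@dataclass
class CNVResult:
    profile: pd.DataFrame  # cells x regions, centered
    regions: pd.DataFrame  # region -> chromosome, first/last gene
    region_states: pd.DataFrame  # clusters x regions, centered state values
    cluster_scores: pd.Series
    cell_scores: pd.Series
    malignant_call: pd.Series
    reference_types: list[str]


def _region_slices(ordering: pd.DataFrame, window: int) -> list[tuple[str, np.ndarray]]:
    """Non-overlapping windows of ``window`` genes within each chromosome.

    The trailing remainder merges into the last full window; a chromosome
    shorter than ``window`` becomes a single whole-chromosome region.
    """
    slices = []
    for chrom in ordering["chromosome"].unique():
        idx = np.flatnonzero((ordering["chromosome"] == chrom).to_numpy())
        if idx.size < window:
            logger.warning(
                "chromosome %s has %d genes < window %d; using one region",
                chrom, idx.size, window,
            )
            slices.append((chrom, idx))
            continue
        n_full = idx.size // window
        for j in range(n_full):
            lo = j * window
            hi = (j + 1) * window if j < n_full - 1 else idx.size
            slices.append((chrom, idx[lo:hi]))
    return slices


def _soft_threshold(prof: np.ndarray, ref_mask: np.ndarray, sd: float) -> np.ndarray:
    """Shrink each region value by ``sd`` reference standard deviations."""
    band = sd * prof[ref_mask].std(axis=0, ddof=1)
    return np.sign(prof) * np.maximum(np.abs(prof) - band, 0.0)


def denoise_profile(
    profile: pd.DataFrame, reference_mask: pd.Series | np.ndarray, sd: float = 1.5
) -> pd.DataFrame:
    """Soft-threshold a profile by the reference cells' per-region noise band.

    Intended for per-cell display and per-cell statistics; cluster-level
    aggregation averages the same noise away without biasing amplitudes, so
    discretization runs on the raw profile.
    """
    mask = np.asarray(reference_mask, dtype=bool)
    vals = _soft_threshold(profile.to_numpy(), mask, sd)
    return pd.DataFrame(vals, index=profile.index, columns=profile.columns)


def cnv_profile(
    expression: ad.AnnData,
    ordering: pd.DataFrame,
    reference_types: list[str],
    cell_types: pd.Series,
    window: int = 51,
    expression_cutoff: float = 0.1,
    clip: float = 1.0,
    median_filter_width: int = 5,
    denoise_sd: float = 1.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Windowed reference-centered expression profile per cell.

    ``expression`` is log-normalized; the cutoff applies to the mean of the
    de-logged (normalized, pre-log) values as advised for droplet data.
    Deviations are soft-thresholded by ``denoise_sd`` reference standard
    deviations per region, so reference cells read as flat and only shifts
    beyond their noise band survive. Returns (profile cells x regions,
    region table).
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    ref_mask = cell_types.reindex(expression.obs_names).isin(reference_types).to_numpy()
    if not ref_mask.any():
        raise ValueError(f"no cells of reference types {reference_types} present")
    common = [g for g in ordering.index if g in set(expression.var_names)]
    sub = expression[:, common]
    X = np.asarray(sub.X.todense()) if sparse.issparse(sub.X) else np.asarray(sub.X)
    mean_norm = np.expm1(X).mean(axis=0)
    keep = mean_norm >= expression_cutoff
    X = X[:, keep]
    ord_kept = ordering.loc[np.asarray(common)[keep]]
    # center against reference cells, gene by gene
    X = X - X[ref_mask].mean(axis=0)
    slices = _region_slices(ord_kept, window)
    prof = np.column_stack([X[:, idx].mean(axis=1) for _, idx in slices])
    prof = prof - np.median(prof, axis=1, keepdims=True)
    prof = np.clip(prof, -clip, clip)
    if median_filter_width and median_filter_width > 1:
        # smooth along regions within each chromosome
        chroms = np.array([c for c, _ in slices])
        for chrom in pd.unique(chroms):
            cols = np.flatnonzero(chroms == chrom)
            if cols.size >= 3:
                prof[:, cols] = median_filter(
                    prof[:, cols], size=(1, min(median_filter_width, cols.size)), mode="nearest"
                )
    if denoise_sd and denoise_sd > 0:
        prof = _soft_threshold(prof, ref_mask, denoise_sd)
    regions = pd.DataFrame(
        {
            "chromosome": [c for c, _ in slices],
            "first_gene": [ord_kept.index[idx[0]] for _, idx in slices],
            "last_gene": [ord_kept.index[idx[-1]] for _, idx in slices],
            "n_genes": [idx.size for _, idx in slices],
        },
        index=pd.Index([f"region_{i + 1}" for i in range(len(slices))], name="region"),
    )
    profile = pd.DataFrame(prof, index=expression.obs_names, columns=regions.index)
    return profile, regions


def discretize_states(
    profile: pd.DataFrame,
    cluster_labels: pd.Series,
    gain_threshold: float = 0.15,
    state_values: tuple[float, ...] = DEFAULT_STATE_VALUES,
    min_cells: int = 3,
) -> pd.DataFrame:
    """Threshold per-cluster mean profiles into centered discrete states.

    The per-region cluster mean ``m`` maps to the largest state value ``v``
    (by magnitude, matching ``m``'s sign) whose activation level
    ``|v| * gain_threshold / 0.5`` is reached, so with the default set a mean
    of ``+-gain_threshold`` is the first (half) gain/loss step. Clusters with
    fewer than ``min_cells`` cells are set all-neutral.
    """
    values = np.asarray(sorted(state_values))
    if 0.0 not in values:
        raise ValueError("state_values must contain the neutral state 0")
    labels = cluster_labels.reindex(profile.index)
    out = {}
    pos_levels = values[values > 0]
    neg_levels = values[values < 0]
    for cl, idx in profile.groupby(labels, observed=True).groups.items():
        if len(idx) < min_cells:
            logger.warning("cluster %s has %d cells < %d; all-neutral states", cl, len(idx), min_cells)
            out[cl] = np.zeros(profile.shape[1])
            continue
        m = profile.loc[idx].mean(axis=0).to_numpy()
        states = np.zeros_like(m)
        for v in pos_levels:  # ascending: final state is the deepest reached
            states[m >= (v / pos_levels[0]) * gain_threshold] = v
        for v in neg_levels[::-1]:
            states[m <= (v / np.abs(neg_levels[-1])) * gain_threshold] = v
        out[cl] = states
    return pd.DataFrame(out, index=profile.columns).T.sort_index()


def malignancy_score(
    region_states: pd.DataFrame, cluster_labels: pd.Series
) -> tuple[pd.Series, pd.Series]:
    """Sum of squared centered region states per cluster, broadcast to cells."""
    cluster_scores = (region_states**2).sum(axis=1)
    cluster_scores.name = "cluster_score"
    cell_scores = pd.Series(
        cluster_scores.reindex(np.asarray(cluster_labels)).to_numpy(),
        index=cluster_labels.index,
        name="cell_score",
    )
    return cluster_scores, cell_scores


def call_malignant(
    cell_scores: pd.Series,
    method: str = "bimodal",
    threshold: float = 0.0,
    seed: int = 0,
) -> pd.Series:
    """Call malignant cells from their scores.

    ``threshold`` flags ``score > threshold``; ``bimodal`` fits a
    two-component Gaussian mixture on ``log1p(score)`` and flags the upper
    component, falling back to the threshold rule when the fit is degenerate.
    """
    scores = cell_scores.astype(float)
    if method == "threshold":
        call = scores > threshold
    elif method == "bimodal":
        x = np.log1p(scores.to_numpy()).reshape(-1, 1)
        if np.unique(x).size < 2:
            logger.warning("scores are constant; bimodal call falls back to threshold")
            call = scores > threshold
        else:
            gm = GaussianMixture(n_components=2, random_state=seed, n_init=3).fit(x)
            hi = int(np.argmax(gm.means_.ravel()))
            if (
                abs(np.diff(gm.means_.ravel())[0]) < 1e-6
                or gm.weights_.min() < 1e-3
            ):
                logger.warning("degenerate bimodal fit; falling back to threshold")
                call = scores > threshold
            else:
                call = pd.Series(gm.predict(x) == hi, index=scores.index)
    else:
        raise ValueError(f"unknown calling method {method!r}")
    call = call.astype(bool)
    call.name = "malignant"
    logger.info("malignant call: method=%s threshold=%s flagged=%d/%d", method, threshold, int(call.sum()), len(call))
    return call


def run_cnv(
    expression: ad.AnnData,
    cluster_labels: pd.Series,
    cell_types: pd.Series,
    reference_types: list[str],
    window: int = 51,
    expression_cutoff: float = 0.1,
    clip: float = 1.0,
    gain_threshold: float = 0.15,
    denoise_sd: float = 1.5,
    call_method: str = "bimodal",
    call_threshold: float = 0.0,
    seed: int = 0,
) -> CNVResult:
    """Profile, discretize, score and call in one pass.

    Discretization uses the raw (pre-denoising) profile: per-cluster means
    average out the per-cell noise the soft threshold targets, and shrinking
    them too would bias true shifts toward neutral. The stored per-cell
    profile is the denoised one.
    """
    ordering = genome_ordering(expression.var)
    raw, regions = cnv_profile(
        expression, ordering, reference_types, cell_types,
        window=window, expression_cutoff=expression_cutoff, clip=clip,
        denoise_sd=0.0,
    )
    ref_mask = cell_types.reindex(expression.obs_names).isin(reference_types).to_numpy()
    profile = denoise_profile(raw, ref_mask, sd=denoise_sd)
    states = discretize_states(raw, cluster_labels, gain_threshold=gain_threshold)
    cluster_scores, cell_scores = malignancy_score(states, cluster_labels)
    call = call_malignant(cell_scores, method=call_method, threshold=call_threshold, seed=seed)
    return CNVResult(
        profile=profile,
        regions=regions,
        region_states=states,
        cluster_scores=cluster_scores,
        cell_scores=cell_scores,
        malignant_call=call,
        reference_types=list(reference_types),
    )
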