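"""Ground-truthed synthetic tumor-biopsy cohorts.

The generator emulates the statistical structure a biliary-tract-cancer
biopsy cohort presents to the downstream pipeline: multiple samples with
patient and pre/on-treatment labels, a mixture of malignant cells and five
non-malignant lineages (T, myeloid, NK, endothelial, fibroblast), planted
low-rank gene-expression programs, chromosome-arm-scale expression shifts
in malignant cells, artificial doublets and per-cell mitochondrial-load
variation.

Every cell's expected expression is a depth-scaled nonnegative combination
``usage @ spectra`` of component programs: ``n_programs`` malignant gene
expression programs (GEPs) plus one identity program per non-malignant
lineage. Counts are Poisson around that rate, or gamma-Poisson (negative
binomial) when ``program_overdispersion > 0``.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Sequence

import anndata as ad
import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .exceptions import ConfigError

logger = logging.getLogger(__name__)

NONMALIGNANT_TYPES = ("T", "myeloid", "NK", "endothelial", "fibroblast")
#: relative frequencies of the non-malignant lineages within a sample
_TYPE_WEIGHTS = (0.35, 0.30, 0.10, 0.10, 0.15)
N_AUTOSOMES = 22


@dataclass
class CohortConfig:
    """Parameters of one synthetic cohort.

    ``cnv_segments`` are ``(chromosome, start_gene_index, end_gene_index,
    fold_change)`` tuples with 0-based half-open *global* gene indices that
    must all fall on the named chromosome and must not overlap within it.
    """

    n_samples: int = 6
    n_patients: int = 3
    timepoints_per_patient: Sequence[str] = ("pre", "on")
    cells_per_sample: int = 300
    n_genes: int = 1000
    n_programs: int = 5
    program_overdispersion: float = 0.15
    cnv_segments: Sequence[tuple] = ()
    malignant_fraction: float = 0.4
    doublet_rate: float = 0.0
    mito_gene_fraction: float = 0.03
    depth_mean: float = 2500.0
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_samples": self.n_samples,
            "n_patients": self.n_patients,
            "cells_per_sample": self.cells_per_sample,
            "n_genes": self.n_genes,
            "n_programs": self.n_programs,
        }
        for name, v in counts.items():
            if int(v) != v or v < 1:
                raise ConfigError(f"{name} must be a count >= 1, got {v!r}")
        for name, v in [
            ("malignant_fraction", self.malignant_fraction),
            ("doublet_rate", self.doublet_rate),
            ("mito_gene_fraction", self.mito_gene_fraction),
        ]:
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v!r}")
        if self.depth_mean <= 0:
            raise ConfigError(f"depth_mean must be positive, got {self.depth_mean!r}")
        if self.program_overdispersion < 0:
            raise ConfigError("program_overdispersion must be >= 0")
        if self.n_programs > self.n_genes:
            raise ConfigError("n_programs may not exceed n_genes")
        bad = set(self.timepoints_per_patient) - {"pre", "on"}
        if bad:
            raise ConfigError(f"unknown timepoint labels: {sorted(bad)}")
        if self.n_samples > self.n_patients * len(self.timepoints_per_patient):
            raise ConfigError(
                "n_samples exceeds n_patients x timepoints_per_patient"
            )
        self._validate_segments()

    def _validate_segments(self) -> None:
        chrom_of = _gene_chromosomes(self.n_genes)
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for seg in self.cnv_segments:
            chrom, start, end, fold = seg
            if not (0 <= start < end <= self.n_genes):
                raise ConfigError(f"segment {seg}: gene indices out of range")
            if fold <= 0:
                raise ConfigError(f"segment {seg}: fold_change must be positive")
            if not np.all(chrom_of[start:end] == chrom):
                raise ConfigError(
                    f"segment {seg}: genes {start}:{end} are not all on {chrom}"
                )
            by_chrom.setdefault(chrom, []).append((start, end))
        for chrom, ivs in by_chrom.items():
            ivs = sorted(ivs)
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                if s2 < e1:
                    raise ConfigError(
                        f"segments on {chrom} overlap: {(s1, e1)} and {(s2, e2)}"
                    )


@dataclass
class SyntheticTruth:
    """Generative ground truth aligned to the cohort's cells and genes.

    ``true_usages`` / ``true_spectra`` cover every generative component:
    the planted malignant GEPs (named in ``malignant_programs``) followed by
    one identity program per non-malignant lineage. Usage rows sum to 1 for
    every cell.
    """

    true_usages: pd.DataFrame
    true_spectra: pd.DataFrame
    true_malignant: pd.Series
    true_doublet: pd.Series
    true_type: pd.Series
    doublet_parents: pd.DataFrame
    malignant_programs: list[str] = field(default_factory=list)
    program_blocks: dict[str, list[str]] = field(default_factory=dict)

    @property
    def true_state(self) -> pd.Series:
        """Dominant malignant GEP per cell (argmax usage over the GEPs)."""
        u = self.true_usages[self.malignant_programs]
        return u.idxmax(axis=1).where(self.true_malignant, other=pd.NA)


def _gene_chromosomes(n_genes: int) -> np.ndarray:
    """Assign genes to 22 autosomes in contiguous, near-equal blocks."""
    sizes = [len(b) for b in np.array_split(np.arange(n_genes), N_AUTOSOMES)]
    out = np.concatenate(
        [np.repeat(f"chr{i + 1}", s) for i, s in enumerate(sizes) if s > 0]
    )
    return out


def _make_genes(config: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_genes
    chrom = _gene_chromosomes(n)
    # uniform 1 kb genes spaced 10 kb apart, restarting per chromosome
    start = np.empty(n, dtype=np.int64)
    for c in pd.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        start[idx] = np.arange(idx.size) * 10_000
    end = start + 1_000
    n_mito = int(round(config.mito_gene_fraction * n))
    mito_idx = rng.choice(n, size=n_mito, replace=False) if n_mito else np.array([], int)
    mito = np.zeros(n, dtype=bool)
    mito[mito_idx] = True
    symbol = np.array([f"G{i:05d}" for i in range(n)], dtype=object)
    symbol[mito] = [f"MT-{i}" for i in np.flatnonzero(mito)]
    gene_id = [f"ENSG{i:08d}" for i in range(n)]
    return pd.DataFrame(
        {
            "gene_id": gene_id,
            "symbol": symbol,
            "chromosome": chrom,
            "start": start,
            "end": end,
            "mito": mito,
        },
        index=pd.Index(symbol, name="gene"),
    )


def _make_spectra(
    config: CohortConfig, genes: pd.DataFrame, rng: np.random.Generator
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Component programs: shared baseline + disjoint marker block (+ mito)."""
    names = [f"program_{i + 1}" for i in range(config.n_programs)] + [
        f"{t}_identity" for t in NONMALIGNANT_TYPES
    ]
    n_comp = len(names)
    n = config.n_genes
    mito = genes["mito"].to_numpy()
    non_mito = np.flatnonzero(~mito)
    block_size = max(5, min(30, non_mito.size // (3 * n_comp)))
    if block_size * n_comp > non_mito.size:
        raise ConfigError("n_genes too small for disjoint program marker blocks")
    block_genes = rng.choice(non_mito, size=block_size * n_comp, replace=False)
    baseline = np.zeros(n)
    baseline[non_mito] = rng.lognormal(0.0, 1.0, size=non_mito.size)
    baseline /= baseline.sum()
    mito_profile = np.zeros(n)
    if mito.any():
        mito_profile[mito] = 1.0 / mito.sum()
    w_mito = 0.10 if mito.any() else 0.0
    spectra = np.empty((n_comp, n))
    blocks: dict[str, list[str]] = {}
    for c, name in enumerate(names):
        idx = block_genes[c * block_size : (c + 1) * block_size]
        block = np.zeros(n)
        block[idx] = 1.0 / idx.size
        spectra[c] = (1.0 - w_mito) * (0.70 * baseline + 0.30 * block) + w_mito * mito_profile
        blocks[name] = list(genes.index[np.sort(idx)])
    return pd.DataFrame(spectra, index=names, columns=genes.index), blocks


def _sample_table(config: CohortConfig) -> pd.DataFrame:
    tps = list(config.timepoints_per_patient)
    rows = []
    for j in range(config.n_samples):
        patient = f"P{(j % config.n_patients) + 1}"
        timepoint = tps[j // config.n_patients]
        rows.append((f"S{j + 1}", patient, timepoint))
    return pd.DataFrame(rows, columns=["sample", "patient", "timepoint"])


def generate_cohort(config: CohortConfig) -> tuple[ad.AnnData, SyntheticTruth]:
    """Draw a full cohort and its ground truth.

    Returns an :class:`anndata.AnnData` of raw integer counts (cells x genes,
    CSR) with sample/patient/timepoint in ``obs`` and gene coordinates plus a
    mitochondrial flag in ``var``, together with the :class:`SyntheticTruth`.
    Identical config (including seed) gives bit-identical output.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng_genes, rng_cells, rng_counts, rng_doublet = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )

    genes = _make_genes(config, rng_genes)
    spectra, blocks = _make_spectra(config, genes, rng_genes)
    gep_names = [f"program_{i + 1}" for i in range(config.n_programs)]
    samples = _sample_table(config)

    n_cells = config.n_samples * config.cells_per_sample
    n_comp = spectra.shape[0]
    usages = np.zeros((n_cells, n_comp))
    cell_sample = np.empty(n_cells, dtype=object)
    cell_type = np.empty(n_cells, dtype=object)
    malignant = np.zeros(n_cells, dtype=bool)

    n_mal = int(round(config.malignant_fraction * config.cells_per_sample))
    type_probs = np.asarray(_TYPE_WEIGHTS) / np.sum(_TYPE_WEIGHTS)
    pos = 0
    for _, row in samples.iterrows():
        for i in range(config.cells_per_sample):
            cell_sample[pos] = row["sample"]
            if i < n_mal:
                malignant[pos] = True
                cell_type[pos] = "tumor"
                dom = rng_cells.integers(config.n_programs)
                w = rng_cells.uniform(0.75, 0.95)
                rest = rng_cells.dirichlet(np.full(config.n_programs - 1, 0.8))
                u = np.insert((1.0 - w) * rest, dom, w)
                usages[pos, : config.n_programs] = u
            else:
                t = rng_cells.choice(len(NONMALIGNANT_TYPES), p=type_probs)
                cell_type[pos] = NONMALIGNANT_TYPES[t]
                usages[pos, config.n_programs + t] = 1.0
            pos += 1

    rates = usages @ spectra.to_numpy()
    # chromosome-scale shifts: multiply segment genes into malignant rates
    for chrom, start, end, fold in config.cnv_segments:
        rates[malignant, start:end] *= fold
    # per-cell mitochondrial load jitter
    mito_cols = genes["mito"].to_numpy()
    if mito_cols.any():
        load = rng_counts.gamma(shape=4.0, scale=0.25, size=n_cells)
        rates[:, mito_cols] *= load[:, None]
    # per-cell depth around depth_mean, rates renormalized to it
    depth = config.depth_mean * rng_counts.gamma(shape=8.0, scale=0.125, size=n_cells)
    rates *= (depth / rates.sum(axis=1))[:, None]

    theta = config.program_overdispersion
    if theta > 0:
        lam = rng_counts.gamma(shape=1.0 / theta, scale=theta * rates)
    else:
        lam = rates
    counts = rng_counts.poisson(lam).astype(np.int64)

    obs = pd.DataFrame(
        {"sample": cell_sample},
        index=pd.Index(
            [f"{s}_c{i % config.cells_per_sample:05d}" for i, s in enumerate(cell_sample)],
            name="cell",
        ),
    )
    obs = obs.join(samples.set_index("sample"), on="sample")
    adata = ad.AnnData(
        X=sparse.csr_matrix(counts),
        obs=obs,
        var=genes[["gene_id", "symbol", "chromosome", "start", "end", "mito"]].copy(),
    )

    truth = SyntheticTruth(
        true_usages=pd.DataFrame(usages, index=obs.index, columns=spectra.index),
        true_spectra=spectra,
        true_malignant=pd.Series(malignant, index=obs.index, name="true_malignant"),
        true_doublet=pd.Series(False, index=obs.index, name="true_doublet"),
        true_type=pd.Series(cell_type, index=obs.index, name="true_type"),
        doublet_parents=pd.DataFrame(
            {
                "parent_type_1": pd.NA,
                "parent_type_2": pd.NA,
                "parent_1": pd.NA,
                "parent_2": pd.NA,
            },
            index=obs.index,
        ),
        malignant_programs=gep_names,
        program_blocks=blocks,
    )
    if config.doublet_rate > 0:
        adata, truth = inject_doublets(
            adata, truth, config.doublet_rate, seed=int(rng_doublet.integers(2**31))
        )
    return adata, truth


def inject_doublets(
    counts: ad.AnnData, truth: SyntheticTruth, rate: float, seed: int
) -> tuple[ad.AnnData, SyntheticTruth]:
    """Replace ``floor(rate * n)`` cells with sums of two same-sample parents.

    The replaced cell's truth records both parent types; its usage is the
    mean of the parents' usages, and it is malignant if either parent is.
    """
    if not 0.0 <= rate < 1.0:
        raise ConfigError(f"doublet rate must lie in [0, 1), got {rate!r}")
    n = counts.n_obs
    n_doub = int(np.floor(rate * n))
    if n_doub == 0:
        return counts, truth
    rng = np.random.default_rng(seed)
    adata = counts.copy()
    X = adata.X.tolil()
    usages = truth.true_usages.copy()
    malignant = truth.true_malignant.copy()
    doublet = truth.true_doublet.copy()
    ctype = truth.true_type.copy()
    parents = truth.doublet_parents.copy()

    targets = rng.choice(n, size=n_doub, replace=False)
    is_target = np.zeros(n, dtype=bool)
    is_target[targets] = True
    sample = adata.obs["sample"].to_numpy()
    pools = {s: np.flatnonzero((sample == s) & ~is_target) for s in pd.unique(sample)}
    for t in targets:
        pool = pools[sample[t]]
        if pool.size < 2:
            logger.warning("sample %s too small for doublet parents; skipping", sample[t])
            continue
        p1, p2 = rng.choice(pool, size=2, replace=False)
        X[t] = (counts.X[p1] + counts.X[p2]).toarray().ravel()
        usages.iloc[t] = (truth.true_usages.iloc[p1] + truth.true_usages.iloc[p2]) / 2.0
        malignant.iloc[t] = bool(truth.true_malignant.iloc[p1] or truth.true_malignant.iloc[p2])
        doublet.iloc[t] = True
        ctype.iloc[t] = truth.true_type.iloc[p1]
        parents.iloc[t] = [
            truth.true_type.iloc[p1],
            truth.true_type.iloc[p2],
            counts.obs_names[p1],
            counts.obs_names[p2],
        ]
    adata.X = X.tocsr()
    new_truth = SyntheticTruth(
        true_usages=usages,
        true_spectra=truth.true_spectra,
        true_malignant=malignant,
        true_doublet=doublet,
        true_type=ctype,
        doublet_parents=parents,
        malignant_programs=list(truth.malignant_programs),
        program_blocks=dict(truth.program_blocks),
    )
    return adata, new_truth


def write_cohort(
    counts: ad.AnnData,
    truth: SyntheticTruth | None,
    directory: str | os.PathLike,
    overwrite: bool = False,
) -> list[str]:
    """Write the 10x-style triplet layout plus truth sidecars.

    Emits ``matrix.mtx`` (genes x cells, integer coordinate format),
    ``barcodes.tsv``, ``features.tsv``, ``cells.tsv`` and, when truth is
    given, ``truth_programs.gmt``. Refuses a non-empty directory unless
    ``overwrite`` is set.
    """
    directory = os.fspath(directory)
    if os.path.isdir(directory) and os.listdir(directory) and not overwrite:
        raise FileExistsError(
            f"{directory} is not empty; pass overwrite=True to replace its contents"
        )
    os.makedirs(directory, exist_ok=True)
    X = sparse.coo_matrix(counts.X.T)  # genes x cells, 10x orientation
    spio.mmwrite(os.path.join(directory, "matrix.mtx"), X, field="integer")
    written = ["matrix.mtx", "barcodes.tsv", "features.tsv", "cells.tsv"]
    counts.obs.index.to_series().to_csv(
        os.path.join(directory, "barcodes.tsv"), sep="\t", header=False, index=False
    )
    counts.var[["gene_id", "symbol", "chromosome", "start", "end"]].to_csv(
        os.path.join(directory, "features.tsv"), sep="\t", header=False, index=False
    )
    cells = counts.obs[["sample", "patient", "timepoint"]].copy()
    if truth is not None:
        cells["true_type"] = truth.true_type.values
        cells["true_malignant"] = truth.true_malignant.values
        cells["true_doublet"] = truth.true_doublet.values
    cells.to_csv(os.path.join(directory, "cells.tsv"), sep="\t", index=True)
    if truth is not None:
        from .io import write_gmt

        write_gmt(
            {name: genes for name, genes in truth.program_blocks.items()},
            os.path.join(directory, "truth_programs.gmt"),
            description="synthetic planted program",
        )
        written.append("truth_programs.gmt")
    return written
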