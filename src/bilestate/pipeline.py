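"""End-to-end analysis on a synthetic cohort, with TSV outputs.

Chains every stage on one cohort: generation, disk round-trip, QC, doublet
removal, normalization, HVG selection, clustering, marker annotation, CNV
malignancy scoring, consensus NMF over a rank grid, tumor-state calls,
percentile covariation with the permutation null, and pre/on-treatment
composition statistics. All randomness derives from one seed and all
outputs are plain TSV/JSON, so a rerun with the same inputs is
bit-identical.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import asdict

import numpy as np
import pandas as pd

from . import abundance, cnmf, cnv, qc, states
from .covary import run_covariation
from .io import read_gmt
from .synthetic import NONMALIGNANT_TYPES, CohortConfig, generate_cohort, write_cohort

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.10g"


def _write(df: pd.DataFrame, outdir: str, name: str) -> None:
    df.to_csv(os.path.join(outdir, name), sep="\t", float_format=FLOAT_FMT)


def run_pipeline(
    config: CohortConfig,
    outdir: str,
    seed: int = 0,
    k_grid: tuple[int, ...] = (4, 5, 6),
    n_runs: int = 8,
    n_hvg: int = 800,
    covary_iterations: int = 200,
    positive_gene: str | None = None,
) -> dict:
    """Run the whole pipeline into ``outdir``; returns a summary dict."""
    os.makedirs(outdir, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    s_doublet, s_cluster, s_cnv, s_cnmf, s_cov, s_score = (
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(6)
    )

    # --- cohort generation + disk round trip
    adata, truth = generate_cohort(config)
    cohort_dir = os.path.join(outdir, "cohort")
    write_cohort(adata, truth, cohort_dir, overwrite=True)
    adata = qc.read_counts(cohort_dir)
    marker_sets = read_gmt(os.path.join(cohort_dir, "truth_programs.gmt"))

    # --- QC, doublets, normalization
    filtered, report = qc.filter_matrix(adata, qc.QCThresholds())
    doublet = qc.detect_doublets(filtered, seed=s_doublet)
    filtered = filtered[~doublet.to_numpy()].copy()
    norm = qc.normalize_log(filtered, target_sum=1000.0)
    _write(pd.DataFrame([{**report.as_dict(), "doublets_removed": int(doublet.sum())}]),
           outdir, "qc_report.tsv")

    # --- clustering and major-type annotation
    hvgs = qc.select_hvg(norm)
    emb = qc.cluster_cells(norm, hvgs, n_components=min(40, len(hvgs) - 1), seed=s_cluster)
    type_markers = {
        t: marker_sets[f"{t}_identity"] for t in NONMALIGNANT_TYPES
        if f"{t}_identity" in marker_sets
    }
    tumor_blocks = {k: v for k, v in marker_sets.items() if k.startswith("program_")}
    type_markers["tumor"] = sorted({g for gs in tumor_blocks.values() for g in gs})
    cell_types = qc.annotate_major_types(norm, emb.cluster_labels, type_markers, seed=s_score)
    _write(pd.DataFrame({"cluster": emb.cluster_labels, "cell_type": cell_types}),
           outdir, "clusters.tsv")

    # --- CNV malignancy scoring
    reference = [t for t in NONMALIGNANT_TYPES if (cell_types == t).any()]
    cnv_res = cnv.run_cnv(norm, emb.cluster_labels, cell_types, reference, seed=s_cnv)
    _write(pd.DataFrame({
        "cell_score": cnv_res.cell_scores,
        "malignant": cnv_res.malignant_call,
    }), outdir, "cnv_scores.tsv")
    _write(cnv_res.region_states, outdir, "cnv_region_states.tsv")

    # --- consensus NMF on malignant cells over the rank grid
    malignant = cnv_res.malignant_call
    tumor_norm = norm[malignant.to_numpy()].copy()
    prep = cnmf.prepare_matrix(tumor_norm, n_hvg=n_hvg)
    decomps = [
        cnmf.run_cnmf(prep.matrix, k, n_runs=n_runs, seed=s_cnmf + k,
                      cells=prep.cells, genes=prep.genes)
        for k in k_grid
    ]
    ktable = cnmf.select_k(decomps)
    _write(ktable.set_index("k"), outdir, "k_selection.tsv")
    best_k = cnmf.suggest_k(ktable)
    best = decomps[list(k_grid).index(best_k)]
    _write(best.consensus_spectra, outdir, "spectra.tsv")
    _write(best.usages, outdir, "usages.tsv")

    # --- tumor state calls via gene-set scores of the five state programs
    block_order = sorted(tumor_blocks, key=lambda s: int(s.rsplit("_", 1)[1]))
    state_sets = dict(zip(states.STATE_NAMES, [tumor_blocks[k] for k in block_order]))
    activities = pd.DataFrame({
        name: states.score_gene_set(tumor_norm, gset, seed=s_score + i)
        for i, (name, gset) in enumerate(state_sets.items())
    })
    calls = states.assign_tumor_states(activities)
    _write(calls, outdir, "states.tsv")

    # --- covariation of programs across samples
    prog_types = {c: None for c in best.usages.columns}
    cov = run_covariation(
        best.usages, tumor_norm.obs["sample"],
        pd.Series("tumor", index=best.usages.index),
        prog_types, n_iterations=covary_iterations, seed=s_cov, min_cells=5,
    )
    _write(cov.correlation[cov.significance_percentile], outdir, "covariation_corr.tsv")
    _write(cov.pvalues, outdir, "covariation_pvalues.tsv")

    # --- composition and treatment comparisons
    sample_meta = (
        norm.obs[["sample", "patient", "timepoint"]].drop_duplicates().set_index("sample")
    )
    comp = abundance.composition_table(cell_types, norm.obs["sample"], sample_meta)
    _write(comp, outdir, "composition.tsv")
    tests = abundance.paired_comparison(comp, mode="paired-only")
    _write(tests.set_index("category") if not tests.empty else tests, outdir, "comparisons.tsv")
    if positive_gene is not None:
        frac, ptest = abundance.positive_fraction_test(
            norm, malignant, positive_gene, sample_meta, norm.obs["sample"]
        )
        _write(ptest.set_index("category"), outdir, "positive_fraction.tsv")

    summary = {
        "seed": seed,
        "config": {k: (list(v) if isinstance(v, (tuple, list)) else v)
                   for k, v in asdict(config).items()},
        "n_cells_retained": int(norm.n_obs),
        "n_genes_retained": int(norm.n_vars),
        "n_clusters": int(emb.cluster_labels.nunique()),
        "n_malignant_called": int(malignant.sum()),
        "selected_k": int(best_k),
        "state_counts": calls["state"].value_counts().to_dict(),
    }
    with open(os.path.join(outdir, "run_log.json"), "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
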