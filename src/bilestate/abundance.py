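"""Per-sample composition tables and pre/on-treatment comparisons.

Comparisons follow the study's statistics: two-sided Student t-tests
(two-sample over all samples, or paired over patients with both
timepoints) with Bonferroni correction over the categories tested in one
invocation. The positive-fraction test compares the per-sample fraction of
malignant cells expressing a gene (e.g. DKK1) between timepoints.
"""

from __future__ import annotations

import difflib
import logging

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse, stats

from .exceptions import ConfigError

logger = logging.getLogger(__name__)

TIMEPOINTS = ("pre", "on")


def composition_table(
    labels: pd.Series,
    sample_labels: pd.Series,
    sample_meta: pd.DataFrame,
    denominator: str = "all",
    parent_labels: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-sample category proportions.

    ``denominator='all'`` divides each category's cell count by the
    sample's total; ``'parent'`` divides by the count of the category's
    parent lineage (``parent_labels`` per cell), and a sample with zero
    parent cells gets a missing entry rather than 0. ``sample_meta`` maps
    sample -> patient and timepoint (index = sample).
    """
    bad = set(sample_meta["timepoint"]) - set(TIMEPOINTS)
    if bad:
        raise ConfigError(f"unknown timepoint labels: {sorted(bad)}")
    labels = labels.astype(str)
    counts = pd.crosstab(sample_labels, labels)
    if denominator == "all":
        prop = counts.div(counts.sum(axis=1), axis=0)
    elif denominator == "parent":
        if parent_labels is None:
            raise ConfigError("denominator='parent' requires parent_labels")
        # each category belongs to exactly one parent lineage
        cat_parent = (
            pd.DataFrame({"cat": labels.values, "parent": parent_labels.values})
            .groupby("cat")["parent"]
            .agg(lambda s: s.mode().iloc[0])
        )
        parent_counts = pd.crosstab(sample_labels, parent_labels.astype(str))
        prop = pd.DataFrame(index=counts.index, columns=counts.columns, dtype=float)
        for cat in counts.columns:
            par = cat_parent.loc[cat]
            denom = parent_counts[par].reindex(counts.index)
            prop[cat] = counts[cat] / denom.where(denom > 0)
    else:
        raise ConfigError(f"unknown denominator {denominator!r}")
    out = sample_meta.reindex(prop.index)[["patient", "timepoint"]].join(prop)
    out.index.name = "sample"
    return out


def _category_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in ("patient", "timepoint")]


def paired_comparison(
    table: pd.DataFrame, mode: str = "paired-only"
) -> pd.DataFrame:
    """Pre vs on-treatment t-test per category with Bonferroni correction.

    ``all-samples`` uses a two-sample Student t-test over every sample;
    ``paired-only`` a paired t-test over patients with both timepoints.
    Categories with too few observations are skipped with a warning.
    """
    if mode not in ("all-samples", "paired-only"):
        raise ConfigError(f"unknown mode {mode!r}")
    cats = _category_columns(table)
    rows = []
    for cat in cats:
        sub = table[["patient", "timepoint", cat]].dropna(subset=[cat])
        pre = sub.loc[sub["timepoint"] == "pre", cat]
        on = sub.loc[sub["timepoint"] == "on", cat]
        if mode == "all-samples":
            if len(pre) < 2 or len(on) < 2:
                logger.warning("category %s: <2 samples per group; skipped", cat)
                continue
            t, p = stats.ttest_ind(pre, on, equal_var=True)
        else:
            wide = sub.pivot_table(index="patient", columns="timepoint", values=cat)
            wide = wide.dropna()
            if len(wide) < 2 or not {"pre", "on"} <= set(wide.columns):
                logger.warning("category %s: <2 complete pairs; skipped", cat)
                continue
            diffs = wide["pre"] - wide["on"]
            if np.allclose(diffs, 0):
                t, p = 0.0, 1.0
            else:
                t, p = stats.ttest_rel(wide["pre"], wide["on"])
            pre, on = wide["pre"], wide["on"]
        rows.append(
            {
                "category": cat,
                "mean_pre": float(np.mean(pre)),
                "mean_on": float(np.mean(on)),
                "t": float(t),
                "p_raw": float(p),
                "mode": mode,
            }
        )
    out = pd.DataFrame(rows)
    if not out.empty:
        out["p_bonferroni"] = np.minimum(1.0, out["p_raw"] * len(out))
    return out


def positive_fraction_test(
    expression: ad.AnnData,
    malignant: pd.Series,
    gene: str,
    sample_meta: pd.DataFrame,
    sample_labels: pd.Series | None = None,
    positivity_threshold: float = 0.0,
    layer: str | None = "counts",
    mode: str = "paired-only",
) -> tuple[pd.Series, pd.DataFrame]:
    """Fraction of gene-positive malignant cells per sample, pre vs on.

    Positivity defaults to raw count > 0 (``layer='counts'``,
    ``positivity_threshold=0``). Returns (per-sample fractions, comparison
    table); when every fraction is 0 in both groups the t statistic is
    undefined and reported missing.
    """
    if gene not in expression.var_names:
        near = difflib.get_close_matches(gene, list(expression.var_names), n=3)
        raise KeyError(f"gene {gene!r} not measured; nearest symbols: {near}")
    if sample_labels is None:
        sample_labels = expression.obs["sample"]
    X = expression.layers[layer] if layer and layer in expression.layers else expression.X
    col = expression.var_names.get_loc(gene)
    vals = np.asarray(X[:, col].todense()).ravel() if sparse.issparse(X) else np.asarray(X)[:, col]
    pos = pd.Series(vals > positivity_threshold, index=expression.obs_names)
    mal = malignant.reindex(expression.obs_names).astype(bool)
    frac = pos[mal].groupby(sample_labels[mal]).mean()
    frac.name = f"{gene}_positive_fraction"
    table = sample_meta.reindex(frac.index)[["patient", "timepoint"]].copy()
    table[frac.name] = frac
    comp = paired_comparison(table, mode=mode)
    if not comp.empty and np.allclose(table[frac.name].fillna(0.0), 0.0):
        comp.loc[:, ["t", "p_raw", "p_bonferroni"]] = np.nan
    if comp.empty:
        comp = pd.DataFrame(
            [{"category": frac.name, "mean_pre": np.nan, "mean_on": np.nan,
              "t": np.nan, "p_raw": np.nan, "mode": mode, "p_bonferroni": np.nan}]
        )
    return frac, comp
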