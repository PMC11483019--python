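# Methods

`bilestate` implements, as a tested and reusable library, the single-cell
analysis pipeline used to characterize malignant cell states and their
microenvironment in biliary tract cancer (BTC) biopsies sampled before and
on treatment: quality control and clustering of droplet scRNA-seq counts,
expression-derived copy-number inference with a squared-deviation
malignancy score, consensus non-negative matrix factorization (cNMF) of
gene expression programs, rule-based annotation of five malignant states,
percentile-aggregated program covariation with a permutation null, and
pre- versus on-treatment compositional statistics. Because patient data
cannot ship with a library, every stage is exercised against a
ground-truthed synthetic cohort generator that emulates the statistical
structure such a cohort presents.

## Synthetic cohorts (`bilestate.synthetic`)

**Generative model.** Every cell's expected expression is a depth-scaled
nonnegative combination `usage @ spectra` of component programs — the same
low-rank assumption cNMF fits. Components comprise `n_programs` malignant
gene expression programs (GEPs) plus one identity program per non-malignant
lineage (T, myeloid, NK, endothelial, fibroblast, at 35/30/10/10/15%
relative frequency). Each component spectrum is 70% a shared lognormal
baseline, 30% a disjoint marker block (5–30 genes depending on gene count),
plus a 10% mitochondrial portion when mitochondrial genes are configured.
Malignant cells draw a dominant GEP weight from U(0.75, 0.95) with the
remainder Dirichlet(0.8)-split over the other GEPs; non-malignant cells
load entirely on their identity program. `SyntheticTruth` records spectra
and usages for *all* components (so usage rows sum to one for every cell)
and names the GEP subset in `malignant_programs`.

**Counts.** Per-cell depth is `depth_mean` × Gamma(8, 1/8) (mean 1, CV
0.35); rates are renormalized to the cell's depth after applying
copy-number fold changes and a Gamma(4, 1/4) per-cell mitochondrial load
multiplier. Counts are Poisson, or gamma-Poisson (negative binomial with a
single shared overdispersion `program_overdispersion`, variance
μ + θμ²) — the simplest model that gives QC and doublet stages realistic
variance. Defaults (6 samples from 3 patients at pre/on timepoints, 300
cells/sample, 2 500 expected counts/cell, θ = 0.15, 3% mitochondrial genes)
are desk-scale stand-ins for a paired-biopsy cohort; `malignant_fraction`
is exposed per cohort rather than fit to any empirical distribution of
tumor purity.

**Copy-number segments** are contiguous runs of genes on one of 22
synthetic autosomes (uniform 1 kb genes spaced 10 kb, 0-based half-open
coordinates); the configured fold change multiplies malignant cells' rates
over the segment. **Doublets** replace `floor(rate·n)` cells with the
summed counts of two same-sample parents; truth records both parents.

**What the generator does not emulate:** ambient RNA, batch effects, UMI
saturation, cell-cycle structure, or spatial organization. Recovery results
on these cohorts therefore demonstrate algorithmic correctness under the
model's own assumptions, not robustness to every artifact of real droplet
data.

## QC and preprocessing (`bilestate.qc`)

Cells with fewer than 50 expressed genes, fewer than 200 total counts, or
more than 25% mitochondrial counts (symbols prefixed `MT-`,
case-sensitive) are removed first; genes detected in fewer than 3 retained
cells second. The gene filter deliberately follows the cell filter (it
depends on which cells remain); the single pass is idempotent on realistic
data, though adversarial inputs where removing a gene drops a cell below
the gene threshold exist. Counts are normalized to 1 000 per cell and
log1p-transformed. Highly variable genes use binned normalized dispersion
(log1p mean in [0.0125, 3], normalized dispersion ≥ 0.5) with 20
equal-frequency mean bins. Clustering standardizes HVGs (clipped at 10),
takes 40 principal components (arpack, seeded), builds a k-nearest-neighbor
graph and runs leiden at resolution 0.5 with a fixed random state; these
standard steps are delegated to scanpy. Major types are annotated per
cluster by argmax of mean marker-set scores, ties broken lexicographically.

**Doublet detection** is a simulated-doublet kNN classifier run per sample:
as many synthetic doublets as cells are made by summing random cell pairs,
each *binomially thinned to a randomly drawn real cell's depth* so its
sampling noise matches the singlets it is compared against (without
thinning, the lower-noise synthetic doublets concentrate near cluster
centroids and flag deep singlets); real cells whose 30-neighbor
neighborhood in 30-component PCA space is more than 50% synthetic are
flagged. Homotypic doublets are largely invisible to any such method; the
recall contract covers heterotypic doublets.

## Copy-number scoring (`bilestate.cnv`)

The profile estimator is a deliberately specifiable stand-in for full
HMM-based CNV callers, because the pipeline's contribution is the
downstream score. Log-normalized expression of genes with mean normalized
(pre-log) expression ≥ 0.1 is centered against the mean of reference
(non-malignant) cells, averaged over non-overlapping genome-ordered windows
of 51 genes within each chromosome (the trailing remainder merges into the
last window; short chromosomes form one region) — giving "region" an
explicit, countable meaning — then re-centered per cell at its median,
clipped to ±1, and median-filtered (width 5) along regions.

The stored per-cell profile is additionally soft-thresholded by 1.5
reference standard deviations per region so reference cells read as flat.
Discretization, however, runs on the *raw* per-cluster means: aggregating
hundreds of cells removes the same per-cell noise without the amplitude
bias the soft threshold would introduce. Cluster means map to centered
states {−2, −1, −0.5, 0, +0.5, +1, +2} via multiples of a gain threshold
(default 0.15 for the first ±0.5 step, 2× for ±1, 4× for ±2); with a
fold-2 gain the cluster-mean log shift is ≈ 0.16–0.2 while lineage-specific
systematic deviations of normal clusters stay ≤ ~0.08, so the default
separates them about two-fold. Clusters under 3 cells are set all-neutral.

The **malignancy score** of a cluster is the sum of squared centered state
values over regions — zero iff every region is neutral — and every cell
inherits its cluster's score. The state-value encoding is configurable
because squaring scaled values versus integer state indices only rescales
scores monotonically. Malignant calls use either a plain score threshold or
the upper component of a two-component Gaussian mixture on log1p scores
(seeded; degenerate fits fall back to the threshold rule, default 0, so an
all-reference input flags nothing). The numeric cut that separated
malignant from normal clusters in the original analysis is not published;
both methods log their effective cut.

## Consensus NMF (`bilestate.cnmf`)

`prepare_matrix` ranks genes by binned normalized dispersion, keeps the top
`n_hvg` (default 2 000), and scales each gene to unit variance without
centering so values stay nonnegative. `factorize_once` is multiplicative-
update NMF with Frobenius loss — chosen because the update is monotone and
the per-iteration objective can be recorded and asserted — with seeded
uniform initialization, objective checks every 10 iterations, and stop at
relative improvement < 1e-4 or 200 iterations (dense restarts on desk-scale
matrices; single restarts can stall in local minima, which is precisely why
the consensus pools many).

The consensus step L2-normalizes all restarts' spectra, computes each
component's local density as its mean cosine distance to its `n_runs − 1`
nearest neighbors, discards components above the density threshold
(default 0.5), k-means-clusters the survivors into k groups (k-means++
seeded by the first run's seed), takes per-cluster elementwise medians as
consensus spectra, refits usages by per-cell nonnegative least squares and
row-normalizes them. Stability is the mean silhouette (Euclidean, on the
normalized components) of that clustering; error is the Frobenius norm of
the refit. `select_k` tabulates (k, stability, error) over a rank grid
(protocol default 5..101 step 3, 33 ranks); rank choice remains a logged
user decision, with `suggest_k` offering the optional rule "max stability
subject to error within 10% of its minimum". Default restarts per rank are
20, a desk-scale reduction of the tool-default 100.

## State annotation (`bilestate.states`)

Gene-set scores are mean set expression minus the mean of expression-
matched controls: genes are split into 25 equal-frequency bins of mean
expression and 50 controls are drawn per set gene from its bin, under a
fixed seed (the dominant control-matching convention in this toolchain; the
sampler is exposed so scores are exactly reproducible). Malignant cells are
assigned one of five states — classical, basal, mesenchymal, neural-like,
endothelial-like — by argmax of normalized activities (cNMF usages when
available, gene-set scores otherwise; both feed the same interface), with
lexicographic tie-breaks and the margin (top minus second) recorded. Cells
whose mesenchymal *and* neural-like normalized activities both reach a
threshold are called "intermediate"; the threshold is not quantified in the
source analysis and defaults to 0.25, logged per run, and a value above 1
disables the rule. `top_program_genes` exports per-program top-n gene sets
(default 50, stable ties); `map_programs_to_reference` correlates
discovered and reference program scores per cell (Pearson, zero-variance
vectors reported missing).

## Covariation (`bilestate.covary`)

For each program and sample, activity is summarized as the percentile
(linear interpolation) of the program's per-cell score over that sample's
cells *of the program's own cell type*; samples with fewer than `min_cells`
such cells are missing. Matrices are built at the 25th/50th/75th/90th/95th
percentiles; program-program Pearson correlation uses pairwise-complete
samples (≥ 3), ordered by average-linkage hierarchical clustering on
Euclidean distance of correlation rows. Significance shuffles the cells'
sample labels — an exact permutation of the label vector, preserving
per-sample cell counts, stratified by cell type so tumor-program
percentiles always aggregate tumor cells (an unstratified variant is a
flag) — recomputes the 75th-percentile correlations, and reports
`p = #(null > observed) / n_iterations` over 1 000 iterations by default.
The estimator can return exactly 0 by construction; an add-one-smoothed
variant is available behind a flag, off by default, and no multiple-testing
correction is applied by default.

## Composition statistics (`bilestate.abundance`)

Per-sample proportions use either all cells or a parent lineage as
denominator (a sample with zero parent cells yields a missing entry, not
0). Pre- versus on-treatment comparisons are two-sided Student t-tests —
two-sample over all samples, or paired over patients with both
timepoints — with Bonferroni correction over the categories tested in one
invocation (`adjusted = min(1, raw × K)`). A paired test on identical pairs
returns t = 0, p = 1 rather than 0/0. The positive-fraction test compares
the per-sample fraction of malignant cells expressing a gene (default
positivity: raw count > 0, since the "gene-positive" definition carries no
published cutoff; normalized thresholds are configurable); all-zero
fractions make the statistic undefined and it is reported missing.

## Numerical and reproducibility choices

All randomness flows from explicit integer seeds through
`numpy.random.SeedSequence` spawns; leiden, arpack PCA, k-means and the
Gaussian mixture take derived seeds, so a full pipeline run writes
bit-identical TSVs when repeated. Degenerate inputs (empty marker
intersections, zero-variance score columns, too-small clusters or samples)
warn and degrade explicitly rather than raising, except where the result
would be meaningless (no reference cells, all cells filtered, all
components density-filtered). Problem sizes in the test-suite and the
acceptance script — cohorts of ~1 000–3 000 cells, 400–2 200 genes, 20 NMF
restarts over ranks {3, 5, 7} — are the package's chosen desk-scale study
conditions; they are large enough that the recovery contracts (AUROC ≥
0.98 for malignancy scores, matched spectra cosine ≥ 0.9, state accuracy ≥
0.9, calibrated permutation and t-test nulls) are meaningful, and small
enough to re-run anywhere.

## Known limitations

- The CNV stand-in infers relative expression shifts, not ploidy; it has no
  allele support and does not reimplement the six-state Bayesian HMM of
  dedicated tools, and its gain threshold is calibrated to cluster-level
  aggregation.
- Homotypic doublets are essentially undetectable by the simulated-doublet
  classifier.
- Percentile covariation quantifies cross-sample co-occurrence only; it
  cannot establish spatial co-localization.
- Plain t-tests on proportions ignore compositional constraints; no
  CLR/mixed-model alternative is provided by design.
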