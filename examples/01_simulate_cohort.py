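"""Generate a ground-truthed synthetic biopsy cohort and write it to disk.

The cohort mimics a paired pre/on-treatment biopsy study: six samples from
three patients, a mix of malignant cells (with planted copy-number gains)
and five non-malignant lineages, and five planted malignant gene programs.
"""

import tempfile

import bilestate as bs

cfg = bs.CohortConfig(
    n_samples=6,
    n_patients=3,
    cells_per_sample=200,
    n_genes=600,
    n_programs=5,
    malignant_fraction=0.4,
    doublet_rate=0.03,
    cnv_segments=[("chr1", 0, 28, 2.0)],  # fold-2 gain over chromosome 1
    seed=0,
)
adata, truth = bs.generate_cohort(cfg)

print(f"cohort: {adata.n_obs} cells x {adata.n_vars} genes")
print(adata.obs.groupby(["patient", "timepoint"], observed=True).size())
print("cell types:", truth.true_type.value_counts().to_dict())
print("malignant cells:", int(truth.true_malignant.sum()))
print("doublets:", int(truth.true_doublet.sum()))

outdir = tempfile.mkdtemp(prefix="bilestate_cohort_")
files = bs.synthetic.write_cohort(adata, truth, outdir, overwrite=True)
print(f"wrote {files} to {outdir}")
# The counts/barcodes/features triplet is the 10x-style layout the QC
# module reads back; truth_programs.gmt holds the planted marker blocks.
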