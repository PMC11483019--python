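"""QC, normalization, HVG, clustering and annotation contracts."""

import anndata as ad
import numpy as np
import pandas as pd
import pytest
from scipy import sparse
from sklearn.metrics import adjusted_rand_score

import bilestate as bs
from bilestate import qc
from bilestate.exceptions import EmptyResultError, FormatError
from bilestate.synthetic import write_cohort

from conftest import dense


def _adata(counts, symbols=None, samples=None):
    counts = np.asarray(counts)
    symbols = symbols or [f"G{i}" for i in range(counts.shape[1])]
    var = pd.DataFrame(
        {"symbol": symbols, "mito": [s.startswith("MT-") for s in symbols]},
        index=pd.Index(symbols, name="gene"),
    )
    obs = pd.DataFrame(index=[f"c{i}" for i in range(counts.shape[0])])
    if samples is not None:
        obs["sample"] = samples
    return ad.AnnData(X=sparse.csr_matrix(counts.astype(np.int64)), obs=obs, var=var)


class TestReadCounts:
    def test_empty_matrix_gives_zero_cells(self, tmp_path):
        d = tmp_path / "empty"
        d.mkdir()
        (d / "matrix.mtx").write_text(
            "%%MatrixMarket matrix coordinate integer general\n3 0 0\n"
        )
        (d / "barcodes.tsv").write_text("")
        (d / "features.tsv").write_text("id1\tA\nid2\tB\nid3\tC\n")
        adata = qc.read_counts(d)
        assert adata.shape == (0, 3)

    def test_dimension_mismatch_names_file(self, small_cohort, tmp_path):
        _, adata, truth = small_cohort
        write_cohort(adata, truth, tmp_path / "c")
        with open(tmp_path / "c" / "features.tsv", "a") as fh:
            fh.write("idX\tXTRA\tchr1\t0\t1\n")
        with pytest.raises(FormatError, match="features.tsv"):
            qc.read_counts(tmp_path / "c")

    def test_duplicate_symbols_disambiguated(self, tmp_path, caplog):
        d = tmp_path / "dup"
        d.mkdir()
        (d / "matrix.mtx").write_text(
            "%%MatrixMarket matrix coordinate integer general\n3 2 2\n1 1 5\n3 2 7\n"
        )
        (d / "barcodes.tsv").write_text("b1\nb2\n")
        (d / "features.tsv").write_text("id1\tDUP\nid2\tDUP\nid3\tOK\n")
        with caplog.at_level("WARNING", logger="bilestate.qc"):
            adata = qc.read_counts(d)
        assert list(adata.var_names) == ["DUP", "DUP-1", "OK"]
        assert "duplicat" in caplog.text


class TestFilterMatrix:
    def test_cell_thresholds(self):
        # cell 0: 40 genes expressed; cell 1: 26% mito; cell 2: clean
        n_genes = 120
        X = np.zeros((3, n_genes), dtype=int)
        X[0, :40] = 10  # 400 counts but only 40 genes
        X[1, :100] = 10
        X[1, 100] = 348  # mito gene: 348/1348 > 25%
        X[2, :100] = 10
        symbols = [f"G{i}" if i != 100 else "MT-1" for i in range(n_genes)]
        adata = _adata(X, symbols)
        out, report = qc.filter_matrix(
            adata, qc.QCThresholds(min_cells_per_gene=1)
        )
        assert list(out.obs_names) == ["c2"]
        assert report.cells_low_genes == 1
        assert report.cells_high_mito == 1

    def test_gene_detected_in_two_retained_cells_removed(self):
        # 5 cells; gene "rare" appears in 2 of the retained cells only
        rng = np.random.default_rng(0)
        X = rng.integers(1, 5, size=(5, 80))
        X[:, 0] = [3, 2, 0, 0, 0]  # gene 0 detected in 2 cells
        adata = _adata(X)
        thr = qc.QCThresholds(min_genes_per_cell=1, min_counts_per_cell=1,
                              min_cells_per_gene=3)
        out, report = qc.filter_matrix(adata, thr)
        assert out.n_obs == 5
        assert "G0" not in out.var_names
        assert report.genes_removed == 1

    def test_all_cells_removed_raises(self):
        adata = _adata(np.ones((3, 10), dtype=int))
        with pytest.raises(EmptyResultError):
            qc.filter_matrix(adata)  # 10 genes < 50, 10 counts < 200

    def test_idempotent_on_cohort(self, small_cohort):
        _, adata, _ = small_cohort
        once, _ = qc.filter_matrix(adata)
        twice, rep = qc.filter_matrix(once)
        assert rep.cells_removed == 0 and rep.genes_removed == 0
        assert once.shape == twice.shape


class TestNormalizeLog:
    def test_stated_transform_arithmetic(self):
        X = np.zeros((1, 40), dtype=int)
        X[0, 0] = 100
        X[0, 1:20] = 100  # total 2000
        adata = _adata(X)
        out = qc.normalize_log(adata, target_sum=1000.0)
        val = dense(out)[0, 0]
        assert val == pytest.approx(np.log(51.0), abs=1e-12)
        assert dense(out)[0, 25] == 0.0  # log1p(0)

    def test_exponentiated_sums_equal_target(self, small_cohort):
        _, adata, _ = small_cohort
        filt, _ = qc.filter_matrix(adata)
        out = qc.normalize_log(filt, target_sum=1000.0)
        sums = np.expm1(dense(out)).sum(axis=1)
        np.testing.assert_allclose(sums, 1000.0, rtol=1e-6)

    def test_zero_total_cell_rejected(self):
        X = np.zeros((2, 5), dtype=int)
        X[0] = 1
        with pytest.raises(ValueError, match="zero total"):
            qc.normalize_log(_adata(X))


class TestSelectHVG:
    def test_constant_gene_excluded(self, small_normalized):
        norm, _ = small_normalized
        norm = norm.copy()
        X = dense(norm)
        X[:, 0] = 1.0  # constant, nonzero
        norm.X = X
        hvgs = qc.select_hvg(norm)
        assert norm.var_names[0] not in hvgs

    def test_high_mean_gene_excluded_regardless_of_dispersion(self, rng):
        X = rng.lognormal(0, 0.5, size=(200, 60))
        X[:, 0] = rng.lognormal(4.5, 2.0, size=200)  # huge mean, huge dispersion
        expr = np.log1p(X)
        df = qc.binned_normalized_dispersion(expr)
        assert df["mean"].iloc[0] > 3.0
        hvgs = qc.select_hvg(expr, mean_max=3.0)
        assert 0 not in list(hvgs)

    def test_matches_binned_dispersion_oracle(self, rng):
        """Explicit-loop oracle for the binned dispersion normalization."""
        expr = np.log1p(rng.lognormal(0.0, 1.0, size=(120, 50)))
        got = set(qc.select_hvg(expr, n_bins=5))

        E = np.expm1(expr)
        means = E.mean(axis=0)
        variances = E.var(axis=0, ddof=1)
        log_mean = np.log1p(means)
        log_disp = np.log(variances / means)
        bins = pd.qcut(pd.Series(log_mean), q=5, duplicates="drop")
        expected = set()
        for g in range(50):
            members = [j for j in range(50) if bins[j] == bins[g]]
            mu = sum(log_disp[j] for j in members) / len(members)
            sd = (
                sum((log_disp[j] - mu) ** 2 for j in members) / (len(members) - 1)
            ) ** 0.5
            norm_disp = (log_disp[g] - mu) / sd
            if 0.0125 <= log_mean[g] <= 3.0 and norm_disp >= 0.5:
                expected.add(g)
        assert got == expected


class TestClusterCells:
    def test_recovers_planted_types(self, stromal_cohort):
        _, adata, truth = stromal_cohort
        norm = qc.normalize_log(adata)
        hvgs = qc.select_hvg(norm)
        emb = qc.cluster_cells(norm, hvgs, n_components=30, seed=0)
        ari = adjusted_rand_score(truth.true_type, emb.cluster_labels)
        assert ari >= 0.9

    def test_duplicating_cells_keeps_cluster_count(self, stromal_cohort):
        _, adata, truth = stromal_cohort
        norm = qc.normalize_log(adata)
        hvgs = qc.select_hvg(norm)
        emb1 = qc.cluster_cells(norm, hvgs, n_components=20, seed=0)
        doubled = ad.concat([norm, norm], index_unique="-")
        emb2 = qc.cluster_cells(doubled, hvgs, n_components=20, seed=0)
        assert emb1.cluster_labels.nunique() == emb2.cluster_labels.nunique()

    def test_deterministic_under_seed(self, stromal_cohort):
        _, adata, _ = stromal_cohort
        norm = qc.normalize_log(adata)
        hvgs = qc.select_hvg(norm)
        l1 = qc.cluster_cells(norm, hvgs, seed=5).cluster_labels
        l2 = qc.cluster_cells(norm, hvgs, seed=5).cluster_labels
        assert (l1 == l2).all()

    def test_neighbor_graph_symmetric(self, stromal_cohort):
        _, adata, _ = stromal_cohort
        norm = qc.normalize_log(adata)
        emb = qc.cluster_cells(norm, qc.select_hvg(norm), seed=0)
        g = emb.neighbor_graph
        assert abs(g - g.T).max() < 1e-12


class TestAnnotateMajorTypes:
    def test_recovers_types_from_marker_blocks(self, stromal_cohort):
        _, adata, truth = stromal_cohort
        norm = qc.normalize_log(adata)
        emb = qc.cluster_cells(norm, qc.select_hvg(norm), n_components=30, seed=0)
        markers = {
            name.replace("_identity", ""): genes
            for name, genes in truth.program_blocks.items()
            if name.endswith("_identity")
        }
        ann = qc.annotate_major_types(norm, emb.cluster_labels, markers, seed=0)
        assert (ann == truth.true_type).mean() >= 0.95

    def test_identical_marker_sets_tie_break_lexicographic(self, caplog, rng):
        X = np.log1p(rng.poisson(5, size=(30, 20)).astype(float))
        adata = _adata(np.zeros((30, 20), dtype=int))
        adata.X = X
        labels = pd.Series(["0"] * 30, index=adata.obs_names)
        markers = {"beta": ["G1", "G2"], "alpha": ["G1", "G2"]}
        with caplog.at_level("WARNING", logger="bilestate.qc"):
            ann = qc.annotate_major_types(adata, labels, markers, seed=0)
        assert set(ann) == {"alpha"}
        assert "tie" in caplog.text

    def test_single_cluster_shares_one_label(self, stromal_cohort):
        _, adata, truth = stromal_cohort
        norm = qc.normalize_log(adata)
        labels = pd.Series(["only"] * norm.n_obs, index=norm.obs_names)
        markers = {
            name.replace("_identity", ""): genes
            for name, genes in truth.program_blocks.items()
            if name.endswith("_identity")
        }
        ann = qc.annotate_major_types(norm, labels, markers, seed=0)
        assert ann.nunique() == 1


class TestDetectDoublets:
    def test_low_false_positive_rate_without_doublets(self):
        cfg = bs.CohortConfig(
            n_samples=2, n_patients=1, cells_per_sample=1000, n_genes=500,
            n_programs=2, malignant_fraction=0.0, doublet_rate=0.0, seed=5,
        )
        adata, _ = bs.generate_cohort(cfg)
        flags = qc.detect_doublets(adata, seed=0)
        assert flags.mean() <= 0.05

    def test_recovers_heterotypic_doublets(self):
        cfg = bs.CohortConfig(
            n_samples=2, n_patients=1, cells_per_sample=1000, n_genes=500,
            n_programs=2, malignant_fraction=0.5, doublet_rate=0.15, seed=6,
        )
        adata, truth = bs.generate_cohort(cfg)
        flags = qc.detect_doublets(adata, seed=0)
        het = truth.true_doublet & (
            truth.doublet_parents["parent_type_1"]
            != truth.doublet_parents["parent_type_2"]
        )
        assert flags[het].mean() >= 0.6

    def test_deterministic(self, stromal_cohort):
        _, adata, _ = stromal_cohort
        f1 = qc.detect_doublets(adata, seed=3)
        f2 = qc.detect_doublets(adata, seed=3)
        assert (f1 == f2).all()

    def test_tiny_sample_skipped_with_warning(self, caplog):
        rng = np.random.default_rng(1)
        adata = _adata(rng.poisson(3, size=(10, 30)), samples=["s1"] * 10)
        with caplog.at_level("WARNING", logger="bilestate.qc"):
            flags = qc.detect_doublets(adata, k_neighbors=30, seed=0)
        assert not flags.any()
        assert "flagging none" in caplog.text
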