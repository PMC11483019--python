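"""Percentile aggregation, program correlation and the permutation null."""

import itertools

import numpy as np
import pandas as pd
import pytest

from bilestate.covary import (
    percentile_matrix,
    permutation_pvalues,
    program_correlations,
    run_covariation,
)


def _cohort_scores(rng, n_samples=6, per_sample=20, programs=("u1", "u2")):
    n = n_samples * per_sample
    scores = pd.DataFrame(
        rng.normal(size=(n, len(programs))), columns=list(programs)
    )
    labels = pd.Series(np.repeat([f"S{i}" for i in range(n_samples)], per_sample),
                       index=scores.index)
    ctypes = pd.Series("tumor", index=scores.index)
    ptypes = {p: "tumor" for p in programs}
    return scores, labels, ctypes, ptypes


class TestPercentileMatrix:
    def test_median_of_five(self):
        scores = pd.DataFrame({"u": [1.0, 2, 3, 4, 5]})
        labels = pd.Series(["s"] * 5)
        ctypes = pd.Series(["tumor"] * 5)
        pm = percentile_matrix(scores, labels, ctypes, {"u": "tumor"}, 50, min_cells=1)
        assert pm.loc["s", "u"] == 3.0

    def test_constant_scores_any_percentile(self):
        scores = pd.DataFrame({"u": [2.5] * 8})
        labels = pd.Series(["s"] * 8)
        ctypes = pd.Series(["tumor"] * 8)
        for q in (25, 50, 75, 90, 95):
            pm = percentile_matrix(scores, labels, ctypes, {"u": "tumor"}, q, min_cells=1)
            assert pm.loc["s", "u"] == 2.5

    def test_linear_interpolation_rule(self):
        scores = pd.DataFrame({"u": np.arange(10.0)})
        labels = pd.Series(["s"] * 10)
        ctypes = pd.Series(["tumor"] * 10)
        pm = percentile_matrix(scores, labels, ctypes, {"u": "tumor"}, 90, min_cells=1)
        assert pm.loc["s", "u"] == pytest.approx(8.1)

    def test_min_cells_yields_missing(self, rng):
        scores, labels, ctypes, ptypes = _cohort_scores(rng, per_sample=4)
        pm = percentile_matrix(scores, labels, ctypes, ptypes, 75, min_cells=5)
        assert pm.isna().all().all()

    def test_type_restriction_ignores_other_cells(self, rng):
        scores = pd.DataFrame({"u": [0.0, 0, 0, 100, 100]})
        labels = pd.Series(["s"] * 5)
        ctypes = pd.Series(["tumor", "tumor", "tumor", "T", "T"])
        pm = percentile_matrix(scores, labels, ctypes, {"u": "tumor"}, 90, min_cells=1)
        assert pm.loc["s", "u"] == 0.0

    def test_percentile_bounds_rejected(self, rng):
        scores, labels, ctypes, ptypes = _cohort_scores(rng)
        with pytest.raises(ValueError):
            percentile_matrix(scores, labels, ctypes, ptypes, 0)

    def test_within_sample_cell_shuffle_leaves_matrix_unchanged(self, rng):
        scores, labels, ctypes, ptypes = _cohort_scores(rng)
        pm1 = percentile_matrix(scores, labels, ctypes, ptypes, 75, min_cells=1)
        # shuffle cells within each sample: percentiles are order-free
        idx = np.arange(len(scores))
        for s in labels.unique():
            sel = np.flatnonzero((labels == s).to_numpy())
            idx[sel] = rng.permutation(sel)
        pm2 = percentile_matrix(
            scores.iloc[idx].reset_index(drop=True),
            labels.reset_index(drop=True),
            ctypes.reset_index(drop=True),
            ptypes, 75, min_cells=1,
        )
        pd.testing.assert_frame_equal(pm1, pm2)


class TestProgramCorrelations:
    def test_identical_and_negated_columns(self):
        m = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [1.0, 2, 3, 4], "c": [-1.0, -2, -3, -4]})
        corr, _, _ = program_correlations(m)
        assert corr.loc["a", "b"] == pytest.approx(1.0)
        assert corr.loc["a", "c"] == pytest.approx(-1.0)

    def test_hand_fixture_matches_manual_pearson(self):
        m = pd.DataFrame({"a": [1.0, 4, 2, 7], "b": [2.0, 5, 1, 9]})
        corr, _, _ = program_correlations(m)
        x, y = m["a"].to_numpy(), m["b"].to_numpy()
        xc, yc = x - x.mean(), y - y.mean()
        manual = (xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum())
        assert corr.loc["a", "b"] == pytest.approx(manual, abs=1e-12)

    def test_zero_variance_column_missing_and_excluded(self, caplog):
        m = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [5.0, 5, 5, 5], "c": [2.0, 1, 4, 3]})
        with caplog.at_level("WARNING", logger="bilestate.covary"):
            corr, _, order = program_correlations(m)
        assert corr.loc["a", "b"] is np.nan or np.isnan(corr.loc["a", "b"])
        assert order[-1] == "b"


class TestPermutationPvalues:
    def test_perfect_signal_gives_zero_p(self, rng):
        # sample-level signal both programs share: observed corr ~ 1
        n_samples, per = 8, 15
        base = rng.normal(size=n_samples) * 3
        rows = []
        for i in range(n_samples):
            for _ in range(per):
                rows.append((base[i] + rng.normal(0, 0.05), base[i] + rng.normal(0, 0.05)))
        scores = pd.DataFrame(rows, columns=["u1", "u2"])
        labels = pd.Series(np.repeat([f"S{i}" for i in range(n_samples)], per))
        ctypes = pd.Series("tumor", index=scores.index)
        p = permutation_pvalues(
            scores, labels, ctypes, {"u1": "tumor", "u2": "tumor"},
            n_iterations=200, seed=0, min_cells=5,
        )
        assert p.loc["u1", "u2"] == 0.0

    def test_pvalues_symmetric_in_unit_interval(self, rng):
        scores, labels, ctypes, ptypes = _cohort_scores(rng, programs=("u1", "u2", "u3"))
        p = permutation_pvalues(scores, labels, ctypes, ptypes, n_iterations=50, seed=1, min_cells=5)
        off = p.to_numpy()[np.triu_indices(3, 1)]
        assert ((off >= 0) & (off <= 1)).all()
        np.testing.assert_allclose(p.to_numpy(), p.to_numpy().T)

    def test_matches_exhaustive_enumeration_on_three_samples(self, rng):
        """Monte-Carlo p within 3 binomial SEs of the exact permutation p."""
        per = 3
        n = 3 * per
        scores = pd.DataFrame(rng.normal(size=(n, 2)), columns=["u1", "u2"])
        labels = pd.Series(np.repeat(["A", "B", "C"], per))
        ctypes = pd.Series("tumor", index=scores.index)
        ptypes = {"u1": "tumor", "u2": "tumor"}
        obs = percentile_matrix(scores, labels, ctypes, ptypes, 75, min_cells=1).corr().loc["u1", "u2"]
        # exact null: every distinct assignment of the label multiset
        count = total = 0
        cells = set(range(n))
        for a_cells in itertools.combinations(range(n), per):
            rest = sorted(cells - set(a_cells))
            for b_cells in itertools.combinations(rest, per):
                assign = np.empty(n, dtype=object)
                assign[list(a_cells)] = "A"
                assign[list(b_cells)] = "B"
                assign[[i for i in rest if i not in set(b_cells)]] = "C"
                c = (
                    percentile_matrix(scores, pd.Series(assign), ctypes, ptypes, 75, min_cells=1)
                    .corr()
                    .loc["u1", "u2"]
                )
                count += c > obs
                total += 1
        exact = count / total
        mc = permutation_pvalues(
            scores, labels, ctypes, ptypes, n_iterations=1000, seed=2, min_cells=1
        ).loc["u1", "u2"]
        se = np.sqrt(exact * (1 - exact) / 1000)
        assert abs(mc - exact) <= max(3 * se, 1e-12)

    def test_add_one_smoothing_bounds_away_from_zero(self, rng):
        scores, labels, ctypes, ptypes = _cohort_scores(rng)
        p = permutation_pvalues(scores, labels, ctypes, ptypes, n_iterations=20,
                                seed=3, min_cells=5, add_one_smoothing=True)
        off = p.loc["u1", "u2"]
        assert off >= 1.0 / 21.0


def test_run_covariation_bundles_all_percentiles(rng):
    scores, labels, ctypes, ptypes = _cohort_scores(rng, n_samples=8, per_sample=25,
                                                    programs=("u1", "u2", "u3"))
    res = run_covariation(scores, labels, ctypes, ptypes, n_iterations=30, seed=0, min_cells=5)
    assert set(res.correlation) == {25, 50, 75, 90, 95}
    assert res.pvalues.shape == (3, 3)
    assert res.significance_percentile == 75
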