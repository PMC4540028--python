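"""RPKM profiling, tissue partitioning and the metabolite-correlation screen."""

import numpy as np
import pandas as pd
import pytest

from neemomics.expression import (
    candidate_screen,
    cluster_tissues,
    ddct_fold_change,
    expression_summary,
    metabolite_correlation,
    permutation_null,
    rpkm,
    tissue_partition,
)
from neemomics.simulate import PanelConfig, generate_panel, simulate_panel_expression


@pytest.fixture(scope="module")
def noiseless_expression():
    cfg = PanelConfig(seed=17, n_contigs=2, contig_length=40_000, n_genes=60,
                      n_ssr_planted=30, n_ssr_polymorphic=6, n_corr_genes=12,
                      expression_noise_cv=0.0)
    panel = generate_panel(cfg)
    return panel, simulate_panel_expression(panel)


class TestRpkm:
    def test_unit_case(self):
        counts = pd.DataFrame({"t": [1000.0]}, index=["g"])
        out = rpkm(counts, pd.Series({"g": 1000}), pd.Series({"t": 1_000_000}))
        assert out.loc["g", "t"] == pytest.approx(1000.0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.integers(1, 500, (5, 3)).astype(float),
                              index=list("abcde"), columns=["t1", "t2", "t3"])
        lengths = pd.Series(rng.integers(300, 3000, 5), index=list("abcde"))
        base = rpkm(counts, lengths)
        doubled = rpkm(counts * 2, lengths)
        pd.testing.assert_frame_equal(base, doubled)

    def test_matches_per_cell_formula(self):
        rng = np.random.default_rng(1)
        counts = pd.DataFrame(rng.integers(0, 800, (6, 4)).astype(float),
                              index=[f"g{i}" for i in range(6)],
                              columns=list("wxyz"))
        lengths = pd.Series(rng.integers(200, 5000, 6), index=counts.index)
        totals = counts.sum()
        out = rpkm(counts, lengths, totals)
        for g in counts.index:
            for t in counts.columns:
                expect = counts.loc[g, t] * 1e9 / (lengths[g] * totals[t])
                assert out.loc[g, t] == pytest.approx(expect)

    def test_missing_length_is_input_error(self):
        counts = pd.DataFrame({"t": [5.0]}, index=["g"])
        with pytest.raises(ValueError, match="length"):
            rpkm(counts, pd.Series(dtype=float))


class TestSummaryAndPartition:
    def test_all_zero_matrix(self):
        m = pd.DataFrame(0.0, index=["a", "b"], columns=["t1", "t2"])
        s = expression_summary(m)
        assert (s == 0).all().all()

    def test_thresholds_monotone(self, noiseless_expression):
        panel, ed = noiseless_expression
        mat = rpkm(ed.counts, ed.gene_lengths, ed.library_sizes)
        s = expression_summary(mat)
        assert (s["rpkm_gt_1"] >= s["rpkm_gt_5"]).all()
        assert (s["rpkm_gt_5"] >= s["rpkm_gt_10"]).all()

    def test_partition_disjoint_and_matches_truth(self, noiseless_expression):
        panel, ed = noiseless_expression
        mat = rpkm(ed.counts, ed.gene_lengths, ed.library_sizes)
        parts = tissue_partition(mat)
        n = sum(len(v) for v in parts.values())
        assert n == len(mat)
        assert not (set(parts["ubiquitous"]) & set(parts["tissue_specific"]))
        # noiseless: recompute the partition directly from the truth matrix
        expressed = ed.expected_rpkm >= 1.0
        k = expressed.sum(axis=1)
        assert set(parts["ubiquitous"]) == set(mat.index[k == mat.shape[1]])
        assert set(parts["tissue_specific"]) == set(mat.index[k == 1])

    def test_single_tissue_rejected(self):
        with pytest.raises(ValueError):
            tissue_partition(pd.DataFrame({"only": [1.0]}, index=["g"]))

    def test_unexpressed_gene_lands_in_other(self):
        m = pd.DataFrame({"t1": [0.0, 2.0], "t2": [0.0, 2.0]}, index=["dead", "live"])
        parts = tissue_partition(m)
        assert "dead" in parts["other"] and "live" in parts["ubiquitous"]


class TestCorrelation:
    def test_identical_profile_r_one(self):
        prof = pd.Series([1.0, 5.0, 2.0, 8.0], index=list("abcd"))
        m = pd.DataFrame([prof * 3.0], index=["g"])
        out = metabolite_correlation(m, prof)
        assert out.loc["g", "r"] == pytest.approx(1.0)

    def test_negated_profile_r_minus_one(self):
        prof = pd.Series([1.0, 5.0, 2.0, 8.0], index=list("abcd"))
        m = pd.DataFrame([-prof + 10.0], index=["g"])
        assert metabolite_correlation(m, prof).loc["g", "r"] == pytest.approx(-1.0)

    def test_matches_direct_covariance_computation(self):
        rng = np.random.default_rng(2)
        m = pd.DataFrame(rng.random((20, 7)), columns=[f"t{i}" for i in range(7)])
        prof = pd.Series(rng.random(7), index=m.columns)
        out = metabolite_correlation(m, prof)
        for g in m.index:
            expect = np.corrcoef(m.loc[g], prof)[0, 1]
            assert out.loc[g, "r"] == pytest.approx(expect)

    def test_zero_variance_flagged_not_zero(self):
        prof = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        m = pd.DataFrame({"a": [5.0], "b": [5.0], "c": [5.0]}, index=["flat"])
        out = metabolite_correlation(m, prof)
        assert not out.loc["flat", "defined"]
        assert np.isnan(out.loc["flat", "r"])

    def test_constant_metabolite_flagged_for_all(self):
        prof = pd.Series([2.0, 2.0, 2.0], index=list("abc"))
        m = pd.DataFrame({"a": [1.0], "b": [4.0], "c": [2.0]}, index=["g"])
        out = metabolite_correlation(m, prof)
        assert not out["defined"].any()

    def test_mismatched_tissues_named(self):
        prof = pd.Series([1.0, 2.0, 3.0], index=["a", "b", "zzz"])
        m = pd.DataFrame(np.ones((1, 3)), columns=list("abc"))
        with pytest.raises(ValueError, match="zzz"):
            metabolite_correlation(m, prof)


class TestScreen:
    def test_noiseless_planted_genes_all_tier_r09(self, noiseless_expression):
        panel, ed = noiseless_expression
        mat = rpkm(ed.counts, ed.gene_lengths, ed.library_sizes)
        scr = candidate_screen(mat, ed.metabolite)
        planted = set(panel.truth.corr_gene_truth)
        tier = scr[scr.tier == "r09"]
        assert planted <= set(tier.index)
        assert (scr.loc[sorted(planted), "r"] >= 1.0 - 1e-9).all()

    def test_inclusive_boundary_at_r_min(self):
        prof = pd.Series([10.0, 1.0, 5.0, 2.0, 8.0, 3.0, 4.0],
                         index=[f"t{i}" for i in range(7)])
        m = pd.DataFrame([prof.values * 2.0], index=["exact"], columns=prof.index)
        scr = candidate_screen(m, prof, r_min=1.0, r_strict=1.0,
                               contrast=("t0", "t1"))
        assert scr.loc["exact", "tier"] == "r09"  # >= semantics at the bound

    def test_contrast_tissue_must_exist(self):
        m = pd.DataFrame(np.ones((1, 3)), columns=list("abc"))
        prof = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        with pytest.raises(ValueError, match="absent"):
            candidate_screen(m, prof, contrast=("a", "nope"))

    def test_empty_matrix_empty_screen(self):
        m = pd.DataFrame(columns=["developing_endosperm", "mature_leaf", "x"])
        prof = pd.Series([1.0, 2.0, 3.0], index=m.columns)
        assert candidate_screen(m, prof).empty

    def test_sorted_by_r_descending(self, noiseless_expression):
        panel, ed = noiseless_expression
        mat = rpkm(ed.counts, ed.gene_lengths, ed.library_sizes)
        scr = candidate_screen(mat, ed.metabolite)
        r = scr["r"].to_numpy()
        assert (np.diff(r) <= 1e-12).all()


class TestPermutationNull:
    def test_shuffled_labels_collapse_tier(self, noiseless_expression):
        panel, ed = noiseless_expression
        mat = rpkm(ed.counts, ed.gene_lengths, ed.library_sizes)
        observed = (candidate_screen(mat, ed.metabolite).tier == "r09").sum()
        null = permutation_null(mat, ed.metabolite, 0.9, 50, seed=3,
                                contrast=("developing_endosperm", "mature_leaf"))
        assert np.median(null) <= 0.2 * observed


class TestClusterTissues:
    def test_leaf_order_is_a_permutation(self, noiseless_expression):
        panel, ed = noiseless_expression
        mat = rpkm(ed.counts, ed.gene_lengths, ed.library_sizes)
        Z, order = cluster_tissues(mat)
        assert sorted(order) == sorted(mat.columns)
        assert Z.shape == (mat.shape[1] - 1, 4)


class TestDdct:
    def test_calibrator_fold_is_one(self):
        ct_t = pd.Series({"leaf": 30.0, "seed": 24.0})
        ct_r = pd.Series({"leaf": 20.0, "seed": 20.0})
        out = ddct_fold_change(ct_t, ct_r, "leaf")
        assert out["leaf"] == pytest.approx(1.0)
        assert out["seed"] == pytest.approx(2.0 ** 6)

    def test_negative_ddct_doubles(self):
        ct_t = pd.Series({"a": 25.0, "b": 24.0})
        ct_r = pd.Series({"a": 20.0, "b": 20.0})
        assert ddct_fold_change(ct_t, ct_r, "a")["b"] == pytest.approx(2.0)

    def test_ddct_three_point_three_two(self):
        ct_t = pd.Series({"a": 20.0, "b": 23.32})
        ct_r = pd.Series({"a": 20.0, "b": 20.0})
        assert ddct_fold_change(ct_t, ct_r, "a")["b"] == pytest.approx(2 ** -3.32)
        assert ddct_fold_change(ct_t, ct_r, "a")["b"] == pytest.approx(0.1, abs=0.0005)

    def test_missing_reference_is_input_error(self):
        ct_t = pd.Series({"a": 20.0, "b": 21.0})
        ct_r = pd.Series({"a": 20.0})
        with pytest.raises(ValueError, match="missing"):
            ddct_fold_change(ct_t, ct_r, "a")


class TestLibraryConservation:
    def test_column_sums_equal_recorded_library_sizes(self, noiseless_expression):
        panel, ed = noiseless_expression
        assert np.allclose(ed.counts.sum(axis=0), ed.library_sizes)
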