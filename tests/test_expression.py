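"""RPKM, size factors, dispersion, the Wald DE test, BH, and clustering."""

import numpy as np
import pandas as pd
import pytest

from lnclink.expression import (
    bh_adjust,
    cluster_expression,
    compute_rpkm,
    de_test,
    differential_expression,
    estimate_dispersion,
    estimate_size_factors,
    select_significant,
    top_branches,
    volcano_coords,
)
from lnclink.models import GeneModel, ValidationError


def _gene(gid, length, biotype="mRNA"):
    return GeneModel(gene_id=gid, chrom="chr1", start=0, end=length,
                     strand="+", biotype=biotype, exon_length_bp=length)


class TestRpkm:
    def test_printed_equation(self, make_counts):
        cm = make_counts([[10, 0, 10, 20]],
                         conditions=["control", "control", "case", "case"],
                         mapped=[1.0, 1.0, 2.0, 1.0])
        rpkm = compute_rpkm(cm, [_gene("g1", 1000)])
        # 10 reads / (1 M mapped * 1 kb) = 10; zero counts stay zero;
        # doubling depth halves RPKM at fixed count
        assert rpkm.iloc[0].tolist() == [10.0, 0.0, 5.0, 20.0]

    def test_order_invariance(self, make_counts):
        cm = make_counts([[10, 20, 30, 40], [1, 2, 3, 4]], mapped=[1, 2, 3, 4])
        genes = [_gene("g1", 500), _gene("g2", 2000)]
        a = compute_rpkm(cm, genes)
        b = compute_rpkm(cm, genes[::-1])
        pd.testing.assert_frame_equal(a, b)
        shuffled = make_counts([[1, 2, 3, 4], [10, 20, 30, 40]],
                               gene_ids=["g2", "g1"], mapped=[1, 2, 3, 4])
        c = compute_rpkm(shuffled, genes)
        pd.testing.assert_frame_equal(a.sort_index(), c.sort_index())

    def test_errors(self, make_counts):
        cm = make_counts([[1, 1, 1, 1]])
        with pytest.raises(ValidationError, match="exon length"):
            compute_rpkm(cm, [])
        cm0 = make_counts([[0, 0, 1, 1]])
        with pytest.raises(ValidationError, match="zero mapped"):
            compute_rpkm(cm0, [_gene("g1", 100)])


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self, make_counts):
        cm = make_counts([[5, 5, 5, 5], [9, 9, 9, 9]])
        assert np.allclose(estimate_size_factors(cm), 1.0)

    def test_exact_doubling(self, make_counts):
        cm = make_counts([[10, 20], [30, 60], [7, 14]],
                         conditions=["control", "case"])
        sf = estimate_size_factors(cm)
        assert np.allclose(sf, [1 / np.sqrt(2), np.sqrt(2)])

    def test_permutation_equivariance(self, make_counts):
        rng = np.random.default_rng(0)
        vals = rng.integers(1, 100, size=(20, 4))
        cm = make_counts(vals)
        perm = [2, 0, 3, 1]
        cm_p = make_counts(vals[:, perm],
                           conditions=[cm.samples.conditions[i] for i in perm])
        assert np.allclose(estimate_size_factors(cm)[perm], estimate_size_factors(cm_p))

    def test_no_all_positive_gene_errors(self, make_counts):
        cm = make_counts([[0, 1, 1, 1], [1, 0, 1, 1]])
        with pytest.raises(ValidationError, match="pseudocount"):
            estimate_size_factors(cm)


class TestDispersion:
    def test_method_of_moments_arithmetic(self, make_counts):
        # within-condition values (10,20,30): m=20, v=100 -> alpha=0.2
        cm = make_counts([[10, 20, 30, 10, 20, 30]],
                         conditions=["control"] * 3 + ["case"] * 3)
        alpha = estimate_dispersion(cm, np.ones(6))
        assert alpha[0] == pytest.approx(0.2)

    def test_constant_replicates_give_zero(self, make_counts):
        cm = make_counts([[7, 7, 7, 7, 7, 7]],
                         conditions=["control"] * 3 + ["case"] * 3)
        assert estimate_dispersion(cm, np.ones(6))[0] == 0.0

    def test_poisson_limit(self, make_counts):
        rng = np.random.default_rng(1)
        vals = rng.poisson(50.0, size=(300, 40))
        cm = make_counts(vals, conditions=["control"] * 20 + ["case"] * 20)
        alpha = estimate_dispersion(cm, np.ones(40))
        assert np.median(alpha) < 0.02


class TestDeTest:
    def test_identical_group_means(self, make_counts):
        cm = make_counts([[10, 20, 30, 10, 20, 30]],
                         conditions=["control"] * 3 + ["case"] * 3)
        tab = de_test(cm, np.ones(6), np.array([0.1]))
        assert tab["log2fc"].iloc[0] == 0.0
        assert tab["p"].iloc[0] == 1.0

    def test_single_replicate_group_rejected(self, make_counts):
        cm = make_counts([[1, 2, 3, 4]], conditions=["control"] * 3 + ["case"])
        with pytest.raises(ValidationError, match="single-replicate"):
            de_test(cm, np.ones(4), np.array([0.1]))

    def test_planted_signal_ranks_above_null(self, default_dataset):
        _genes, _seqs, truth, counts = default_dataset
        tab = differential_expression(counts)
        block = {g for b in truth.corr_blocks for g in b["members"]}
        planted = set(truth.de_genes)
        z_planted = tab.loc[[g for g in tab.index if g in planted], "z"].abs().mean()
        z_null = tab.loc[[g for g in tab.index
                          if g not in planted and g not in block], "z"].abs().mean()
        assert z_planted > 3 * z_null


class TestBH:
    def test_hand_computed_step_up(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_single_p(self):
        assert bh_adjust([0.3]) == pytest.approx([0.3])

    def test_rejects_out_of_range(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.5])
        with pytest.raises(ValidationError):
            bh_adjust([-0.1])

    def test_monotone_in_p(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(size=200)
        padj = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(padj[order]) >= -1e-12).all()


class TestSelection:
    def test_strict_boundary(self):
        tab = pd.DataFrame({"log2fc": [1.0, 1.01], "p": [1e-6, 1e-6],
                            "padj": [1e-6, 1e-6]}, index=["a", "b"])
        sel = select_significant(tab)
        assert not sel.loc["a", "significant"]
        assert sel.loc["b", "significant"] and sel.loc["b", "direction"] == "up"

    def test_toy_table_partition(self):
        tab = pd.DataFrame(
            {"log2fc": [2.0, -3.0, 0.5, 1.5, -1.2],
             "p": [1e-4] * 5,
             "padj": [0.001, 0.01, 0.001, 0.2, 0.04]},
            index=list("abcde"))
        sel = select_significant(tab)
        assert set(sel.index[sel["direction"] == "up"]) == {"a"}
        assert set(sel.index[sel["direction"] == "down"]) == {"b", "e"}
        assert set(sel.index[sel["direction"] == "none"]) == {"c", "d"}
        assert (sel["direction"] != "").all()


def test_volcano_coordinates():
    tab = pd.DataFrame({"log2fc": [1.5, -2.0], "padj": [1.0, 0.01]},
                       index=["a", "b"])
    vc = volcano_coords(tab)
    assert vc.loc["a", "y"] == 0.0
    assert vc.loc["b", "y"] == pytest.approx(2.0)
    assert (vc["x"] == tab["log2fc"]).all()


class TestClustering:
    def test_identical_samples_merge_at_zero(self):
        expr = pd.DataFrame({"s1": [1, 2, 3], "s2": [1, 2, 3], "s3": [9, 1, 4]})
        merges = cluster_expression(expr, axis="samples")
        (a, b, h) = merges[0]
        assert {a, b} == {("s1",), ("s2",)}
        assert h == pytest.approx(0.0, abs=1e-12)

    def test_three_leaves_match_exhaustive_linkage(self):
        rng = np.random.default_rng(3)
        expr = pd.DataFrame(rng.uniform(1, 100, size=(10, 3)),
                            columns=["a", "b", "c"])
        merges = cluster_expression(expr, axis="samples", log_transform=True)
        mat = np.log2(expr.to_numpy().T + 1)
        d = {}
        for i, x in enumerate("abc"):
            for j, y in enumerate("abc"):
                if i < j:
                    d[(x, y)] = 1 - np.corrcoef(mat[i], mat[j])[0, 1]
        first = min(d, key=lambda k: d[k])
        assert set(merges[0][0] + merges[0][1]) == set(first)
        rest = [z for z in "abc" if z not in first]
        expected_h = np.mean([d[tuple(sorted((first[0], rest[0])))],
                              d[tuple(sorted((first[1], rest[0])))]])
        assert merges[1][2] == pytest.approx(expected_h)

    def test_case_control_split_on_planted_data(self, default_dataset):
        genes, _seqs, _truth, counts = default_dataset
        rpkm = compute_rpkm(counts, genes)
        de = differential_expression(counts)
        sig = de.index[de["significant"]]
        merges = cluster_expression(rpkm.loc[sig], axis="samples")
        left, right = top_branches(merges)
        groups = {frozenset(s for s in side) for side in (left, right)}
        assert groups == {frozenset({"ctrl_1", "ctrl_2", "ctrl_3"}),
                          frozenset({"case_1", "case_2", "case_3"})}

    def test_zero_variance_item_warns_not_crashes(self):
        expr = pd.DataFrame({"s1": [1, 1], "s2": [1, 5], "s3": [1, 9]})
        merges = cluster_expression(expr, axis="genes", log_transform=False)
        assert len(merges) == 1 and merges[0][2] == pytest.approx(1.0)
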