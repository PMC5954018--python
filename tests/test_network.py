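"""Co-expression network construction and cross-species overlap."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lnclink.models import OrthologMap, ValidationError
from lnclink.network import (
    build_coexpression_network,
    cross_species_overlap,
    filter_targets_by_de,
    pearson_r,
)


class TestFilterTargets:
    def test_examples(self):
        assert filter_targets_by_de({"a"}, {"b"}) == set()
        assert filter_targets_by_de({"a", "b", "c"}, {"b", "c", "d"}) == {"b", "c"}
        out = filter_targets_by_de({"a", "b"}, {"b"})
        assert len(out) <= 2 and len(out) <= 1


class TestPearson:
    def test_perfect_and_hand_computed(self):
        assert pearson_r([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)
        # product-moment formula by hand: r = 9 / sqrt(84)
        assert pearson_r([1, 2, 3], [1, 2, 4]) == pytest.approx(9 / np.sqrt(84))

    def test_symmetry_and_errors(self):
        x, y = [1.0, 5.0, 2.0, 8.0], [2.0, 1.0, 9.0, 3.0]
        assert pearson_r(x, y) == pytest.approx(pearson_r(y, x))
        with pytest.raises(ValidationError):
            pearson_r([1, 2, 3], [1, 2])
        with pytest.raises(ValidationError):
            pearson_r([1, 2], [1, 2])

    def test_zero_variance_defined_as_zero(self):
        assert pearson_r([1, 1, 1], [1, 2, 3]) == 0.0


def _expr(rows: dict[str, list[float]]) -> pd.DataFrame:
    return pd.DataFrame(rows).T


class TestNetwork:
    def test_planted_blocks_fully_recovered(self, default_dataset):
        genes, _seqs, truth, counts = default_dataset
        from lnclink.expression import compute_rpkm

        rpkm = compute_rpkm(counts, genes)
        cand = [(b["members"][0], b["members"][1]) for b in truth.corr_blocks]
        lncs = {c[0] for c in cand}
        tgts = {c[1] for c in cand}
        _nodes, edges, summary = build_coexpression_network(
            lncs, tgts, rpkm, cand, {}, threshold=0.95)
        assert len(edges) == len(cand)
        assert summary["n_edges"] == len(cand)

    def test_threshold_one_keeps_only_exact_collinearity(self):
        expr = _expr({"l1": [1, 2, 3, 4, 5, 6], "m1": [2, 4, 6, 8, 10, 12],
                      "m2": [1, 2, 3, 4, 5, 7]})
        # r is computed on log2(x+1), so feed values already collinear there
        expr = 2 ** expr - 1
        _n, edges, _s = build_coexpression_network(
            {"l1"}, {"m1", "m2"}, expr, [("l1", "m1"), ("l1", "m2")], {},
            threshold=1.0)
        assert edges == []  # strict: r must exceed 1.0, impossible
        _n, edges, _s = build_coexpression_network(
            {"l1"}, {"m1", "m2"}, expr, [("l1", "m1"), ("l1", "m2")], {},
            threshold=0.999999)
        assert [(u, v) for u, v, _ in edges] == [("l1", "m1")]

    def test_brute_force_equivalence_and_order_invariance(self):
        rng = np.random.default_rng(5)
        ids = [f"l{i}" for i in range(6)] + [f"m{i}" for i in range(8)]
        expr = pd.DataFrame(rng.lognormal(3, 1, size=(14, 6)), index=ids)
        lncs = {i for i in ids if i.startswith("l")}
        tgts = {i for i in ids if i.startswith("m")}
        cand = [(l, m) for l in sorted(lncs) for m in sorted(tgts)]
        threshold = 0.3
        _n, edges, _s = build_coexpression_network(
            lncs, tgts, expr, cand, {}, threshold=threshold)
        log_expr = np.log2(expr + 1)
        expected = set()
        for l in lncs:
            for m in tgts:
                r = np.corrcoef(log_expr.loc[l], log_expr.loc[m])[0, 1]
                if r > threshold:
                    expected.add((l, m))
        assert {(u, v) for u, v, _ in edges} == expected
        # recomputing each reported edge's r from the expression matrix
        for u, v, r in edges:
            assert r == pytest.approx(
                np.corrcoef(log_expr.loc[u], log_expr.loc[v])[0, 1])
            assert r > threshold
        # order invariance
        rng.shuffle(cand)
        _n2, edges2, _s2 = build_coexpression_network(
            lncs, tgts, expr, cand, {}, threshold=threshold)
        assert edges2 == edges

    def test_absolute_mode_keeps_anticorrelated(self):
        expr = _expr({"l1": [1, 2, 3, 4, 5, 6], "m1": [6, 5, 4, 3, 2, 1]})
        expr = 2 ** expr - 1
        _n, signed, _ = build_coexpression_network(
            {"l1"}, {"m1"}, expr, [("l1", "m1")], {}, threshold=0.95)
        assert signed == []
        _n, absolute, _ = build_coexpression_network(
            {"l1"}, {"m1"}, expr, [("l1", "m1")], {}, threshold=0.95, absolute=True)
        assert len(absolute) == 1 and absolute[0][2] < -0.95

    def test_node_attributes_and_degree_summary(self):
        expr = _expr({"l1": [1, 2, 3, 4], "m1": [1, 2, 3, 4], "m2": [1, 2, 3, 4.1]})
        nodes, edges, summary = build_coexpression_network(
            {"l1"}, {"m1", "m2"}, expr, [("l1", "m1"), ("l1", "m2")],
            {"l1": "up", "m1": "down", "m2": "up"}, threshold=0.95)
        assert nodes["l1"] == {"kind": "lncRNA", "direction": "up"}
        assert nodes["m1"] == {"kind": "mRNA", "direction": "down"}
        assert summary["max_targets_per_lncRNA"] == 2
        assert summary["max_lncRNAs_per_target"] == 1

    def test_between_block_false_edges_match_null_rate(self):
        """Independent genes at n = 6 exceed r > 0.95 about as often as the
        null distribution of the correlation coefficient predicts."""
        rng = np.random.default_rng(23)
        n_pairs = 2000
        x = rng.standard_normal((n_pairs, 6))
        y = rng.standard_normal((n_pairs, 6))
        r = np.array([np.corrcoef(a, b)[0, 1] for a, b in zip(x, y)])
        n_false = int((r > 0.95).sum())
        # P(r > 0.95 | rho = 0, n = 6) from the exact t transform
        t = 0.95 * 2 / np.sqrt(1 - 0.95**2)
        p_null = float(stats.t.sf(t, df=4))
        upper = stats.binom.ppf(0.9999, n_pairs, p_null)
        assert n_false <= upper


class TestCrossSpecies:
    def test_identity_map_full_overlap(self):
        res = cross_species_overlap({"a": "up"}, {"a"}, OrthologMap({"a": "a"}))
        assert res["common"].tolist() == [True]

    def test_partial_overlap(self):
        res = cross_species_overlap(
            {"m1": "up", "m2": "down"}, {"H2", "H3"},
            OrthologMap({"m1": "H1", "m2": "H2"}))
        common = res[res["common"]]
        assert common["mouse_gene_id"].tolist() == ["m2"]
        assert common["human_gene_id"].tolist() == ["H2"]
        assert common["mouse_direction"].tolist() == ["down"]

    def test_unmapped_reported_not_dropped(self):
        res = cross_species_overlap({"m1": "up"}, set(), OrthologMap({}))
        assert len(res) == 1
        assert not res["mapped"].iloc[0]
        assert not res["common"].any()
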