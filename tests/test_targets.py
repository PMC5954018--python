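"""Cis pairing, complementarity alignment, duplex energy, E-values, trans hits."""

from functools import lru_cache

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lnclink.models import GeneModel, ValidationError
from lnclink.targets import (
    AlignmentScoring,
    EnergyModel,
    calibrate_evalue,
    complement_align,
    evalue,
    find_cis_targets,
    find_trans_targets,
    gene_gap,
    hybrid_energy,
    intersect_cis_trans,
    reverse_complement,
)


def _gene(gid, start, end, biotype, chrom="chr1", strand="+"):
    return GeneModel(gene_id=gid, chrom=chrom, start=start, end=end,
                     strand=strand, biotype=biotype, exon_length_bp=end - start)


class TestCis:
    def test_gap_arithmetic_against_ten_kb_rule(self):
        lnc = _gene("l", 0, 1000, "lncRNA")
        hit = _gene("m1", 10_999, 12_000, "mRNA")
        far = _gene("m2", 11_000, 12_000, "mRNA")
        pairs = find_cis_targets([lnc], [hit, far])
        assert [(p.lnc_id, p.mrna_id, p.gap_bp) for p in pairs] == [("l", "m1", 9999)]
        # m2 sits at gap exactly 10,000: excluded by the strict inequality
        assert gene_gap(lnc, far) == 10_000

    def test_overlap_counts_as_zero_gap(self):
        lnc = _gene("l", 500, 1500, "lncRNA")
        m = _gene("m", 1000, 3000, "mRNA")
        (p,) = find_cis_targets([lnc], [m])
        assert p.gap_bp == 0

    def test_different_chromosomes_never_pair(self):
        lnc = _gene("l", 0, 1000, "lncRNA")
        m = _gene("m", 500, 1500, "mRNA", chrom="chr2")
        assert find_cis_targets([lnc], [m]) == []

    def test_empty_inputs(self):
        assert find_cis_targets([], []) == []

    def test_brute_force_equivalence_on_random_annotations(self):
        rng = np.random.default_rng(7)
        lncs, mrnas = [], []
        for i in range(40):
            chrom = f"chr{rng.integers(1, 4)}"
            start = int(rng.integers(0, 200_000))
            end = start + int(rng.integers(100, 5000))
            lncs.append(_gene(f"l{i}", start, end, "lncRNA", chrom=chrom))
        for i in range(60):
            chrom = f"chr{rng.integers(1, 4)}"
            start = int(rng.integers(0, 200_000))
            end = start + int(rng.integers(100, 5000))
            mrnas.append(_gene(f"m{i}", start, end, "mRNA", chrom=chrom))
        got = {(p.lnc_id, p.mrna_id, p.gap_bp) for p in find_cis_targets(lncs, mrnas)}
        expected = set()
        for a in lncs:
            for b in mrnas:
                if a.chrom != b.chrom:
                    continue
                gap = max(0, b.start - a.end, a.start - b.end)
                if gap < 10_000:
                    expected.add((a.gene_id, b.gene_id, gap))
        assert got == expected


def _oracle_local_score(a: str, b: str, match=2.0, mismatch=-3.0, gap=-5.0) -> float:
    """Independent recursive definition of the best local alignment score."""

    @lru_cache(maxsize=None)
    def from_pos(i: int, j: int) -> float:
        options = [0.0]
        if i < len(a) and j < len(b):
            s = match if a[i] == b[j] else mismatch
            options.append(s + from_pos(i + 1, j + 1))
        if i < len(a):
            options.append(gap + from_pos(i + 1, j))
        if j < len(b):
            options.append(gap + from_pos(i, j + 1))
        return max(options)

    return max(from_pos(i, j) for i in range(len(a) + 1) for j in range(len(b) + 1))


class TestComplementAlign:
    def test_poly_a_vs_poly_t_full_duplex(self):
        score, span, cols = complement_align("A" * 10, "T" * 10)
        assert score == 20.0
        assert span == (0, 10, 0, 10)
        assert all(x == y == "A" for x, y in cols)

    def test_empty_sequence(self):
        assert complement_align("", "ACGT")[0] == 0.0

    def test_matches_exhaustive_oracle_on_short_pairs(self):
        rng = np.random.default_rng(11)
        bases = np.array(list("ACGT"))
        for _ in range(300):
            la, lb = rng.integers(1, 9), rng.integers(1, 9)
            a = "".join(rng.choice(bases, la))
            b = "".join(rng.choice(bases, lb))
            score, _span, _cols = complement_align(a, b)
            assert score == _oracle_local_score(a, reverse_complement(b))

    def test_role_swap_symmetry(self):
        rng = np.random.default_rng(13)
        bases = np.array(list("ACGT"))
        for _ in range(20):
            a = "".join(rng.choice(bases, 40))
            b = "".join(rng.choice(bases, 60))
            s_ab = complement_align(a, b)[0]
            s_ba = complement_align(b, a)[0]
            assert s_ab == s_ba

    def test_columns_are_consistent_with_score(self):
        rng = np.random.default_rng(17)
        bases = np.array(list("ACGT"))
        sc = AlignmentScoring()
        for _ in range(20):
            a = "".join(rng.choice(bases, 50))
            b = "".join(rng.choice(bases, 50))
            score, _span, cols = complement_align(a, b)
            recomputed = sum(
                sc.gap if "-" in (x, y) else (sc.match if x == y else sc.mismatch)
                for x, y in cols
            )
            assert recomputed == score


class TestHybridEnergy:
    def test_gc_run_passes_threshold(self):
        cols = [("G", "G")] * 10
        assert hybrid_energy(cols) == -30.0

    def test_empty_alignment_zero(self):
        assert hybrid_energy([]) == 0.0

    def test_pair_energies_and_penalties(self):
        model = EnergyModel()
        assert hybrid_energy([("A", "A")], model) == -2.0
        assert hybrid_energy([("T", "T")], model) == -2.0
        assert hybrid_energy([("C", "C")], model) == -3.0
        assert hybrid_energy([("G", "A")], model) == -1.0  # G:U wobble
        assert hybrid_energy([("T", "C")], model) == -1.0
        assert hybrid_energy([("A", "G")], model) == 1.0  # mismatch
        assert hybrid_energy([("A", "-")], model) == 1.0  # gap
        no_wobble = EnergyModel(wobble_enabled=False)
        assert hybrid_energy([("G", "A")], no_wobble) == 1.0

    def test_additivity_of_a_mismatch(self):
        base = [("G", "G")] * 8
        with_mm = base + [("A", "G")]
        with_pair = base + [("A", "A")]
        assert hybrid_energy(with_mm) == hybrid_energy(base) + 1.0
        assert hybrid_energy(with_pair) == hybrid_energy(base) - 2.0


class TestEvalue:
    def test_closed_form(self):
        e = evalue(40.0, 100, 100, lam=0.5, K=0.1)
        assert e == pytest.approx(0.1 * 1e4 * np.exp(-20.0))
        assert e == pytest.approx(2.06e-6, rel=0.01)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(1, 100), st.floats(0.1, 10))
    def test_monotone_decreasing_in_score(self, s, delta):
        assert evalue(s + delta, 500, 500, 0.5, 0.1) < evalue(s, 500, 500, 0.5, 0.1)

    def test_calibration_validation(self):
        with pytest.raises(ValidationError, match=">= 500"):
            calibrate_evalue([1.0] * 100, 100, 100)
        with pytest.raises(ValidationError, match="degenerate"):
            calibrate_evalue([5.0] * 600, 100, 100)

    def test_planted_exact_30mer_is_significant(self):
        """An exact 30-nt complement in 1-kb random sequences passes e < 1e-5."""
        rng = np.random.default_rng(1729)
        bases = np.array(list("ACGT"))
        mk = lambda n: "".join(rng.choice(bases, n))
        mrnas = {f"m{i}": mk(1000) for i in range(12)}
        lncs = {f"l{i}": mk(1000) for i in range(12)}
        seg = mrnas["m0"][100:130]
        lncs["l0"] = lncs["l0"][:200] + reverse_complement(seg) + lncs["l0"][230:]
        hits = find_trans_targets(lncs, mrnas, seed=1729)
        assert [(h.lnc_id, h.mrna_id) for h in hits] == [("l0", "m0")]
        assert hits[0].evalue < 1e-5 and hits[0].energy_G < -20


class TestFindTrans:
    def test_empty_lnc_list(self):
        assert find_trans_targets({}, {"m": "ACGT" * 100}) == []

    def test_missing_sequence_names_gene(self):
        with pytest.raises(ValidationError, match="l1"):
            find_trans_targets({"l1": ""}, {"m": "ACGT" * 100})

    def test_retained_hits_respect_both_thresholds(self, default_dataset):
        genes, seqs, truth, _counts = default_dataset
        lnc_ids = sorted({p["lnc"] for p in truth.trans_pairs})
        lncs = {g: seqs[g] for g in lnc_ids}
        mrnas = {g.gene_id: seqs[g.gene_id] for g in genes if g.biotype == "mRNA"}
        hits = find_trans_targets(lncs, mrnas, seed=1729)
        assert hits, "planted trans pairs should produce hits"
        for h in hits:
            assert h.evalue < 1e-5
            assert h.energy_G < -20
        evs = [h.evalue for h in hits]
        assert evs == sorted(evs)


class TestIntersect:
    def test_disjoint(self):
        from lnclink.models import CisPair, TransHit

        cis = [CisPair("a", "x", 5)]
        trans = [TransHit("b", "y", 60, -70, 1e-9, (0, 1, 0, 1))]
        out = intersect_cis_trans(cis, trans)
        assert out["n_lncRNAs"] == out["n_targets"] == out["n_connections"] == 0

    def test_set_arithmetic_example(self):
        from lnclink.models import CisPair, TransHit

        cis = [CisPair("a", "x", 5), CisPair("a", "y", 5)]
        trans = [TransHit("a", "x", 60, -70, 1e-9, (0, 1, 0, 1)),
                 TransHit("b", "x", 60, -70, 1e-9, (0, 1, 0, 1))]
        out = intersect_cis_trans(cis, trans)
        assert out["lncRNAs"] == ["a"]
        assert out["targets"] == ["x"]
        assert out["connections"] == [("a", "x")]
        assert out["n_connections"] <= min(len(cis), len(trans))
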