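"""Skews, codon degeneracy, strand-symmetry tests, reversal decisions."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from Bio.Seq import Seq

from mitorearr.composition import (DegenerateSiteSet, classify_codon_degeneracy,
                                   compare_skew_groups, decide_reversal,
                                   extract_degenerate_sets,
                                   per_gene_skew_table, skew,
                                   strand_symmetry_test)

# ---------------------------------------------------------------------------
# independent transcription of the vertebrate mitochondrial code families
# ---------------------------------------------------------------------------

_NNN4_FAMILIES = ("CT", "GT", "TC", "CC", "AC", "GC", "CG", "GG")
_NNR2 = {"TTA", "TTG", "ATA", "ATG", "TGA", "TGG",
         "CAA", "CAG", "AAA", "AAG", "GAA", "GAG"}
_NNY2 = {"TTT", "TTC", "ATT", "ATC", "TAT", "TAC", "CAT", "CAC",
         "AAT", "AAC", "GAT", "GAC", "TGT", "TGC", "AGT", "AGC"}
_STOPS = {"TAA", "TAG", "AGA", "AGG"}


def oracle_degeneracy(codon):
    if codon in _STOPS:
        return "other"
    if codon[:2] in _NNN4_FAMILIES:
        return "NNN4"
    if codon in _NNR2:
        return "NNR2"
    if codon in _NNY2:
        return "NNY2"
    return "other"


class TestDegeneracy:
    def test_all_64_codons_against_code_table_transcription(self):
        bases = "ACGT"
        for c in (a + b + c for a in bases for b in bases for c in bases):
            assert classify_codon_degeneracy(c) == oracle_degeneracy(c), c

    @pytest.mark.parametrize("codon,want", [
        ("CTC", "NNN4"),   # Leu, CTN family
        ("AAA", "NNR2"),   # Lys
        ("TGA", "NNR2"),   # Trp in the vertebrate mito code
        ("AGA", "other"),  # stop in the vertebrate mito code
        ("ATA", "NNR2"),   # Met (ATR)
        ("ANA", "other"),  # ambiguity
    ])
    def test_named_examples(self, codon, want):
        assert classify_codon_degeneracy(codon) == want


class TestSkew:
    def test_formula_examples(self):
        assert skew("TTAA").AT_skew == 0
        assert skew("AAAT").AT_skew == pytest.approx(0.5)
        assert skew("GGC").GC_skew == pytest.approx(1 / 3)
        assert skew("NNNN").AT_skew is None

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACGT", min_size=4, max_size=200))
    def test_complement_antisymmetry(self, s):
        r = skew(s)
        rc = skew(str(Seq(s).reverse_complement()))
        if r.AT_skew is not None:
            assert rc.AT_skew == pytest.approx(-r.AT_skew)
        if r.GC_skew is not None:
            assert rc.GC_skew == pytest.approx(-r.GC_skew)
        if r.AT_skew is not None:
            assert -1 <= r.AT_skew <= 1

    def test_position_counts_partition_gene(self, ancestor_genome):
        table = per_gene_skew_table([ancestor_genome])
        cox1 = table[(table.unit == "cox1")]
        full = cox1[cox1.partition == "full"].iloc[0]
        by_pos = cox1[cox1.partition.isin(["pos1", "pos2", "pos3"])]
        for b in "ACGT":
            assert by_pos[f"n{b}"].sum() == full[f"n{b}"]

    def test_counts_match_generator_tallies(self, ancestor_genome):
        table = per_gene_skew_table([ancestor_genome])
        cob = [f for f in ancestor_genome.features if f.label == "cob"][0]
        seq = ancestor_genome.feature_sequence(cob)
        row = table[(table.unit == "cob") & (table.partition == "full")].iloc[0]
        assert row.nA == seq.count("A") and row.nT == seq.count("T")


class TestDegenerateSets:
    def test_toy_gene_hand_count(self):
        nnn4, nn2 = extract_degenerate_sets({"g": "CTACTGAAA"})
        assert nnn4.counts == {"A": 1, "C": 0, "G": 1, "T": 0}
        assert nn2.counts == {"A": 1, "C": 0, "G": 0, "T": 0}
        assert (nnn4.n_codons, nn2.n_codons) == (2, 1)

    def test_exclusion_removes_exactly_that_gene(self):
        genes = {"g1": "CTACTG", "nad1": "CTT"}
        with_all, _ = extract_degenerate_sets(genes)
        without, _ = extract_degenerate_sets(genes, exclude=("nad1",))
        assert with_all.counts["T"] - without.counts["T"] == 1
        assert without.excluded_genes == ["nad1"]


class TestSymmetryTest:
    def test_balanced_counts(self):
        s = DegenerateSiteSet("NNN4", {"A": 500, "T": 500, "G": 10, "C": 10},
                              1020)
        at, gc = strand_symmetry_test(s)
        assert at.statistic == 0 and at.p_value == pytest.approx(1.0)
        assert not at.rejected

    def test_extreme_counts_rejected(self):
        s = DegenerateSiteSet("NNN4", {"A": 100, "T": 0, "G": 5, "C": 5}, 110)
        at, _ = strand_symmetry_test(s)
        assert at.statistic == pytest.approx(10.0) and at.rejected

    def test_type_one_error_calibration(self):
        """Rejection rate under a symmetric binomial null is ~ alpha."""
        rng = np.random.default_rng(12)
        n = 500
        a = rng.binomial(n, 0.5, size=10_000)
        z = (2 * a - n) / np.sqrt(n)
        from scipy import stats
        p = 2 * stats.norm.sf(np.abs(z))
        rate = float((p < 0.05).mean())
        assert abs(rate - 0.05) <= 0.01


class TestCompareSkewGroups:
    def test_identical_groups(self):
        t, p = compare_skew_groups([0.5, 0.5, 0.5], [0.5, 0.5, 0.5])
        assert p == 1.0

    def test_operates_on_absolute_values(self):
        t, p = compare_skew_groups([0.5, 0.5, 0.5], [-0.5, -0.5, -0.5])
        assert p == 1.0

    def test_matches_pooled_variance_formula(self):
        rng = np.random.default_rng(7)
        a = np.abs(rng.normal(0.3, 0.05, 12))
        b = np.abs(rng.normal(0.4, 0.05, 9))
        t, p = compare_skew_groups(a, b)
        na, nb = len(a), len(b)
        sp2 = (((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1))
               / (na + nb - 2))
        t_ref = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))
        from scipy import stats
        p_ref = 2 * stats.t.sf(abs(t_ref), na + nb - 2)
        assert t == pytest.approx(t_ref, abs=1e-10)
        assert p == pytest.approx(p_ref, abs=1e-10)


def _sites(a, c, g, t, cls="NNN4"):
    return DegenerateSiteSet(cls, {"A": a, "C": c, "G": g, "T": t},
                             a + c + g + t)


class TestReversalDecision:
    def test_unrearranged_bias_is_none(self):
        # strong bias with the expected signs: A > T, C > G
        dec = decide_reversal("g", _sites(600, 500, 200, 400),
                              _sites(300, 250, 100, 200, "NNR2_NNY2"))
        assert dec.decision == "none"

    def test_full_reversal(self):
        # both classes: signs opposite to expectation and both pairs rejected
        dec = decide_reversal("g", _sites(400, 200, 500, 600),
                              _sites(200, 100, 250, 300, "NNR2_NNY2"))
        assert dec.decision == "full"
        assert all(dec.sign_opposed.values())

    def test_partial_reversal(self):
        # AT flipped in both classes, GC still in the expected orientation
        dec = decide_reversal("g", _sites(400, 500, 200, 600),
                              _sites(200, 250, 100, 300, "NNR2_NNY2"))
        assert dec.decision == "partial"
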