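"""Spacer extraction, remnant scanning, peptide check, classification."""

import numpy as np
import pytest
from Bio.Seq import Seq

from mitorearr.genome_io import AnnotatedGenome, FeatureRecord
from mitorearr.simulate import make_null_spacers
from mitorearr.spacers import (ScanThresholds, Spacer, classify_spacers,
                               extract_spacers, peptide_check, scan_spacer)


def _genome(seq, feats):
    return AnnotatedGenome(identifier="g", sequence=seq, features=[
        FeatureRecord(lab, strand, s, e, ftype)
        for lab, strand, s, e, ftype in feats])


class TestExtractSpacers:
    def test_contiguous_annotation_yields_none(self):
        g = _genome("A" * 200, [("cox1", "H", 0, 100, "PCG"),
                                ("D", "H", 100, 170, "tRNA"),
                                ("cox2", "H", 170, 200, "PCG")])
        assert extract_spacers(g) == []

    def test_planted_gap_with_flanks(self):
        g = _genome("A" * 100 + "C" * 60 + "G" * 40,
                    [("E", "L", 0, 100, "tRNA"), ("T", "H", 160, 200, "tRNA")])
        sp = extract_spacers(g, min_length=10)
        assert len(sp) >= 1
        first = sp[0]
        assert (first.flank_upstream, first.flank_downstream) == ("E", "T")
        assert first.sequence == "C" * 60 and first.length == 60

    def test_origin_spanning_spacer(self):
        g = _genome("C" * 20 + "A" * 160 + "C" * 20,
                    [("cox1", "H", 20, 180, "PCG")])
        sp = extract_spacers(g, min_length=10)
        assert len(sp) == 1
        assert sp[0].sequence == "C" * 40
        assert sp[0].end > g.length  # wrapped coordinates

    def test_duplicate_flank_names_carry_copy_tags(self):
        g = _genome("A" * 300,
                    [("T", "H", 0, 70, "tRNA"), ("P", "L", 70, 140, "tRNA"),
                     ("T", "H", 200, 270, "tRNA")])
        sp = extract_spacers(g, min_length=10)
        assert sp[0].flank_upstream == "P"
        assert sp[0].flank_downstream == "T_b"


def _library(rng):
    genes = {}
    for name, n in (("cob", 600), ("nad6", 300), ("CoRe", 500), ("T", 70)):
        genes[name] = "".join(rng.choice(list("ACGT"), size=n))
    return genes


class TestScanSpacer:
    def test_planted_exact_cob_three_prime_remnant(self):
        """A 34-nt exact copy of the cob 3' end is the top hit."""
        rng = np.random.default_rng(1)
        lib = _library(rng)
        remnant = lib["cob"][-34:]
        seq = ("".join(rng.choice(list("ACGT"), 25)) + remnant
               + "".join(rng.choice(list("ACGT"), 25)))
        sp = Spacer("g", "E", "T_b", 0, len(seq), seq)
        hits = scan_spacer(sp, lib)
        assert hits and hits[0].target_gene == "cob"
        assert hits[0].identity == 100.0
        # the random flank may extend the exact match by chance
        assert hits[0].alignment_length >= 34
        assert hits[0].target_region == "3'-terminal"
        assert hits[0].strand == "H"

    def test_reverse_complement_remnant_found_on_l_strand(self):
        rng = np.random.default_rng(2)
        lib = _library(rng)
        remnant = str(Seq(lib["cob"][100:140]).reverse_complement())
        sp = Spacer("g", "x", "y", 0, 40, remnant)
        hits = scan_spacer(sp, lib)
        assert hits and hits[0].target_gene == "cob"
        assert hits[0].strand == "L"

    def test_empty_library_errors(self):
        with pytest.raises(ValueError, match="empty"):
            scan_spacer(Spacer("g", "x", "y", 0, 5, "ACGTA"), {})

    def test_self_alignment_is_maximal(self):
        rng = np.random.default_rng(3)
        lib = _library(rng)
        sp = Spacer("g", "x", "y", 0, 80, lib["CoRe"][200:280])
        hits = scan_spacer(sp, lib)
        assert hits[0].target_gene == "CoRe" and hits[0].identity == 100.0

    def test_sensitivity_and_false_positives(self):
        """Planted remnants >= 20 nt at <= 10% divergence: all found;
        length-matched nulls: <= 1% hit rate."""
        rng = np.random.default_rng(4)
        lib = _library(rng)
        detected = 0
        n_trials = 40
        for _ in range(n_trials):
            gene = ("cob", "nad6", "CoRe")[rng.integers(3)]
            L = int(rng.integers(20, 61))
            start = int(rng.integers(0, len(lib[gene]) - L))
            rem = list(lib[gene][start:start + L])
            for p in rng.choice(L, size=int(0.1 * L), replace=False):
                rem[p] = rng.choice([b for b in "ACGT" if b != rem[p]])
            seq = ("".join(rng.choice(list("ACGT"), 20)) + "".join(rem)
                   + "".join(rng.choice(list("ACGT"), 20)))
            hits = scan_spacer(Spacer("g", "x", "y", 0, len(seq), seq), lib)
            detected += any(h.target_gene == gene for h in hits)
        assert detected == n_trials
        fp = sum(bool(scan_spacer(sp, lib))
                 for sp in make_null_spacers(60, 100, seed=5))
        assert fp <= 1


class TestPeptideCheck:
    def test_in_frame_remnant_translates_identically(self):
        rng = np.random.default_rng(6)
        lib = _library(rng)
        gene = "ATG" + "".join(
            rng.choice(["CTT", "GCA", "ACC", "GGA", "TCA"], size=60)) + "TAA"
        lib["cob"] = gene
        remnant = gene[30:78]  # in frame, 16 codons
        sp = Spacer("g", "x", "y", 0, len(remnant), remnant)
        hit = scan_spacer(sp, lib)[0]
        pm = peptide_check(hit, gene_sequence=gene)
        assert pm["identical_run"] == len(pm["remnant_peptide"]) == 16

    def test_nonsynonymous_change_splits_run(self):
        rng = np.random.default_rng(7)
        gene = "ATG" + "CTT" * 30 + "TAA"
        remnant = list(gene[30:75])  # 15 Leu codons
        remnant[22] = "G"  # CTT -> CGT (Leu -> Arg) in codon 8
        sp = Spacer("g", "x", "y", 0, 45, "".join(remnant))
        lib = {"cob": gene}
        hit = scan_spacer(sp, lib, ScanThresholds())[0]
        pm = peptide_check(hit, gene_sequence=gene)
        assert pm["identical_run"] == 7

    def test_non_coding_target_has_no_peptide(self):
        hit_like = scan_spacer(
            Spacer("g", "x", "y", 0, 30, "ACGT" * 8), {"T": "ACGT" * 20},
            ScanThresholds(min_score=1, min_length=1, min_identity=0,
                           exact_min=1))
        assert peptide_check(hit_like[0], gene_sequence=None) is None


class TestClassification:
    def test_planted_remnant_classified_gr_isp(self):
        rng = np.random.default_rng(8)
        cob = "".join(rng.choice(list("ACGT"), 300))
        spacer_seq = cob[250:] + "".join(rng.choice(list("ACGT"), 20))
        seq = cob + spacer_seq + "".join(rng.choice(list("ACGT"), 70))
        g = _genome(seq, [("cob", "H", 0, 300, "PCG"),
                          ("T", "H", 370, 440, "tRNA")])
        out = classify_spacers([g], event_losses={"g": {"cob"}})
        gr = [c for c in out if c.spacer_class == "GR_ISP"]
        assert gr and gr[0].hits[0].target_gene == "cob"
        assert gr[0].corroborates == ["cob"]

    def test_random_spacer_classified_std_isp(self):
        rng = np.random.default_rng(9)
        seq = ("".join(rng.choice(list("ACGT"), 300))
               + "".join(rng.choice(list("ACGT"), 80))
               + "".join(rng.choice(list("ACGT"), 70)))
        g = _genome(seq, [("cob", "H", 0, 300, "PCG"),
                          ("T", "H", 380, 450, "tRNA")])
        out = classify_spacers([g])
        assert all(c.spacer_class == "STD_ISP" for c in out)
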