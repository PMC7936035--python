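"""Genome / tree / report I-O: dialects, synonyms, coordinates, round trips."""

import numpy as np
import pytest

from mitorearr.genome_io import (AnnotatedGenome, FeatureRecord, ParseError,
                                 convert_coordinates, read_feature_table,
                                 read_newick, write_feature_table,
                                 write_newick, write_report)

TSV = """label\tstrand\tstart\tend\ttype
COX1\tH\t0\t60\tPCG
tRNA-Asp\tH\t60\t130\ttRNA
D-loop\tH\t130\t200\tcontrol_region
"""


@pytest.fixture
def genome_file(tmp_path):
    p = tmp_path / "g.tsv"
    p.write_text(TSV)
    return p


class TestFeatureTable:
    def test_synonyms_normalized(self, genome_file):
        g = read_feature_table(genome_file, sequence="A" * 200)
        assert [f.label for f in g.features] == ["cox1", "D", "CoRe"]
        assert g.features[2].feature_type == "control_region"

    def test_roundtrip_bit_exact(self, genome_file, tmp_path):
        g = read_feature_table(genome_file, sequence="A" * 200)
        out = tmp_path / "out.tsv"
        write_feature_table(g, out)
        g2 = read_feature_table(out, sequence="A" * 200)
        assert [(f.label, f.strand, f.start, f.end, f.feature_type)
                for f in g.features] == \
               [(f.label, f.strand, f.start, f.end, f.feature_type)
                for f in g2.features]

    def test_malformed_coordinates_name_line(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("cox1\tH\tzero\t60\tPCG\n")
        with pytest.raises(ParseError, match="bad.tsv:1"):
            read_feature_table(p, sequence="A" * 100)

    def test_duplicate_feature_errors(self, tmp_path):
        p = tmp_path / "dup.tsv"
        p.write_text("cox1\tH\t0\t60\tPCG\ncox1\tH\t0\t60\tPCG\n")
        with pytest.raises(ParseError, match="duplicate"):
            read_feature_table(p, sequence="A" * 100)

    def test_origin_spanning_feature(self):
        g = AnnotatedGenome(
            identifier="g", sequence="ACGTACGTAC",
            features=[FeatureRecord("CoRe", "H", 8, 12, "control_region")])
        feat = g.features[0]
        assert feat.origin_spanning and feat.length == 4
        assert g.feature_sequence(feat) == "ACAC"

    def test_one_based_closed_roundtrip(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            start = int(rng.integers(0, 1000))
            end = start + int(rng.integers(1, 500))
            there = convert_coordinates(start, end, "zero_half_open",
                                        "one_closed")
            back = convert_coordinates(*there, "one_closed", "zero_half_open")
            assert back == (start, end)
            assert there[1] - there[0] + 1 == end - start

    def test_one_based_dialect_read(self, tmp_path):
        p = tmp_path / "one.tsv"
        p.write_text("cox1\tH\t1\t60\tPCG\n")
        g = read_feature_table(p, sequence="A" * 100, coords="one_closed")
        assert (g.features[0].start, g.features[0].end) == (0, 60)


class TestGenBankFlat:
    def test_read_genbank_record(self, tmp_path):
        from Bio.Seq import Seq
        from Bio.SeqFeature import SeqFeature, SimpleLocation
        from Bio.SeqRecord import SeqRecord
        from Bio import SeqIO

        rng = np.random.default_rng(2)
        seq = "".join(rng.choice(list("ACGT"), size=300))
        rec = SeqRecord(Seq(seq), id="testmito", name="testmito",
                        description="synthetic mitogenome fragment",
                        annotations={"molecule_type": "DNA",
                                     "topology": "circular"})
        rec.features = [
            SeqFeature(SimpleLocation(0, 90, 1), type="CDS",
                       qualifiers={"gene": ["COX1"]}),
            SeqFeature(SimpleLocation(90, 160, 1), type="tRNA",
                       qualifiers={"product": ["tRNA-Asp"]}),
            SeqFeature(SimpleLocation(160, 250, -1), type="CDS",
                       qualifiers={"gene": ["ND6"]}),
            SeqFeature(SimpleLocation(250, 300, 1), type="D-loop"),
        ]
        path = tmp_path / "test.gb"
        SeqIO.write([rec], str(path), "genbank")

        g = read_feature_table(path, dialect="genbank_flat")
        assert g.sequence == seq
        assert [(f.label, f.strand, f.start, f.end) for f in g.features] == [
            ("cox1", "H", 0, 90), ("D", "H", 90, 160),
            ("nad6", "L", 160, 250), ("CoRe", "H", 250, 300)]
        assert g.features[2].feature_type == "PCG"


class TestNewick:
    def test_basic_topology(self):
        t = read_newick("((A,B),C);")
        assert len(t.leaf_nodes()) == 3
        assert len(t.seed_node.child_nodes()) == 2

    def test_roundtrip_topology(self, tmp_path):
        t = read_newick("((A,B),(C,D));")
        out = tmp_path / "t.nwk"
        write_newick(t, out)
        t2 = read_newick(str(out))
        assert ({frozenset(l.taxon.label for l in n.leaf_iter())
                 for n in t.preorder_node_iter()}
                == {frozenset(l.taxon.label for l in n.leaf_iter())
                    for n in t2.preorder_node_iter()})

    def test_unknown_tip_validation(self):
        with pytest.raises(ParseError, match="ZZZ"):
            read_newick("((A,ZZZ),C);", genome_ids={"A", "B", "C"})


class TestReports:
    def test_empty_table_header_only(self, tmp_path):
        out = tmp_path / "r.tsv"
        write_report({"empty": []}, out, format="tsv")
        assert out.read_text().splitlines()[0] == "# empty"

    def test_json_roundtrip(self, tmp_path):
        import json

        tables = {"counts": [{"gene": "cox1", "n": 3}],
                  "nested": {"a": [1, 2, 3]}}
        out = tmp_path / "r.json"
        write_report(tables, out, format="json")
        assert json.loads(out.read_text()) == tables

    def test_event_path_serializes(self, tmp_path):
        import json

        from mitorearr.fixtures import NOTO1GO, VERTGO
        from mitorearr.inference import infer_events

        path = infer_events(VERTGO, NOTO1GO, max_depth=2)[0]
        out = tmp_path / "p.json"
        write_report({"path": path}, out, format="json")
        data = json.loads(out.read_text())["path"]
        assert data["events"][0]["kind"] == "tdrl"
        assert data["cost"] == 1
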