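"""Canonical gene-order model: normal form, equality, slices, fixtures."""

import numpy as np
import pytest

from mitorearr.fixtures import (CHAMGO, DISSOGO, GYMNGO, NAMED_ORDERS, NOTO1GO,
                                NOTO2GO, NOTO3GO, NOTOTHENIID_TIPS, RACOGO,
                                TREMAGO, VERTGO)
from mitorearr.gene_order import (GeneOrder, GeneOrderError, distinct_orders,
                                  extract_gene_order, orders_equal,
                                  parse_notation, region_slice)


def rotate(order, k):
    e = order.elements
    return GeneOrder(e[k:] + e[:k], circular=True)


def mirror(order):
    from mitorearr.gene_order import _mirror
    return GeneOrder(_mirror(order.elements), circular=True)


class TestCanonicalize:
    @pytest.mark.parametrize("k", [0, 1, 5, 17, 38])
    def test_rotation_invariance(self, k):
        assert orders_equal(rotate(VERTGO, k), VERTGO)

    def test_idempotence(self):
        once = rotate(VERTGO, 7).canonicalize()
        assert once.canonicalize().elements == once.elements

    def test_mirror_complement_reads_as_same_molecule(self):
        # circular DNA has no intrinsic reading side
        for k in (0, 3, 20):
            assert orders_equal(mirror(rotate(VERTGO, k)), VERTGO)
        assert orders_equal(mirror(TREMAGO), TREMAGO)

    def test_all_readings_share_one_normal_form(self):
        # brute force over every rotation of both readings
        n = len(NOTO1GO.elements)
        canon = NOTO1GO.canonicalize().elements
        for k in range(n):
            assert rotate(NOTO1GO, k).canonicalize().elements == canon
            assert mirror(rotate(NOTO1GO, k)).canonicalize().elements == canon

    def test_missing_cox1_requires_fallback(self):
        partial = GeneOrder((("rrnS", 1), ("V", 1), ("rrnL", 1)))
        with pytest.raises(GeneOrderError):
            partial.canonicalize()
        out = partial.canonicalize(start="rrnS")
        assert out.partial and out.elements[0] == ("rrnS", 1)


class TestEquality:
    def test_noto2_noto3_differ_by_core1(self):
        assert not orders_equal(NOTO2GO, NOTO3GO)
        assert len(NOTO2GO.elements) == len(NOTO3GO.elements) + 1

    def test_copy_tags_do_not_affect_equality(self):
        tagged = parse_notation(
            NOTO1GO.canonicalize().notation())  # notation carries (a)/(b)/(1)
        assert orders_equal(tagged, NOTO1GO)

    def test_notation_roundtrip(self):
        for order in NAMED_ORDERS.values():
            assert orders_equal(parse_notation(order.canonicalize().notation()),
                                order)


class TestDistinctOrders:
    def test_eight_nototheniid_gene_orders(self):
        orders = [NAMED_ORDERS[g] for g in NOTOTHENIID_TIPS.values()]
        n, classes = distinct_orders(orders)
        assert n == 8

    def test_copies_collapse(self):
        n, _ = distinct_orders([rotate(VERTGO, k) for k in range(5)])
        assert n == 1

    def test_random_distinct_permutations(self):
        rng = np.random.default_rng(5)
        labels = ["cox1", "nad2", "T", "P", "CoRe", "E"]
        seen, orders = set(), []
        while len(orders) < 6:
            perm = ["cox1"] + list(rng.permutation(labels[1:]))
            signs = [1] + [int(s) for s in rng.choice([1, -1], size=5)]
            key = tuple(zip(perm, signs))
            if key not in seen:
                seen.add(key)
                orders.append(GeneOrder(key))
        n, _ = distinct_orders(orders)
        assert n == len(orders)


class TestRegionSlice:
    def test_vertgo_hotspot(self):
        sl = region_slice(VERTGO, "nad5", "F")
        assert sl.notation() == "nad5,-nad6,-E,cob,T,-P,CoRe,F"

    def test_noto1_hotspot(self):
        sl = region_slice(NOTO1GO, "nad5", "F")
        assert sl.notation() == ("nad5,T(a),-P(a),CoRe(1),-nad6,-E,cob,"
                                 "T(b),-P(b),CoRe(2),F")

    def test_single_element_slice(self):
        assert region_slice(VERTGO, "cob", "cob").notation() == "cob"

    def test_absent_label_errors(self):
        with pytest.raises(GeneOrderError):
            region_slice(VERTGO, "nad5", "nope")

    def test_fixture_hotspots_mutually_distinct(self):
        slices = [region_slice(o, "nad5", "F").elements
                  for o in (VERTGO, NOTO1GO, NOTO2GO, NOTO3GO, DISSOGO,
                            TREMAGO, CHAMGO, GYMNGO, RACOGO)]
        assert len(set(slices)) == len(slices)

    def test_orders_equal_vertgo_outside_hotspot_except_tremago(self):
        for order in (NOTO1GO, NOTO2GO, NOTO3GO, DISSOGO, CHAMGO, GYMNGO,
                      RACOGO):
            assert (region_slice(order, "F", "nad5").elements
                    == region_slice(VERTGO, "F", "nad5").elements)
        assert (region_slice(TREMAGO, "M", "nad5").elements
                == region_slice(VERTGO, "M", "nad5").elements)


class TestExtractGeneOrder:
    def test_simulated_ancestor_is_vertgo(self, ancestor_genome):
        assert orders_equal(extract_gene_order(ancestor_genome), VERTGO)

    def test_partial_genome_fallback(self, ancestor_genome):
        class Partial:
            identifier = "partial"
            features = [f for f in ancestor_genome.features
                        if f.label != "cox1"]

        go = extract_gene_order(Partial(), fallback_start="rrnS")
        assert go.partial and go.elements[0][0] == "rrnS"
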