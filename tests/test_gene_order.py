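"""Canonical circular orders, arrangement typing, diffs, breakpoints."""

import numpy as np
import pytest

from anomito.gene_order import (CanonicalizationError, GeneOrder,
                                adjacency_set, breakpoint_distance,
                                canonicalize, diff_vs_reference,
                                load_reference, partition_types,
                                read_gene_orders, write_gene_orders)

GENES = ["cox1", "cox2", "nad1", "nad2", "trnA", "trnI", "trnM", "trnD",
         "trnW", "trnY", "trnQ", "rrnL", "rrnS", "atp6", "cob"]


def random_order(rng: np.random.Generator, k: int,
                 accession: str = "R") -> GeneOrder:
    genes = list(rng.permutation(GENES[:k]))
    return GeneOrder(accession,
                     tuple(("+" if rng.random() < 0.6 else "-") + g
                           for g in genes))


def all_equivalent_forms(order: tuple[str, ...]):
    """Every rotation and strand-reflection of a circular signed order."""
    def neg(g):
        return "+" + g[1:] if g.startswith("-") else "-" + g[1:]
    forms = []
    n = len(order)
    for o in (order, tuple(neg(g) for g in reversed(order))):
        for r in range(n):
            forms.append(o[r:] + o[:r])
    return forms


class TestCanonicalize:
    def test_rotation_to_cox1(self):
        o = GeneOrder("a", ("+trnW", "+cox1", "-trnY"))
        assert canonicalize(o).order == ("+cox1", "-trnY", "+trnW")

    def test_reflection_when_cox1_on_minus_strand(self):
        o = GeneOrder("a", ("-cox1", "+trnY", "-trnW"))
        assert canonicalize(o).order == ("+cox1", "+trnW", "-trnY")

    def test_idempotent(self):
        o = GeneOrder("a", ("+cox1", "-trnQ", "+nad2"))
        assert canonicalize(canonicalize(o)).order == canonicalize(o).order

    def test_missing_cox1_raises(self):
        with pytest.raises(CanonicalizationError):
            canonicalize(GeneOrder("a", ("+trnW", "-trnY")))

    def test_unique_form_starting_at_plus_cox1_over_all_equivalents(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            o = random_order(rng, 8)
            canon = canonicalize(o).order
            starts = [f for f in all_equivalent_forms(o.order)
                      if f[0] == "+cox1"]
            assert len(starts) == 1 and starts[0] == canon


class TestPartitionTypes:
    def test_three_identical_one_distinct(self):
        base = ("+cox1", "+trnA", "-trnW")
        orders = [GeneOrder(f"a{i}", base) for i in range(3)]
        orders.append(GeneOrder("b", ("+cox1", "-trnW", "+trnA")))
        types = partition_types(orders)
        assert len(types) == 2
        assert sorted(len(t.members) for t in types) == [1, 3]

    def test_planted_classes_recovered(self):
        rng = np.random.default_rng(3)
        classes = [random_order(rng, 10, f"c{i}").order for i in range(7)]
        # make circular-rotated/reflected members of each class
        orders = []
        for i, cls in enumerate(classes):
            for j, form in enumerate(all_equivalent_forms(cls)[:3]):
                orders.append(GeneOrder(f"m{i}_{j}", form))
        types = partition_types(orders)
        expected = len({canonicalize(GeneOrder("x", c)).order
                        for c in classes})
        assert len(types) == expected

    def test_membership_invariant_under_input_permutation(self):
        rng = np.random.default_rng(4)
        orders = [random_order(rng, 8, f"a{i}") for i in range(10)]
        t1 = partition_types(orders)
        t2 = partition_types(orders[::-1])
        sets1 = {frozenset(t.members) for t in t1}
        sets2 = {frozenset(t.members) for t in t2}
        assert sets1 == sets2


class TestDiffVsReference:
    REF = load_reference("paper")

    def test_identical_orders_empty_diff(self):
        diff = diff_vs_reference(self.REF, self.REF)
        assert diff.is_empty
        assert diff.conserved_blocks[0] == self.REF.order

    def test_swapped_adjacent_trnI_trnM_reported_translocated(self):
        order = list(self.REF.order)
        i, m = order.index("+trnI"), order.index("+trnM")
        order[i], order[m] = order[m], order[i]
        diff = diff_vs_reference(GeneOrder("x", tuple(order)), self.REF)
        assert set(diff.translocated) == {"trnI", "trnM"}
        assert not diff.inverted

    def test_single_inverted_gene_detected(self):
        order = list(self.REF.order)
        j = order.index("+trnK")
        order[j] = "-trnK"
        diff = diff_vs_reference(GeneOrder("x", tuple(order)), self.REF)
        assert diff.inverted == ("trnK",)
        assert not diff.translocated

    def test_self_diff_empty_for_random_orders(self):
        rng = np.random.default_rng(9)
        for _ in range(200):
            o = random_order(rng, int(rng.integers(4, 13)))
            if not any(g.endswith("cox1") for g in o.order):
                continue
            assert diff_vs_reference(o, o).is_empty

    def test_genes_absent_from_reference_ignored(self):
        ref = GeneOrder("r", ("+cox1", "+trnA", "+trnW"))
        o = GeneOrder("x", ("+cox1", "+trnA", "+nad2", "+trnW"))
        assert diff_vs_reference(o, ref).is_empty


class TestBreakpointDistance:
    def test_identical_is_zero(self):
        rng = np.random.default_rng(1)
        o = random_order(rng, 10)
        assert breakpoint_distance(o, o) == 0

    def test_adjacent_transposition_in_8_gene_circle(self):
        base = tuple("+g%d" % i for i in range(8))
        base = tuple(f"+{g}" for g in
                     ["cox1", "cox2", "nad1", "nad2", "trnA", "trnI",
                      "trnM", "trnD"])
        moved = (base[0], base[2], base[1]) + base[3:]
        d = breakpoint_distance(GeneOrder("a", base), GeneOrder("b", moved))
        assert d == 3

    def test_symmetric_on_equal_gene_sets(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            k = int(rng.integers(4, 13))
            o1, o2 = random_order(rng, k, "a"), random_order(rng, k, "b")
            assert breakpoint_distance(o1, o2) == breakpoint_distance(o2, o1)

    def test_zero_iff_equal_canonical_orders(self):
        rng = np.random.default_rng(8)
        for _ in range(100):
            k = int(rng.integers(4, 13))
            o1, o2 = random_order(rng, k, "a"), random_order(rng, k, "b")
            d = breakpoint_distance(o1, o2)
            same = any(f == o2.order for f in all_equivalent_forms(o1.order))
            assert (d == 0) == same


class TestReferences:
    def test_paper_reference_has_32_genes_starting_cox1(self):
        ref = load_reference("paper")
        assert len(ref.order) == 32 and ref.order[0] == "+cox1"

    def test_canonical37_reference_complete(self):
        ref = load_reference("canonical37")
        assert len(ref.order) == 37
        assert {g.lstrip("+-") for g in ref.order} >= {"trnG", "trnA", "trnV",
                                                       "rrnL", "rrnS"}

    def test_unknown_reference_rejected(self):
        with pytest.raises(ValueError):
            load_reference("nope")


class TestTabularRoundTrip:
    def test_write_read_identity(self, tmp_path):
        rng = np.random.default_rng(5)
        orders = [random_order(rng, 9, f"a{i}") for i in range(5)]
        path = tmp_path / "orders.tsv"
        write_gene_orders(orders, path)
        back = read_gene_orders(path)
        assert [(o.accession, o.order) for o in back] == \
            [(o.accession, o.order) for o in orders]
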