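import pytest

from tickmito.gene_order import (ANCESTRAL_ARTHROPOD, ArrangementCatalog,
                                 GeneOrder, assign_arrangement_type,
                                 compare_to_benchmark, extract_gene_order,
                                 format_order, parse_order_string,
                                 rearrangement_frequency)
from tickmito.io import rotate_record
from tickmito.simulate import (RearrangementEvent, SimulationParams,
                               apply_rearrangement_events, simulate_mitogenome)

T1 = GeneOrder("T1", ANCESTRAL_ARTHROPOD)


def _flip(order, genes):
    return GeneOrder("flip", tuple(
        (n, -s if n in genes else s) for n, s in order.elements))


class TestGeneOrder:
    def test_duplicate_elements_rejected(self):
        with pytest.raises(ValueError):
            GeneOrder("x", (("trnI", 1), ("trnI", 1)))

    def test_canonical_rotation(self):
        rotated = GeneOrder("x", T1.elements[5:] + T1.elements[:5])
        assert rotated.canonical().elements == T1.elements

    def test_canonical_reflection(self):
        reflected = GeneOrder("x", tuple(
            (n, -s) for n, s in reversed(T1.elements)))
        assert reflected.canonical().elements == T1.elements

    def test_parse_format_round_trip(self):
        text = format_order(T1)
        assert parse_order_string(text, "T1").elements == T1.elements

    def test_anchor_fallback(self):
        order = GeneOrder("x", (("COX1", 1), ("COX2", 1), ("COX3", 1)))
        assert order.canonical().elements[0][0] == "COX1"


class TestExtract:
    def test_simulated_t1(self, sim_record):
        rec, _ = sim_record
        assert extract_gene_order(rec).elements == T1.elements

    def test_rotation_oracle(self, sim_record):
        rec, _ = sim_record
        for offset in (1, 5000, len(rec) - 3):
            assert (extract_gene_order(rotate_record(rec, offset)).elements
                    == T1.elements)

    def test_reflection_oracle(self, sim_record):
        from tickmito.io import MitogenomeRecord, reverse_complement
        from dataclasses import replace
        rec, _ = sim_record
        n = len(rec)
        flipped = MitogenomeRecord(
            rec.id, reverse_complement(rec.sequence),
            [replace(f, start=n - f.end, end=n - f.start, strand=-f.strand)
             for f in rec.features if not f.wraps_origin])
        assert extract_gene_order(flipped).elements == T1.elements


class TestCompare:
    def test_identity(self):
        comp = compare_to_benchmark(T1, T1)
        assert comp.rs == 0
        assert set(comp.status.values()) == {"kept"}

    def test_in_place_inversions(self):
        comp = compare_to_benchmark(_flip(T1, {"trnC", "trnP"}), T1)
        flagged = {g: s for g, s in comp.status.items() if s != "kept"}
        assert flagged == {"trnC": "inverted", "trnP": "inverted"}
        assert comp.rs == 2

    def test_single_transposition_neighbor_diff(self):
        moved, _ = apply_rearrangement_events(
            T1, [RearrangementEvent("transposition", ("trnV",), after="trnM")])
        comp = compare_to_benchmark(moved, T1)
        # manual neighbor-table diff: predecessors changed for trnV (now after
        # trnM), for ND2 (old successor of trnM), and for rrnS (old successor
        # of trnV)
        flagged = {g for g, s in comp.status.items() if s != "kept"}
        assert flagged == {"trnV", "ND2", "rrnS"}
        assert comp.rs == 3

    def test_cr_duplication_scored(self):
        dup, _ = apply_rearrangement_events(
            T1, [RearrangementEvent("cr_duplication", after="CYTB")])
        comp = compare_to_benchmark(dup, T1)
        assert comp.status["CR2"] == "duplicated"
        assert comp.scores["CR2"] == 1
        # the gene after CR2 is judged against its pre-duplication neighbor
        assert comp.status["trnS2"] == "kept"

    def test_rotation_and_reflection_invariance(self):
        target = _flip(T1, {"trnC"})
        rs0 = compare_to_benchmark(target, T1).rs
        rotated = GeneOrder("r", target.elements[7:] + target.elements[:7])
        reflected = GeneOrder("f", tuple(
            (n, -s) for n, s in reversed(target.elements)))
        assert compare_to_benchmark(rotated, T1).rs == rs0
        assert compare_to_benchmark(reflected, T1).rs == rs0
        bench_rot = GeneOrder("b", ANCESTRAL_ARTHROPOD[11:] + ANCESTRAL_ARTHROPOD[:11])
        assert compare_to_benchmark(target, bench_rot).rs == rs0

    def test_foreign_gene_scored_translocated(self):
        target = GeneOrder("x", T1.elements[:-1])  # drop CR
        bench = GeneOrder("b", T1.elements[:-1] + (("CR", 1),))
        extra = GeneOrder("y", (("trnI", 1), ("CR2", 1)) + T1.elements[1:-1])
        comp = compare_to_benchmark(extra, bench)
        assert comp.status["CR2"] == "duplicated"
        del target

    def test_disjoint_translocations_lower_bound(self):
        moved, _ = apply_rearrangement_events(T1, [
            RearrangementEvent("transposition", ("trnV",), after="trnM"),
            RearrangementEvent("transposition", ("trnD",), after="trnT"),
        ])
        comp = compare_to_benchmark(moved, T1)
        assert comp.scores["trnV"] >= 1 and comp.scores["trnD"] >= 1
        assert comp.rs >= 2


class TestRF:
    def test_all_identical_rf_zero(self):
        comps = [compare_to_benchmark(T1, T1) for _ in range(3)]
        rf, conserved = rearrangement_frequency(comps, T1)
        assert set(rf.values()) == {0.0}
        assert len(conserved) == len(T1.elements)

    def test_fifty_percent(self):
        moved, _ = apply_rearrangement_events(
            T1, [RearrangementEvent("transposition", ("trnV",), after="trnM")])
        comps = [compare_to_benchmark(T1, T1),
                 compare_to_benchmark(moved, T1)]
        rf, _ = rearrangement_frequency(comps, T1)
        assert rf["trnV"] == 50.0

    def test_rf_invariant_under_duplication_of_comparisons(self):
        moved, _ = apply_rearrangement_events(
            T1, [RearrangementEvent("transposition", ("trnV",), after="trnM")])
        one = rearrangement_frequency([compare_to_benchmark(moved, T1)], T1)[0]
        three = rearrangement_frequency(
            [compare_to_benchmark(moved, T1)] * 3, T1)[0]
        assert one == three

    def test_conserved_segment_from_planted_block(self):
        # shuffle genes outside a planted 9-gene block; the block must come
        # back as the maximal zero-RF run
        block = ["trnY", "COX1", "trnS1", "COX2", "trnK", "ATP8", "ATP6",
                 "COX3", "trnG"]
        order = parse_order_string(
            ",".join(("-" if s == -1 else "") + n
                     for n, s in ANCESTRAL_ARTHROPOD), "x")
        # build a shuffled target outside the block: swap trnI<->trnM and
        # trnH<->trnT, flip trnP
        elems = list(order.elements)
        names = [n for n, _ in elems]
        for a, b in (("trnI", "trnM"), ("trnH", "trnT")):
            i, j = names.index(a), names.index(b)
            elems[i], elems[j] = elems[j], elems[i]
            names = [n for n, _ in elems]
        target = _flip(GeneOrder("shuf", tuple(elems)), {"trnP"})
        comp = compare_to_benchmark(target, T1)
        rf, conserved = rearrangement_frequency([comp], T1)
        assert set(block) <= set(conserved)
        for g in block:
            assert rf[g] == 0.0


class TestCatalog:
    def test_builtin_t1_match(self, sim_record):
        rec, _ = sim_record
        order = extract_gene_order(rec)
        assert assign_arrangement_type(order, ArrangementCatalog.builtin()) == "T1"

    def test_one_move_is_novel(self):
        moved, _ = apply_rearrangement_events(
            T1, [RearrangementEvent("transposition", ("trnV",), after="trnM")])
        assert assign_arrangement_type(moved, ArrangementCatalog.builtin()) == "novel"

    def test_user_catalog_round_trip(self, tmp_path):
        moved, _ = apply_rearrangement_events(
            T1, [RearrangementEvent("transposition", ("trnV",), after="trnM")])
        path = tmp_path / "catalog.txt"
        path.write_text(f"T2 = {format_order(moved)}\n# comment line\n")
        cat = ArrangementCatalog.from_file(path)
        assert set(cat.orders) == {"T1", "T2"}
        assert assign_arrangement_type(moved, cat) == "T2"

    def test_empty_catalog_rejected(self):
        with pytest.raises(ValueError):
            assign_arrangement_type(T1, ArrangementCatalog())
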