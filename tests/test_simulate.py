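import math

import numpy as np
import pytest

from tickmito.distance import (DistanceMatrix, delimit_species_groups,
                               k2p_distance, pairwise_matrix)
from tickmito.gene_order import ANCESTRAL_ARTHROPOD, GeneOrder
from tickmito.io import validate_pcg_codons
from tickmito.simulate import (GenerationError, PlantedSSR, RearrangementEvent,
                               SimulationParams, apply_rearrangement_events,
                               base_probabilities, evolve_pair, random_sequence,
                               simulate_marker_alignment, simulate_mitogenome)

T1 = GeneOrder("T1", ANCESTRAL_ARTHROPOD)


class TestGenerator:
    def test_determinism(self):
        params = SimulationParams(seed=9, planted_ssrs=(PlantedSSR("AAT", 6),))
        rec1, truth1 = simulate_mitogenome(params)
        rec2, truth2 = simulate_mitogenome(params)
        assert rec1.sequence == rec2.sequence
        assert rec1.features == rec2.features
        assert truth1.ssrs == truth2.ssrs

    def test_gene_content(self, sim_record):
        rec, _ = sim_record
        names = {f.name for f in rec.features}
        assert len(names) == 38  # 37 genes + CR
        assert {"COX1", "trnL1", "rrnS", "CR"} <= names

    def test_genome_size_in_tick_range(self, sim_record):
        rec, _ = sim_record
        assert 14_000 <= len(rec) <= 15_500

    def test_codons_valid(self, sim_record):
        rec, _ = sim_record
        reports = validate_pcg_codons(rec)
        assert len(reports) == 13
        assert all(r.start_ok and r.stop_ok for r in reports)

    def test_at_target_within_3se(self):
        for target in (0.72, 0.78, 0.81):
            rec, _ = simulate_mitogenome(
                SimulationParams(seed=50, at_fraction=target))
            n = len(rec)
            observed = (rec.sequence.count("A") + rec.sequence.count("T")) / n
            se = math.sqrt(target * (1 - target) / n)
            assert abs(observed - target) <= 3 * se

    def test_planted_ssr_exact_recovery(self, planted_record):
        from tickmito.ssr import find_perfect_ssrs
        rec, truth = planted_record
        found = {(l.start, l.end, l.std_motif)
                 for l in find_perfect_ssrs(rec.sequence)}
        assert len(truth.ssrs) == 3
        for planted in truth.ssrs:
            assert (planted["start"], planted["end"],
                    planted["std_motif"]) in found

    def test_oversized_plant_raises(self):
        params = SimulationParams(
            seed=1, planted_ssrs=(PlantedSSR("ACGTAC", 100, host="trnI"),),
            max_retries=3)
        with pytest.raises(GenerationError):
            simulate_mitogenome(params)

    def test_invalid_at_fraction(self):
        with pytest.raises(ValueError):
            SimulationParams(at_fraction=1.2)

    def test_base_probabilities_hit_targets(self):
        p = base_probabilities(0.78, at_skew=-0.02, gc_skew=-0.17)
        assert sum(p.values()) == pytest.approx(1.0)
        assert p["A"] + p["T"] == pytest.approx(0.78)
        assert (p["A"] - p["T"]) / (p["A"] + p["T"]) == pytest.approx(-0.02)
        assert (p["G"] - p["C"]) / (p["G"] + p["C"]) == pytest.approx(-0.17)


class TestEvolvePair:
    def test_zero_distance_identity(self):
        assert evolve_pair("ACGTACGT", 0.0, 2.0, 3) == "ACGTACGT"

    def test_mean_k2p_recovery(self, rng):
        L = 10_000
        root = random_sequence(L, base_probabilities(0.75), rng)
        ests = [k2p_distance(root, evolve_pair(root, 0.05, 2.0, s))
                for s in range(20)]
        mean = float(np.mean(ests))
        se = float(np.std(ests, ddof=1)) / math.sqrt(len(ests))
        assert abs(mean - 0.05) <= 3 * se

    def test_high_kappa_suppresses_transversions(self, rng):
        from tickmito.distance import count_pair
        root = random_sequence(5000, base_probabilities(0.5), rng)
        mutated = evolve_pair(root, 0.10, 100.0, 5)
        c = count_pair(root, mutated)
        assert c.transitions > 10 * max(c.transversions, 1)

    def test_out_of_range_distance(self):
        with pytest.raises(ValueError):
            evolve_pair("ACGT" * 100, 50.0, 2.0, 1)

    def test_ambiguous_bases_untouched(self):
        out = evolve_pair("NNNN", 0.3, 2.0, 1)
        assert out == "NNNN"


class TestRearrangementEvents:
    def test_empty_event_list_identity(self):
        out, truth = apply_rearrangement_events(T1, [])
        assert out.elements == T1.elements
        assert truth.events == []

    def test_events_logged(self):
        out, truth = apply_rearrangement_events(T1, [
            RearrangementEvent("inversion", ("trnC",)),
            RearrangementEvent("cr_duplication", after="CYTB"),
        ])
        assert [e["kind"] for e in truth.events] == ["inversion", "cr_duplication"]
        assert "CR2" in out.names
        assert out.sign_of("trnC") == 1  # flipped from -1

    def test_absent_gene_rejected(self):
        small = GeneOrder("s", (("COX1", 1), ("COX2", 1)))
        with pytest.raises(ValueError):
            apply_rearrangement_events(
                small, [RearrangementEvent("inversion", ("trnV",))])

    def test_double_cr_duplication_rejected(self):
        with pytest.raises(ValueError):
            apply_rearrangement_events(T1, [
                RearrangementEvent("cr_duplication", after="CYTB"),
                RearrangementEvent("cr_duplication", after="COX1"),
            ])

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            apply_rearrangement_events(
                T1, [RearrangementEvent("fusion", ("COX1",))])


class TestMarkerAlignment:
    def test_groups_recovered_by_delimitation(self):
        seqs, labels = simulate_marker_alignment(
            8, 1200, group_sizes=(3, 3, 2), d_within=0.003, d_between=0.10,
            seed=4)
        mats = {m: pairwise_matrix(seqs, marker=m) for m in ("rrnL", "COX1")}
        groups = delimit_species_groups(mats)
        got = {frozenset(v) for v in groups.values()}
        expected = {}
        for tid, g in labels.items():
            expected.setdefault(g, set()).add(tid)
        assert got == {frozenset(v) for v in expected.values()}

    def test_two_taxa_zero_divergence(self):
        seqs, _ = simulate_marker_alignment(
            2, 500, group_sizes=(2,), d_within=0.0, d_between=0.1, seed=1)
        a, b = seqs.values()
        assert a == b

    def test_threshold_monotonicity_sweep(self):
        from tickmito.distance import SpeciesGroupingConfig
        seqs, _ = simulate_marker_alignment(
            6, 2000, group_sizes=(3, 3), d_within=0.02, d_between=0.09, seed=8)
        mats = {"rrnL": pairwise_matrix(seqs, marker="rrnL")}
        counts = []
        for t in (0.005, 0.03, 0.06, 0.15):
            cfg = SpeciesGroupingConfig(thresholds={"rrnL": t})
            counts.append(len(delimit_species_groups(mats, cfg)))
        assert counts == sorted(counts, reverse=True)

    def test_bad_group_sizes(self):
        with pytest.raises(ValueError):
            simulate_marker_alignment(5, 100, (2, 2), 0.01, 0.1)

    def test_within_must_be_below_between(self):
        with pytest.raises(ValueError):
            simulate_marker_alignment(4, 100, (2, 2), 0.2, 0.1)
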