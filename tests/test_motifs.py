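"""Motif detection, library filtering/clustering, threading screens and
the no-design control derivation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from champ.fixtures import (
    PairLibrarySpec,
    make_pair_library_fixture,
    make_thread_screen_fixture,
)
from champ.geometry import generate_crick_backbone, pair_descriptors
from champ.motifs import (
    PairLibraryEntry,
    SMALL_RESIDUES,
    cluster_geometries,
    derive_control_sequence,
    filter_library,
    find_small_x6_small,
    idealize_cluster,
    pairwise_identity,
    thread_and_clash,
)
from champ.sequences import (
    CHAMP1,
    CHAMP2,
    HEPOR_TM,
    MEPOR_TM,
    MEPOR_TM_START,
    PSII_TM1_INTERFACE,
    PSII_TM1_LIKE,
)


def brute_force_hits(seq, min_repeats):
    hits = []
    for start in range(len(seq)):
        if seq[start] not in SMALL_RESIDUES:
            continue
        if start >= 7 and seq[start - 7] in SMALL_RESIDUES:
            continue
        k = 1
        while start + 7 * k < len(seq) and seq[start + 7 * k] in SMALL_RESIDUES:
            k += 1
        if k >= min_repeats:
            hits.append(tuple(start + 1 + 7 * j for j in range(k)))
    return hits


class TestMotifDetection:
    def test_target_tm_motif_at_native_numbering(self):
        hits = find_small_x6_small(MEPOR_TM, numbering_start=MEPOR_TM_START)
        assert len(hits) == 1
        assert hits[0].positions == (230, 237, 244)
        assert hits[0].residues == "SSA"

    def test_poly_leucine_has_no_hits(self):
        assert find_small_x6_small("L" * 30) == []

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.text(alphabet="GASLIVFT", min_size=8, max_size=40),
           st.integers(min_value=2, max_value=4))
    def test_matches_exhaustive_scan(self, seq, min_repeats):
        got = [h.positions for h in find_small_x6_small(seq, min_repeats)]
        assert got == brute_force_hits(seq, min_repeats)

    def test_min_repeats_below_two_rejected(self):
        with pytest.raises(ValueError):
            find_small_x6_small("GAS", min_repeats=1)


class TestLibraryFiltering:
    def _entry(self, seq_a, seq_b):
        return PairLibraryEntry(id="x", seq_a=seq_a, seq_b=seq_b)

    def test_constructed_library_filters_exactly(self):
        good = "L" + "S" + "LIVFLI" + "A" + "LIVFLI" + "G" + "LIVFLI"  # 22, 3 repeats
        assert len(good) == 22
        short = good[:21]
        two_repeats = "L" + "S" + "LIVFLI" + "A" + "L" * 22
        entries = [
            self._entry(good, good),
            self._entry(short, good),  # length boundary
            self._entry(two_repeats, good),  # repeat count
            self._entry(good, two_repeats),
        ]
        kept = filter_library(entries)
        assert kept == [entries[0]]


class TestGeometryClustering:
    def test_three_archetypes_recovered_pure(self):
        lib = make_pair_library_fixture(PairLibrarySpec(n_per_archetype=8, seed=5))
        clusters = cluster_geometries(lib)
        assert len(clusters) == 3
        for cluster in clusters:
            assert len({e.label for e in cluster}) == 1

    def test_duplicated_entries_form_single_cluster(self):
        lib = make_pair_library_fixture(
            PairLibrarySpec(archetypes={"tight": (8.1, -175.0, 2.0)},
                            n_per_archetype=1, coord_noise=0.0, seed=0)
        )
        clusters = cluster_geometries(lib * 5)
        assert len(clusters) == 1

    def test_singleton_library(self):
        lib = make_pair_library_fixture(
            PairLibrarySpec(archetypes={"tight": (8.1, -175.0, 2.0)},
                            n_per_archetype=1, seed=0)
        )
        assert cluster_geometries(lib) == [lib]

    def test_consensus_recovers_archetype_and_regenerates(self):
        lib = make_pair_library_fixture(
            PairLibrarySpec(archetypes={"tight": (8.1, -175.0, 2.0)},
                            n_per_archetype=6, coord_noise=0.2, seed=9)
        )
        consensus = idealize_cluster(lib)
        assert 2 * consensus.r0 == pytest.approx(8.1, abs=0.3)
        assert consensus.alpha == pytest.approx(-2.5, abs=0.8)
        pair = generate_crick_backbone(consensus, 25)
        d = pair_descriptors(*pair)
        assert d.closest_approach_distance == pytest.approx(8.1, abs=0.4)
        assert d.crossing_angle == pytest.approx(-175.0, abs=2.0)

    def test_single_member_consensus_is_that_member(self):
        lib = make_pair_library_fixture(
            PairLibrarySpec(archetypes={"tight": (8.1, -175.0, 2.0)},
                            n_per_archetype=1, seed=1)
        )
        consensus = idealize_cluster(lib)
        assert consensus.r0 == lib[0].params.r0

    def test_empty_cluster_rejected(self):
        with pytest.raises(ValueError):
            idealize_cluster([])


class TestThreading:
    def test_glycine_thread_has_no_clashes(self):
        entry = make_thread_screen_fixture()[0]  # tightest pair
        report = thread_and_clash("G" * 25, entry, "a")
        assert report.clash_count == 0
        assert report.clash_count == len(report.clashing_pairs)

    def test_bulky_residue_at_tight_interface_clashes(self):
        entry = make_thread_screen_fixture()[0]
        seq = list("G" * 25)
        seq[12] = "F"  # central interface position of a 7.4-A pair
        report = thread_and_clash("".join(seq), entry, "a")
        assert report.clash_count >= 1

    def test_exactly_one_of_twelve_threadings_is_clash_free(self):
        """Threading the target TM sequence onto all 12 helices of the
        six-pair screen leaves a single clash-free case."""
        screen = make_thread_screen_fixture()
        free = [
            (e.id, which)
            for e in screen
            for which in ("a", "b")
            if thread_and_clash(MEPOR_TM, e, which).clash_free
        ]
        assert free == [("pair_5", "a")]

    def test_register_overflow_rejected(self):
        entry = make_thread_screen_fixture()[0]
        with pytest.raises(ValueError, match="overflow"):
            thread_and_clash(MEPOR_TM, entry, "a", register=5)


class TestControlSequence:
    def test_fixed_seed_reproducible(self):
        a = derive_control_sequence(PSII_TM1_LIKE, PSII_TM1_INTERFACE, seed=4)
        b = derive_control_sequence(PSII_TM1_LIKE, PSII_TM1_INTERFACE, seed=4)
        assert a == b

    def test_interface_positions_copied_verbatim(self):
        for seed in range(5):
            seq = derive_control_sequence(PSII_TM1_LIKE, PSII_TM1_INTERFACE, seed=seed)
            for p in PSII_TM1_INTERFACE:
                assert seq[p - 1] == PSII_TM1_LIKE[p - 1]

    def test_c_terminal_rule_and_motif_depth(self):
        seq = derive_control_sequence(PSII_TM1_LIKE, PSII_TM1_INTERFACE, seed=0)
        assert len(seq) == len(PSII_TM1_LIKE) + 2
        assert seq[-2:] == "AL"  # alanine never the last apolar residue
        hits = find_small_x6_small(seq, min_repeats=2)
        assert max(len(h.positions) for h in hits) == 4

    def test_identity_to_source_in_expected_band(self):
        """Copied interface + random apolar lipid positions put the control
        near half identity to its donor helix."""
        ids = [
            pairwise_identity(
                derive_control_sequence(PSII_TM1_LIKE, PSII_TM1_INTERFACE, seed=s),
                PSII_TM1_LIKE,
            )[0]
            for s in range(10)
        ]
        assert 40.0 <= float(np.mean(ids)) <= 60.0


class TestPairwiseIdentity:
    def test_identical_sequences(self):
        assert pairwise_identity("LIVGAS", "LIVGAS", mode="fixed") == (100.0, [])

    def test_target_vs_human_homolog_has_three_mismatches(self):
        pct, mismatches = pairwise_identity(MEPOR_TM, HEPOR_TM, mode="fixed")
        assert len(mismatches) == 3
        native = [m + MEPOR_TM_START - 1 for m in mismatches]
        assert native == [235, 237, 238]

    def test_designed_binders_differ_at_11_and_12(self):
        _, mismatches = pairwise_identity(CHAMP1, CHAMP2, mode="fixed")
        assert mismatches == [11, 12]

    def test_symmetry(self):
        a, b = CHAMP1, CHAMP2
        assert pairwise_identity(a, b)[0] == pairwise_identity(b, a)[0]

    def test_best_offset_finds_embedded_copy(self):
        inner = "LIVGASFM"
        outer = "AAA" + inner + "TT"
        pct, mism = pairwise_identity(outer, inner)
        assert pct == 100.0
        assert mism == []

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            pairwise_identity("", "A")
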