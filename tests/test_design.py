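"""Position designation, the annealed packer, packing score, lipid-facing
randomization and final selection."""

import numpy as np
import pytest
from scipy.stats import chisquare

from champ.design import (
    DesignConstraints,
    assign_lipid_facing,
    burial_metric,
    consensus_sequence,
    designate_positions,
    design_sequences,
    packing_score,
    select_designs,
    sequence_profile,
)
from champ.geometry import build_ideal_helix, kabsch
from champ.membrane import MembraneFrame, TMComplexModel
from champ.packing import (
    PackProblem,
    PackingConfig,
    ResidueAtoms,
    packing_score as shell_score,
)
from champ.sidechains import ROTAMERS


class TestDesignation:
    def test_template_complex_yields_13_of_24_interfacial(self, complex_model):
        classes = designate_positions(complex_model)
        assert len(complex_model.embedded_binder_positions()) == 24
        assert len(classes.small_motif) == 4
        assert len(classes.interface) == 9
        assert classes.n_interfacial == 13
        # motif positions are spaced exactly 7
        diffs = np.diff(classes.small_motif)
        assert set(diffs) == {7}

    def test_classes_partition_embedded_positions(self, complex_model):
        classes = designate_positions(complex_model)
        all_positions = (
            set(classes.small_motif) | set(classes.interface) | set(classes.lipid_facing)
        )
        assert sorted(all_positions) == complex_model.embedded_binder_positions()

    def test_classification_equals_bruteforce_burial(self, complex_model):
        classes = designate_positions(complex_model, cutoff=9.0)
        for p in classes.interface:
            assert burial_metric(complex_model, p) < 9.0
        for p in classes.lipid_facing:
            assert burial_metric(complex_model, p) >= 9.0

    def test_distant_helices_have_no_interface(self, complex_model):
        from dataclasses import replace
        from champ.geometry import HelixBackbone

        far = HelixBackbone(
            complex_model.binder.sequence,
            complex_model.binder.coords + np.array([50.0, 0.0, 0.0]),
        )
        model = replace(complex_model, binder=far, template=None)
        classes = designate_positions(model)
        assert classes.interface == []


def toy_problem():
    """Tiny two-helix packing problem (6 positions x 3 rotamers) small
    enough for exhaustive enumeration."""
    a = build_ideal_helix("A" * 9, id="A")
    b = build_ideal_helix("A" * 9, id="B")
    coords = b.coords.copy()
    coords[..., 0] = -coords[..., 0]  # mirror x -> antiparallel-ish placement
    coords = coords + np.array([8.0, 0.0, 0.0])
    from champ.geometry import HelixBackbone

    b = HelixBackbone("A" * 9, coords[:, :, :], "B")
    positions = [(1, i) for i in (1, 2, 3, 4, 5, 6)]
    choices = {p: [("L", rot) for rot in ROTAMERS["L"][:3]] for p in positions}
    return PackProblem([a, b], {}, positions, choices, PackingConfig(sweeps=40))


class TestPacker:
    def test_annealer_matches_exhaustive_minimum(self):
        """Monte-Carlo packing reaches the exhaustive optimum in at least
        95 of 100 seeds on a toy instance."""
        problem = toy_problem()
        _, e_star = problem.exhaustive()
        hits = 0
        for seed in range(100):
            _, e = problem.anneal(np.random.default_rng(seed))
            if e <= e_star + 1e-9:
                hits += 1
        assert hits >= 95

    def test_annealer_never_beats_exhaustive(self):
        problem = toy_problem()
        _, e_star = problem.exhaustive()
        for seed in range(20):
            _, e = problem.anneal(np.random.default_rng(seed))
            assert e >= e_star - 1e-9


class TestDesignSequences:
    def test_same_seed_reproduces_candidates(self, complex_model):
        a = design_sequences(complex_model, n_designs=2, seed=3, n_perturbations=1)
        b = design_sequences(complex_model, n_designs=2, seed=3, n_perturbations=1)
        assert [c.sequence for c in a] == [c.sequence for c in b]
        assert [c.energy for c in a] == [c.energy for c in b]

    def test_motif_positions_use_small_alphabet(self, design_candidates):
        for cand in design_candidates:
            for p in cand.classes.small_motif:
                assert cand.sequence[p - 1] in "GSA"

    def test_all_positions_respect_class_alphabets(self, design_candidates):
        constraints = DesignConstraints()
        for cand in design_candidates:
            cand.validate(constraints)

    def test_n_designs_below_one_rejected(self, complex_model):
        with pytest.raises(ValueError):
            design_sequences(complex_model, n_designs=0)


class TestPackingScore:
    def test_score_in_unit_interval(self, design_candidates):
        for cand in design_candidates:
            assert 0.0 <= cand.packing_score <= 1.0

    def test_separating_the_binder_decreases_score(self, design_candidates):
        cand = design_candidates[0]
        model = cand.model
        # translate binder +2 A away from the target along the interface normal
        from champ.geometry import HelixBackbone, _helix_axis

        _, u = _helix_axis(model.target.ca)
        w = model.binder.ca.mean(0) - model.target.ca.mean(0)
        w = w - np.dot(w, u) * u
        w = w / np.linalg.norm(w)
        moved = HelixBackbone(model.binder.sequence, model.binder.coords + 2.0 * w, "B")
        sc = {}
        for key, atoms in model.sidechains.items():
            if key[0] == 1 and len(atoms.names):
                sc[key] = ResidueAtoms(atoms.names, atoms.xyz + 2.0 * w, atoms.radii)
            else:
                sc[key] = atoms
        shifted = shell_score([model.target, moved], sc)
        assert shifted < cand.packing_score

    def test_invariant_under_global_rigid_motion(self, design_candidates, rng):
        cand = design_candidates[0]
        model = cand.model
        base = shell_score(model.helices, model.sidechains)
        rot, _, _ = kabsch(rng.normal(size=(4, 3)), rng.normal(size=(4, 3)))
        shift = rng.normal(scale=30, size=3)
        moved_helices = [h.transformed(rot, shift) for h in model.helices]
        moved_sc = {
            k: ResidueAtoms(v.names, v.xyz @ rot.T + shift, v.radii) if len(v.names) else v
            for k, v in model.sidechains.items()
        }
        assert shell_score(moved_helices, moved_sc) == pytest.approx(base, abs=1e-6)

    def test_missing_sidechains_rejected(self, complex_model, design_candidates):
        from dataclasses import replace

        cand = replace(design_candidates[0], model=replace(complex_model, sidechains={}))
        with pytest.raises(ValueError, match="side chains"):
            packing_score(cand)


class TestLipidFacing:
    def test_letter_marginals_match_weights(self):
        """100k draws from the weighted apolar distribution: leucine near
        60% and a chi-square test against the configured weights."""
        weights = {"A": 0.10, "I": 0.10, "V": 0.10, "F": 0.10, "L": 0.60}
        rng = np.random.default_rng(123)
        letters = list(weights)
        probs = np.array([weights[k] for k in letters])
        draws = rng.choice(len(letters), size=100_000, p=probs)
        counts = np.bincount(draws, minlength=5)
        frac_l = counts[letters.index("L")] / 100_000
        assert frac_l == pytest.approx(0.60, abs=0.005)
        _, p = chisquare(counts, probs * 100_000)
        assert p > 0.01

    def test_reassignment_reproducible_and_restricted(self, design_candidates):
        constraints = DesignConstraints()
        a = assign_lipid_facing(design_candidates[0], constraints, seed=5)
        b = assign_lipid_facing(design_candidates[0], constraints, seed=5)
        assert a.sequence == b.sequence
        a.validate(constraints, strict_lipid=True)

    def test_no_forbidden_ala_pairs_after_redraw(self, design_candidates):
        from champ.motifs import _has_forbidden_ala

        constraints = DesignConstraints()
        for seed in range(10):
            cand = assign_lipid_facing(design_candidates[0], constraints, seed=seed)
            lipid = set(cand.classes.lipid_facing)
            assert not _has_forbidden_ala(cand.sequence, lipid)

    def test_zero_lipid_positions_is_identity(self, design_candidates):
        from dataclasses import replace
        from champ.design import PositionClasses

        cand = design_candidates[0]
        all_iface = PositionClasses(
            classes={p: "interface" for p in cand.classes.classes}, burial=cand.classes.burial
        )
        fixed = replace(cand, classes=all_iface)
        assert assign_lipid_facing(fixed, seed=1) is fixed


class TestSelection:
    def test_three_sequence_families_give_three_clusters(self, design_candidates):
        """Constructed candidate set with three distinct sequence families:
        clustering recovers them and representatives are score maxima."""
        from dataclasses import replace

        base = design_candidates[0]
        families = {
            "LLLLLLLLLLLLLLLLLLLLLLLL": (0.90, 0.85, 0.80),
            "FFFFFFFFFFFFFFFFFFFFFFFF": (0.70, 0.65, 0.60),
            "GGGGGGGGGGGGGGGGGGGGGGGG": (0.50, 0.45, 0.40),
        }
        cands = []
        for seq, scores in families.items():
            for i, s in enumerate(scores):
                c = replace(base, sequence=seq[:23] + "AIV"[i])
                c.packing_score = s
                cands.append(c)
        reps, clusters = select_designs(cands, top_fraction=1.0, strain_threshold=1e9)
        assert len(clusters) == 3
        best_by_family = sorted(
            (max(s) for s in families.values()), reverse=True
        )
        assert [r.packing_score for r in reps] == best_by_family

    def test_identical_candidates_one_cluster_one_representative(self, design_candidates):
        cands = [design_candidates[0]] * 5
        reps, clusters = select_designs(cands, top_fraction=1.0, strain_threshold=1e9)
        assert len(clusters) == 1
        assert len(reps) == 1

    def test_small_sets_round_decile_up(self, design_candidates):
        reps, clusters = select_designs(
            design_candidates[:3], top_fraction=0.10, strain_threshold=1e9
        )
        assert sum(len(c) for c in clusters) == 1


class TestProfile:
    def test_single_sequence_gives_one_hot_columns(self):
        prof = sequence_profile(["GAS"])
        assert prof.values.sum(axis=0) == pytest.approx([1, 1, 1])
        assert prof.loc["G", 1] == 1.0 and prof.loc["A", 2] == 1.0

    def test_large_uniform_sample_near_uniform_columns(self):
        rng = np.random.default_rng(5)
        alphabet = "GSA"
        seqs = ["".join(rng.choice(list(alphabet), size=8)) for _ in range(3000)]
        prof = sequence_profile(seqs)
        sub = prof.loc[list(alphabet)]
        assert np.allclose(sub.values, 1 / 3, atol=0.05)
        assert np.allclose(prof.values.sum(axis=0), 1.0)

    def test_motif_columns_supported_only_on_small_alphabet(self, design_candidates):
        prof = sequence_profile([c.sequence for c in design_candidates])
        for p in design_candidates[0].classes.small_motif:
            support = prof.index[prof[p] > 0].tolist()
            assert set(support) <= set("GSA")

    def test_ragged_lengths_rejected(self):
        with pytest.raises(ValueError, match="ragged"):
            sequence_profile(["AAA", "AAAA"])
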