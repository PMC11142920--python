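"""Binder sequence design: position designation, constrained packing,
packing-quality scoring, lipid-facing randomization, and final
selection by top-fraction ranking plus substitution-matrix clustering.

Position classes on the binder helix:

``small_motif``
    the four positions (spaced 7) facing the target's small-X6-small
    surface; designable alphabet {G, S, A};
``interface``
    other buried positions (CB close to the target helix axis);
    designable alphabet {G, A, T, S, V, L, I, F, M};
``lipid_facing``
    everything else; packed with the interface alphabet during design
    and later reassigned from a weighted apolar distribution
    (A/I/V/F 10% each, L 60%) with rejection of emergent Ala-X3-Ala /
    Ala-X6-Ala pairs.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from champ.geometry import HelixBackbone, _helix_axis, _project_point
from champ.membrane import TMComplexModel
from champ.motifs import APOLAR_WEIGHTS, FORBIDDEN_ALA_SPACINGS, _has_forbidden_ala
from champ.packing import (
    PackProblem,
    PackingConfig,
    ResidueAtoms,
    packing_score as _shell_packing_score,
    repack_rotamers,
    sidechain_atoms,
)
from champ.sidechains import ROTAMERS

SMALL_MOTIF_ALPHABET = "GSA"
INTERFACE_ALPHABET = "GATSVLIFM"

#: CB-to-partner-axis distance (A) below which an embedded binder
#: position counts as potentially interfacial.  Calibrated on the
#: idealized antiparallel template so that 13 of the 24 embedded binder
#: positions are designated interfacial (4 motif + 9 other); the
#: nearest burial values on either side of the cutoff sit at ~8.7 and
#: ~9.7 A, so the designation is not knife-edged.
BURIAL_CUTOFF = 9.0


@dataclass
class DesignConstraints:
    small_motif_alphabet: str = SMALL_MOTIF_ALPHABET
    interface_alphabet: str = INTERFACE_ALPHABET
    lipid_weights: dict = field(default_factory=lambda: dict(APOLAR_WEIGHTS))
    forbidden_ala_spacings: tuple = FORBIDDEN_ALA_SPACINGS
    max_attempts: int = 2000

    def __post_init__(self):
        if abs(sum(self.lipid_weights.values()) - 1.0) > 1e-9:
            raise ValueError("lipid-facing weights must sum to 1")
        if not self.small_motif_alphabet or not self.interface_alphabet:
            raise ValueError("alphabets must be non-empty")

    def alphabet_for(self, cls: str) -> str:
        if cls == "small_motif":
            return self.small_motif_alphabet
        if cls == "interface":
            return self.interface_alphabet
        return self.interface_alphabet  # lipid positions during packing


@dataclass
class PositionClasses:
    """Class and burial metric per embedded binder position (1-based)."""

    classes: dict  # pos -> "small_motif" | "interface" | "lipid_facing"
    burial: dict  # pos -> CB-to-target-axis distance, A

    @property
    def small_motif(self) -> list[int]:
        return sorted(p for p, c in self.classes.items() if c == "small_motif")

    @property
    def interface(self) -> list[int]:
        return sorted(p for p, c in self.classes.items() if c == "interface")

    @property
    def lipid_facing(self) -> list[int]:
        return sorted(p for p, c in self.classes.items() if c == "lipid_facing")

    @property
    def n_interfacial(self) -> int:
        return len(self.small_motif) + len(self.interface)


@dataclass
class DesignCandidate:
    sequence: str
    model: TMComplexModel
    classes: PositionClasses
    energy: float
    seed: int
    packing_score: float | None = None
    flags: list = field(default_factory=list)

    def validate(self, constraints: DesignConstraints, strict_lipid: bool = False) -> None:
        """Check every position against its class alphabet.

        Lipid-facing positions are packed with the interface alphabet
        during design and only restricted to the weighted apolar set
        after reassignment; ``strict_lipid`` enforces the latter.
        """
        for p, cls in self.classes.classes.items():
            aa = self.sequence[p - 1]
            if cls == "small_motif" and aa not in constraints.small_motif_alphabet:
                raise ValueError(f"position {p}: {aa} outside small-motif alphabet")
            if cls == "interface" and aa not in constraints.interface_alphabet:
                raise ValueError(f"position {p}: {aa} outside interface alphabet")
            if cls == "lipid_facing":
                allowed = set(constraints.lipid_weights)
                if not strict_lipid:
                    allowed |= set(constraints.interface_alphabet)
                if aa not in allowed:
                    raise ValueError(f"position {p}: {aa} outside lipid-facing alphabet")


def burial_metric(model: TMComplexModel, position: int) -> float:
    """CB distance from binder position (1-based) to the target helix axis.

    The axis is the finite segment spanned by the target helix (not an
    infinite line), so binder positions overhanging the target's ends
    read as less buried.
    """
    pts, axis = _helix_axis(model.target.ca)
    mu = pts.mean(axis=0)
    t = np.dot(model.target.ca - mu, axis)
    t_lo, t_hi = float(t.min()), float(t.max())
    bb = model.binder.coords[position - 1]
    cb = sidechain_atoms("A", bb, ()).xyz[0]
    proj = float(np.clip(np.dot(cb - mu, axis), t_lo, t_hi))
    return float(np.linalg.norm(cb - (mu + proj * axis)))


def designate_positions(
    model: TMComplexModel,
    cutoff: float = BURIAL_CUTOFF,
    margin: float = 6.0,
) -> PositionClasses:
    """Deterministically classify embedded binder positions by burial.

    The small-X6-small frame is the 4-deep spacing-7 frame with the
    lowest mean burial; other embedded positions closer than ``cutoff``
    to the target axis are ``interface``; the rest face lipid.
    """
    embedded = model.embedded_binder_positions(margin)
    burial = {p: burial_metric(model, p) for p in embedded}
    frames = []
    for start in range(1, 8):
        positions = [p for p in range(start, model.binder.n_res + 1, 7) if p in burial]
        if len(positions) == 4:
            frames.append(positions)
    motif = min(frames, key=lambda f: np.mean([burial[p] for p in f])) if frames else []
    classes = {}
    for p in embedded:
        if p in motif:
            classes[p] = "small_motif"
        elif burial[p] < cutoff:
            classes[p] = "interface"
        else:
            classes[p] = "lipid_facing"
    return PositionClasses(classes=classes, burial=burial)


# ---------------------------------------------------------------------------
# packing problems


def _target_sidechains(
    model: TMComplexModel, cfg: PackingConfig, seed: int = 0
) -> dict[tuple, ResidueAtoms]:
    """Fixed target side chains: rotamer repack of the target sequence
    against the polyalanine binder backbone."""
    helices = model.helices
    seqs = [model.target.sequence, "A" * model.binder.n_res]
    mobile = [(0, i) for i in range(model.target.n_res)]
    rng = np.random.default_rng(seed)
    packed, _ = repack_rotamers(helices, seqs, mobile, {}, rng, cfg)
    return packed


def build_design_problem(
    model: TMComplexModel,
    classes: PositionClasses,
    constraints: DesignConstraints,
    cfg: PackingConfig,
    target_sc: dict[tuple, ResidueAtoms],
) -> PackProblem:
    choices = {}
    for p, cls in classes.classes.items():
        key = (1, p - 1)
        choices[key] = [
            (aa, rot)
            for aa in constraints.alphabet_for(cls)
            for rot in ROTAMERS[aa]
        ]
    return PackProblem(model.helices, target_sc, list(choices), choices, cfg)


def design_sequences(
    model: TMComplexModel,
    constraints: DesignConstraints | None = None,
    n_designs: int = 10,
    seed: int = 0,
    cfg: PackingConfig | None = None,
    n_perturbations: int = 2,
) -> list[DesignCandidate]:
    """Design binder sequences by class-ordered annealed packing.

    Each candidate anneals the small-motif positions first, then adds
    the interface boundary, then all remaining designable positions,
    and finally tries small rigid-body perturbations of the binder
    (within +/-0.5 A, +/-5 degrees) with a rotamer-only repack, keeping
    the lowest-energy pose.  Deterministic for a given seed.
    """
    if n_designs < 1:
        raise ValueError("n_designs must be >= 1")
    constraints = constraints or DesignConstraints()
    cfg = cfg or PackingConfig()
    classes = designate_positions(model)
    target_sc = _target_sidechains(model, cfg, seed=0)
    problem = build_design_problem(model, classes, constraints, cfg, target_sc)
    motif_keys = [(1, p - 1) for p in classes.small_motif]
    iface_keys = motif_keys + [(1, p - 1) for p in classes.interface]
    all_keys = problem.positions
    # polyalanine start
    ala_init = {}
    for key in all_keys:
        ala_init[key] = next(
            i for i, (aa, _) in enumerate(problem.choices[key]) if aa == "A"
        )
    candidates = []
    for d in range(n_designs):
        rng = np.random.default_rng(np.random.SeedSequence([seed, d]))
        assign, _ = problem.anneal(rng, active=motif_keys, init=ala_init)
        assign, _ = problem.anneal(rng, active=iface_keys, init=assign)
        assign, energy = problem.anneal(rng, active=all_keys, init=assign)
        seq = _assignment_sequence(problem, assign, model.binder.n_res)
        sidechains = dict(target_sc)
        sidechains.update(problem.atoms_for(assign))
        best_model = replace(model, sidechains=sidechains)
        best_energy = energy
        # rigid-body micro-perturbation with rotamer-only repack
        for _ in range(n_perturbations):
            pert_model = _perturb_binder(model, rng)
            seqs = [model.target.sequence, seq]
            mobile = list(problem.positions)
            packed, e = repack_rotamers(
                pert_model.helices, seqs, mobile, target_sc, rng, cfg
            )
            if e < best_energy:
                best_energy = e
                sc = dict(target_sc)
                sc.update(packed)
                best_model = replace(pert_model, sidechains=sc)
        cand = DesignCandidate(
            sequence=seq, model=best_model, classes=classes,
            energy=float(best_energy), seed=d,
        )
        cand.validate(constraints)
        candidates.append(cand)
    return candidates


def _assignment_sequence(problem: PackProblem, assign: dict, n_res: int) -> str:
    seq = ["A"] * n_res
    for (ch, i), choice in assign.items():
        seq[i] = problem.choices[(ch, i)][choice][0]
    return "".join(seq)


def _perturb_binder(model: TMComplexModel, rng: np.random.Generator) -> TMComplexModel:
    shift = rng.uniform(-0.5, 0.5, size=3)
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = math.radians(rng.uniform(-5.0, 5.0))
    kx = np.array([
        [0, -axis[2], axis[1]],
        [axis[2], 0, -axis[0]],
        [-axis[1], axis[0], 0],
    ])
    rot = np.eye(3) + math.sin(angle) * kx + (1 - math.cos(angle)) * (kx @ kx)
    centroid = model.binder.ca.mean(axis=0)
    coords = (model.binder.coords - centroid) @ rot.T + centroid + shift
    binder = HelixBackbone(model.binder.sequence, coords, model.binder.id)
    return replace(model, binder=binder, sidechains={})


# ---------------------------------------------------------------------------
# scoring, randomization, selection


def packing_score(candidate: DesignCandidate) -> float:
    """PackStat-style interfacial void score in [0, 1] (higher = tighter)."""
    if not candidate.model.sidechains:
        raise ValueError("candidate has no side chains placed")
    score = _shell_packing_score(candidate.model.helices, candidate.model.sidechains)
    candidate.packing_score = score
    return score


def assign_lipid_facing(
    candidate: DesignCandidate,
    constraints: DesignConstraints | None = None,
    seed: int = 0,
) -> DesignCandidate:
    """Reassign lipid-facing letters from the weighted apolar
    distribution, rejecting whole draws that create forbidden emergent
    Ala pairs at lipid-facing positions.  Identity operation when there
    are no lipid-facing positions."""
    constraints = constraints or DesignConstraints()
    lipid = candidate.classes.lipid_facing
    if not lipid:
        return candidate
    letters = list(constraints.lipid_weights)
    probs = np.array([constraints.lipid_weights[k] for k in letters])
    probs = probs / probs.sum()
    rng = np.random.default_rng(seed)
    for _ in range(constraints.max_attempts):
        seq = list(candidate.sequence)
        for p, k in zip(lipid, rng.choice(len(letters), size=len(lipid), p=probs)):
            seq[p - 1] = letters[k]
        new_seq = "".join(seq)
        if _has_forbidden_ala(new_seq, set(lipid)):
            continue
        return _rebuild_lipid_sidechains(candidate, new_seq, lipid)
    raise RuntimeError(
        f"lipid-facing redraw failed {constraints.max_attempts} times; "
        f"positions {lipid} cannot avoid forbidden Ala spacings"
    )


def _rebuild_lipid_sidechains(
    candidate: DesignCandidate, new_seq: str, lipid: list[int]
) -> DesignCandidate:
    sidechains = dict(candidate.model.sidechains)
    binder = candidate.model.binder
    for p in lipid:
        aa = new_seq[p - 1]
        bb = binder.coords[p - 1]
        best = min(
            (sidechain_atoms(aa, bb, rot) for rot in ROTAMERS[aa]),
            key=lambda at: _self_clash(at, binder, p),
        )
        sidechains[(1, p - 1)] = best
    model = replace(candidate.model, sidechains=sidechains)
    return replace(candidate, sequence=new_seq, model=model)


def _self_clash(atoms: ResidueAtoms, binder: HelixBackbone, pos: int) -> float:
    if not len(atoms.names):
        return 0.0
    others = np.concatenate(
        [binder.coords[j] for j in range(binder.n_res) if abs(j - (pos - 1)) >= 2]
    )
    from scipy.spatial.distance import cdist

    d = cdist(atoms.xyz, others)
    return float(np.sum(np.clip(3.0 - d, 0, None) ** 2))


def choose_blosum(avg_identity_pct: float):
    """BLOSUM matrix nearest the average pairwise identity of the set."""
    available = {45: "BLOSUM45", 50: "BLOSUM50", 62: "BLOSUM62",
                 80: "BLOSUM80", 90: "BLOSUM90"}
    key = min(available, key=lambda k: abs(k - avg_identity_pct))
    return substitution_matrices.load(available[key])


def _blosum_distance_matrix(seqs: list[str]) -> np.ndarray:
    from champ.motifs import pairwise_identity

    n = len(seqs)
    ids = []
    for i in range(n):
        for j in range(i + 1, n):
            ids.append(pairwise_identity(seqs[i], seqs[j], mode="fixed")[0])
    mat = choose_blosum(float(np.mean(ids)) if ids else 80.0)
    def sim(a, b):
        return sum(mat[x, y] for x, y in zip(a, b))
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            s = sim(seqs[i], seqs[j]) / math.sqrt(sim(seqs[i], seqs[i]) * sim(seqs[j], seqs[j]))
            d[i, j] = d[j, i] = max(0.0, 1.0 - s)
    return d


def select_designs(
    candidates: list[DesignCandidate],
    top_fraction: float = 0.10,
    distance_threshold: float = 0.15,
    strain_threshold: float = 4.0,
) -> tuple[list[DesignCandidate], list[list[DesignCandidate]]]:
    """Top-fraction selection followed by hierarchical sequence clustering.

    Candidates are ranked by packing score (ties broken toward the
    lexicographically smallest sequence); the top decile (rounded up) is
    clustered by average linkage on a BLOSUM-similarity distance, the
    matrix chosen to match the set's average pairwise identity.  Each
    cluster's representative is its highest-scoring member.  Clusters
    whose consensus motif letters strain the template geometry are
    flagged (``geometry_strain``), not dropped.
    """
    if not candidates:
        raise ValueError("no candidates to select from")
    for c in candidates:
        if c.packing_score is None:
            packing_score(c)
    ranked = sorted(candidates, key=lambda c: (-c.packing_score, c.sequence))
    n_top = max(1, math.ceil(top_fraction * len(ranked)))
    top = ranked[:n_top]
    seqs = [c.sequence for c in top]
    if len(top) == 1:
        clusters = [top]
    else:
        d = _blosum_distance_matrix(seqs)
        z = linkage(squareform(d, checks=False), method="average")
        labels = fcluster(z, t=distance_threshold, criterion="distance")
        groups: dict[int, list] = {}
        for lab, cand in zip(labels, top):
            groups.setdefault(int(lab), []).append(cand)
        clusters = [groups[k] for k in sorted(groups)]
    representatives = []
    for cluster in clusters:
        rep = min(cluster, key=lambda c: (-c.packing_score, c.sequence))
        strain = _consensus_motif_strain(cluster)
        if strain > strain_threshold:
            for c in cluster:
                if "geometry_strain" not in c.flags:
                    c.flags.append("geometry_strain")
        representatives.append(rep)
    representatives.sort(key=lambda c: (-c.packing_score, c.sequence))
    return representatives, clusters


def _consensus_motif_strain(cluster: list[DesignCandidate]) -> float:
    """Best achievable steric energy of the cluster's consensus letters at
    the motif positions on the unperturbed template backbone; high
    values mean the consensus distorts ideal target geometry."""
    rep = cluster[0]
    consensus = consensus_sequence([c.sequence for c in cluster])
    cfg = PackingConfig()
    model = rep.model
    helices = model.helices
    seqs = [model.target.sequence, consensus]
    mobile = [(1, p - 1) for p in rep.classes.small_motif]
    fixed = {k: v for k, v in model.sidechains.items() if k not in mobile}
    rng = np.random.default_rng(0)
    _, energy = repack_rotamers(helices, seqs, mobile, fixed, rng, cfg)
    return float(energy)


def consensus_sequence(seqs: list[str]) -> str:
    return "".join(
        Counter(col).most_common(1)[0][0] for col in zip(*seqs)
    )


def sequence_profile(sequences: list[str]) -> pd.DataFrame:
    """Column-stochastic per-position amino-acid frequency matrix."""
    if not sequences:
        raise ValueError("no sequences")
    lengths = {len(s) for s in sequences}
    if len(lengths) > 1:
        raise ValueError(f"ragged sequence lengths: {sorted(lengths)}")
    alphabet = sorted("ACDEFGHIKLMNPQRSTVWY")
    counts = np.zeros((len(alphabet), lengths.pop()))
    index = {aa: i for i, aa in enumerate(alphabet)}
    for seq in sequences:
        for j, aa in enumerate(seq):
            counts[index[aa], j] += 1
    freq = counts / counts.sum(axis=0, keepdims=True)
    return pd.DataFrame(freq, index=alphabet,
                        columns=[i + 1 for i in range(freq.shape[1])])
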