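"""Small-X6-small motif detection, helix-pair library filtering and
clustering, consensus template idealization, threading clash screens,
and derivation of the no-design control sequence.

A small-X6-small motif is a run of small residues (Gly/Ala/Ser) spaced
exactly 7 apart along the sequence, i.e. repeating every other helical
turn, which lets two helix backbones approach closely.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from champ.geometry import (
    CrickParams,
    GeometryError,
    HelixBackbone,
    HelixPairGeometry,
    generate_crick_backbone,
)
from champ.packing import (
    PackingConfig,
    ResidueAtoms,
    count_clashes,
    repack_rotamers,
)

SMALL_RESIDUES = frozenset("GAS")
APOLAR_WEIGHTS = {"A": 0.10, "I": 0.10, "V": 0.10, "F": 0.10, "L": 0.60}
#: spacings that would create forbidden emergent Ala pairs (Ala-X3-Ala,
#: Ala-X6-Ala)
FORBIDDEN_ALA_SPACINGS = (4, 7)


@dataclass
class MotifHit:
    """One maximal small-X6-small run."""

    positions: tuple  # 1-based indices of the small residues
    residues: str  # letters at those positions
    spacing: int = 7

    def __post_init__(self):
        if any(b - a != self.spacing for a, b in zip(self.positions, self.positions[1:])):
            raise ValueError("motif positions must be evenly spaced")
        if any(r not in SMALL_RESIDUES for r in self.residues):
            raise ValueError("motif residues must be small (G/A/S)")


@dataclass
class PairLibraryEntry:
    """One interacting TM helix pair from a (synthetic or mined) library."""

    id: str
    seq_a: str
    seq_b: str
    helix_a: HelixBackbone | None = None
    helix_b: HelixBackbone | None = None
    params: CrickParams | None = None
    geometry: HelixPairGeometry | None = None
    label: str | None = None  # ground-truth archetype label, fixtures only

    def __post_init__(self):
        if self.helix_a is not None and len(self.seq_a) != self.helix_a.n_res:
            raise ValueError("seq_a length does not match helix_a")
        if self.helix_b is not None and len(self.seq_b) != self.helix_b.n_res:
            raise ValueError("seq_b length does not match helix_b")


@dataclass
class ClashReport:
    threaded_sequence: str
    clashing_pairs: list = field(default_factory=list)  # (res_i, res_j, distance)

    @property
    def clash_count(self) -> int:
        return len(self.clashing_pairs)

    @property
    def clash_free(self) -> bool:
        return not self.clashing_pairs


# ---------------------------------------------------------------------------
# motif detection and library filtering


def find_small_x6_small(
    sequence: str,
    min_repeats: int = 3,
    numbering_start: int = 1,
) -> list[MotifHit]:
    """All maximal runs of >= ``min_repeats`` small residues spaced 7.

    Runs in different frames (different start offsets mod 7) are
    reported separately; each maximal run is reported exactly once.
    """
    if min_repeats < 2:
        raise ValueError("min_repeats must be >= 2")
    n = len(sequence)
    hits = []
    for start in range(n):
        if sequence[start] not in SMALL_RESIDUES:
            continue
        if start - 7 >= 0 and sequence[start - 7] in SMALL_RESIDUES:
            continue  # not maximal: extends an earlier run
        k = 1
        while start + 7 * k < n and sequence[start + 7 * k] in SMALL_RESIDUES:
            k += 1
        if k >= min_repeats:
            pos = tuple(start + 7 * j + numbering_start for j in range(k))
            res = "".join(sequence[start + 7 * j] for j in range(k))
            hits.append(MotifHit(positions=pos, residues=res))
    return hits


def filter_library(
    entries: list[PairLibraryEntry], min_repeats: int = 3, min_len: int = 22
) -> list[PairLibraryEntry]:
    """Keep pairs in which both helices are long enough and both carry a
    small-X6-small run of the required depth."""
    out = []
    for entry in entries:
        ok = True
        for seq in (entry.seq_a, entry.seq_b):
            if len(seq) < min_len or not find_small_x6_small(seq, min_repeats):
                ok = False
                break
        if ok:
            out.append(entry)
    return out


# ---------------------------------------------------------------------------
# geometry clustering and consensus


def _geometry_features(entries: list[PairLibraryEntry]) -> np.ndarray:
    feats = []
    for e in entries:
        g = e.geometry
        if g is None:
            raise ValueError(f"entry {e.id} has no geometry descriptors")
        ang = math.radians(g.crossing_angle)
        feats.append([
            g.closest_approach_distance,
            math.cos(ang),
            math.sin(ang),
            abs(g.axial_z_offset),
        ])
    return np.array(feats)


def cluster_geometries(
    entries: list[PairLibraryEntry],
    distance_threshold: float = 1.5,
    feature_scales: tuple = (1.0, 0.15, 0.15, 1.5),
) -> list[list[PairLibraryEntry]]:
    """Agglomerative (average linkage) clustering of pair geometries.

    Features are (distance, cos/sin of the crossing angle, |z offset|),
    each divided by its configured scale; the crossing angle enters
    through its sine/cosine so the metric is circular.  Deterministic
    for a given threshold.
    """
    if len(entries) == 1:
        return [list(entries)]
    if len(entries) < 1:
        raise ValueError("need at least one entry")
    feats = _geometry_features(entries) / np.asarray(feature_scales)
    z = linkage(feats, method="average")
    labels = fcluster(z, t=distance_threshold, criterion="distance")
    clusters: dict[int, list] = {}
    for lab, entry in zip(labels, entries):
        clusters.setdefault(int(lab), []).append(entry)
    return [clusters[k] for k in sorted(clusters)]


def _circular_median_deg(values: np.ndarray) -> float:
    """Median direction: the value minimizing summed circular distance."""
    best, best_cost = None, np.inf
    for v in values:
        cost = np.sum(np.abs((values - v + 180.0) % 360.0 - 180.0))
        if cost < best_cost:
            best, best_cost = v, cost
    return float(best)


def idealize_cluster(members: list[PairLibraryEntry]) -> CrickParams:
    """Consensus Crick parameters of a cluster: per-parameter median
    (circular median for phases)."""
    if not members:
        raise ValueError("cannot idealize an empty cluster")
    params = [m.params for m in members]
    if any(p is None for p in params):
        raise ValueError("all members need fitted Crick parameters")
    med = lambda key: float(np.median([getattr(p, key) for p in params]))
    cmed = lambda key: _circular_median_deg(np.array([getattr(p, key) for p in params]))
    orientation = max(
        ("antiparallel", "parallel"),
        key=lambda o: sum(p.orientation == o for p in params),
    )
    return CrickParams(
        r0=med("r0"), r1=med("r1"), w0=med("w0"), w1=med("w1"),
        alpha=med("alpha"), phi1_a=cmed("phi1_a"), phi1_b=cmed("phi1_b"),
        dphi0=cmed("dphi0"), z_offset=med("z_offset"), orientation=orientation,
    )


# ---------------------------------------------------------------------------
# threading and the no-design control


def thread_and_clash(
    target_seq: str,
    entry: PairLibraryEntry,
    which_helix: str = "a",
    register: int = 0,
    seed: int = 0,
    cfg: PackingConfig | None = None,
) -> ClashReport:
    """Thread a sequence onto one helix of a pair and count steric
    clashes with the partner helix after a simplified rotamer repack.

    ``register`` shifts the threaded sequence along the helix; the
    partner keeps its native sequence.  A clash is a cross-helix
    heavy-atom pair closer than the configured cutoff (default 2.8 A).
    """
    cfg = cfg or PackingConfig()
    if which_helix not in ("a", "b"):
        raise ValueError("which_helix must be 'a' or 'b'")
    host = entry.helix_a if which_helix == "a" else entry.helix_b
    partner = entry.helix_b if which_helix == "a" else entry.helix_a
    partner_seq = entry.seq_b if which_helix == "a" else entry.seq_a
    if host is None or partner is None:
        raise ValueError("entry lacks backbone coordinates")
    if register < 0 or register + len(target_seq) > host.n_res:
        raise ValueError(
            f"register {register} overflows host helix of {host.n_res} residues"
        )
    threaded = list("A" * host.n_res)
    threaded[register : register + len(target_seq)] = list(target_seq)
    threaded = "".join(threaded)
    helices = [host, partner]
    seqs = [threaded, partner_seq]
    # repack only residues near the interface; lipid-facing rotamers
    # cannot create cross-helix clashes
    from scipy.spatial.distance import cdist

    dmat = cdist(host.ca, partner.ca)
    mobile = [(0, i) for i in range(host.n_res) if dmat[i].min() < 11.0]
    mobile += [(1, j) for j in range(partner.n_res) if dmat[:, j].min() < 11.0]
    rng = np.random.default_rng(seed)
    packed, _ = repack_rotamers(helices, seqs, mobile, {}, rng, cfg)
    empty = ResidueAtoms([], np.empty((0, 3)), np.empty(0))
    pairs = []
    # clashes are attributed to the threaded sequence: pairs between the
    # threaded helix's side-chain atoms and any partner heavy atom
    for i in range(host.n_res):
        a = packed.get((0, i), empty)
        if not len(a.names):
            continue
        for j in range(partner.n_res):
            b = packed.get((1, j), empty)
            bb_b = _with_backbone(b, partner.coords[j])
            for dist in count_clashes(a, bb_b, cfg.clash_cutoff):
                pairs.append((i + 1, j + 1, float(dist)))
    return ClashReport(threaded_sequence=threaded, clashing_pairs=pairs)


def _with_backbone(sc: ResidueAtoms, backbone: np.ndarray) -> ResidueAtoms:
    names = ["N", "CA", "C", "O"] + sc.names
    xyz = np.concatenate([backbone, sc.xyz]) if len(sc.names) else backbone
    radii = np.concatenate([[1.55, 1.7, 1.7, 1.52], sc.radii])
    return ResidueAtoms(names, xyz, radii)


def derive_control_sequence(
    source_seq: str,
    interface_positions: tuple,
    seed: int = 0,
    weights: dict | None = None,
    max_attempts: int = 2000,
    required_motif_count: int = 4,
) -> str:
    """Derive a no-design control sequence from a natural donor helix.

    Interface letters are copied verbatim from the source; lipid-facing
    letters are drawn from the weighted apolar distribution; Ala and Leu
    are appended at the C terminus so the small-X6-small residue count
    reaches the required depth while alanine is never the last apolar
    residue.  Draws are rejected (whole sequence) while a forbidden
    emergent Ala-X3-Ala / Ala-X6-Ala pair exists at lipid-facing
    positions or the final motif count is off.
    """
    weights = weights or APOLAR_WEIGHTS
    interface = set(interface_positions)
    bad = [p for p in interface if not 1 <= p <= len(source_seq)]
    if bad:
        raise ValueError(f"interface positions out of range: {bad}")
    letters = list(weights)
    probs = np.array([weights[k] for k in letters], dtype=float)
    probs = probs / probs.sum()
    rng = np.random.default_rng(seed)
    lipid = [p for p in range(1, len(source_seq) + 1) if p not in interface]
    for _ in range(max_attempts):
        seq = list(source_seq)
        draws = rng.choice(len(letters), size=len(lipid), p=probs)
        for p, k in zip(lipid, draws):
            seq[p - 1] = letters[k]
        seq = seq + ["A", "L"]  # C-terminal extension
        candidate = "".join(seq)
        if _has_forbidden_ala(candidate, set(lipid) | {len(candidate) - 1}):
            continue
        hits = find_small_x6_small(candidate, min_repeats=2)
        n_motif = max((len(h.positions) for h in hits), default=0)
        if n_motif != required_motif_count:
            continue
        return candidate
    raise RuntimeError(
        f"no control sequence satisfying the motif/Ala constraints found in "
        f"{max_attempts} attempts (source motif layout may be incompatible)"
    )


def _has_forbidden_ala(seq: str, variable_positions: set) -> bool:
    for i, aa in enumerate(seq, start=1):
        if aa != "A":
            continue
        for gap in FORBIDDEN_ALA_SPACINGS:
            j = i + gap
            if j <= len(seq) and seq[j - 1] == "A":
                if i in variable_positions or j in variable_positions:
                    return True
    return False


def pairwise_identity(
    a: str, b: str, mode: str = "best_offset"
) -> tuple[float, list[int]]:
    """Percent identity and 1-based mismatch positions.

    ``fixed`` compares equal-length sequences position by position;
    ``best_offset`` slides the shorter sequence over the longer without
    gaps and reports the best window (denominator = aligned length).
    Mismatch positions refer to the first sequence.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    if mode == "fixed":
        if len(a) != len(b):
            raise ValueError("fixed mode requires equal-length sequences")
        offsets = [0]
        swap = False
    elif mode == "best_offset":
        swap = len(a) < len(b)
        if swap:
            a, b = b, a
        offsets = range(len(a) - len(b) + 1)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    best = None
    for off in offsets:
        window = a[off : off + len(b)]
        mism = [i + 1 + off for i, (x, y) in enumerate(zip(window, b)) if x != y]
        pct = 100.0 * (len(b) - len(mism)) / len(b)
        if best is None or pct > best[0]:
            best = (pct, mism)
    return best
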