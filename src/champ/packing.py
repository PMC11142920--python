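"""Simplified side-chain packing engine.

Energy model (all weights in :data:`PackingConfig`):

* a soft 6-12 steric term between heavy atoms, attractive at van der
  Waals contact and capped at short range so that clashing rotamers are
  strongly but finitely penalized;
* a geometric hydrogen-bond term: donor/acceptor oxygen-nitrogen pairs
  closer than 3.5 A with a donor-base angle above 120 degrees score a
  fixed bonus;
* per-residue reference energies that make larger side chains pay for
  the contacts they gain, so polyalanine is neither degenerate nor
  unbeatable.

Packing is simulated annealing over a discrete rotamer/identity space
with geometric cooling; on toy problems it is checked against
exhaustive enumeration.  All randomness flows through a caller-supplied
``numpy`` generator, so runs are reproducible per seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import product

import numpy as np
from scipy.spatial.distance import cdist

from champ.geometry import HelixBackbone
from champ.sidechains import ROTAMERS, atom_element, atom_radius, build_sidechain


@dataclass
class PackingConfig:
    lj_eps: float = 0.15  # well depth, arbitrary energy units
    lj_radius_scale: float = 0.95  # contact distance = scale * (r_i + r_j)
    lj_cap: float = 20.0  # short-range repulsion cap per atom pair
    hbond_energy: float = -1.0
    hbond_dist: float = 3.5  # donor-acceptor heavy atom distance, A
    hbond_angle: float = 120.0  # minimum donor-base angle, deg
    clash_cutoff: float = 2.8  # heavy-atom distance counted as a clash, A
    reference: dict = field(default_factory=lambda: {
        "G": 0.0, "A": 0.0, "S": 0.15, "C": 0.2, "T": 0.2, "V": 0.3,
        "L": 0.5, "I": 0.5, "M": 0.6, "F": 0.7,
        "P": 0.3, "N": 0.3, "D": 0.3, "Q": 0.4, "E": 0.4, "H": 0.5,
        "K": 0.5, "R": 0.6, "W": 0.9, "Y": 0.8,
    })
    # annealing schedule
    t_start: float = 5.0
    t_end: float = 0.05
    sweeps: int = 60  # Monte-Carlo sweeps over all designable positions


_HB_DONOR_BASE = {"OG": "CB", "OG1": "CB"}  # side-chain hydroxyl donors


@dataclass
class ResidueAtoms:
    """Heavy atoms of one residue: names, coordinates, radii."""

    names: list
    xyz: np.ndarray
    radii: np.ndarray


def sidechain_atoms(
    resname: str, backbone: np.ndarray, chis: tuple
) -> ResidueAtoms:
    """Side-chain heavy atoms (CB and beyond) for one residue."""
    n, ca, c = backbone[0], backbone[1], backbone[2]
    atoms = build_sidechain(resname, n, ca, c, chis)
    names = list(atoms)
    if not names:
        return ResidueAtoms([], np.empty((0, 3)), np.empty(0))
    xyz = np.array([atoms[k] for k in names])
    radii = np.array([atom_radius(resname, k) for k in names])
    return ResidueAtoms(names, xyz, radii)


def _pair_energy(
    a: ResidueAtoms, b: ResidueAtoms, cfg: PackingConfig,
    a_res: str = "X", b_res: str = "X",
    a_backbone: np.ndarray | None = None,
) -> float:
    """Steric + hydrogen-bond energy between two atom groups."""
    if len(a.names) == 0 or len(b.names) == 0:
        return 0.0
    d = cdist(a.xyz, b.xyz)
    r0 = cfg.lj_radius_scale * (a.radii[:, None] + b.radii[None, :])
    x = np.clip(r0 / np.maximum(d, 0.5), None, 2.2)
    lj = cfg.lj_eps * (x**12 - 2.0 * x**6)
    e = float(np.minimum(lj, cfg.lj_cap).sum())
    # hydrogen bonds between oxygens/nitrogens
    for i, na in enumerate(a.names):
        if atom_element(na) not in ("O", "N"):
            continue
        for j, nb in enumerate(b.names):
            if atom_element(nb) not in ("O", "N"):
                continue
            if d[i, j] < cfg.hbond_dist:
                base = _HB_DONOR_BASE.get(na)
                ok = True
                if base is not None and a_backbone is not None:
                    ok = _angle(a_backbone[1], a.xyz[i], b.xyz[j]) > cfg.hbond_angle
                if ok:
                    e += cfg.hbond_energy
    return e


def _angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    v1 = a - b
    v2 = c - b
    cosv = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return math.degrees(math.acos(np.clip(cosv, -1.0, 1.0)))


def count_clashes(a: ResidueAtoms, b: ResidueAtoms, cutoff: float) -> list[float]:
    if len(a.names) == 0 or len(b.names) == 0:
        return []
    d = cdist(a.xyz, b.xyz)
    return d[d < cutoff].tolist()


class PackProblem:
    """Discrete packing problem over designable positions of a two-helix
    complex.

    ``positions`` are (chain_index, residue_index) pairs; every other
    residue contributes fixed atoms to the environment.  Energies are
    precomputed into self/pair tables so annealing and exhaustive
    enumeration share the exact same energy surface.
    """

    def __init__(
        self,
        helices: list[HelixBackbone],
        fixed_sidechains: dict[tuple, ResidueAtoms],
        positions: list[tuple],
        choices: dict[tuple, list],
        cfg: PackingConfig | None = None,
    ):
        self.cfg = cfg or PackingConfig()
        self.helices = helices
        self.positions = list(positions)
        self.choices = {p: list(choices[p]) for p in self.positions}
        self.fixed = fixed_sidechains
        self._build_tables()

    # -- table construction -------------------------------------------------
    def _residue_backbone(self, key: tuple) -> np.ndarray:
        ch, i = key
        return self.helices[ch].coords[i]

    def _candidate_atoms(self, key: tuple) -> list[ResidueAtoms]:
        out = []
        for aa, chis in self.choices[key]:
            out.append(sidechain_atoms(aa, self._residue_backbone(key), chis))
        return out

    def _environment(self, key: tuple) -> ResidueAtoms:
        """Fixed atoms a designable residue interacts with, merged into one
        group: backbone atoms of non-adjacent residues plus fixed side
        chains of non-designable residues."""
        ch, i = key
        names, xyz, radii = [], [], []
        bb_radii = [atom_radius("A", a) for a in ("N", "CA", "C", "O")]
        for hch, helix in enumerate(self.helices):
            for j in range(helix.n_res):
                if hch == ch and abs(j - i) < 2:
                    continue
                names += ["N", "CA", "C", "O"]
                xyz.append(helix.coords[j])
                radii += bb_radii
                fk = (hch, j)
                if fk in self.fixed and fk not in self.choices:
                    fa = self.fixed[fk]
                    if len(fa.names):
                        names += fa.names
                        xyz.append(fa.xyz)
                        radii += list(fa.radii)
        return ResidueAtoms(names, np.concatenate(xyz), np.array(radii))

    def _build_tables(self):
        cfg = self.cfg
        self.cand_atoms = {p: self._candidate_atoms(p) for p in self.positions}
        self.self_energy = {}
        for p in self.positions:
            env = self._environment(p)
            bbp = self._residue_backbone(p)
            energies = []
            for (aa, chis), atoms in zip(self.choices[p], self.cand_atoms[p]):
                e = cfg.reference.get(aa, 0.0)
                e += _pair_energy(atoms, env, cfg, a_backbone=bbp)
                energies.append(e)
            self.self_energy[p] = np.array(energies)
        # pairwise tables between designable positions whose CAs are close
        self.pair_keys = []
        self.pair_energy = {}
        for ia, p in enumerate(self.positions):
            for q in self.positions[ia + 1:]:
                ca_p = self._residue_backbone(p)[1]
                ca_q = self._residue_backbone(q)[1]
                if np.linalg.norm(ca_p - ca_q) > 14.0:
                    continue
                tab = np.zeros((len(self.choices[p]), len(self.choices[q])))
                bbp = self._residue_backbone(p)
                for ci, atoms_p in enumerate(self.cand_atoms[p]):
                    for cj, atoms_q in enumerate(self.cand_atoms[q]):
                        tab[ci, cj] = _pair_energy(atoms_p, atoms_q, self.cfg,
                                                   a_backbone=bbp)
                if np.abs(tab).max() > 1e-9:
                    self.pair_keys.append((p, q))
                    self.pair_energy[(p, q)] = tab

    # -- energies ------------------------------------------------------------
    def total_energy(self, assignment: dict) -> float:
        e = sum(self.self_energy[p][assignment[p]] for p in self.positions)
        for (p, q), tab in self.pair_energy.items():
            e += tab[assignment[p], assignment[q]]
        return float(e)

    # -- solvers -------------------------------------------------------------
    def anneal(
        self,
        rng: np.random.Generator,
        active: list | None = None,
        init: dict | None = None,
    ) -> tuple[dict, float]:
        """Simulated annealing with geometric cooling; returns the best
        assignment seen and its energy.

        ``active`` restricts moves to a subset of positions (others stay
        at their ``init`` choice), which implements class-ordered packing
        passes (core first, then boundary, then the rest).
        """
        cfg = self.cfg
        if init is not None:
            assign = dict(init)
        else:
            assign = {
                p: int(rng.integers(len(self.choices[p]))) for p in self.positions
            }
        movable = list(active) if active is not None else self.positions
        energy = self.total_energy(assign)
        best = dict(assign)
        best_e = energy
        n_moves = max(1, cfg.sweeps * len(movable))
        temps = cfg.t_start * (cfg.t_end / cfg.t_start) ** (
            np.arange(n_moves) / max(n_moves - 1, 1)
        )
        # per-position incident pair list for delta energies
        incident = {p: [] for p in self.positions}
        for (p, q), tab in self.pair_energy.items():
            incident[p].append((q, tab, False))
            incident[q].append((p, tab, True))
        for t in temps:
            p = movable[int(rng.integers(len(movable)))]
            old = assign[p]
            new = int(rng.integers(len(self.choices[p])))
            if new == old:
                continue
            delta = self.self_energy[p][new] - self.self_energy[p][old]
            for q, tab, transposed in incident[p]:
                if transposed:
                    delta += tab[assign[q], new] - tab[assign[q], old]
                else:
                    delta += tab[new, assign[q]] - tab[old, assign[q]]
            if delta <= 0 or rng.random() < math.exp(-delta / t):
                assign[p] = new
                energy += delta
                if energy < best_e - 1e-12:
                    best_e = energy
                    best = dict(assign)
        return best, float(best_e)

    def exhaustive(self) -> tuple[dict, float]:
        """Exact minimum by enumeration (only for toy problems)."""
        sizes = [len(self.choices[p]) for p in self.positions]
        if np.prod(sizes, dtype=float) > 2e6:
            raise ValueError("exhaustive enumeration only supported on toy problems")
        best = None
        best_e = np.inf
        for combo in product(*[range(s) for s in sizes]):
            assign = dict(zip(self.positions, combo))
            e = self.total_energy(assign)
            if e < best_e:
                best_e = e
                best = assign
        return best, float(best_e)

    def atoms_for(self, assignment: dict) -> dict[tuple, ResidueAtoms]:
        return {p: self.cand_atoms[p][assignment[p]] for p in self.positions}


def repack_rotamers(
    helices: list[HelixBackbone],
    sequences: list[str],
    mobile: list[tuple],
    fixed_sidechains: dict[tuple, ResidueAtoms],
    rng: np.random.Generator,
    cfg: PackingConfig | None = None,
) -> tuple[dict[tuple, ResidueAtoms], float]:
    """Repack rotamers (fixed identities) at ``mobile`` positions."""
    choices = {}
    for ch, i in mobile:
        aa = sequences[ch][i]
        choices[(ch, i)] = [(aa, r) for r in ROTAMERS[aa]]
    prob = PackProblem(helices, fixed_sidechains, mobile, choices, cfg)
    assign, energy = prob.anneal(rng)
    return prob.atoms_for(assign), energy


# ---------------------------------------------------------------------------
# packing quality score


def packing_score(
    helices: list[HelixBackbone],
    sidechains: dict[tuple, ResidueAtoms],
    probe_radii: tuple = (0.9, 1.2, 1.5, 1.8),
    grid_spacing: float = 0.7,
    interface_cb_dist: float = 7.0,
) -> float:
    """Interfacial void score in [0, 1]; higher = fewer voids.

    Occupancy fractions at multiple probe radii are averaged over a shell
    of grid points near the surface of both chains.  The grid is built in
    a frame derived from the interface atoms themselves, so the score is
    invariant under global rigid motion.
    """
    groups = []
    for ch, helix in enumerate(helices):
        for i in range(helix.n_res):
            names = ["N", "CA", "C", "O"]
            xyz = [helix.coords[i, k] for k in range(4)]
            radii = [atom_radius("A", a) for a in names]
            sc = sidechains.get((ch, i))
            if sc is not None and len(sc.names):
                names = names + sc.names
                xyz = xyz + list(sc.xyz)
                radii = radii + list(sc.radii)
            groups.append((ch, np.array(xyz), np.array(radii)))
    chains = np.concatenate([[g[0]] * len(g[1]) for g in groups])
    xyz = np.concatenate([g[1] for g in groups])
    radii = np.concatenate([g[2] for g in groups])
    if len(set(chains.tolist())) < 2:
        raise ValueError("packing score needs two chains")

    # interface atoms: within interface_cb_dist + 2 of the other chain
    d01 = cdist(xyz[chains == 0], xyz[chains == 1])
    near0 = (d01.min(axis=1) < interface_cb_dist + 2.0)
    near1 = (d01.min(axis=0) < interface_cb_dist + 2.0)
    iface = np.concatenate([near0, near1])
    if iface.sum() < 4:
        return 0.0
    pts_ref = xyz[np.concatenate([np.flatnonzero(chains == 0)[near0],
                                  np.flatnonzero(chains == 1)[near1]])]
    # deterministic local frame from interface atoms
    mu = pts_ref.mean(axis=0)
    cov = np.cov((pts_ref - mu).T)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    axes = evecs[:, order]
    # fix axis signs by the first atom's coordinates
    anchor = pts_ref[0] - mu
    for k in range(3):
        if np.dot(axes[:, k], anchor) < 0:
            axes[:, k] = -axes[:, k]
    if np.linalg.det(axes) < 0:
        axes[:, 2] = -axes[:, 2]
    local = (pts_ref - mu) @ axes
    lo = local.min(axis=0) - 2.0
    hi = local.max(axis=0) + 2.0
    grids = [np.arange(lo[k], hi[k] + grid_spacing, grid_spacing) for k in range(3)]
    gx, gy, gz = np.meshgrid(*grids, indexing="ij")
    pts_local = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
    pts = pts_local @ axes.T + mu

    # distance from each grid point to each chain's atom surfaces
    gap0 = cdist(pts, xyz[chains == 0]) - radii[chains == 0]
    gap1 = cdist(pts, xyz[chains == 1]) - radii[chains == 1]
    m0 = gap0.min(axis=1)
    m1 = gap1.min(axis=1)
    surf = np.minimum(m0, m1)
    shell = (surf > 0.0) & (surf < 3.0) & (m0 < 4.5) & (m1 < 4.5)
    if shell.sum() == 0:
        return 0.0
    occ = [float(np.mean(surf[shell] < r)) for r in probe_radii]
    return float(np.mean(occ))
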