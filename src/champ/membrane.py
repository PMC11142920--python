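"""Implicit-bilayer orientation and binder placement.

The bilayer is a slab normal to +z, centered at z = 0.  A helix is
oriented by minimizing a per-residue transfer energy: each residue type
carries a water-to-bilayer pseudo-energy that is switched on by a
sigmoid burial profile of its CA depth.  Only the rigid orientation
(z shift, tilt, tilt azimuth) is optimized, never internal geometry.

The binder helix is then placed against the oriented target using the
idealized antiparallel two-helix template, registered on the target's
small-X6-small motif.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from champ.geometry import (
    CrickParams,
    GeometryError,
    HelixBackbone,
    _helix_axis,
    generate_crick_backbone,
    pair_descriptors,
    superpose,
)
from champ.motifs import MotifHit, find_small_x6_small

#: water -> bilayer transfer pseudo-energies (negative = prefers the core)
TRANSFER_ENERGY = {
    "A": -0.4, "C": -0.5, "D": 3.5, "E": 3.5, "F": -1.4, "G": -0.1,
    "H": 2.0, "I": -1.2, "K": 3.5, "L": -1.3, "M": -1.0, "N": 1.2,
    "P": 1.0, "Q": 1.2, "R": 3.5, "S": 0.3, "T": 0.3, "V": -1.0,
    "W": -0.6, "Y": -0.2,
}


@dataclass
class MembraneFrame:
    """Implicit bilayer slab: normal +z, center z = 0."""

    half_thickness: float = 15.0  # A, hydrophobic half-width
    interface_width: float = 2.0  # A, sigmoid softness at the interface

    def __post_init__(self):
        if self.half_thickness <= 0:
            raise ValueError("half thickness must be > 0")

    def burial(self, z: np.ndarray) -> np.ndarray:
        """Smooth 0..1 burial weight of a depth z."""
        return 1.0 / (1.0 + np.exp((np.abs(z) - self.half_thickness) / self.interface_width))


@dataclass
class TMComplexModel:
    """Target + binder helices in a membrane frame."""

    target: HelixBackbone
    binder: HelixBackbone
    frame: MembraneFrame
    register: dict = field(default_factory=dict)  # binder pos -> target pos (1-based)
    template: CrickParams | None = None
    sidechains: dict = field(default_factory=dict)  # (chain_idx, res_idx) -> ResidueAtoms

    def __post_init__(self):
        _, u = _helix_axis(self.target.ca)
        _, v = _helix_axis(self.binder.ca)
        if self.template is not None and self.template.orientation == "antiparallel":
            if float(np.dot(u, v)) >= 0:
                raise GeometryError("binder is not antiparallel to the target")

    @property
    def helices(self) -> list[HelixBackbone]:
        return [self.target, self.binder]

    def embedded_binder_positions(self, margin: float = 6.0) -> list[int]:
        """1-based binder positions whose CA lies within the hydrophobic
        slab extended by the interfacial (headgroup) shell."""
        zmax = self.frame.half_thickness + margin
        return [
            i + 1
            for i in range(self.binder.n_res)
            if abs(self.binder.ca[i, 2]) <= zmax
        ]


def _orient(helix: HelixBackbone, z_shift: float, tilt_deg: float, azim_deg: float) -> HelixBackbone:
    """Tilt the helix about its centroid, then shift along z."""
    t = math.radians(tilt_deg)
    a = math.radians(azim_deg)
    axis = np.array([math.cos(a), math.sin(a), 0.0])
    k = axis
    kx = np.array([
        [0, -k[2], k[1]],
        [k[2], 0, -k[0]],
        [-k[1], k[0], 0],
    ])
    rot = np.eye(3) + math.sin(t) * kx + (1 - math.cos(t)) * (kx @ kx)
    centroid = helix.ca.mean(axis=0)
    coords = (helix.coords - centroid) @ rot.T + centroid
    coords[..., 2] += z_shift - centroid[2]
    return HelixBackbone(helix.sequence, coords, helix.id)


#: elastic cost of tilting away from the membrane normal (hydrophobic
#: mismatch / lipid deformation proxy): E = weight * (1 - cos tilt).
#: Large enough that a uniformly hydrophobic helix stays near-upright
#: instead of lying flat to maximize burial; asymmetric sequences still
#: shift and tilt as their flanks demand.
TILT_PENALTY = 60.0


def transfer_energy(
    helix: HelixBackbone, frame: MembraneFrame, scale: dict | None = None
) -> float:
    """Per-residue water->bilayer transfer energy (no tilt elasticity)."""
    scale = scale or TRANSFER_ENERGY
    g = np.array([scale[aa] for aa in helix.sequence])
    return float(np.sum(g * frame.burial(helix.ca[:, 2])))


def orientation_energy(
    helix: HelixBackbone,
    frame: MembraneFrame,
    z: float,
    tilt: float,
    azim: float,
    scale: dict | None = None,
    tilt_penalty: float = TILT_PENALTY,
) -> float:
    """Full orientation objective: transfer energy + tilt elasticity."""
    e = transfer_energy(_orient(helix, z, tilt, azim), frame, scale)
    return e + tilt_penalty * (1.0 - math.cos(math.radians(tilt)))


def insert_in_membrane(
    helix: HelixBackbone,
    frame: MembraneFrame | None = None,
    scale: dict | None = None,
    refine: bool = True,
) -> tuple[HelixBackbone, float, float]:
    """Orient a helix in the implicit bilayer.

    Deterministic grid search over (z shift, tilt, tilt azimuth)
    followed by a local simplex refinement; grid ties are broken toward
    zero tilt and zero depth.  Returns (oriented helix, depth of the CA
    centroid, tilt in degrees).  A helix too short to span the slab is
    still placed (best effort).
    """
    frame = frame or MembraneFrame()
    if helix.n_res < 15:
        import warnings

        warnings.warn("helix may be too short to span the bilayer; best-effort placement")

    def energy(z, tilt, azim):
        # orientations outside the TM regime are out of scope
        if not (-12.5 <= z <= 12.5) or not (0.0 <= tilt <= 44.0):
            return 1e6
        return orientation_energy(helix, frame, z, tilt, azim, scale)

    best = None
    for tilt in range(0, 45, 5):
        for azim in range(0, 360, 30) if tilt else [0]:
            for z in range(-10, 11, 2):
                e = energy(z, tilt, azim)
                key = (round(e, 9), tilt, abs(z))
                if best is None or key < best[0]:
                    best = (key, (float(z), float(tilt), float(azim)))
    (e_grid, *_), (z0, t0, a0) = best
    z, tilt, azim = z0, t0, a0
    if refine:
        res = minimize(
            lambda x: energy(*x), [z0, t0, a0], method="Nelder-Mead",
            options={"xatol": 1e-4, "fatol": 1e-9, "maxiter": 400},
        )
        if res.fun < e_grid - 1e-9:
            z, tilt, azim = (float(v) for v in res.x)
    oriented = _orient(helix, z, tilt, azim)
    depth = float(oriented.ca[:, 2].mean())
    return oriented, depth, abs(float(tilt)) % 360.0


def place_binder(
    target: HelixBackbone,
    template: CrickParams,
    motif: MotifHit | None = None,
    binder_length: int = 24,
    frame: MembraneFrame | None = None,
    register_shift: int = 0,
) -> TMComplexModel:
    """Place a polyalanine binder helix against the oriented target.

    The idealized two-helix template is generated from ``template``,
    its first helix is superposed onto the target so that the target's
    small-X6-small motif occupies the template's partner-facing face,
    and the second (binder) helix is carried along.  ``register_shift``
    moves the register by whole motif repeats (multiples of 7).
    """
    frame = frame or MembraneFrame()
    if motif is None:
        hits = find_small_x6_small(target.sequence, min_repeats=3)
        if not hits:
            raise GeometryError("target has no small-X6-small motif")
        motif = hits[0]
    n_tpl = max(target.n_res, binder_length) + 14
    tpl_a, tpl_b = generate_crick_backbone(template, n_tpl)
    # template-A positions facing the partner: the minor-helix phase of
    # the generated template puts t = 0 (the central residue) on the
    # interface, so partner-facing positions are center + multiples of 7
    center = (n_tpl - 1) // 2 + 1  # 1-based
    mid_motif = motif.positions[len(motif.positions) // 2]
    offset = (mid_motif + register_shift) - center
    register = {}
    for i in range(1, n_tpl + 1):
        j = i + offset
        if 1 <= j <= target.n_res:
            register[i] = j
    rot, trans, _ = superpose(tpl_a, target, register)
    placed_b = tpl_b.transformed(rot, trans)
    # Trim the binder to length.  The window start is chosen congruent
    # (mod 7) with the most target-buried binder position, so the
    # binder's own small-X6-small frame falls on positions 1, 8, 15, 22;
    # among such windows, take the one best centered in the slab.
    if binder_length < n_tpl:
        tpts, taxis = _helix_axis(target.ca)
        mu = tpts.mean(axis=0)
        def axis_dist(p):
            v = p - mu
            return float(np.linalg.norm(v - np.dot(v, taxis) * taxis))
        burial = [axis_dist(placed_b.ca[i]) for i in range(n_tpl)]
        p_star = int(np.argmin(burial))
        starts = [
            s for s in range(p_star % 7, n_tpl - binder_length + 1, 7)
        ] or [max(0, min(p_star, n_tpl - binder_length))]
        def window_extent(s):
            z = placed_b.ca[s : s + binder_length, 2]
            return float(np.max(np.abs(z)))
        lo = min(starts, key=window_extent)
        coords = placed_b.coords[lo : lo + binder_length]
        placed_b = HelixBackbone("A" * binder_length, coords, "B")
    else:
        placed_b = HelixBackbone("A" * placed_b.n_res, placed_b.coords, "B")
    # register map: binder position -> nearest target position by CA distance
    reg = {}
    for i in range(placed_b.n_res):
        j = int(np.argmin(np.linalg.norm(target.ca - placed_b.ca[i], axis=1)))
        reg[i + 1] = j + 1
    model = TMComplexModel(
        target=target, binder=placed_b, frame=frame, register=reg, template=template
    )
    desc = pair_descriptors(target, placed_b)
    want = 2.0 * template.r0
    if abs(desc.closest_approach_distance - want) > 0.5:
        raise GeometryError(
            f"binder placement deviates from template: distance "
            f"{desc.closest_approach_distance:.2f} vs {want:.2f}"
        )
    return model
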