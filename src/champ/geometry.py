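"""Parametric helix and coiled-coil geometry.

Coordinates are in Angstroms in a right-handed frame with the membrane
normal along +z.  Two-helix geometry follows the Crick coiled-coil
parameterization in its antiparallel special case:

* Helix A runs N->C along +z; its CA trace winds around the superhelical
  (z) axis at radius ``r0`` with superhelical frequency ``w0`` (degrees
  per residue) while the minor alpha-helix winds at radius ``r1`` with
  frequency ``w1``.
* Helix B is generated from the same equations and then rotated by 180
  degrees about the x axis (a proper rotation, ``(x, y, z) -> (x, -y,
  -z)``), so it runs N->C along -z, and finally shifted along z by
  ``z_offset``.  Its superhelical phase ``dphi0`` is measured from the
  superhelical axis after that rotation.
* Left-handed supercoils carry ``alpha < 0`` and ``w0 < 0`` (the two
  always share a sign); the signed interhelical crossing angle is then
  negative, so a tight antiparallel left-handed pair sits near -175
  degrees rather than +175.

The axial rise per residue along z implied by the parameterization is
``r0 * w0 / tan(alpha)`` (both negative for a left-handed pair, giving a
positive rise).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares

BACKBONE_ATOMS = ("N", "CA", "C", "O")

#: canonical alpha-helix defaults (config-overridable)
CANONICAL_RISE = 1.51  # A per residue along the helix axis
CANONICAL_TWIST = 100.0  # degrees per residue
CANONICAL_CA_RADIUS = 2.26  # A, CA distance from the helix axis
#: minor-helix frequency matching the 3.5-residue interface repeat of
#: a small-X6-small surface (two turns per 7 residues)
MOTIF_TWIST = 720.0 / 7.0

# Cylindrical placement of backbone atoms relative to the CA helix,
# measured from an ideal-internal-coordinate helix (phi=-57.8, psi=-47):
# (radius A, phase offset deg, z offset A), phase measured in the helix
# twist direction.  Used as starting values; phases/z-offsets of N and C
# are re-solved per (rise, twist) so bond lengths stay ideal.
_ATOM_CYL = {
    "N": (1.558, -26.77, -0.915),
    "C": (1.678, 26.81, 1.065),
    "O": (1.937, 20.43, 2.252),
}

_STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")


class GeometryError(ValueError):
    """Raised for invalid geometric inputs or non-convergent fits."""


@dataclass
class HelixBackbone:
    """An alpha-helical backbone: per-residue N, CA, C, O coordinates.

    ``coords`` has shape (n_res, 4, 3) with atoms ordered N, CA, C, O.
    """

    sequence: str
    coords: np.ndarray
    id: str = "helix"

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.sequence), 4, 3):
            raise GeometryError(
                f"coords shape {self.coords.shape} does not match sequence "
                f"length {len(self.sequence)}"
            )
        if len(self.sequence) < 4:
            raise GeometryError("a helix needs at least 4 residues")

    @property
    def n_res(self) -> int:
        return len(self.sequence)

    @property
    def ca(self) -> np.ndarray:
        return self.coords[:, 1, :]

    def atom(self, name: str) -> np.ndarray:
        return self.coords[:, BACKBONE_ATOMS.index(name), :]

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "HelixBackbone":
        new = self.coords @ np.asarray(rotation).T + np.asarray(translation)
        return HelixBackbone(self.sequence, new, self.id)

    def validate(self, tol_ca: float = 0.3, tol_bond: float = 0.1) -> None:
        """Check CA-CA spacing and backbone bond lengths against ideal values."""
        d = np.linalg.norm(np.diff(self.ca, axis=0), axis=1)
        if np.any(np.abs(d - 3.8) > tol_ca):
            bad = int(np.argmax(np.abs(d - 3.8)))
            raise GeometryError(
                f"CA-CA distance {d[bad]:.2f} A at residue {bad + 1} outside 3.8 +/- {tol_ca}"
            )
        n, ca, c, o = (self.atom(a) for a in BACKBONE_ATOMS)
        for name, left, right, ideal in [
            ("N-CA", n, ca, 1.458),
            ("CA-C", ca, c, 1.525),
            ("C=O", c, o, 1.231),
        ]:
            b = np.linalg.norm(right - left, axis=1)
            if np.any(np.abs(b - ideal) > tol_bond):
                raise GeometryError(f"{name} bond length outside {ideal} +/- {tol_bond}")
        pep = np.linalg.norm(self.atom("N")[1:] - self.atom("C")[:-1], axis=1)
        if np.any(np.abs(pep - 1.329) > tol_bond):
            raise GeometryError(f"peptide C-N bond length outside 1.329 +/- {tol_bond}")


@dataclass
class CrickParams:
    """Crick parameters for an (anti)parallel two-helix coiled coil."""

    r0: float  # superhelical radius, A
    r1: float = CANONICAL_CA_RADIUS  # helical (minor) radius, A
    w0: float = -0.93  # superhelical frequency, deg/residue (sign = handedness)
    w1: float = MOTIF_TWIST  # helical frequency, deg/residue
    alpha: float = -2.5  # pitch angle, deg (sign = handedness)
    phi1_a: float = 180.0  # minor-helix phase of helix A, deg
    phi1_b: float = 180.0  # minor-helix phase of helix B, deg
    dphi0: float = 180.0  # superhelical phase of helix B, deg
    z_offset: float = 0.0  # axial offset of helix B, A
    orientation: str = "antiparallel"

    def __post_init__(self):
        if self.orientation not in ("parallel", "antiparallel"):
            raise GeometryError(f"unknown orientation {self.orientation!r}")
        if self.r0 < 0:
            raise GeometryError("superhelical radius r0 must be >= 0")
        if not (1.5 <= self.r1 <= 3.0):
            raise GeometryError("helical radius r1 must lie in [1.5, 3.0] A")
        if self.r0 > 1e-6 and self.w0 * self.alpha < 0:
            raise GeometryError(
                "w0 and alpha must share a sign (handedness convention, see module docs)"
            )

    @property
    def rise_per_res(self) -> float:
        """Axial rise per residue along the superhelical axis, A."""
        if self.r0 < 1e-6 or abs(self.alpha) < 1e-9:
            return CANONICAL_RISE
        return self.r0 * math.radians(self.w0) / math.tan(math.radians(self.alpha))

    @property
    def is_degenerate(self) -> bool:
        """True when r0 ~ 0 (no supercoil: coaxial helices)."""
        return self.r0 < 1e-3

    @property
    def pair_geometry(self) -> tuple[float, float, float]:
        """(interhelical distance, signed crossing angle, z offset) implied
        by the parameters (antiparallel convention)."""
        distance = 2.0 * self.r0
        crossing = 180.0 - 2.0 * abs(self.alpha)
        if self.alpha < 0:
            crossing = -crossing
        return distance, crossing, self.z_offset

    @classmethod
    def from_pair_geometry(
        cls,
        distance: float,
        crossing_angle: float,
        z_offset: float = 0.0,
        rise: float = CANONICAL_RISE,
        r1: float = CANONICAL_CA_RADIUS,
        w1: float = MOTIF_TWIST,
    ) -> "CrickParams":
        """Construct antiparallel params from (interhelical distance,
        signed crossing angle, z offset).

        The crossing angle must be near +/-180 (antiparallel); its sign
        sets the handedness (negative = left-handed).
        """
        if not 90.0 < abs(crossing_angle) <= 180.0:
            raise GeometryError("antiparallel crossing angle must be in (90, 180]")
        r0 = distance / 2.0
        alpha = -(180.0 - abs(crossing_angle)) / 2.0
        if crossing_angle > 0:
            alpha = -alpha
        dz = rise * math.cos(math.radians(alpha))
        if abs(alpha) < 1e-9 or r0 < 1e-6:
            w0 = 0.0
        else:
            w0 = math.degrees(dz * math.tan(math.radians(alpha)) / r0)
        # place helix B on the opposite side of the superhelical axis at
        # the z where the two helices cross
        dphi0 = 180.0 - (w0 * z_offset / dz if dz else 0.0)
        return cls(
            r0=r0, r1=r1, w0=w0, w1=w1, alpha=alpha,
            dphi0=dphi0, z_offset=z_offset, orientation="antiparallel",
        )


@dataclass
class HelixPairGeometry:
    """Measured descriptors of a two-helix pair."""

    closest_approach_distance: float  # A, between fitted helix axes
    crossing_angle: float  # deg, signed (left-handed negative)
    axial_z_offset: float  # A along the superhelical axis
    handedness: str  # "left" | "right"
    contact_register: tuple = ()  # (residue_a, residue_b) at closest approach, 1-based

    def __post_init__(self):
        if self.closest_approach_distance <= 0:
            raise GeometryError("closest approach distance must be > 0")
        if not -180.0 < self.crossing_angle <= 180.0:
            raise GeometryError("crossing angle must lie in (-180, 180]")


# ---------------------------------------------------------------------------
# construction


from functools import lru_cache


@lru_cache(maxsize=32)
def _backbone_constants(rise: float, twist: float, radius: float):
    """Cylindrical (radius, phase deg, dz) for N, C, O on a CA helix of the
    given rise/twist/CA-radius, solved (least squares, since the fixed
    atom radii may leave no exact root) so that N-CA, CA-C, peptide C-N
    and C=O bond lengths and the N-CA-C angle stay ideal."""
    tw = math.radians(twist)

    def cyl(r, ph, dz, i=0.0):
        a = tw * i + math.radians(ph)
        return np.array([r * math.cos(a), r * math.sin(a), rise * i + dz])

    ca0 = cyl(radius, 0.0, 0.0, 0.0)
    ca1 = cyl(radius, 0.0, 0.0, 1.0)
    r_n, p_n0, z_n0 = _ATOM_CYL["N"]
    r_c, p_c0, z_c0 = _ATOM_CYL["C"]

    def eqs(x):
        p_n, z_n, p_c, z_c = x
        n0 = cyl(r_n, p_n, z_n, 0.0)
        n1 = cyl(r_n, p_n, z_n, 1.0)
        c0 = cyl(r_c, p_c, z_c, 0.0)
        v1 = n0 - ca0
        v2 = c0 - ca0
        ang = math.degrees(
            math.acos(np.clip(np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)), -1, 1))
        )
        return [
            np.linalg.norm(n0 - ca0) - 1.458,
            np.linalg.norm(c0 - ca0) - 1.525,
            np.linalg.norm(n1 - c0) - 1.329,
            0.02 * (ang - 111.2),  # ~1 deg weighted like 0.02 A
        ]

    sol = least_squares(eqs, [p_n0, z_n0, p_c0, z_c0], xtol=1e-14, ftol=1e-14)
    p_n, z_n, p_c, z_c = (float(v) for v in sol.x)
    # O bonded to C only: keep the ideal C->O offset direction, length 1.231
    c = cyl(r_c, p_c, z_c)
    o_ref = cyl(*_ATOM_CYL["O"])
    c_ref = cyl(r_c, p_c0, z_c0)
    direction = o_ref - c_ref
    o = c + direction / np.linalg.norm(direction) * 1.231
    r_o = math.hypot(o[0], o[1])
    p_o = math.degrees(math.atan2(o[1], o[0]))
    return {
        "N": (r_n, p_n, z_n),
        "C": (r_c, p_c, z_c),
        "O": (r_o, p_o, float(o[2])),
    }


def _check_sequence(sequence: str) -> None:
    for i, aa in enumerate(sequence):
        if aa not in _STANDARD_AA:
            raise GeometryError(
                f"non-standard residue letter {aa!r} at position {i + 1}"
            )


def build_ideal_helix(
    sequence: str,
    rise: float = CANONICAL_RISE,
    twist: float = CANONICAL_TWIST,
    id: str = "helix",
) -> HelixBackbone:
    """Build an ideal straight alpha-helix along +z, N-terminus at lowest z.

    The CA radius is chosen so consecutive CA atoms are 3.80 A apart at
    the requested rise and twist; N, C and O are placed on coaxial
    helices using offsets measured from ideal internal coordinates.
    """
    _check_sequence(sequence)
    if len(sequence) < 4:
        raise GeometryError("sequence length must be >= 4")
    n = len(sequence)
    tw = math.radians(twist)
    radius = math.sqrt((3.80**2 - rise**2) / (2.0 * (1.0 - math.cos(tw))))
    consts = _backbone_constants(round(rise, 6), round(twist, 6), round(radius, 6))
    coords = np.empty((n, 4, 3))
    for i in range(n):
        for k, name in enumerate(BACKBONE_ATOMS):
            if name == "CA":
                r, dphi, dz = radius, 0.0, 0.0
            else:
                r, dphi, dz = consts[name]
            ang = tw * i + math.radians(dphi)
            coords[i, k] = (r * math.cos(ang), r * math.sin(ang), rise * i + dz)
    return HelixBackbone(sequence, coords, id)


def _crick_ca(t: np.ndarray, p: CrickParams, phi0: float, phi1: float) -> np.ndarray:
    """CA positions of one Crick helix at residue parameters t (canonical frame)."""
    w0 = np.radians(p.w0)
    w1 = np.radians(p.w1)
    a = np.radians(p.alpha)
    ph0 = np.radians(phi0)
    ph1 = np.radians(phi1)
    w0t = w0 * t + ph0
    w1t = w1 * t + ph1
    x = p.r0 * np.cos(w0t) + p.r1 * np.cos(w0t) * np.cos(w1t) \
        - p.r1 * np.cos(a) * np.sin(w0t) * np.sin(w1t)
    y = p.r0 * np.sin(w0t) + p.r1 * np.sin(w0t) * np.cos(w1t) \
        + p.r1 * np.cos(a) * np.cos(w0t) * np.sin(w1t)
    z = p.rise_per_res * t - p.r1 * np.sin(a) * np.sin(w1t)
    return np.stack([x, y, z], axis=-1)


_RX180 = np.diag([1.0, -1.0, -1.0])


def _crick_pair_ca(p: CrickParams, n_res: int) -> tuple[np.ndarray, np.ndarray]:
    """CA traces of both helices in the canonical frame (helix A centered)."""
    t = np.arange(n_res, dtype=float) - (n_res - 1) / 2.0
    ca_a = _crick_ca(t, p, 0.0, p.phi1_a)
    ca_b = _crick_ca(t, p, p.dphi0, p.phi1_b)
    if p.orientation == "antiparallel":
        ca_b = ca_b @ _RX180.T
    ca_b = ca_b + np.array([0.0, 0.0, p.z_offset])
    return ca_a, ca_b


def _backbone_from_ca(ca: np.ndarray, sequence: str, id: str) -> HelixBackbone:
    """Dress a CA trace with N, C, O using local helical frames.

    Each residue's frame is built from the local helix axis (fit through
    neighboring CA centroids) and the CA radial direction, then the
    cylindrical offsets of the ideal helix are applied.
    """
    n = len(ca)
    coords = np.empty((n, 4, 3))
    coords[:, 1] = ca
    axis_pts, axis_dir = _helix_axis(ca)
    # local twist/rise/radius measured from the trace itself so the solved
    # backbone constants keep bond lengths ideal for any minor frequency
    on_ax = np.array([_project_point(p, axis_pts, axis_dir) for p in ca])
    radial_all = ca - on_ax
    radius = float(np.mean(np.linalg.norm(radial_all, axis=1)))
    rise = float(np.mean(np.dot(np.diff(on_ax, axis=0), axis_dir)))
    rhat = radial_all / np.linalg.norm(radial_all, axis=1, keepdims=True)
    angs = [
        math.atan2(np.dot(np.cross(rhat[i], rhat[i + 1]), axis_dir),
                   np.dot(rhat[i], rhat[i + 1]))
        for i in range(n - 1)
    ]
    twist = float(np.degrees(np.mean(angs)))
    consts = _backbone_constants(round(rise, 4), round(twist, 4), round(radius, 4))
    for i in range(n):
        on_axis = _project_point(ca[i], axis_pts, axis_dir)
        radial = ca[i] - on_axis
        rn = np.linalg.norm(radial)
        radial = radial / rn if rn > 1e-9 else _any_perp(axis_dir)
        tang = np.cross(axis_dir, radial)
        for k, name in enumerate(BACKBONE_ATOMS):
            if name == "CA":
                continue
            r, dphi, dz = consts[name]
            ang = math.radians(dphi)
            direction = math.cos(ang) * radial + math.sin(ang) * tang
            coords[i, k] = on_axis + r * direction + axis_dir * dz
    return HelixBackbone(sequence, coords, id)


def _any_perp(v: np.ndarray) -> np.ndarray:
    ref = np.array([1.0, 0.0, 0.0]) if abs(v[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    p = np.cross(v, ref)
    return p / np.linalg.norm(p)


def generate_crick_backbone(
    params: CrickParams, n_res: int, sequence: str | None = None
) -> tuple[HelixBackbone, HelixBackbone]:
    """Generate the two full backbones of an idealized coiled-coil pair.

    Helix A runs along +z; for the antiparallel case helix B runs along
    -z.  ``sequence`` (applied to both helices) defaults to polyalanine.
    """
    if n_res < 7:
        raise GeometryError("n_res must be >= 7")
    seq = sequence if sequence is not None else "A" * n_res
    if len(seq) != n_res:
        raise GeometryError("sequence length must equal n_res")
    ca_a, ca_b = _crick_pair_ca(params, n_res)
    helix_a = _backbone_from_ca(ca_a, seq, "A")
    helix_b = _backbone_from_ca(ca_b, seq, "B")
    return helix_a, helix_b


# ---------------------------------------------------------------------------
# axes and descriptors


def _helix_axis(ca: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-helix axis: least-squares line through rolling 4-CA centroids.

    Robust to end fraying.  Returns (centroid points, unit direction);
    the direction points from N- to C-terminus.
    """
    if len(ca) < 5:
        centroids = ca
    else:
        centroids = np.array([ca[i : i + 4].mean(axis=0) for i in range(len(ca) - 3)])
    mu = centroids.mean(axis=0)
    _, _, vt = np.linalg.svd(centroids - mu)
    direction = vt[0]
    if np.dot(direction, ca[-1] - ca[0]) < 0:
        direction = -direction
    return centroids, direction


def _project_point(p: np.ndarray, axis_pts: np.ndarray, axis_dir: np.ndarray) -> np.ndarray:
    mu = axis_pts.mean(axis=0)
    return mu + np.dot(p - mu, axis_dir) * axis_dir


def _line_closest_points(
    p1: np.ndarray, u: np.ndarray, p2: np.ndarray, v: np.ndarray
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Closest points between two infinite lines; flag True if parallel."""
    w0 = p1 - p2
    a, b, c = np.dot(u, u), np.dot(u, v), np.dot(v, v)
    d, e = np.dot(u, w0), np.dot(v, w0)
    denom = a * c - b * b
    if denom < 1e-12:
        # parallel: project p2 onto line 1
        s = 0.0
        t = e / c
        return p1, p2 + t * v, True
    s = (b * e - c * d) / denom
    t = (a * e - b * d) / denom
    return p1 + s * u, p2 + t * v, False


def pair_descriptors(
    helix_a: HelixBackbone, helix_b: HelixBackbone
) -> HelixPairGeometry:
    """Measure (closest approach, signed crossing angle, z offset) of a pair.

    The crossing angle is the angle from helix A's axis direction to
    helix B's, measured by the right-hand rule about the unit vector
    pointing from A to B at closest approach; left-handed crossings come
    out negative.  For parallel axes the angle is exactly 0 or 180.
    """
    pts_a, u = _helix_axis(helix_a.ca)
    pts_b, v = _helix_axis(helix_b.ca)
    ca_pt_a, ca_pt_b, is_parallel = _line_closest_points(
        pts_a.mean(axis=0), u, pts_b.mean(axis=0), v
    )
    if is_parallel:
        w = pts_b.mean(axis=0) - _project_point(pts_b.mean(axis=0), pts_a, u)
        dist = float(np.linalg.norm(w))
        angle = 0.0 if np.dot(u, v) > 0 else 180.0
    else:
        w = ca_pt_b - ca_pt_a
        dist = float(np.linalg.norm(w))
        what = w / dist if dist > 1e-9 else _any_perp(u)
        angle = float(
            np.degrees(np.arctan2(np.dot(np.cross(u, v), what), np.dot(u, v)))
        )
        if angle <= -180.0:
            angle += 360.0
    antiparallel = np.dot(u, v) < 0
    # superhelical axis direction, oriented along helix A
    zs = u - v if antiparallel else u + v
    zs = zs / np.linalg.norm(zs)
    z_off = float(np.dot(helix_b.ca.mean(axis=0) - helix_a.ca.mean(axis=0), zs))
    reg_a = int(np.argmin(np.linalg.norm(helix_a.ca - ca_pt_a, axis=1))) + 1
    reg_b = int(np.argmin(np.linalg.norm(helix_b.ca - ca_pt_b, axis=1))) + 1
    handed = "left" if angle < 0 else "right"
    return HelixPairGeometry(
        closest_approach_distance=dist,
        crossing_angle=angle,
        axial_z_offset=z_off,
        handedness=handed,
        contact_register=((reg_a, reg_b),),
    )


# ---------------------------------------------------------------------------
# superposition


def kabsch(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition (rotation, translation, rmsd)."""
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    h = (mobile - mc).T @ (reference - rc)
    u, _, vt = np.linalg.svd(h)
    sign = np.sign(np.linalg.det(vt.T @ u.T))
    d = np.diag([1.0, 1.0, sign])
    rot = vt.T @ d @ u.T
    trans = rc - rot @ mc
    moved = mobile @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((moved - reference) ** 2, axis=1))))
    return rot, trans, rmsd


def superpose(
    mobile: HelixBackbone,
    reference: HelixBackbone,
    register: dict[int, int] | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition of CA atoms over a residue register.

    ``register`` maps 1-based mobile residue -> 1-based reference
    residue; defaults to the identity over the shorter helix.
    Returns (rotation matrix, translation vector, rmsd).
    """
    if register is None:
        n = min(mobile.n_res, reference.n_res)
        register = {i: i for i in range(1, n + 1)}
    if len(register) < 4:
        raise GeometryError("register must map at least 4 residue pairs")
    bad = [
        (m, r)
        for m, r in register.items()
        if not (1 <= m <= mobile.n_res) or not (1 <= r <= reference.n_res)
    ]
    if bad:
        raise GeometryError(f"register indices out of range: {bad}")
    mob = np.array([mobile.ca[m - 1] for m in register])
    ref = np.array([reference.ca[register[m] - 1] for m in register])
    return kabsch(mob, ref)


# ---------------------------------------------------------------------------
# fitting


def measure_twist(helix: HelixBackbone) -> float:
    """Mean per-residue twist of the CA helix, degrees.

    Uses second differences of the CA trace: for an ideal helix these
    chords lie exactly in the plane perpendicular to the axis and rotate
    by the twist per residue, so the measurement is exact (no axis-fit
    end bias)."""
    ca = helix.ca
    v = np.diff(ca, axis=0)
    w = np.diff(v, axis=0)
    crosses = [np.cross(w[i], w[i + 1]) for i in range(len(w) - 1)]
    axis = np.sum(crosses, axis=0)
    axis = axis / np.linalg.norm(axis)
    angs = [
        np.arctan2(np.dot(np.cross(w[i], w[i + 1]), axis), np.dot(w[i], w[i + 1]))
        for i in range(len(w) - 1)
    ]
    return float(np.degrees(np.mean(angs)))


def _canonical_transform(
    helix_a: HelixBackbone, helix_b: HelixBackbone, desc: HelixPairGeometry
) -> tuple[np.ndarray, np.ndarray]:
    """Rotation/translation taking the pair near its canonical Crick frame."""
    pts_a, u = _helix_axis(helix_a.ca)
    pts_b, v = _helix_axis(helix_b.ca)
    antiparallel = np.dot(u, v) < 0
    zs = u - v if antiparallel else u + v
    zs /= np.linalg.norm(zs)
    pa, pb, _ = _line_closest_points(pts_a.mean(axis=0), u, pts_b.mean(axis=0), v)
    # x axis: from superhelical axis toward helix A at the crossing
    xs = pa - (pa + pb) / 2.0
    xs = xs - np.dot(xs, zs) * zs
    nx = np.linalg.norm(xs)
    xs = xs / nx if nx > 1e-9 else _any_perp(zs)
    ys = np.cross(zs, xs)
    rot = np.stack([xs, ys, zs])  # world -> canonical
    # translate so helix A's CA centroid sits at z = 0 on the canonical frame
    center = helix_a.ca.mean(axis=0)
    origin = (pa + pb) / 2.0
    origin = origin + np.dot(center - origin, zs) * zs
    return rot, -rot @ origin


def _pack_params(p: CrickParams) -> np.ndarray:
    return np.array(
        [p.r0, p.r1, p.w0, p.w1, p.alpha, p.phi1_a, p.phi1_b, p.dphi0, p.z_offset]
    )


def _unpack_params(x: np.ndarray, orientation: str) -> CrickParams:
    return CrickParams(
        r0=abs(float(x[0])),
        r1=float(np.clip(x[1], 1.5, 3.0)),
        w0=float(x[2]),
        w1=float(x[3]),
        alpha=float(x[4]),
        phi1_a=float(x[5]) % 360.0,
        phi1_b=float(x[6]) % 360.0,
        dphi0=float(x[7]) % 360.0,
        z_offset=float(x[8]),
        orientation=orientation,
    )


def _rot_small(rx: float, ry: float, rz: float) -> np.ndarray:
    cx, sx = math.cos(rx), math.sin(rx)
    cy, sy = math.cos(ry), math.sin(ry)
    cz, sz = math.cos(rz), math.sin(rz)
    mx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    my = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    mz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return mz @ my @ mx


def fit_crick(
    helix_a: HelixBackbone,
    helix_b: HelixBackbone | None = None,
    orientation: str = "antiparallel",
    max_nfev: int = 400,
) -> tuple[CrickParams, float]:
    """Best-fit Crick parameters to the CA coordinates of a helix pair.

    Minimizes CA RMSD between the data and a rigidly-transformed ideal
    Crick pair over all nine shape parameters plus a residual rigid-body
    correction, multi-starting over the minor-helix phases.  Returns the
    parameters and the final CA RMSD in A.

    With a single helix the supercoil is degenerate: r0 is reported as 0
    and only (r1, w1, phi1) are fit.
    """
    if helix_a.n_res < 7 or (helix_b is not None and helix_b.n_res < 7):
        raise GeometryError("both helices must have >= 7 residues")
    if helix_b is None:
        return _fit_single(helix_a)
    n = min(helix_a.n_res, helix_b.n_res)
    # grossly unequal lengths: truncate the longer helix symmetrically
    ca_a = _truncate_center(helix_a.ca, n)
    ca_b = _truncate_center(helix_b.ca, n)
    ha = HelixBackbone("A" * n, _dress_dummy(ca_a), "A")
    hb = HelixBackbone("A" * n, _dress_dummy(ca_b), "B")
    desc = pair_descriptors(ha, hb)
    rot0, tr0 = _canonical_transform(ha, hb, desc)
    data = np.concatenate([ca_a @ rot0.T + tr0, ca_b @ rot0.T + tr0])

    init = CrickParams.from_pair_geometry(
        max(desc.closest_approach_distance, 0.5),
        desc.crossing_angle if abs(desc.crossing_angle) > 90 else -175.0,
        desc.axial_z_offset,
    )
    t = np.arange(n, dtype=float) - (n - 1) / 2.0

    def residuals(x):
        p = CrickParams.__new__(CrickParams)
        (p.r0, p.r1, p.w0, p.w1, p.alpha,
         p.phi1_a, p.phi1_b, p.dphi0, p.z_offset) = x[:9]
        p.orientation = orientation
        ca_ma = _crick_ca(t, p, 0.0, p.phi1_a)
        ca_mb = _crick_ca(t, p, p.dphi0, p.phi1_b)
        if orientation == "antiparallel":
            ca_mb = ca_mb @ _RX180.T
        ca_mb = ca_mb + np.array([0.0, 0.0, p.z_offset])
        model = np.concatenate([ca_ma, ca_mb])
        rig = _rot_small(*x[9:12])
        model = model @ rig.T + x[12:15]
        return (model - data).ravel()

    # Bounds around the robust axis-based descriptor estimates keep the
    # weakly-identified supercoil parameters (r0, w0, alpha) from drifting
    # into degenerate large-radius/low-frequency basins under noise.
    lo = np.full(15, -np.inf)
    hi = np.full(15, np.inf)
    lo[0], hi[0] = 0.6 * init.r0, 1.5 * init.r0 + 0.5
    lo[1], hi[1] = 1.5, 3.0
    if init.alpha < 0:
        lo[2], hi[2] = -4.0, -1e-4
        lo[4], hi[4] = min(init.alpha - 5.0, -6.0), -1e-3
    else:
        lo[2], hi[2] = 1e-4, 4.0
        lo[4], hi[4] = 1e-3, max(init.alpha + 5.0, 6.0)
    lo[3], hi[3] = 80.0, 125.0
    lo[8], hi[8] = init.z_offset - 4.0, init.z_offset + 4.0
    best = None
    x0_base = np.clip(_pack_params(init), lo[:9] + 1e-6, hi[:9] - 1e-6)
    starts = [(init.phi1_a % 360.0, init.phi1_b % 360.0)]
    starts += [(pa, pb) for pa in (0.0, 120.0, 240.0) for pb in (0.0, 120.0, 240.0)]
    for ph_a, ph_b in starts:
        x0 = np.concatenate([x0_base, np.zeros(6)])
        x0[5], x0[6] = ph_a, ph_b
        try:
            res = least_squares(
                residuals, x0, method="trf", bounds=(lo, hi),
                max_nfev=max_nfev, xtol=1e-15, ftol=1e-15, gtol=1e-15,
            )
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
        if np.sqrt(best.cost / n) < 0.01:  # clean data: global basin found
            break
    if best is None:
        raise GeometryError("Crick fit did not converge from any phase start")
    rmsd = float(np.sqrt(best.cost * 2.0 / (2 * n)))
    if rmsd > 5.0:
        raise GeometryError(f"Crick fit non-convergent: final CA RMSD {rmsd:.2f} A")
    params = _unpack_params(_normalize_fit(best.x), orientation)
    return params, rmsd


def _normalize_fit(x: np.ndarray) -> np.ndarray:
    """Canonicalize fitted parameters (sign conventions, phase wrapping)."""
    x = x.copy()
    if x[0] < 0:  # negative r0: rotate superhelical phase by 180
        x[0] = -x[0]
        x[7] += 180.0
    if x[1] < 0:  # negative r1: shift both minor phases by 180
        x[1] = -x[1]
        x[5] += 180.0
        x[6] += 180.0
    if x[3] < 0:  # negative minor frequency: mirror phases
        x[3] = -x[3]
        x[5], x[6] = -x[5], -x[6]
    return x


def _truncate_center(ca: np.ndarray, n: int) -> np.ndarray:
    extra = len(ca) - n
    lo = extra // 2
    return ca[lo : lo + n]


def _dress_dummy(ca: np.ndarray) -> np.ndarray:
    """Minimal (n,4,3) array with CA filled; other atoms near CA."""
    coords = np.repeat(ca[:, None, :], 4, axis=1)
    return coords


def _fit_single(helix: HelixBackbone) -> tuple[CrickParams, float]:
    """Degenerate single-helix case: straight axis, r0 = 0 (flagged)."""
    pts, axis = _helix_axis(helix.ca)
    mu = pts.mean(axis=0)
    radial = np.array([p - _project_point(p, pts, axis) for p in helix.ca])
    r1 = float(np.clip(np.mean(np.linalg.norm(radial, axis=1)), 1.5, 3.0))
    w1 = measure_twist(helix)
    return (
        CrickParams(r0=0.0, r1=r1, w0=0.0, w1=abs(w1), alpha=0.0,
                    orientation="antiparallel"),
        float(np.std(np.linalg.norm(radial, axis=1))),
    )
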