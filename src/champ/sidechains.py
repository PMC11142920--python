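"""Side-chain construction from internal coordinates and a compact
backbone-independent rotamer library.

Heavy atoms only, placed by NeRF (natural extension reference frame)
from ideal bond lengths/angles.  The residues that matter for interface
design ({G, A, S, T, C, V, L, I, F, M}) carry full heavy-atom
topologies; the remaining types are represented coarsely as CB plus a
single centroid pseudo-atom ("CEN") sized per residue, which is all the
threading clash screens need.

The rotamer library is a small discrete chi-angle set (at most 9
rotamers per residue), sufficient for packing-driven design at helical
interfaces.
"""

from __future__ import annotations

import math
from itertools import product

import numpy as np

# chirality: improper torsion C-N-CA-CB = +122.6 deg for L-amino acids
_CB_TORSION = 122.6


def nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray,
         bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom d with |d-c| = bond, angle(d,c,b), torsion(d,c,b,a)."""
    angle = math.radians(angle_deg)
    tors = math.radians(torsion_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d2 = np.array([
        -bond * math.cos(angle),
        bond * math.sin(angle) * math.cos(tors),
        bond * math.sin(angle) * math.sin(tors),
    ])
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


# topology rows: (atom, (ref_a, ref_b, ref_c), bond, angle, torsion)
# torsion is a float (fixed) or ("chi", index, offset_deg)
_TOPOLOGY: dict[str, list] = {
    "G": [],
    "A": [],
    "S": [("OG", ("N", "CA", "CB"), 1.417, 110.8, ("chi", 1, 0.0))],
    "C": [("SG", ("N", "CA", "CB"), 1.808, 113.8, ("chi", 1, 0.0))],
    "T": [
        ("OG1", ("N", "CA", "CB"), 1.433, 109.5, ("chi", 1, 0.0)),
        ("CG2", ("N", "CA", "CB"), 1.521, 110.5, ("chi", 1, -120.0)),
    ],
    "V": [
        ("CG1", ("N", "CA", "CB"), 1.527, 110.5, ("chi", 1, 0.0)),
        ("CG2", ("N", "CA", "CB"), 1.527, 110.5, ("chi", 1, -120.0)),
    ],
    "L": [
        ("CG", ("N", "CA", "CB"), 1.530, 116.3, ("chi", 1, 0.0)),
        ("CD1", ("CA", "CB", "CG"), 1.524, 110.7, ("chi", 2, 0.0)),
        ("CD2", ("CA", "CB", "CG"), 1.524, 110.7, ("chi", 2, 120.0)),
    ],
    "I": [
        ("CG1", ("N", "CA", "CB"), 1.530, 110.4, ("chi", 1, 0.0)),
        ("CG2", ("N", "CA", "CB"), 1.530, 110.5, ("chi", 1, -120.0)),
        ("CD1", ("CA", "CB", "CG1"), 1.513, 113.9, ("chi", 2, 0.0)),
    ],
    "M": [
        ("CG", ("N", "CA", "CB"), 1.520, 114.1, ("chi", 1, 0.0)),
        ("SD", ("CA", "CB", "CG"), 1.803, 112.7, ("chi", 2, 0.0)),
        ("CE", ("CB", "CG", "SD"), 1.791, 100.9, ("chi", 3, 0.0)),
    ],
    "F": [
        ("CG", ("N", "CA", "CB"), 1.502, 113.8, ("chi", 1, 0.0)),
        ("CD1", ("CA", "CB", "CG"), 1.391, 120.8, ("chi", 2, 0.0)),
        ("CD2", ("CA", "CB", "CG"), 1.391, 120.8, ("chi", 2, 180.0)),
        ("CE1", ("CB", "CG", "CD1"), 1.393, 120.8, 180.0),
        ("CE2", ("CB", "CG", "CD2"), 1.393, 120.8, 180.0),
        ("CZ", ("CG", "CD1", "CE1"), 1.390, 120.0, 0.0),
    ],
}

# coarse single-centroid side chains (distance from CB along chi1, radius A)
_COARSE = {
    "P": (1.2, 1.9), "N": (1.6, 2.1), "D": (1.6, 2.1), "Q": (2.2, 2.2),
    "E": (2.2, 2.2), "H": (2.2, 2.3), "K": (3.0, 2.2), "R": (3.4, 2.4),
    "W": (2.6, 2.9), "Y": (2.8, 2.7),
}

_CHI3 = (-60.0, 60.0, 180.0)

#: chi-angle tuples per residue type (<= 9 rotamers each)
ROTAMERS: dict[str, list[tuple]] = {
    "G": [()],
    "A": [()],
    "S": [(c,) for c in _CHI3],
    "C": [(c,) for c in _CHI3],
    "T": [(c,) for c in _CHI3],
    "V": [(c,) for c in _CHI3],
    "L": [c for c in product(_CHI3, _CHI3)],
    "I": [c for c in product(_CHI3, _CHI3)],
    "M": [c + (180.0,) for c in product(_CHI3, _CHI3)],
    "F": [(c1, c2) for c1 in _CHI3 for c2 in (90.0, 30.0)],
}
for _aa in _COARSE:
    ROTAMERS[_aa] = [(c,) for c in _CHI3]

VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80}


def atom_element(name: str) -> str:
    return "S" if name in ("SD", "SG") else name[0]


def atom_radius(resname: str, atom: str) -> float:
    if atom == "CEN":
        return _COARSE[resname][1]
    return VDW_RADII[atom_element(atom)]


def n_chi(resname: str) -> int:
    return max((len(r) for r in ROTAMERS.get(resname, [()])), default=0)


def build_sidechain(
    resname: str, n: np.ndarray, ca: np.ndarray, c: np.ndarray,
    chis: tuple = (),
) -> dict[str, np.ndarray]:
    """Heavy side-chain atoms (beyond CA) for one residue.

    ``chis`` is the rotamer's chi tuple; missing angles default to 180.
    Glycine returns an empty dict.
    """
    if resname == "G":
        return {}
    atoms = {"N": n, "CA": ca, "C": c}
    atoms["CB"] = nerf(c, n, ca, 1.530, 110.5, _CB_TORSION)
    def chi(i):
        return chis[i - 1] if len(chis) >= i else 180.0

    if resname in _TOPOLOGY:
        for name, refs, bond, angle, tors in _TOPOLOGY[resname]:
            if isinstance(tors, tuple):
                tors = chi(tors[1]) + tors[2]
            atoms[name] = nerf(atoms[refs[0]], atoms[refs[1]], atoms[refs[2]],
                               bond, angle, tors)
    elif resname in _COARSE:
        dist = _COARSE[resname][0]
        atoms["CEN"] = nerf(n, ca, atoms["CB"], dist + 0.3, 114.0, chi(1))
    else:
        raise KeyError(f"no side-chain topology for residue {resname!r}")
    return {k: v for k, v in atoms.items() if k not in ("N", "CA", "C")}
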