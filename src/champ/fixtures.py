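"""Synthetic fixture generators.

Everything here is generated programmatically and deterministically from
a seed: helix-pair libraries sampled around geometry archetypes (a
stand-in for a mined structural database), FRET titrations under known
stoichiometry models, disulfide species tables, and chemical-shift
tables with helical-periodic perturbation structure tied to a complex
model's interhelical closeness.  Ground truth is always returned (or
written as a sidecar) so recovery tests can score against it.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from champ.assays import StoichModel, nic_profile
from champ.geometry import (
    CrickParams,
    HelixBackbone,
    build_ideal_helix,
    fit_crick,
    generate_crick_backbone,
    pair_descriptors,
)
from champ.membrane import MembraneFrame, TMComplexModel, insert_in_membrane, place_binder
from champ.motifs import PairLibraryEntry
from champ.sequences import MEPOR_TM

#: the idealized antiparallel small-X6-small template geometry
#: (interhelical distance A, crossing angle deg, z offset A)
TEMPLATE_GEOMETRY = (8.1, -175.0, 2.0)

#: geometry archetypes for library fixtures: the antiparallel template
#: plus a wider antiparallel and a right-handed parallel-like family
ARCHETYPES = {
    "antiparallel_tight": (8.1, -175.0, 2.0),
    "antiparallel_wide": (10.5, -160.0, 0.0),
    "right_handed": (9.0, 165.0, -1.0),
}

_APOLAR = "LIVFM"


def template_params() -> CrickParams:
    return CrickParams.from_pair_geometry(*TEMPLATE_GEOMETRY)


def demo_complex(
    target_sequence: str = MEPOR_TM, binder_length: int = 24
) -> TMComplexModel:
    """The canonical demo complex: the target TM helix oriented in the
    bilayer with a polyalanine binder placed from the template."""
    target = build_ideal_helix(target_sequence, id="A")
    oriented, _, _ = insert_in_membrane(target)
    return place_binder(oriented, template_params(), binder_length=binder_length)


def _motif_sequence(rng: np.random.Generator, length: int, start: int) -> str:
    seq = [
        _APOLAR[int(rng.integers(len(_APOLAR)))] for _ in range(length)
    ]
    for k in range(3):
        pos = start + 7 * k
        if pos < length:
            seq[pos] = "GAS"[int(rng.integers(3))]
    return "".join(seq)


@dataclass
class PairLibrarySpec:
    archetypes: dict = field(default_factory=lambda: dict(ARCHETYPES))
    n_per_archetype: int = 10
    coord_noise: float = 0.3  # A, Gaussian per coordinate
    n_res: int = 25
    seed: int = 0
    fit: str = "descriptors"  # "descriptors" | "crick" | "none"


def make_pair_library_fixture(spec: PairLibrarySpec) -> list[PairLibraryEntry]:
    """Sample helix pairs around the archetype geometries.

    Each entry perturbs the archetype (distance, angle, z offset) by a
    small amount, generates ideal backbones, adds coordinate noise, and
    records measured descriptors; ``fit="crick"`` additionally runs the
    full Crick fit per entry (slower).  Archetype labels are retained
    for cluster-purity tests.
    """
    rng = np.random.default_rng(spec.seed)
    entries = []
    for label, (d, ang, zoff) in spec.archetypes.items():
        for k in range(spec.n_per_archetype):
            dd = d + rng.normal(0, 0.15)
            aa = ang + rng.normal(0, 1.5)
            zz = zoff + rng.normal(0, 0.3)
            params = CrickParams.from_pair_geometry(dd, aa, zz)
            ha, hb = generate_crick_backbone(params, spec.n_res)
            if spec.coord_noise > 0:
                ha = HelixBackbone(
                    ha.sequence, ha.coords + rng.normal(0, spec.coord_noise, ha.coords.shape), "A"
                )
                hb = HelixBackbone(
                    hb.sequence, hb.coords + rng.normal(0, spec.coord_noise, hb.coords.shape), "B"
                )
            seq_a = _motif_sequence(rng, spec.n_res, 2)
            seq_b = _motif_sequence(rng, spec.n_res, 2)
            ha = HelixBackbone(seq_a, ha.coords, "A")
            hb = HelixBackbone(seq_b, hb.coords, "B")
            geometry = pair_descriptors(ha, hb)
            if spec.fit == "crick":
                fitted, _ = fit_crick(ha, hb)
            elif spec.fit == "descriptors":
                fitted = CrickParams.from_pair_geometry(
                    geometry.closest_approach_distance,
                    geometry.crossing_angle,
                    geometry.axial_z_offset,
                )
            else:
                fitted = None
            entries.append(
                PairLibraryEntry(
                    id=f"{label}_{k}", seq_a=seq_a, seq_b=seq_b,
                    helix_a=ha, helix_b=hb, params=fitted,
                    geometry=geometry, label=label,
                )
            )
    return entries


def make_thread_screen_fixture(seed: int = 0, n_pairs: int = 6) -> list[PairLibraryEntry]:
    """A small library for the threading clash screen in which exactly
    one of the 2 * n_pairs helices accommodates a threaded bulky TM
    sequence: every pair is tightly packed with aromatic interface
    residues except the last pair's first helix, whose partner presents
    an all-small interface across a slightly wider groove."""
    rng = np.random.default_rng(seed)
    entries = []
    n_res = 25
    for k in range(n_pairs):
        open_case = k == n_pairs - 1
        d = 9.0 if open_case else 7.4
        params = CrickParams.from_pair_geometry(d, -175.0, 2.0)
        ha, hb = generate_crick_backbone(params, n_res)
        seq = ["L"] * n_res
        # interface positions face the partner at the central frame
        center = (n_res - 1) // 2
        iface = [p for p in range(n_res) if (p - center) % 7 == 0 or (p - center) % 7 in (3, 4)]
        seq_a = list(seq)
        seq_b = list(seq)
        for p in iface:
            # in the open pair only helix A's partner (helix B) presents a
            # small interface, so threading onto A is the single open case
            seq_b[p] = "G" if open_case else "F"
            seq_a[p] = "F"
        entries.append(
            PairLibraryEntry(
                id=f"pair_{k}", seq_a="".join(seq_a), seq_b="".join(seq_b),
                helix_a=HelixBackbone("".join(seq_a), ha.coords, "A"),
                helix_b=HelixBackbone("".join(seq_b), hb.coords, "B"),
                params=params, geometry=pair_descriptors(ha, hb),
                label="open" if open_case else "blocked",
            )
        )
    return entries


# ---------------------------------------------------------------------------
# assay fixtures


@dataclass
class TitrationSpec:
    stoichiometry: str = "dimer"
    transfer_efficiency: float = 0.8
    bound_fraction: float = 0.95
    lam: float = 0.0
    noise: float = 0.02
    n_points: int = 9
    seed: int = 0


def make_titration_fixture(spec: TitrationSpec) -> tuple[pd.DataFrame, dict]:
    """Noisy titration table plus its generating ground truth."""
    rng = np.random.default_rng(spec.seed)
    f = np.linspace(0.0, 1.0, spec.n_points)
    model = StoichModel(
        spec.stoichiometry, spec.transfer_efficiency, spec.bound_fraction, spec.lam
    )
    y = model.intensity(f) + rng.normal(0.0, spec.noise, f.shape)
    y = np.clip(y, 0.01, 1.2)
    y[f == 0] = 1.0
    df = pd.DataFrame({
        "acceptor_fraction": f,
        "intensity": y,
        "sd": np.full_like(f, spec.noise),
    })
    return df, asdict(spec)


@dataclass
class SpeciesSpec:
    f_aa: float = 0.25
    f_ab: float = 0.50
    f_bb: float = 0.25
    total_area: float = 1000.0
    noise: float = 0.0
    seed: int = 0


def make_species_fixture(spec: SpeciesSpec) -> tuple[pd.DataFrame, dict]:
    rng = np.random.default_rng(spec.seed)
    fractions = np.array([spec.f_aa, spec.f_ab, spec.f_bb])
    fractions = fractions / fractions.sum()
    areas = fractions * spec.total_area
    if spec.noise > 0:
        areas = np.clip(areas * (1 + rng.normal(0, spec.noise, 3)), 0, None)
    df = pd.DataFrame({"species": ["AA", "AB", "BB"], "area": areas})
    return df, asdict(spec)


@dataclass
class CSPSpec:
    n_res: int = 25
    period: float = 3.6
    amplitude: float = 0.5
    phase: float = 0.0
    noise: float = 0.0
    base_shift: float = 58.0  # CA ppm neighborhood
    scale_ppm: float = 0.6  # largest induced shift, ppm
    from_nic: bool = False  # tie the pattern to the demo model's NIC
    seed: int = 0


def make_csp_fixture(spec: CSPSpec, model: TMComplexModel | None = None):
    """Free/bound CA shift tables with periodic perturbation structure.

    With ``from_nic`` the perturbation pattern is the normalized
    interhelical closeness of a complex model; otherwise a pure cosine
    of the requested period.  Returns (free table, bound table, ground
    truth dict with the true per-residue pattern).
    """
    rng = np.random.default_rng(spec.seed)
    if spec.from_nic:
        model = model or demo_complex()
        nic = nic_profile(model)
        pattern = nic.closeness.to_numpy()[: spec.n_res]
        residues = nic.closeness.index.to_numpy()[: spec.n_res]
    else:
        residues = np.arange(1, spec.n_res + 1)
        pattern = 0.5 + spec.amplitude * np.cos(
            2 * np.pi * residues / spec.period + spec.phase
        )
        pattern = (pattern - pattern.min()) / np.ptp(pattern)
    noisy = np.clip(pattern + rng.normal(0, spec.noise, pattern.shape), 0, None)
    free_shift = spec.base_shift + 0.02 * residues
    bound_shift = free_shift + noisy * spec.scale_ppm
    free = pd.DataFrame({"residue": residues, "atom": "CA", "shift_ppm": free_shift})
    bound = pd.DataFrame({"residue": residues, "atom": "CA", "shift_ppm": bound_shift})
    truth = {"pattern": pattern.tolist(), "residues": residues.tolist(),
             "spec": asdict(spec)}
    return free, bound, truth


def write_assay_fixtures(outdir, seed: int = 0) -> dict:
    """Write the standard assay fixture set (CSV/TSV + ground-truth
    sidecars) into a directory; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for stoich in ("monomer", "dimer", "trimer"):
        df, truth = make_titration_fixture(
            TitrationSpec(stoichiometry=stoich, lam=0.5 if stoich == "monomer" else 0.0,
                          seed=seed)
        )
        p = outdir / f"titration_{stoich}.csv"
        df.to_csv(p, index=False)
        (outdir / f"titration_{stoich}.truth.json").write_text(json.dumps(truth))
        paths[f"titration_{stoich}"] = p
    df, truth = make_species_fixture(SpeciesSpec(seed=seed))
    df.to_csv(outdir / "species_null.csv", index=False)
    (outdir / "species_null.truth.json").write_text(json.dumps(truth))
    paths["species_null"] = outdir / "species_null.csv"
    df, truth = make_species_fixture(SpeciesSpec(f_aa=0.1, f_ab=0.8, f_bb=0.1, seed=seed))
    df.to_csv(outdir / "species_hetero.csv", index=False)
    (outdir / "species_hetero.truth.json").write_text(json.dumps(truth))
    paths["species_hetero"] = outdir / "species_hetero.csv"
    free, bound, truth = make_csp_fixture(CSPSpec(seed=seed))
    free.to_csv(outdir / "shifts_free.tsv", sep="\t", index=False)
    bound.to_csv(outdir / "shifts_bound.tsv", sep="\t", index=False)
    (outdir / "shifts.truth.json").write_text(json.dumps(truth))
    paths["shifts_free"] = outdir / "shifts_free.tsv"
    paths["shifts_bound"] = outdir / "shifts_bound.tsv"
    return paths
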