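"""File I/O: PDB backbones, FASTA sequence sets, YAML configs, run records.

Conventions: chain A is the target helix, chain B the designed binder.
Occupancy/B-factor are ignored on read and written as 1.00/0.00.
"""

from __future__ import annotations

import json
import platform
from dataclasses import asdict, is_dataclass
from pathlib import Path

import numpy as np
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from champ.geometry import BACKBONE_ATOMS, HelixBackbone

_AA3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
_AA1TO3 = {v: k for k, v in _AA3TO1.items()}


class PDBFormatError(ValueError):
    pass


def read_structure(path) -> dict[str, tuple[HelixBackbone, list[dict]]]:
    """Read helix backbones (plus any side-chain atoms) from a PDB file.

    Returns ``{chain_id: (HelixBackbone, sidechains)}`` where
    ``sidechains`` is a per-residue list of ``{atom_name: xyz}`` for
    non-backbone heavy atoms.  HETATM records are ignored; for alternate
    locations the highest-occupancy one is kept.
    """
    chains: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith("ATOM"):
                continue
            try:
                name = line[12:16].strip()
                altloc = line[16]
                resname = line[17:20].strip()
                chain_id = line[21].strip() or "A"
                resseq = int(line[22:26])
                x = float(line[30:38])
                y = float(line[38:46])
                z = float(line[46:54])
                occ = float(line[54:60]) if line[54:60].strip() else 1.0
            except (ValueError, IndexError) as exc:
                raise PDBFormatError(
                    f"{path}: malformed ATOM record at line {lineno}: {exc}"
                ) from None
            if name.startswith("H") or name == "OXT":
                continue
            ch = chains.setdefault(chain_id, {})
            res = ch.setdefault(resseq, {"resname": resname, "atoms": {}, "occ": {}})
            if name in res["atoms"] and altloc.strip():
                if occ <= res["occ"].get(name, 1.0):
                    continue
            res["atoms"][name] = np.array([x, y, z])
            res["occ"][name] = occ

    out = {}
    for chain_id, residues in chains.items():
        seq = []
        coords = []
        sidechains = []
        for resseq in sorted(residues):
            res = residues[resseq]
            aa = _AA3TO1.get(res["resname"])
            if aa is None:
                raise PDBFormatError(
                    f"{path}: unknown residue {res['resname']} {resseq} in chain {chain_id}"
                )
            missing = [a for a in BACKBONE_ATOMS if a not in res["atoms"]]
            if missing:
                raise PDBFormatError(
                    f"{path}: residue {res['resname']} {resseq} chain {chain_id} "
                    f"missing backbone atoms {missing}"
                )
            seq.append(aa)
            coords.append([res["atoms"][a] for a in BACKBONE_ATOMS])
            sidechains.append(
                {a: v for a, v in res["atoms"].items() if a not in BACKBONE_ATOMS}
            )
        out[chain_id] = (
            HelixBackbone("".join(seq), np.array(coords), id=chain_id),
            sidechains,
        )
    return out


def write_structure(
    path,
    helices: dict[str, HelixBackbone],
    sidechains: dict[str, list[dict]] | None = None,
    remarks: list[str] | None = None,
) -> None:
    """Write helices (and optional per-residue side-chain atoms) as PDB."""
    lines = []
    for remark in remarks or []:
        lines.append(f"REMARK 250 {remark}")
    serial = 1
    for chain_id in sorted(helices):
        helix = helices[chain_id]
        sc = (sidechains or {}).get(chain_id)
        for i in range(helix.n_res):
            resname = _AA1TO3[helix.sequence[i]]
            atoms = [(a, helix.coords[i, k]) for k, a in enumerate(BACKBONE_ATOMS)]
            if sc and i < len(sc):
                atoms += sorted(sc[i].items())
            for name, xyz in atoms:
                pad = name.ljust(3) if len(name) < 4 else name
                lines.append(
                    f"ATOM  {serial:5d}  {pad:<3s}{resname:>4s} {chain_id}{i + 1:4d}    "
                    f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
                )
                serial += 1
        lines.append(f"TER   {serial:5d}")
        serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path, sequences: dict[str, str]) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def dump_config(path, config: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)


def _jsonable(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in asdict(obj).items()}
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_run_record(path, command: str, config: dict, seed: int | None) -> None:
    """Emit a machine-readable record sufficient to reproduce a run."""
    import champ

    record = {
        "command": command,
        "seed": seed,
        "config": _jsonable(config),
        "versions": {
            "champ": champ.__version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
        },
    }
    with open(path, "w") as fh:
        json.dump(record, fh, indent=2)
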