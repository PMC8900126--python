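"""Coordinate export: XYZ and minimal PDB.

Bead element codes: backbone = C, charge bead = O, alkyl bead = S.
Internal coordinates are nm for conformers and A for packed systems; both
formats are written in Angstroms (XYZ at full precision, PDB at the
format's 3 decimals). PDB uses HETATM records, 1-based residue numbering,
and one chain ID per polymer.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .assembly import BEAD_ACID, BEAD_ALKYL, BEAD_BACKBONE, PackedSystem
from .errors import ConfigurationError
from .structure import Conformer

ELEMENT_BY_TYPE = {BEAD_BACKBONE: "C", BEAD_ACID: "O", BEAD_ALKYL: "S"}
TYPE_BY_ELEMENT = {v: k for k, v in ELEMENT_BY_TYPE.items()}
_CHAIN_ALPHABET = "ABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789abcdefghijklmnopqrstuvwxyz"

EXPORT_FORMATS = ("xyz", "pdb")


def _as_bead_arrays(obj) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(positions_A, bead_types, chain_ids) for a Conformer or PackedSystem."""
    if isinstance(obj, Conformer):
        pos = np.vstack([obj.backbone, obj.charge_beads, obj.alkyl_beads]) * 10.0
        types = np.concatenate(
            [
                np.full(obj.backbone.shape[0], BEAD_BACKBONE, dtype=np.int8),
                np.full(obj.charge_beads.shape[0], BEAD_ACID, dtype=np.int8),
                np.full(obj.alkyl_beads.shape[0], BEAD_ALKYL, dtype=np.int8),
            ]
        )
        return pos, types, np.zeros(len(pos), dtype=int)
    if isinstance(obj, PackedSystem):
        return obj.positions, obj.bead_types, obj.chain_ids
    raise TypeError(f"cannot export coordinates of {type(obj).__name__}")


def export_coordinates(obj, path, fmt: str = "xyz") -> None:
    if fmt == "xyz":
        write_xyz(obj, path)
    elif fmt == "pdb":
        write_pdb(obj, path)
    else:
        raise ConfigurationError(
            f"unsupported coordinate format {fmt!r}; expected one of {EXPORT_FORMATS}"
        )


def write_xyz(obj, path) -> None:
    pos, types, _ = _as_bead_arrays(obj)
    lines = [str(len(pos)), "cmcnano beads (A); C=backbone O=charge S=alkyl"]
    for t, (x, y, z) in zip(types, pos):
        lines.append(
            f"{ELEMENT_BY_TYPE[int(t)]} {float(x)!r} {float(y)!r} {float(z)!r}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_xyz(path) -> tuple[np.ndarray, np.ndarray]:
    """Return (positions_A, bead_types)."""
    lines = Path(path).read_text().splitlines()
    n = int(lines[0])
    pos = np.empty((n, 3))
    types = np.empty(n, dtype=np.int8)
    for i, line in enumerate(lines[2 : 2 + n]):
        el, x, y, z = line.split()
        types[i] = TYPE_BY_ELEMENT[el]
        pos[i] = (float(x), float(y), float(z))
    return pos, types


def write_pdb(obj, path) -> None:
    pos, types, chains = _as_bead_arrays(obj)
    lines = []
    serial = 1
    for t, (x, y, z), cid in zip(types, pos, chains):
        el = ELEMENT_BY_TYPE[int(t)]
        chain_char = _CHAIN_ALPHABET[int(cid) % len(_CHAIN_ALPHABET)]
        lines.append(
            f"HETATM{serial % 100000:5d} {el:<4s} BEA {chain_char}{(int(cid) % 9999) + 1:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {el:>2s}"
        )
        serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def read_pdb(path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return (positions_A, bead_types, chain_ids) from a minimal PDB."""
    pos, types, chains = [], [], []
    for line in Path(path).read_text().splitlines():
        if not line.startswith(("HETATM", "ATOM")):
            continue
        el = line[76:78].strip() or line[12:16].strip()
        types.append(TYPE_BY_ELEMENT[el])
        pos.append(
            (float(line[30:38]), float(line[38:46]), float(line[46:54]))
        )
        chains.append(_CHAIN_ALPHABET.index(line[21]))
    return (
        np.array(pos).reshape(-1, 3),
        np.array(types, dtype=np.int8),
        np.array(chains, dtype=int),
    )
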