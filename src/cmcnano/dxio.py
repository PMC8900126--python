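"""OpenDX regular-grid scalar I/O (APBS-compatible layout).

Values are written z-fastest (C order of an (nx, ny, nz) array), three per
line, as in APBS output. Lengths are in the grid's native nm; potentials
in mV.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .fields import GridSpec, PotentialGrid, debye_length


def write_dx(grid: PotentialGrid, path) -> None:
    if not np.all(np.isfinite(grid.values)):
        raise ValueError("grid contains NaN/inf values; refusing to export")
    nx, ny, nz = grid.spec.shape
    h = grid.spec.spacing
    ox, oy, oz = grid.spec.origin
    lines = [
        "# cmcnano screened-Coulomb potential (mV), lengths in nm",
        f"# eps_r {grid.eps_r} ionic_strength {grid.ionic_strength} "
        f"T {grid.temperature} debye_length {grid.debye_length_nm}",
        f"object 1 class gridpositions counts {nx} {ny} {nz}",
        f"origin {ox:.6e} {oy:.6e} {oz:.6e}",
        f"delta {h:.6e} 0.000000e+00 0.000000e+00",
        f"delta 0.000000e+00 {h:.6e} 0.000000e+00",
        f"delta 0.000000e+00 0.000000e+00 {h:.6e}",
        f"object 2 class gridconnections counts {nx} {ny} {nz}",
        f"object 3 class array type double rank 0 items {nx * ny * nz} data follows",
    ]
    flat = grid.values.ravel(order="C")
    for start in range(0, flat.size, 3):
        lines.append(" ".join(f"{v:.10e}" for v in flat[start : start + 3]))
    lines += [
        'attribute "dep" string "positions"',
        'object "regular positions regular connections" class field',
        'component "positions" value 1',
        'component "connections" value 2',
        'component "data" value 3',
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_dx(path) -> PotentialGrid:
    shape = None
    origin = None
    deltas = []
    values: list[float] = []
    n_items = None
    params = {"eps_r": 80.0, "ionic_strength": 0.1, "T": 298.0}
    reading = False
    for line in Path(path).read_text().splitlines():
        s = line.strip()
        if s.startswith("#"):
            toks = s[1:].split()
            for key in ("eps_r", "ionic_strength", "T"):
                if key in toks:
                    params[key] = float(toks[toks.index(key) + 1])
            continue
        if s.startswith("object 1"):
            shape = tuple(int(t) for t in s.split()[-3:])
        elif s.startswith("origin"):
            origin = tuple(float(t) for t in s.split()[1:4])
        elif s.startswith("delta"):
            deltas.append([float(t) for t in s.split()[1:4]])
        elif "data follows" in s:
            n_items = int(s.split("items")[1].split()[0])
            reading = True
        elif reading and s and not s.startswith(("attribute", "object", "component")):
            values.extend(float(t) for t in s.split())
        elif s.startswith(("attribute", "component")) or (
            reading and s.startswith("object")
        ):
            reading = False
    if shape is None or origin is None or len(deltas) != 3 or n_items is None:
        raise ValueError(f"{path}: not a parseable OpenDX regular-grid file")
    spacing = deltas[0][0]
    if len(values) != n_items:
        raise ValueError(f"{path}: expected {n_items} values, found {len(values)}")
    spec = GridSpec(origin=origin, spacing=spacing, shape=shape)
    return PotentialGrid(
        spec=spec,
        values=np.array(values).reshape(shape, order="C"),
        eps_r=params["eps_r"],
        ionic_strength=params["ionic_strength"],
        temperature=params["T"],
        debye_length_nm=debye_length(params["ionic_strength"]),
    )
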