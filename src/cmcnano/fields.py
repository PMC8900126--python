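"""Screened-Coulomb electrostatic potential grids, hotspots, and Zn placement.

The potential of a set of point charges {q_i, r_i} in a uniform dielectric
with linear (Debye-Hueckel) screening is

    phi(r) = sum_i k * q_i * exp(-|r - r_i| / lambda_D) / (eps_r * |r - r_i|)

with k = e / (4 pi eps0), so a unit charge at 1 nm in eps_r = 80 without
screening gives ~18 mV. The Debye length of a 1:1 electrolyte at 298 K is
lambda_D = 0.304 / sqrt(I) nm (I in mol/L). To avoid the point-charge
singularity, the distance entering each charge's contribution is clamped at
one grid spacing. Distances in nm, potentials in mV.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage

from .constants import COULOMB_V_NM, DEBYE_PREFACTOR_NM


def debye_length(ionic_strength: float) -> float:
    """Debye screening length (nm) of a 1:1 electrolyte at 298 K."""
    if ionic_strength <= 0:
        return math.inf
    return DEBYE_PREFACTOR_NM / math.sqrt(ionic_strength)


@dataclass(frozen=True)
class GridSpec:
    """Regular-grid geometry: origin (nm), isotropic spacing (nm), shape."""

    origin: tuple[float, float, float]
    spacing: float
    shape: tuple[int, int, int]

    def __post_init__(self):
        if self.spacing <= 0:
            raise ValueError("grid spacing must be > 0")
        if any(s < 1 for s in self.shape):
            raise ValueError("grid shape must be >= 1 in every dimension")

    @classmethod
    def around(
        cls, points: np.ndarray, spacing: float = 0.2, padding: float = 1.0
    ) -> "GridSpec":
        """Smallest grid covering ``points`` with ``padding`` nm margins."""
        points = np.atleast_2d(points)
        lo = points.min(axis=0) - padding
        hi = points.max(axis=0) + padding
        shape = tuple(int(math.ceil((h - l) / spacing)) + 1 for l, h in zip(lo, hi))
        return cls(origin=tuple(float(x) for x in lo), spacing=spacing, shape=shape)

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return tuple(
            self.origin[d] + self.spacing * np.arange(self.shape[d]) for d in range(3)
        )

    def coordinates(self) -> np.ndarray:
        """All voxel centre coordinates, shape (nx*ny*nz, 3), C order."""
        ax = self.axes()
        g = np.meshgrid(*ax, indexing="ij")
        return np.stack([a.ravel() for a in g], axis=1)


@dataclass
class PotentialGrid:
    """Scalar screened-electrostatic-potential field on a regular grid."""

    spec: GridSpec
    values: np.ndarray  # (nx, ny, nz), mV
    eps_r: float
    ionic_strength: float
    temperature: float
    debye_length_nm: float

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.spec.shape:
            raise ValueError("values shape must match grid spec")
        expected = debye_length(self.ionic_strength)
        if not math.isclose(self.debye_length_nm, expected, rel_tol=1e-9):
            raise ValueError(
                f"stored Debye length {self.debye_length_nm} nm inconsistent "
                f"with I={self.ionic_strength} M (expected {expected} nm)"
            )

    def voxel_coords(self, index: tuple[int, int, int]) -> np.ndarray:
        return np.array(self.spec.origin) + self.spec.spacing * np.array(index)


def potential_at_points(
    points: np.ndarray,
    charge_positions: np.ndarray,
    charge_values: np.ndarray,
    eps_r: float = 80.0,
    ionic_strength: float = 0.1,
    cap_distance: float | None = None,
) -> np.ndarray:
    """Screened-Coulomb potential (mV) at arbitrary probe points.

    ``cap_distance`` clamps per-charge distances from below (None = no cap).
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    charge_positions = np.atleast_2d(np.asarray(charge_positions, dtype=float))
    charge_values = np.asarray(charge_values, dtype=float)
    lam = debye_length(ionic_strength)
    out = np.zeros(points.shape[0])
    # Chunk over probe points to bound memory.
    chunk = max(1, int(4e6 // max(1, charge_positions.shape[0])))
    for start in range(0, points.shape[0], chunk):
        p = points[start : start + chunk]
        d = np.linalg.norm(p[:, None, :] - charge_positions[None, :, :], axis=2)
        if cap_distance is not None:
            np.maximum(d, cap_distance, out=d)
        with np.errstate(divide="ignore"):
            contrib = np.exp(-d / lam) / d if math.isfinite(lam) else 1.0 / d
        out[start : start + chunk] = contrib @ charge_values
    return out * (COULOMB_V_NM / eps_r) * 1e3  # V*nm/e -> mV


def gather_charges(obj) -> tuple[np.ndarray, np.ndarray]:
    """Extract (positions_nm, charges_e) from conformers or packed systems."""
    from .assembly import PackedSystem  # local import to avoid a cycle
    from .structure import Conformer

    if isinstance(obj, Conformer):
        return obj.charge_beads, obj.charge_values
    if isinstance(obj, PackedSystem):
        idx = np.flatnonzero(obj.bead_types == 1)
        return obj.positions[idx] / 10.0, np.full(idx.size, -1.0)  # A -> nm
    if isinstance(obj, (list, tuple)):
        pos = [np.empty((0, 3))]
        for c in obj:
            p, _ = gather_charges(c)
            pos.append(p)
        pos = np.vstack(pos)
        return pos, np.full(pos.shape[0], -1.0)
    raise TypeError(f"cannot extract charges from {type(obj).__name__}")


def compute_potential_grid(
    source,
    grid_spec: GridSpec | None = None,
    eps_r: float = 80.0,
    ionic_strength: float = 0.1,
    temperature: float = 298.0,
    spacing: float = 0.2,
    padding: float = 1.0,
) -> PotentialGrid:
    """Evaluate the screened-Coulomb potential of a charge set on a grid.

    ``source`` may be a Conformer, a list of Conformers, a PackedSystem, or
    a ``(positions_nm, charges_e)`` pair. If ``grid_spec`` is omitted a grid
    is built around the charges with the given spacing and padding.
    """
    if isinstance(source, tuple) and len(source) == 2:
        positions, charges = (np.asarray(a, dtype=float) for a in source)
        positions = np.atleast_2d(positions)
    else:
        positions, charges = gather_charges(source)

    if positions.shape[0] == 0:
        warnings.warn("no charges supplied; returning a zero potential grid")
        if grid_spec is None:
            grid_spec = GridSpec(origin=(0.0, 0.0, 0.0), spacing=spacing, shape=(1, 1, 1))
        return PotentialGrid(
            spec=grid_spec,
            values=np.zeros(grid_spec.shape),
            eps_r=eps_r,
            ionic_strength=ionic_strength,
            temperature=temperature,
            debye_length_nm=debye_length(ionic_strength),
        )

    if grid_spec is None:
        grid_spec = GridSpec.around(positions, spacing=spacing, padding=padding)
    phi = potential_at_points(
        grid_spec.coordinates(),
        positions,
        charges,
        eps_r=eps_r,
        ionic_strength=ionic_strength,
        cap_distance=grid_spec.spacing,
    )
    return PotentialGrid(
        spec=grid_spec,
        values=phi.reshape(grid_spec.shape),
        eps_r=eps_r,
        ionic_strength=ionic_strength,
        temperature=temperature,
        debye_length_nm=debye_length(ionic_strength),
    )


@dataclass
class Hotspot:
    """A face-connected region of strongly negative potential."""

    hotspot_id: int
    voxels: np.ndarray  # (m, 3) integer indices
    min_potential: float  # mV
    centroid: np.ndarray  # (3,) nm
    n_voxels: int
    nearby_charges: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    zn_capacity: int | None = None


# 6-connectivity (faces only)
_FACE_STRUCTURE = ndimage.generate_binary_structure(3, 1)


def find_hotspots(
    grid: PotentialGrid,
    threshold_mV: float = -10.0,
    min_voxels: int = 5,
    charge_positions: np.ndarray | None = None,
    charge_radius: float = 1.0,
) -> list[Hotspot]:
    """Face-connected components of voxels below a negative threshold.

    Components smaller than ``min_voxels`` are dropped; the survivors are
    sorted by their minimum potential (deepest first). If
    ``charge_positions`` is given, charges within ``charge_radius`` nm of a
    component's centroid are attached to it.
    """
    if threshold_mV >= 0:
        raise ValueError("hotspot threshold must be negative (mV)")
    mask = grid.values < threshold_mV
    labels, n_comp = ndimage.label(mask, structure=_FACE_STRUCTURE)
    hotspots = []
    origin = np.array(grid.spec.origin)
    for lbl in range(1, n_comp + 1):
        vox = np.argwhere(labels == lbl)
        if vox.shape[0] < min_voxels:
            continue
        vals = grid.values[tuple(vox.T)]
        centroid = origin + grid.spec.spacing * vox.mean(axis=0)
        nearby = np.array([], dtype=int)
        if charge_positions is not None and len(charge_positions):
            d = np.linalg.norm(np.atleast_2d(charge_positions) - centroid, axis=1)
            nearby = np.flatnonzero(d <= charge_radius)
        hotspots.append(
            Hotspot(
                hotspot_id=-1,
                voxels=vox,
                min_potential=float(vals.min()),
                centroid=centroid,
                n_voxels=int(vox.shape[0]),
                nearby_charges=nearby,
            )
        )
    hotspots.sort(key=lambda h: h.min_potential)
    for i, h in enumerate(hotspots):
        h.hotspot_id = i
    return hotspots


@dataclass
class ZnPlacement:
    """Greedy Zn2+ placements inside hotspot regions."""

    positions: np.ndarray  # (n, 3) nm
    hotspot_ids: np.ndarray  # (n,)
    occupancy: dict[int, int]  # hotspot id -> ions placed


def place_zn_ions(
    grid: PotentialGrid,
    hotspots: Sequence[Hotspot],
    min_separation: float = 0.4,
    max_ions: int | None = None,
) -> ZnPlacement:
    """Place ions greedily at successive potential minima within hotspots.

    Candidate sites are hotspot voxel centres visited from most to least
    negative potential; a site is accepted if it is at least
    ``min_separation`` nm from every accepted ion. Updates each hotspot's
    ``zn_capacity``.
    """
    if min_separation <= 0:
        raise ValueError("min_separation must be > 0")
    candidates = []
    for h in hotspots:
        vals = grid.values[tuple(h.voxels.T)]
        coords = np.array(grid.spec.origin) + grid.spec.spacing * h.voxels
        for v, c in zip(vals, coords):
            candidates.append((float(v), h.hotspot_id, c))
    candidates.sort(key=lambda t: t[0])

    placed: list[np.ndarray] = []
    ids: list[int] = []
    occupancy = {h.hotspot_id: 0 for h in hotspots}
    for _, hid, c in candidates:
        if max_ions is not None and len(placed) >= max_ions:
            break
        if placed and np.min(
            np.linalg.norm(np.array(placed) - c, axis=1)
        ) < min_separation:
            continue
        placed.append(c)
        ids.append(hid)
        occupancy[hid] += 1
    for h in hotspots:
        h.zn_capacity = occupancy[h.hotspot_id]
    return ZnPlacement(
        positions=np.array(placed).reshape(-1, 3),
        hotspot_ids=np.array(ids, dtype=int),
        occupancy=occupancy,
    )
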