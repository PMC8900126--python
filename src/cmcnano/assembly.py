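"""Multi-chain packing in a periodic cubic box and self-assembly clustering.

Chains (as coarse-grained conformers) are placed by seeded rejection
packing: random rigid-body rotation + translation, periodic wrapping, and
re-draw on steric overlap. Bulk density follows from the composition masses
and the box volume. Hydrophobic (alkyl-bead) and acidic (carboxylate-bead)
clusters are connected components of the contact graph under minimum-image
distances; acidic clusters whose centroid falls 10-15 A from an alkyl
cluster centroid are flagged as candidate Zn2+ binding sites.

All lengths in this module are in Angstroms (conformers, which use nm, are
converted on packing).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .composition import chain_statistics
from .constants import MASS_CONVENTIONS, N_AVOGADRO
from .errors import ConfigurationError, PackingError
from .structure import Conformer

NM_TO_ANGSTROM = 10.0

#: Bead type codes in packed systems.
BEAD_BACKBONE, BEAD_ACID, BEAD_ALKYL = 0, 1, 2

DEFAULT_ALKYL_CUTOFF = 6.0  # A
DEFAULT_ACID_CUTOFF = 8.0  # A
DEFAULT_CONTACT_DISTANCE = 3.0  # A
DEFAULT_PROXIMITY_RANGE = (10.0, 15.0)  # A


def minimum_image_displacement(
    a: np.ndarray, b: np.ndarray, box_edge: float | None
) -> np.ndarray:
    """Displacement b - a under the minimum-image convention."""
    d = np.asarray(b, dtype=float) - np.asarray(a, dtype=float)
    if box_edge is not None:
        d -= box_edge * np.round(d / box_edge)
    return d


def minimum_image_distance(a, b, box_edge: float | None) -> float:
    return float(np.linalg.norm(minimum_image_displacement(a, b, box_edge)))


@dataclass
class PackedSystem:
    """Conformers placed in a cubic box (lengths in Angstroms)."""

    box_edge: float
    positions: np.ndarray  # (n, 3), wrapped into [0, box_edge)
    bead_types: np.ndarray  # (n,) int8, BEAD_* codes
    chain_ids: np.ndarray  # (n,) int
    total_mass_gmol: float
    mass_convention: str = "sodium_salt"
    periodic: bool = True
    n_chains: int = 0

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        self.bead_types = np.asarray(self.bead_types, dtype=np.int8)
        self.chain_ids = np.asarray(self.chain_ids, dtype=int)
        if not (len(self.positions) == len(self.bead_types) == len(self.chain_ids)):
            raise ValueError("positions, bead_types, chain_ids must align")

    @property
    def n_beads(self) -> int:
        return self.positions.shape[0]

    @property
    def density(self) -> float:
        """Bulk density in g/cm^3: total mass / (N_A * box volume)."""
        volume_cm3 = (self.box_edge * 1e-8) ** 3
        return self.total_mass_gmol / (N_AVOGADRO * volume_cm3)

    def beads_of_type(self, bead_type: int) -> np.ndarray:
        return np.flatnonzero(self.bead_types == bead_type)


def _conformer_beads(conf: Conformer) -> tuple[np.ndarray, np.ndarray]:
    """Stack a conformer's beads (in A) with their type codes."""
    pos = np.vstack([conf.backbone, conf.charge_beads, conf.alkyl_beads])
    types = np.concatenate(
        [
            np.full(conf.backbone.shape[0], BEAD_BACKBONE, dtype=np.int8),
            np.full(conf.charge_beads.shape[0], BEAD_ACID, dtype=np.int8),
            np.full(conf.alkyl_beads.shape[0], BEAD_ALKYL, dtype=np.int8),
        ]
    )
    return pos * NM_TO_ANGSTROM, types


def system_density(
    conformers: Sequence[Conformer],
    box_edge: float,
    mass_convention: str = "sodium_salt",
) -> float:
    """Bulk density (g/cm^3) of a set of chains in a cubic box, no packing."""
    total = sum(
        chain_statistics(c.chain, mass_convention).mean_monomer_mass
        * c.chain.n_monomers
        for c in conformers
    )
    return total / (N_AVOGADRO * (box_edge * 1e-8) ** 3)


def pack_chains(
    conformer_pool: Sequence[Conformer],
    n_chains: int,
    box_edge: float,
    contact_distance: float = DEFAULT_CONTACT_DISTANCE,
    max_attempts: int = 200,
    seed: int | None = None,
    mass_convention: str = "sodium_salt",
    periodic: bool = True,
) -> PackedSystem:
    """Pack ``n_chains`` conformers into a cubic box by rejection sampling.

    Each chain is drawn from ``conformer_pool`` (cycling), given a uniform
    random rotation and translation, wrapped periodically, and accepted if
    no bead comes within ``contact_distance`` A of an already placed bead
    (set ``contact_distance=0`` to disable the check). Density is computed
    from the composition masses under ``mass_convention``.

    Raises
    ------
    PackingError
        If a chain cannot be placed within ``max_attempts``; the exception
        carries the achieved chain count.
    """
    if n_chains < 0:
        raise ValueError("n_chains must be >= 0")
    if box_edge <= 0:
        raise ValueError("box_edge must be > 0")
    if mass_convention not in MASS_CONVENTIONS:
        raise ConfigurationError(f"unknown mass convention {mass_convention!r}")
    rng = np.random.default_rng(seed)

    all_pos: list[np.ndarray] = []
    all_types: list[np.ndarray] = []
    all_chain: list[np.ndarray] = []
    total_mass = 0.0
    tree: cKDTree | None = None
    placed = np.empty((0, 3))

    for ci in range(n_chains):
        conf = conformer_pool[ci % len(conformer_pool)]
        beads, types = _conformer_beads(conf)
        center = beads.mean(axis=0)
        ok = False
        for _ in range(max(1, max_attempts)):
            rot = Rotation.from_quat(_random_quaternion(rng))
            shift = rng.uniform(0.0, box_edge, size=3)
            pos = rot.apply(beads - center) + shift
            if periodic:
                pos = np.mod(pos, box_edge)
                pos[pos >= box_edge] = 0.0  # guard against float round-up
            if contact_distance <= 0 or tree is None:
                ok = True
                break
            dist, _ = tree.query(pos, k=1, distance_upper_bound=contact_distance)
            if np.all(np.isinf(dist)):
                ok = True
                break
        if not ok:
            raise PackingError(
                f"failed to place chain {ci} within {max_attempts} attempts "
                f"({ci} chains placed)",
                achieved=ci,
            )
        all_pos.append(pos)
        all_types.append(types)
        all_chain.append(np.full(len(pos), ci))
        total_mass += (
            chain_statistics(conf.chain, mass_convention).mean_monomer_mass
            * conf.chain.n_monomers
        )
        placed = np.vstack([placed, pos]) if len(all_pos) > 1 else pos
        if contact_distance > 0:
            tree = cKDTree(placed, boxsize=box_edge if periodic else None)

    return PackedSystem(
        box_edge=box_edge,
        positions=np.vstack(all_pos) if all_pos else np.empty((0, 3)),
        bead_types=np.concatenate(all_types) if all_types else np.array([], np.int8),
        chain_ids=np.concatenate(all_chain) if all_chain else np.array([], int),
        total_mass_gmol=total_mass,
        mass_convention=mass_convention,
        periodic=periodic,
        n_chains=n_chains,
    )


def _random_quaternion(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    return q / np.linalg.norm(q)


@dataclass
class Cluster:
    """A connected component of beads in mutual contact."""

    member_indices: np.ndarray  # bead indices into the system arrays
    chain_ids: np.ndarray  # distinct chain ids represented
    size: int
    centroid: np.ndarray  # (3,) A, minimum-image unwrapped then wrapped
    flagged: bool = False  # acidic clusters: within proximity of alkyl cluster
    distance_to_alkyl: float | None = None  # A, nearest alkyl-cluster centroid


@dataclass
class ClusterReport:
    """Hydrophobic and acidic cluster inventory of a packed system."""

    hydrophobic: list[Cluster] = field(default_factory=list)
    acidic: list[Cluster] = field(default_factory=list)

    @property
    def flagged_zn_sites(self) -> list[Cluster]:
        return [c for c in self.acidic if c.flagged]


def _connected_components(n: int, pairs) -> list[np.ndarray]:
    """Union-find connected components of n nodes given an edge iterable."""
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j in pairs:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return [np.array(g) for g in groups.values()]


def _periodic_centroid(pos: np.ndarray, box_edge: float | None) -> np.ndarray:
    """Centroid of a compact bead group under minimum image."""
    ref = pos[0]
    disp = pos - ref
    if box_edge is not None:
        disp -= box_edge * np.round(disp / box_edge)
        return np.mod(ref + disp.mean(axis=0), box_edge)
    return ref + disp.mean(axis=0)


def _cluster_beads(
    system: PackedSystem, bead_type: int, cutoff: float
) -> list[Cluster]:
    idx = system.beads_of_type(bead_type)
    if idx.size == 0:
        return []
    pos = system.positions[idx]
    box = system.box_edge if system.periodic else None
    if box is not None:
        # cKDTree periodic mode requires coordinates strictly inside the box
        wrapped = np.mod(pos, box)
        wrapped[wrapped >= box] = 0.0
        tree = cKDTree(wrapped, boxsize=box)
    else:
        tree = cKDTree(pos)
    pairs = tree.query_pairs(cutoff)
    comps = _connected_components(idx.size, pairs)
    clusters = []
    for comp in comps:
        if comp.size < 2:
            continue
        members = idx[comp]
        clusters.append(
            Cluster(
                member_indices=members,
                chain_ids=np.unique(system.chain_ids[members]),
                size=int(comp.size),
                centroid=_periodic_centroid(pos[comp], box),
            )
        )
    clusters.sort(key=lambda c: -c.size)
    return clusters


def detect_hydrophobic_clusters(
    system: PackedSystem, cutoff: float = DEFAULT_ALKYL_CUTOFF
) -> ClusterReport:
    """Connected components (size >= 2) of alkyl beads within ``cutoff`` A."""
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    return ClusterReport(hydrophobic=_cluster_beads(system, BEAD_ALKYL, cutoff))


def detect_acidic_clusters_near(
    system: PackedSystem,
    hydrophobic_clusters: Sequence[Cluster] | ClusterReport,
    acid_cutoff: float = DEFAULT_ACID_CUTOFF,
    proximity_range: tuple[float, float] = DEFAULT_PROXIMITY_RANGE,
) -> ClusterReport:
    """Cluster carboxylate beads; flag clusters proximal to alkyl clusters.

    An acidic cluster is flagged as a candidate Zn2+ binding site when its
    centroid lies within ``proximity_range`` (default 10-15 A) of any
    hydrophobic-cluster centroid under minimum image.
    """
    if isinstance(hydrophobic_clusters, ClusterReport):
        hydro = hydrophobic_clusters.hydrophobic
    else:
        hydro = list(hydrophobic_clusters)
    acidic = _cluster_beads(system, BEAD_ACID, acid_cutoff)
    box = system.box_edge if system.periodic else None
    lo, hi = proximity_range
    for cl in acidic:
        if hydro:
            dists = [
                minimum_image_distance(cl.centroid, h.centroid, box) for h in hydro
            ]
            cl.distance_to_alkyl = min(dists)
            cl.flagged = lo <= cl.distance_to_alkyl <= hi
    return ClusterReport(hydrophobic=list(hydro), acidic=acidic)
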