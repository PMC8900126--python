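"""Coarse-grained 3-D chain embedding and persistence-length estimation.

One backbone bead per monomer, joined by virtual bonds of fixed length
``b``; backbones are freely-rotating chains with a fixed angle between
consecutive bond vectors and uniform dihedrals, so the persistence length
obeys ``Lp = -b / ln<cos(theta)>``. Each charged CM group contributes a
charge bead and each CM8 group an alkyl bead, offset from the backbone bead
in a random direction perpendicular to the local tangent. Coordinates are
in nanometres.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .composition import CM, CM8, OH, Chain
from .errors import EmbeddingError, EstimationError

#: Virtual bond length per glucose unit, nm (half the ~1.03 nm cellobiose repeat).
DEFAULT_BOND_LENGTH = 0.515
#: Charge-bead offset from its backbone bead, nm.
CHARGE_BEAD_OFFSET = 0.35
#: Alkyl-bead offset from its backbone bead, nm.
ALKYL_BEAD_OFFSET = 0.55


@dataclass(frozen=True)
class ThetaPolicy:
    """Bond-angle policy for the freely-rotating backbone.

    ``kind`` is one of ``"fixed"`` (angle ``theta`` in radians between
    consecutive bond vectors), ``"lp"`` (angle chosen so the ideal-chain
    persistence length equals ``lp`` nm), or ``"uniform"`` (isotropic
    random-walk steps).
    """

    kind: str
    theta: float | None = None
    lp: float | None = None

    @classmethod
    def fixed(cls, theta: float) -> "ThetaPolicy":
        return cls(kind="fixed", theta=theta)

    @classmethod
    def target_lp(cls, lp: float) -> "ThetaPolicy":
        if lp <= 0:
            raise ValueError("target persistence length must be > 0")
        return cls(kind="lp", lp=lp)

    @classmethod
    def uniform(cls) -> "ThetaPolicy":
        return cls(kind="uniform")

    def cos_theta(self, b: float) -> float | None:
        """cos(bond angle), or None for the uniform policy."""
        if self.kind == "fixed":
            return math.cos(self.theta)
        if self.kind == "lp":
            return math.exp(-b / self.lp)
        if self.kind == "uniform":
            return None
        raise ValueError(f"unknown theta policy kind {self.kind!r}")


@dataclass
class Conformer:
    """A 3-D bead realization of one chain (coordinates in nm)."""

    backbone: np.ndarray  # (N, 3)
    charge_beads: np.ndarray  # (n_cm, 3)
    alkyl_beads: np.ndarray  # (n_cm8, 3)
    charge_monomers: np.ndarray  # monomer index of each charge bead
    alkyl_monomers: np.ndarray  # monomer index of each alkyl bead
    bond_length: float
    chain: Chain | None = None
    policy: ThetaPolicy | None = None
    seed: int | None = None

    @property
    def n_monomers(self) -> int:
        return self.backbone.shape[0]

    @property
    def n_beads(self) -> int:
        return (
            self.backbone.shape[0]
            + self.charge_beads.shape[0]
            + self.alkyl_beads.shape[0]
        )

    @property
    def charge_values(self) -> np.ndarray:
        """Charge of each charge bead, in e (one bead per CM group)."""
        return np.full(self.charge_beads.shape[0], -1.0)

    def bond_vectors(self) -> np.ndarray:
        return np.diff(self.backbone, axis=0)

    def end_to_end_distance(self) -> float:
        return float(np.linalg.norm(self.backbone[-1] - self.backbone[0]))


def _random_unit_perpendicular(t: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Uniform random unit vector in the plane normal to unit vector t."""
    helper = np.array([1.0, 0.0, 0.0])
    if abs(t[0]) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(t, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(t, e1)
    phi = rng.uniform(0.0, 2.0 * math.pi)
    return math.cos(phi) * e1 + math.sin(phi) * e2


def _build_backbone(
    n: int, b: float, cos_theta: float | None, rng: np.random.Generator
) -> np.ndarray:
    dirs = np.empty((n - 1, 3)) if n > 1 else np.empty((0, 3))
    if n > 1:
        d = np.array([0.0, 0.0, 1.0])
        dirs[0] = d
        for i in range(1, n - 1):
            if cos_theta is None:
                c = rng.uniform(-1.0, 1.0)
            else:
                c = cos_theta
            s = math.sqrt(max(0.0, 1.0 - c * c))
            perp = _random_unit_perpendicular(d, rng)
            d = c * d + s * perp
            d /= np.linalg.norm(d)
            dirs[i] = d
    coords = np.zeros((n, 3))
    if n > 1:
        coords[1:] = np.cumsum(dirs * b, axis=0)
    return coords


def embed_chain(
    chain: Chain,
    b: float = DEFAULT_BOND_LENGTH,
    theta_policy: ThetaPolicy | None = None,
    excluded_volume_radius: float | None = None,
    seed: int | None = None,
    max_retries: int = 100,
) -> Conformer:
    """Embed a chain as a freely-rotating bead backbone with side beads.

    Parameters
    ----------
    chain
        Source sequence; CM groups get charge beads, CM8 groups alkyl beads.
    b
        Virtual bond length (nm), > 0.
    theta_policy
        Bond-angle policy; defaults to a 5 nm target persistence length.
    excluded_volume_radius
        If set, reject and regenerate conformers in which any two
        nonadjacent backbone beads come closer than twice this radius.
    max_retries
        Retry budget for the self-avoidance rejection loop.

    Raises
    ------
    EmbeddingError
        If self-avoidance cannot be satisfied within ``max_retries``.
    """
    if b <= 0:
        raise ValueError("bond length must be > 0")
    if theta_policy is None:
        theta_policy = ThetaPolicy.target_lp(5.0)
    rng = np.random.default_rng(seed)
    n = chain.n_monomers
    cos_theta = theta_policy.cos_theta(b)

    for attempt in range(max_retries):
        backbone = _build_backbone(n, b, cos_theta, rng)
        if excluded_volume_radius is None or n < 3:
            break
        tree = cKDTree(backbone)
        pairs = tree.query_pairs(2.0 * excluded_volume_radius)
        if all(j - i <= 1 for i, j in pairs):
            break
    else:
        raise EmbeddingError(
            f"self-avoiding embedding failed after {max_retries} retries",
            retries=max_retries,
        )

    # Local tangents: mean of adjacent bond directions.
    if n > 1:
        bonds = np.diff(backbone, axis=0)
        bond_dirs = bonds / np.linalg.norm(bonds, axis=1, keepdims=True)
        tangents = np.empty((n, 3))
        tangents[0] = bond_dirs[0]
        tangents[-1] = bond_dirs[-1]
        if n > 2:
            mid = bond_dirs[:-1] + bond_dirs[1:]
            mid /= np.linalg.norm(mid, axis=1, keepdims=True)
            tangents[1:-1] = mid
    else:
        tangents = np.array([[0.0, 0.0, 1.0]])

    charge_pos, charge_mono = [], []
    alkyl_pos, alkyl_mono = [], []
    for i, row in enumerate(chain.codes):
        for code in row:
            if code == CM:
                u = _random_unit_perpendicular(tangents[i], rng)
                charge_pos.append(backbone[i] + CHARGE_BEAD_OFFSET * u)
                charge_mono.append(i)
            elif code == CM8:
                u = _random_unit_perpendicular(tangents[i], rng)
                alkyl_pos.append(backbone[i] + ALKYL_BEAD_OFFSET * u)
                alkyl_mono.append(i)

    return Conformer(
        backbone=backbone,
        charge_beads=np.array(charge_pos).reshape(-1, 3),
        alkyl_beads=np.array(alkyl_pos).reshape(-1, 3),
        charge_monomers=np.array(charge_mono, dtype=int),
        alkyl_monomers=np.array(alkyl_mono, dtype=int),
        bond_length=b,
        chain=chain,
        policy=theta_policy,
        seed=seed,
    )


@dataclass
class LpEstimate:
    """Persistence-length estimate from bond-vector correlations."""

    lp: float  # nm; math.inf for a rod
    se: float  # nm; 0 when lp is inf
    n_lags: int
    correlations: np.ndarray = field(repr=False, default=None)
    is_rod: bool = False


def bond_correlations(
    conformers: Sequence[Conformer], max_lag: int | None = None
) -> np.ndarray:
    """Mean tangent correlation <u_i . u_{i+k}> for k = 1..max_lag."""
    n_bonds = min(c.n_monomers - 1 for c in conformers)
    if max_lag is None:
        max_lag = max(1, n_bonds // 2)
    max_lag = min(max_lag, n_bonds - 1)
    sums = np.zeros(max_lag)
    counts = np.zeros(max_lag)
    for c in conformers:
        bonds = c.bond_vectors()
        u = bonds / np.linalg.norm(bonds, axis=1, keepdims=True)
        for k in range(1, max_lag + 1):
            dots = np.einsum("ij,ij->i", u[:-k], u[k:])
            sums[k - 1] += dots.sum()
            counts[k - 1] += dots.size
    return sums / counts


def estimate_persistence_length(
    conformers: Sequence[Conformer] | Conformer,
    max_lag: int | None = None,
    corr_floor: float = math.exp(-2.0),
) -> LpEstimate:
    """Estimate Lp by log-linear regression of tangent correlations.

    Fits ``ln C(k) = -(k b / Lp)`` (through the origin) over the leading
    run of positive correlations, truncated where C(k) drops below
    ``corr_floor`` (default two decay lengths) — beyond that the sample
    correlations are noise-dominated and their logs are biased. A rod (no
    decay) is reported as ``lp = inf`` with ``is_rod`` set.

    Raises
    ------
    EstimationError
        If the correlation at lag 1 is nonpositive (decay too fast to
        resolve at this bond length).
    """
    if isinstance(conformers, Conformer):
        conformers = [conformers]
    if not conformers:
        raise EstimationError("need at least one conformer")
    if any(c.n_monomers < 10 for c in conformers):
        raise EstimationError("conformers must have at least 10 monomers")
    b = conformers[0].bond_length
    corr = bond_correlations(conformers, max_lag=max_lag)
    if corr[0] <= 0:
        raise EstimationError(
            "tangent correlation nonpositive at lag 1; cannot estimate Lp"
        )
    # Leading run of correlations above the floor (log defined and reliable).
    below = np.flatnonzero(corr <= corr_floor)
    cutoff = below[0] if below.size else corr.size
    cutoff = max(cutoff, 1)
    k = np.arange(1, cutoff + 1, dtype=float)
    y = np.log(corr[:cutoff])
    slope = float(np.sum(k * y) / np.sum(k * k))
    if slope >= 0.0:
        return LpEstimate(
            lp=math.inf, se=0.0, n_lags=cutoff, correlations=corr, is_rod=True
        )
    lp = -b / slope
    if k.size > 1:
        resid = y - slope * k
        var_slope = float(np.sum(resid**2) / (k.size - 1) / np.sum(k * k))
        se = b / slope**2 * math.sqrt(var_slope)
    else:
        se = math.nan
    return LpEstimate(lp=lp, se=se, n_lags=cutoff, correlations=corr)
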