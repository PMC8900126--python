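"""Seeded synthetic-input generators with ground-truth sidecars.

Every generator is deterministic under its seed and returns, next to the
generated object, a :class:`SyntheticSpec` recording the generator name,
the ground-truth parameters, and the noise model, so that downstream
recovery tests read truth only from the sidecar.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .assays import ElementalMeasurement, TitrationCurve
from .assembly import (
    BEAD_ACID,
    BEAD_ALKYL,
    BEAD_BACKBONE,
    PackedSystem,
)
from .constants import (
    CM8_INCREMENT,
    M_ANHYDROGLUCOSE,
    M_C,
    M_N,
    cm_increment,
)


@dataclass
class SyntheticSpec:
    """Sidecar record of a synthetic data set."""

    generator: str
    truth: dict
    noise: dict = field(default_factory=dict)
    seed: int | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def gen_pyrene_curve(
    true_cac: float = 0.62,
    left_slope: float = 0.0,
    right_slope: float = 0.5,
    left_intercept: float = 0.60,
    noise_sigma: float = 0.01,
    n_points: int = 12,
    top_conc: float = 15.0,
    dilution_factor: float = 2.0,
    seed: int | None = None,
) -> tuple[TitrationCurve, SyntheticSpec]:
    """Two-regime pyrene I3/I1 titration curve over a dilution series.

    Concentrations run down from ``top_conc`` by repeated division by
    ``dilution_factor``. Below the true CAC the ratio follows the left line;
    above it, a right line continuous at the breakpoint. Additive i.i.d.
    Gaussian noise of SD ``noise_sigma`` is applied to the ratios.
    """
    if dilution_factor <= 1:
        raise ValueError("dilution_factor must be > 1")
    conc = top_conc / dilution_factor ** np.arange(n_points)
    if not conc.min() < true_cac < conc.max():
        raise ValueError(
            f"true CAC {true_cac} outside the generated concentration range "
            f"[{conc.min():.4g}, {conc.max():.4g}]"
        )
    y_at_cac = left_intercept + left_slope * true_cac
    ratios = np.where(
        conc <= true_cac,
        left_intercept + left_slope * conc,
        y_at_cac + right_slope * (conc - true_cac),
    )
    rng = np.random.default_rng(seed)
    if noise_sigma > 0:
        ratios = ratios + rng.normal(0.0, noise_sigma, size=ratios.shape)
    curve = TitrationCurve(concentrations=conc, ratios=ratios)
    spec = SyntheticSpec(
        generator="pyrene_curve",
        truth={
            "true_cac": true_cac,
            "left_slope": left_slope,
            "right_slope": right_slope,
            "left_intercept": left_intercept,
            "n_points": n_points,
            "top_conc": top_conc,
            "dilution_factor": dilution_factor,
        },
        noise={"model": "additive_gaussian", "sigma": noise_sigma},
        seed=seed,
    )
    return curve, spec


def gen_elemental_readings(
    amide_ds: float = 0.22,
    ds_cm: float = 0.9,
    sample_conc: float = 0.2,
    noise_rel: float = 0.0,
    seed: int | None = None,
) -> tuple[ElementalMeasurement, SyntheticSpec]:
    """TOC/TN readings (mg/L) forward-modelled from a known amide fraction.

    Per monomer: carbons 6 + 2*ds_cm + 8*ds_cm*amide_ds, nitrogens
    ds_cm*amide_ds; the monomer mass uses sodium-salt bookkeeping (the
    convention cancels in the N/C ratio the estimator uses). Multiplicative
    Gaussian noise of relative SD ``noise_rel`` is applied independently to
    TOC and TN.
    """
    if not 0.0 <= amide_ds <= 1.0:
        raise ValueError("amide_ds must be in [0, 1]")
    carbons = 6.0 + 2.0 * ds_cm + 8.0 * ds_cm * amide_ds
    nitrogens = ds_cm * amide_ds
    monomer_mass = (
        M_ANHYDROGLUCOSE
        + ds_cm * (1.0 - amide_ds) * cm_increment("sodium_salt")
        + ds_cm * amide_ds * CM8_INCREMENT
    )
    mg_per_l = sample_conc * 1000.0
    toc = mg_per_l * carbons * M_C / monomer_mass
    tn = mg_per_l * nitrogens * M_N / monomer_mass
    rng = np.random.default_rng(seed)
    if noise_rel > 0:
        toc *= 1.0 + rng.normal(0.0, noise_rel)
        tn *= 1.0 + rng.normal(0.0, noise_rel)
    meas = ElementalMeasurement(
        toc_mg_l=float(max(toc, 0.0)),
        tn_mg_l=float(max(tn, 0.0)),
        sample_mg_ml=sample_conc,
        ds_cm=ds_cm,
        toc_sigma=float(toc * noise_rel),
        tn_sigma=float(tn * noise_rel),
    )
    spec = SyntheticSpec(
        generator="elemental_readings",
        truth={"amide_ds": amide_ds, "ds_cm": ds_cm, "sample_conc": sample_conc},
        noise={"model": "multiplicative_gaussian", "rel_sigma": noise_rel},
        seed=seed,
    )
    return meas, spec


def _tight_cluster(
    center: np.ndarray, size: int, radius: float, rng: np.random.Generator
) -> np.ndarray:
    """``size`` points within ``radius`` of each other, centroid at center."""
    pts = rng.uniform(-radius / 2.0, radius / 2.0, size=(size, 3))
    return center + pts - pts.mean(axis=0)


def gen_planted_system(
    alkyl_cluster_sizes: tuple[int, ...] = (5,),
    alkyl_chain_counts: tuple[int, ...] = (3,),
    acid_cluster_sizes: tuple[int, ...] = (9,),
    alkyl_acid_distance: float = 12.0,
    box_edge: float = 100.0,
    n_background: int = 0,
    background_min_separation: float = 20.0,
    seed: int | None = None,
) -> tuple[PackedSystem, SyntheticSpec]:
    """Packed-system fixture with planted clusters and known answers.

    Each alkyl cluster i has ``alkyl_cluster_sizes[i]`` alkyl beads drawn
    from ``alkyl_chain_counts[i]`` distinct chains, placed so all pairwise
    distances are well under the default 6 A contact cutoff; the matching
    acid cluster sits with its centroid exactly ``alkyl_acid_distance`` A
    from the alkyl-cluster centroid. Optional background beads are isolated
    (pairwise farther than ``background_min_separation``).
    """
    if len(alkyl_cluster_sizes) != len(alkyl_chain_counts):
        raise ValueError("alkyl sizes and chain counts must align")
    n_sites = max(len(alkyl_cluster_sizes), len(acid_cluster_sizes))
    margin = alkyl_acid_distance + 10.0
    if box_edge < 2 * margin + 20.0 * max(1, n_sites):
        raise ValueError(
            f"box edge {box_edge} A too small for {n_sites} planted site(s) "
            f"at distance {alkyl_acid_distance} A"
        )
    rng = np.random.default_rng(seed)

    positions, types, chains = [], [], []
    next_chain = 0
    centers_used: list[np.ndarray] = []

    def fresh_center() -> np.ndarray:
        for _ in range(10_000):
            c = rng.uniform(margin, box_edge - margin, size=3)
            if all(np.linalg.norm(c - u) > 2.5 * margin for u in centers_used):
                centers_used.append(c)
                return c
        raise ValueError("could not place planted sites; box too crowded")

    site_records = []
    for i in range(n_sites):
        center = fresh_center()
        rec: dict = {}
        if i < len(alkyl_cluster_sizes):
            size = alkyl_cluster_sizes[i]
            n_chains = alkyl_chain_counts[i]
            pts = _tight_cluster(center, size, radius=2.5, rng=rng)
            positions.append(pts)
            types.append(np.full(size, BEAD_ALKYL, dtype=np.int8))
            ids = np.array(
                [next_chain + (j % n_chains) for j in range(size)], dtype=int
            )
            chains.append(ids)
            next_chain += n_chains
            rec["alkyl_size"] = size
            rec["alkyl_chains"] = n_chains
            rec["alkyl_centroid"] = pts.mean(axis=0).tolist()
        if i < len(acid_cluster_sizes):
            size = acid_cluster_sizes[i]
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            acid_center = center + alkyl_acid_distance * direction
            pts = _tight_cluster(acid_center, size, radius=2.5, rng=rng)
            positions.append(pts)
            types.append(np.full(size, BEAD_ACID, dtype=np.int8))
            chains.append(np.full(size, next_chain, dtype=int))
            next_chain += 1
            rec["acid_size"] = size
            rec["acid_centroid"] = pts.mean(axis=0).tolist()
            rec["alkyl_acid_distance"] = alkyl_acid_distance
        site_records.append(rec)

    for _ in range(n_background):
        for _ in range(10_000):
            c = rng.uniform(0.0, box_edge, size=3)
            existing = np.vstack(positions) if positions else np.empty((0, 3))
            if existing.size == 0 or np.min(
                np.linalg.norm(existing - c, axis=1)
            ) > background_min_separation:
                break
        else:
            raise ValueError("could not place isolated background beads")
        positions.append(c.reshape(1, 3))
        types.append(np.array([BEAD_BACKBONE], dtype=np.int8))
        chains.append(np.array([next_chain], dtype=int))
        next_chain += 1

    pos = np.vstack(positions) if positions else np.empty((0, 3))
    system = PackedSystem(
        box_edge=box_edge,
        positions=np.mod(pos, box_edge),
        bead_types=np.concatenate(types) if types else np.array([], np.int8),
        chain_ids=np.concatenate(chains) if chains else np.array([], int),
        total_mass_gmol=0.0,  # fixture geometry only; no mass bookkeeping
        periodic=True,
        n_chains=next_chain,
    )
    spec = SyntheticSpec(
        generator="planted_system",
        truth={
            "sites": site_records,
            "box_edge": box_edge,
            "n_background": n_background,
        },
        seed=seed,
    )
    return system, spec
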