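"""Bespoke assay computations: CAC from pyrene titration and amide DS
from elemental analysis.

The critical aggregation concentration (CAC) is the abscissa of the
intersection of two least-squares lines fitted to the low- and
high-concentration regimes of a pyrene I3/I1 titration curve; the split is
chosen by exhaustive search over admissible breakpoints.

The amide degree of substitution inverts the molar N/C ratio of an
elemental (TOC/TN) measurement through the monomer stoichiometry: a glucose
unit contributes 6 ring carbons, each carboxymethyl 2 more, each octylamide
8 more plus exactly one nitrogen, so

    N/C = (ds_cm * a) / (6 + 2*ds_cm + 8*ds_cm*a)

which is strictly increasing in the amide fraction ``a`` and solved in
closed form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .constants import M_C, M_N
from .errors import OutOfModelError, ParallelSegmentsError


@dataclass
class TitrationCurve:
    """Pyrene I3/I1 ratio versus polymer concentration.

    ``concentrations`` are in mg/mL, strictly monotone (a dilution series);
    ``ratios`` are the dimensionless I3/I1 values (I3 ~ 383 nm, I1 ~ 373 nm).
    """

    concentrations: np.ndarray
    ratios: np.ndarray
    replicates: int = 1

    def __post_init__(self):
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.ratios = np.asarray(self.ratios, dtype=float)
        if self.concentrations.shape != self.ratios.shape:
            raise ValueError("concentrations and ratios must align")
        if self.concentrations.size < 6:
            raise ValueError("need at least 6 titration points")
        if np.any(self.concentrations <= 0):
            raise ValueError("concentrations must be strictly positive")
        d = np.diff(self.concentrations)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("concentrations must be strictly monotone")


@dataclass
class LineSegment:
    slope: float
    intercept: float
    n_points: int


@dataclass
class CacFit:
    """Two-line breakpoint fit of a titration curve."""

    cac: float  # mg/mL
    left: LineSegment
    right: LineSegment
    split_index: int  # first index of the right segment (ascending order)
    residual_sum: float
    cac_se: float
    x_transform: str


def _line_fit(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, np.ndarray]:
    """Least-squares line; returns slope, intercept, SSR, covariance."""
    A = np.stack([x, np.ones_like(x)], axis=1)
    coef, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    ssr = float(resid @ resid)
    dof = max(1, x.size - 2)
    sigma2 = ssr / dof
    cov = sigma2 * np.linalg.inv(A.T @ A)
    return float(coef[0]), float(coef[1]), ssr, cov


def fit_cac(
    curve: TitrationCurve,
    x_transform: str = "linear",
    min_points_per_side: int = 3,
    parallel_tol: float = 1e-12,
) -> CacFit:
    """Fit the two-regime titration curve and return the line intersection.

    Every admissible split into a left segment (low concentration) and a
    right segment (high concentration), each with at least
    ``min_points_per_side`` points, is fitted by least squares; the split
    with the smallest total residual wins. The CAC is the abscissa of the
    intersection, mapped back through the concentration transform.

    Raises
    ------
    ParallelSegmentsError
        If the best split's two lines are parallel within tolerance (e.g.
        data on a single straight line).
    """
    if x_transform not in ("linear", "log10"):
        raise ValueError(f"unknown x_transform {x_transform!r}")
    order = np.argsort(curve.concentrations)
    conc = curve.concentrations[order]
    y = curve.ratios[order]
    x = np.log10(conc) if x_transform == "log10" else conc
    n = x.size
    if n < 2 * min_points_per_side:
        raise ValueError(
            f"need at least {2 * min_points_per_side} points for a two-line fit"
        )

    best = None
    for k in range(min_points_per_side, n - min_points_per_side + 1):
        ml, bl, ssr_l, cov_l = _line_fit(x[:k], y[:k])
        mr, br, ssr_r, cov_r = _line_fit(x[k:], y[k:])
        total = ssr_l + ssr_r
        if best is None or total < best[0]:
            best = (total, k, (ml, bl, cov_l), (mr, br, cov_r))

    total, k, (ml, bl, cov_l), (mr, br, cov_r) = best
    dm = ml - mr
    scale = max(abs(ml), abs(mr), 1.0)
    if abs(dm) <= parallel_tol * scale:
        raise ParallelSegmentsError(
            f"fitted segments are parallel (slopes {ml:.3g}, {mr:.3g}); "
            "no intersection exists"
        )
    x_star = (br - bl) / dm
    # Delta-method SE of the intersection abscissa from the two fits'
    # (independent) covariance matrices.
    g_l = np.array([x_star / dm, 1.0 / dm])  # d x*/d(ml, bl) up to sign
    g_r = np.array([-x_star / dm, -1.0 / dm])
    var = float(g_l @ cov_l @ g_l + g_r @ cov_r @ g_r)
    se = math.sqrt(max(var, 0.0))
    if x_transform == "log10":
        cac = 10.0**x_star
        se = cac * math.log(10.0) * se  # propagate through the exponent
    else:
        cac = x_star
    return CacFit(
        cac=cac,
        left=LineSegment(ml, bl, k),
        right=LineSegment(mr, br, n - k),
        split_index=k,
        residual_sum=total,
        cac_se=se,
        x_transform=x_transform,
    )


# ---------------------------------------------------------------------------
# Elemental analysis -> amide DS
# ---------------------------------------------------------------------------


@dataclass
class ElementalMeasurement:
    """TOC/TN readings of a dissolved polymer sample."""

    toc_mg_l: float
    tn_mg_l: float
    sample_mg_ml: float = 0.2
    ds_cm: float = 0.9
    toc_sigma: float = 0.0  # absolute SDs (mg/L) for error propagation
    tn_sigma: float = 0.0

    def __post_init__(self):
        if self.toc_mg_l < 0 or self.tn_mg_l < 0:
            raise ValueError("TOC/TN readings must be nonnegative")
        if self.toc_mg_l == 0 and self.tn_mg_l > 0:
            raise ValueError("nonzero TN with zero TOC is not physical")

    @property
    def nc_molar(self) -> float:
        """Molar N/C ratio of the readings."""
        if self.toc_mg_l == 0:
            return 0.0
        return (self.tn_mg_l / M_N) / (self.toc_mg_l / M_C)


@dataclass
class DsEstimate:
    """Amide degree of substitution with propagated uncertainty."""

    amide_ds_percent: float
    se_percent: float
    nc_molar: float


def amide_nc_ratio(amide_fraction: float, ds_cm: float = 0.9) -> float:
    """Forward model: molar N/C of a chain at a given amide fraction."""
    return (ds_cm * amide_fraction) / (
        6.0 + 2.0 * ds_cm + 8.0 * ds_cm * amide_fraction
    )


def estimate_amide_ds(measurement: ElementalMeasurement) -> DsEstimate:
    """Invert the molar N/C ratio to the amide fraction (as percent).

    Solving ``r = ds*a / (6 + 2 ds + 8 ds a)`` for ``a`` gives

        a = r (6 + 2 ds) / (ds (1 - 8 r))

    valid for ``0 <= r < ds / (6 + 2 ds + 8 ds)`` (the ratio of a fully
    amidated chain).

    Raises
    ------
    OutOfModelError
        If the measured N/C falls outside the invertible range.
    """
    ds = measurement.ds_cm
    if not 0 < ds <= 3:
        raise ValueError(f"ds_cm must be in (0, 3], got {ds}")
    r = measurement.nc_molar
    r_max = amide_nc_ratio(1.0, ds)
    if not 0.0 <= r < r_max:
        raise OutOfModelError(
            f"molar N/C = {r:.6g} outside the invertible range [0, {r_max:.6g})"
        )
    a = r * (6.0 + 2.0 * ds) / (ds * (1.0 - 8.0 * r))

    # Propagate reading SDs through r and then a (delta method).
    se = 0.0
    if (measurement.toc_sigma or measurement.tn_sigma) and measurement.toc_mg_l > 0:
        dr_dtn = (M_C / M_N) / measurement.toc_mg_l
        dr_dtoc = -r / measurement.toc_mg_l
        var_r = (dr_dtn * measurement.tn_sigma) ** 2 + (
            dr_dtoc * measurement.toc_sigma
        ) ** 2
        da_dr = (6.0 + 2.0 * ds) / (ds * (1.0 - 8.0 * r) ** 2)
        se = abs(da_dr) * math.sqrt(var_r)
    return DsEstimate(
        amide_ds_percent=100.0 * a, se_percent=100.0 * se, nc_molar=r
    )
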