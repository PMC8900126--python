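"""Monomer state space, substitution-pattern distribution, and chain generation.

A glucose monomer can carry a substituent at ring positions 2, 3 and 6. Each
position is in one of three states: ``OH`` (unsubstituted hydroxyl), ``CM``
(carboxymethyl, charge -1e) or ``CM8`` (N-octyl-amidated carboxymethyl,
charge 0, one alkyl tail). That gives 3**3 = 27 monomer states.

Before amidation only ``OH``/``CM`` occur, so chains are sampled from a
distribution over the 8 binary substitution patterns. The two published
marginal summaries for DS~0.9 CMC (positional substitution counts and
substitution-class counts) are mutually inconsistent at the third decimal;
:func:`fit_pattern_distribution` reconciles them by constrained weighted
least squares, pinning the total CM per monomer at ``ds_cm`` (0.9 by
default) and keeping every marginal inside (or at the boundary of) its
target range.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import minimize

from .constants import (
    CM8_INCREMENT,
    M_ANHYDROGLUCOSE,
    MASS_CONVENTIONS,
    cm_increment,
)
from .errors import ConfigurationError, FitError

# Per-position state codes used in integer sequence arrays.
OH, CM, CM8 = 0, 1, 2
STATE_NAMES = ("OH", "CM", "CM8")
STATE_CODES = {name: code for code, name in enumerate(STATE_NAMES)}

POSITIONS = (2, 3, 6)

#: The 8 pre-amidation patterns as (pos2, pos3, pos6) CM indicators,
#: in lexicographic order: (0,0,0), (0,0,1), ..., (1,1,1).
PATTERNS8 = tuple(itertools.product((0, 1), repeat=3))
_PATTERNS8_ARR = np.array(PATTERNS8, dtype=np.int8)
_PATTERN_CM_COUNT = _PATTERNS8_ARR.sum(axis=1)

#: Default positional substitution-probability target ranges at DS~0.9
#: (fractions per monomer; published as counts per 1000-mer).
DEFAULT_POSITIONAL_RANGES = {
    2: (0.360, 0.370),
    3: (0.160, 0.170),
    6: (0.350, 0.360),
}

#: Default substitution-class fraction target ranges (unsub, mono, di, tri).
DEFAULT_CLASS_RANGES = (
    (0.330, 0.340),
    (0.440, 0.450),
    (0.190, 0.200),
    (0.020, 0.030),
)

DEFAULT_DS_CM = 0.9
#: Default amidation fraction: 200 amide groups out of 900 CM on a 1000-mer.
DEFAULT_AMIDE_FRACTION = 200.0 / 900.0

SITE_RULES = ("tri_full", "tri_ge2")


@dataclass(frozen=True)
class MonomerState:
    """One glucose unit's substitution pattern with derived properties."""

    pos2: str
    pos3: str
    pos6: str
    charge: int
    mass: float
    n_alkyl: int
    n_cm_total: int

    @property
    def states(self) -> tuple[str, str, str]:
        return (self.pos2, self.pos3, self.pos6)


def _monomer_mass(codes: Sequence[int], mass_convention: str) -> float:
    inc_cm = cm_increment(mass_convention)
    mass = M_ANHYDROGLUCOSE
    for c in codes:
        if c == CM:
            mass += inc_cm
        elif c == CM8:
            mass += CM8_INCREMENT
    return mass


def build_monomer_library(
    mass_convention: str = "sodium_salt",
) -> dict[tuple[str, str, str], MonomerState]:
    """Enumerate all 27 monomer states.

    Parameters
    ----------
    mass_convention
        ``"sodium_salt"`` (charged carboxymethyls carry a Na+ counter-ion in
        the mass) or ``"free_acid"``.

    Returns
    -------
    dict
        Mapping ``(pos2, pos3, pos6)`` state-name triple -> MonomerState.
    """
    if mass_convention not in MASS_CONVENTIONS:
        raise ConfigurationError(
            f"unknown mass convention {mass_convention!r}; "
            f"expected one of {MASS_CONVENTIONS}"
        )
    library = {}
    for codes in itertools.product((OH, CM, CM8), repeat=3):
        names = tuple(STATE_NAMES[c] for c in codes)
        library[names] = MonomerState(
            pos2=names[0],
            pos3=names[1],
            pos6=names[2],
            charge=-sum(1 for c in codes if c == CM),
            mass=_monomer_mass(codes, mass_convention),
            n_alkyl=sum(1 for c in codes if c == CM8),
            n_cm_total=sum(1 for c in codes if c != OH),
        )
    return library


# ---------------------------------------------------------------------------
# Pattern distribution
# ---------------------------------------------------------------------------


def _marginals_of(probs: np.ndarray) -> np.ndarray:
    """Positional CM probabilities (p2, p3, p6) of an 8-pattern law."""
    return probs @ _PATTERNS8_ARR


def _class_fractions_of(probs: np.ndarray) -> np.ndarray:
    """(f0, f1, f2, f3) substitution-class fractions of an 8-pattern law."""
    f = np.zeros(4)
    np.add.at(f, _PATTERN_CM_COUNT, probs)
    return f


@dataclass
class PatternDistribution:
    """Probability law over the 8 pre-amidation substitution patterns.

    Attributes
    ----------
    probs
        Length-8 array ordered as :data:`PATTERNS8`.
    p2, p3, p6
        Fitted positional CM marginals.
    f0, f1, f2, f3
        Fitted class fractions (unsubstituted, mono, di, tri).
    provenance
        Target ranges, residuals and any recorded inconsistency.
    """

    probs: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape != (8,):
            raise ValueError("probs must have shape (8,)")
        if np.any(self.probs < -1e-12):
            raise ValueError("probs must be nonnegative")
        if abs(self.probs.sum() - 1.0) > 1e-9:
            raise ValueError("probs must sum to 1")
        self.probs = np.clip(self.probs, 0.0, None)
        self.probs /= self.probs.sum()

    @property
    def positional_marginals(self) -> np.ndarray:
        return _marginals_of(self.probs)

    @property
    def p2(self) -> float:
        return float(self.positional_marginals[0])

    @property
    def p3(self) -> float:
        return float(self.positional_marginals[1])

    @property
    def p6(self) -> float:
        return float(self.positional_marginals[2])

    @property
    def class_fractions(self) -> np.ndarray:
        return _class_fractions_of(self.probs)

    @property
    def f0(self) -> float:
        return float(self.class_fractions[0])

    @property
    def f1(self) -> float:
        return float(self.class_fractions[1])

    @property
    def f2(self) -> float:
        return float(self.class_fractions[2])

    @property
    def f3(self) -> float:
        return float(self.class_fractions[3])

    @property
    def mean_cm_per_monomer(self) -> float:
        return float(self.positional_marginals.sum())

    def to_json(self, path) -> None:
        import json
        from pathlib import Path

        doc = {
            "patterns": ["".join(map(str, pat)) for pat in PATTERNS8],
            "probs": self.probs.tolist(),
            "positional_marginals": self.positional_marginals.tolist(),
            "class_fractions": self.class_fractions.tolist(),
            "provenance": self.provenance,
        }
        Path(path).write_text(json.dumps(doc, indent=1) + "\n")

    @classmethod
    def from_json(cls, path) -> "PatternDistribution":
        import json
        from pathlib import Path

        doc = json.loads(Path(path).read_text())
        return cls(np.array(doc["probs"]), provenance=doc.get("provenance", {}))

    @classmethod
    def from_independent(cls, p: Sequence[float]) -> "PatternDistribution":
        """Product law with independent per-position CM probabilities."""
        p = np.asarray(p, dtype=float)
        probs = np.array(
            [
                np.prod(np.where(pat, p, 1.0 - p))
                for pat in _PATTERNS8_ARR
            ]
        )
        return cls(probs, provenance={"kind": "independent_product", "p": p.tolist()})


def fit_pattern_distribution(
    positional_targets: Mapping[int, tuple[float, float]] | None = None,
    class_targets: Sequence[tuple[float, float]] | None = None,
    weights: tuple[float, float] = (1.0, 1.0),
    total_cm: float | None = DEFAULT_DS_CM,
    tol: float = 1e-10,
) -> PatternDistribution:
    """Reconcile positional and class marginal targets into one 8-pattern law.

    Minimizes ``w_pos * ||marginals - positional midpoints||^2 +
    w_class * ||class fractions - class midpoints||^2`` over nonnegative,
    normalized pattern probabilities, subject to every marginal lying within
    (or at the boundary of) its target range and, when ``total_cm`` is given,
    the mean CM per monomer equalling ``total_cm`` exactly.

    The default targets cannot all hold in their interiors simultaneously:
    the positional ranges cap the per-monomer CM total at 0.900 while the
    class ranges allow up to 0.910. The fit pins the total at ``total_cm``
    and records the residuals in ``provenance``.

    Raises
    ------
    FitError
        If no nonnegative distribution satisfies the constraints.
    """
    if positional_targets is None:
        positional_targets = DEFAULT_POSITIONAL_RANGES
    if class_targets is None:
        class_targets = DEFAULT_CLASS_RANGES

    pos_lo = np.array([positional_targets[p][0] for p in POSITIONS])
    pos_hi = np.array([positional_targets[p][1] for p in POSITIONS])
    cls_lo = np.array([lo for lo, _ in class_targets])
    cls_hi = np.array([hi for _, hi in class_targets])
    if np.any(pos_lo > pos_hi) or np.any(cls_lo > cls_hi):
        raise FitError("target ranges must satisfy low <= high")
    pos_mid = 0.5 * (pos_lo + pos_hi)
    cls_mid = 0.5 * (cls_lo + cls_hi)
    w_pos, w_cls = weights

    def objective(x):
        m = _marginals_of(x)
        f = _class_fractions_of(x)
        return w_pos * np.sum((m - pos_mid) ** 2) + w_cls * np.sum((f - cls_mid) ** 2)

    constraints = [{"type": "eq", "fun": lambda x: x.sum() - 1.0}]
    if total_cm is not None:
        constraints.append(
            {"type": "eq", "fun": lambda x: _marginals_of(x).sum() - total_cm}
        )
    # Range constraints, g(x) >= 0 form.
    constraints.append({"type": "ineq", "fun": lambda x: _marginals_of(x) - pos_lo})
    constraints.append({"type": "ineq", "fun": lambda x: pos_hi - _marginals_of(x)})
    constraints.append({"type": "ineq", "fun": lambda x: _class_fractions_of(x) - cls_lo})
    constraints.append({"type": "ineq", "fun": lambda x: cls_hi - _class_fractions_of(x)})

    # Start from the independent product at the positional midpoints.
    x0 = PatternDistribution.from_independent(np.clip(pos_mid, 1e-6, 1 - 1e-6)).probs
    result = minimize(
        objective,
        x0,
        method="SLSQP",
        bounds=[(0.0, 1.0)] * 8,
        constraints=constraints,
        options={"maxiter": 500, "ftol": 1e-14},
    )

    x = np.clip(result.x, 0.0, None)
    s = x.sum()
    residual_report = {
        "positional_targets": {p: list(positional_targets[p]) for p in POSITIONS},
        "class_targets": [list(r) for r in class_targets],
        "fitted_marginals": _marginals_of(x / s).tolist() if s > 0 else None,
        "fitted_class_fractions": _class_fractions_of(x / s).tolist() if s > 0 else None,
        "objective": float(result.fun),
        "solver_status": int(result.status),
        "solver_message": result.message,
    }
    if not result.success or s <= 0:
        raise FitError(
            f"pattern distribution fit failed: {result.message}",
            residuals=residual_report,
        )
    x /= s
    m = _marginals_of(x)
    f = _class_fractions_of(x)
    # Verify feasibility within a loose numerical tolerance.
    viol = max(
        float(np.max(pos_lo - m, initial=0.0)),
        float(np.max(m - pos_hi, initial=0.0)),
        float(np.max(cls_lo - f, initial=0.0)),
        float(np.max(f - cls_hi, initial=0.0)),
    )
    if total_cm is not None:
        viol = max(viol, abs(float(m.sum()) - total_cm))
    if viol > 1e-6:
        raise FitError(
            f"no nonnegative distribution satisfies the target ranges "
            f"(max violation {viol:.3e})",
            residuals=residual_report,
        )
    provenance = dict(residual_report)
    provenance["constraint_violation"] = viol
    provenance["note"] = (
        "positional ranges cap total CM at 0.900/monomer while class ranges "
        "allow up to 0.910; total pinned at "
        + ("free" if total_cm is None else f"{total_cm:g}")
    )
    return PatternDistribution(x, provenance=provenance)


def default_distribution() -> PatternDistribution:
    """The reconciled distribution at the published DS~0.9 target ranges."""
    return fit_pattern_distribution()


# ---------------------------------------------------------------------------
# Chains
# ---------------------------------------------------------------------------


@dataclass
class Chain:
    """A monomer-state sequence.

    Attributes
    ----------
    codes
        Integer array of shape (N, 3): per-monomer states at positions
        (2, 3, 6), values in {OH=0, CM=1, CM8=2}.
    ds_cm
        Degree of carboxymethyl substitution the chain was generated at.
    amide_fraction
        Fraction of CM groups converted to CM8.
    seed
        RNG seed used for generation (None for hand-built chains).
    """

    codes: np.ndarray
    ds_cm: float = DEFAULT_DS_CM
    amide_fraction: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.ndim != 2 or self.codes.shape[1] != 3:
            raise ValueError("codes must have shape (N, 3)")
        if self.codes.size and not np.isin(self.codes, (OH, CM, CM8)).all():
            raise ValueError("codes must be in {0, 1, 2}")

    def __len__(self) -> int:
        return self.codes.shape[0]

    def __eq__(self, other) -> bool:
        if not isinstance(other, Chain):
            return NotImplemented
        return (
            np.array_equal(self.codes, other.codes)
            and self.ds_cm == other.ds_cm
            and self.amide_fraction == other.amide_fraction
            and self.seed == other.seed
        )

    @property
    def n_monomers(self) -> int:
        return self.codes.shape[0]

    @property
    def total_charge(self) -> int:
        """Total charge in units of e: -1 per CM position."""
        return -int(np.count_nonzero(self.codes == CM))

    @property
    def n_cm_total(self) -> int:
        """Positions carrying a carboxymethyl group, amidated or not."""
        return int(np.count_nonzero(self.codes != OH))

    @property
    def n_cm8(self) -> int:
        return int(np.count_nonzero(self.codes == CM8))

    @property
    def n_alkyl(self) -> int:
        return self.n_cm8

    def state_names(self) -> list[tuple[str, str, str]]:
        return [tuple(STATE_NAMES[c] for c in row) for row in self.codes]

    def monomer_states(
        self, mass_convention: str = "sodium_salt"
    ) -> list[MonomerState]:
        lib = build_monomer_library(mass_convention)
        return [lib[names] for names in self.state_names()]


def generate_chain(
    dist: PatternDistribution,
    n: int,
    amide_fraction: float = 0.0,
    enforce_exact_counts: bool = True,
    seed: int | None = None,
    max_repair_steps: int = 1_000_000,
) -> Chain:
    """Generate a chain of ``n`` monomers from a pattern distribution.

    Patterns are drawn i.i.d. from ``dist``. With ``enforce_exact_counts``
    a repair pass resamples randomly chosen monomers from ``dist`` (accepting
    only draws that bring the count closer) until the total CM count equals
    ``round(ds_cm * n)``, where ``ds_cm`` is the distribution's mean CM per
    monomer. Then exactly ``round(amide_fraction * CM count)`` CM groups,
    chosen uniformly at random, are converted to CM8.

    Identical seeds produce identical chains.
    """
    if n < 1:
        raise ValueError(f"chain length must be >= 1, got {n}")
    if not 0.0 <= amide_fraction <= 1.0:
        raise ValueError(f"amide_fraction must be in [0, 1], got {amide_fraction}")
    rng = np.random.default_rng(seed)
    ds_cm = dist.mean_cm_per_monomer
    idx = rng.choice(8, size=n, p=dist.probs)
    codes = _PATTERNS8_ARR[idx].astype(np.int8).copy()

    if enforce_exact_counts:
        target = round(ds_cm * n)
        current = int(codes.sum())
        steps = 0
        while current != target:
            if steps >= max_repair_steps:
                raise RuntimeError("exact-count repair did not converge")
            steps += 1
            i = rng.integers(n)
            j = rng.choice(8, p=dist.probs)
            new_cm = int(_PATTERN_CM_COUNT[j])
            old_cm = int(codes[i].sum())
            proposed = current - old_cm + new_cm
            if abs(proposed - target) < abs(current - target):
                codes[i] = _PATTERNS8_ARR[j]
                current = proposed

    # Amidation: convert CM groups (flattened positions) to CM8.
    cm_flat = np.flatnonzero(codes.ravel() == CM)
    n_amide = round(amide_fraction * cm_flat.size)
    if n_amide > 0:
        chosen = rng.choice(cm_flat, size=n_amide, replace=False)
        flat = codes.ravel()
        flat[chosen] = CM8
        codes = flat.reshape(n, 3)

    return Chain(codes=codes, ds_cm=ds_cm, amide_fraction=amide_fraction, seed=seed)


@dataclass
class ChainStats:
    """Sequence-level summary of one chain."""

    n_monomers: int
    cm_by_position: dict[int, int]  # CM or CM8 count per ring position
    charged_by_position: dict[int, int]  # CM-only count per ring position
    class_counts: tuple[int, int, int, int]  # unsub / mono / di / tri
    total_charge: int
    n_cm_total: int
    n_alkyl: int
    mean_monomer_mass: float
    mass_convention: str


def chain_statistics(
    chain: Chain, mass_convention: str = "sodium_salt"
) -> ChainStats:
    """Per-position, per-class, charge, alkyl and mass summary of a chain."""
    codes = chain.codes
    sub = codes != OH
    n_sub_per_monomer = sub.sum(axis=1)
    class_counts = tuple(
        int(np.count_nonzero(n_sub_per_monomer == k)) for k in range(4)
    )
    inc = cm_increment(mass_convention)
    total_mass = (
        chain.n_monomers * M_ANHYDROGLUCOSE
        + int(np.count_nonzero(codes == CM)) * inc
        + chain.n_cm8 * CM8_INCREMENT
    )
    return ChainStats(
        n_monomers=chain.n_monomers,
        cm_by_position={
            p: int(sub[:, i].sum()) for i, p in enumerate(POSITIONS)
        },
        charged_by_position={
            p: int(np.count_nonzero(codes[:, i] == CM))
            for i, p in enumerate(POSITIONS)
        },
        class_counts=class_counts,
        total_charge=chain.total_charge,
        n_cm_total=chain.n_cm_total,
        n_alkyl=chain.n_alkyl,
        mean_monomer_mass=total_mass / chain.n_monomers,
        mass_convention=mass_convention,
    )


@dataclass
class SiteReport:
    """Count of candidate strongly-negative monomer sites on a chain."""

    rule: str
    count: int
    params: dict = field(default_factory=dict)


def count_negative_sites(chain: Chain, rule: str = "tri_full") -> SiteReport:
    """Count monomers qualifying as candidate negative-potential sites.

    Rules
    -----
    ``tri_full``
        All three positions are charged CM (charge -3e).
    ``tri_ge2``
        The monomer is tri-substituted (every position CM or CM8) and at
        least two positions remain charged CM.
    """
    codes = chain.codes
    if rule == "tri_full":
        count = int(np.count_nonzero((codes == CM).all(axis=1)))
        params = {"min_cm": 3}
    elif rule == "tri_ge2":
        tri = (codes != OH).all(axis=1)
        count = int(np.count_nonzero(tri & ((codes == CM).sum(axis=1) >= 2)))
        params = {"min_cm": 2}
    else:
        raise ConfigurationError(
            f"unknown site rule {rule!r}; expected one of {SITE_RULES}"
        )
    return SiteReport(rule=rule, count=count, params=params)
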