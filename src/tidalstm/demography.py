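"""Paired merchantable/unmerchantable stage-structured projection matrices.

Each species is modeled as two interacting populations of the same DBH
size-class scheme: merchantable (M) trees, free of severe stem defects, and
unmerchantable (UM) trees. The state vector stacks the two blocks as
``(M_1..M_k, UM_1..UM_k)``. Trees survive in place (stasis), advance one
class per year (upgrowth ``G``), and while advancing a merchantable tree may
irreversibly develop defects with probability ``x`` and enter the UM block.
Both blocks reproduce into the first merchantable class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SizeClassScheme",
    "VitalRates",
    "TransitionMatrix",
    "PopulationState",
    "EigenSystem",
    "build_transition_matrix",
    "project_one_year",
    "dominant_eigenvalue",
    "empirical_lambda",
    "estimate_defect_transition",
]

#: width (cm) of every size class after the first (5-9.9 cm) class
CLASS_WIDTH_CM = 2.5
FIRST_CLASS_LOWER_CM = 5.0
FIRST_CLASS_WIDTH_CM = 5.0


@dataclass(frozen=True)
class SizeClassScheme:
    """DBH size classes: 5-9.9 cm, then 2.5 cm classes, open-ended top class.

    Parameters
    ----------
    lower_bounds : tuple of float
        Lower DBH bound (cm) of each class. Must start at 5 with the second
        bound at 10; subsequent bounds step by 2.5 cm. The last class is
        open-ended (absorbing for growth).
    """

    lower_bounds: tuple[float, ...]

    def __post_init__(self) -> None:
        b = np.asarray(self.lower_bounds, dtype=float)
        if b.size < 2:
            raise ValueError("need at least two size classes")
        if b[0] != FIRST_CLASS_LOWER_CM:
            raise ValueError("first class must start at 5 cm DBH")
        if b[1] != FIRST_CLASS_LOWER_CM + FIRST_CLASS_WIDTH_CM:
            raise ValueError("first class is 5-9.9 cm (second bound must be 10)")
        steps = np.diff(b[1:])
        if steps.size and not np.allclose(steps, CLASS_WIDTH_CM):
            raise ValueError("classes after the first must be 2.5 cm wide")

    @classmethod
    def from_max_dbh(cls, max_dbh_cm: float) -> "SizeClassScheme":
        """Scheme spanning 5 cm up to an open top class at ``max_dbh_cm``."""
        if max_dbh_cm < 10:
            raise ValueError("max DBH must be at least 10 cm")
        upper = np.arange(10.0, max_dbh_cm + 1e-9, CLASS_WIDTH_CM)
        return cls(tuple([FIRST_CLASS_LOWER_CM, *upper]))

    @property
    def n_classes(self) -> int:
        return len(self.lower_bounds)

    @property
    def midpoints(self) -> np.ndarray:
        """Class midpoint DBH (cm); the open top class is given one width."""
        b = np.asarray(self.lower_bounds)
        widths = np.empty_like(b)
        widths[:-1] = np.diff(b)
        widths[-1] = CLASS_WIDTH_CM
        return b + widths / 2.0

    def class_of_dbh(self, dbh_cm: float) -> int:
        if dbh_cm < self.lower_bounds[0]:
            raise ValueError(f"DBH {dbh_cm} below the 5 cm census threshold")
        return int(np.searchsorted(self.lower_bounds, dbh_cm, side="right") - 1)

    def eligible_classes(self, mcd_cm: float) -> np.ndarray:
        """Indices of classes whose lower bound is >= the minimum cut diameter."""
        return np.flatnonzero(np.asarray(self.lower_bounds) >= mcd_cm)


@dataclass
class VitalRates:
    """Per-class annual vital rates.

    S: survival probability; G: probability a survivor advances one class
    (stasis is ``S - G``); F: per-capita fertility into class M1;
    x: probability that a merchantable tree advancing out of class i turns
    unmerchantable. ``x[0]`` must be 0 (class-1 advances keep merchantable
    status) and ``G`` of the open top class must be 0.
    """

    S: np.ndarray
    G: np.ndarray
    F: np.ndarray
    x: np.ndarray

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        self.G = np.asarray(self.G, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        self.x = np.asarray(self.x, dtype=float)

    def validate(self, scheme: SizeClassScheme) -> None:
        k = scheme.n_classes
        for name, arr in (("S", self.S), ("G", self.G), ("F", self.F), ("x", self.x)):
            if arr.shape != (k,):
                raise ValueError(f"{name} has {arr.shape} entries, scheme has {k} classes")
        for name, arr in (("S", self.S), ("G", self.G), ("x", self.x)):
            if np.any(arr < 0) or np.any(arr > 1):
                raise ValueError(f"{name} entries must lie in [0, 1]")
        if np.any(self.F < 0):
            raise ValueError("fertility must be non-negative")
        if np.any(self.G > self.S + 1e-12):
            raise ValueError("upgrowth G cannot exceed survival S in any class")
        if self.G[-1] != 0:
            raise ValueError("open top class is absorbing: G of the last class must be 0")
        if self.x[0] != 0:
            raise ValueError("x is undefined for the first class (must be 0)")


@dataclass
class TransitionMatrix:
    """Annual projection matrix over the stacked ``(M, UM)`` state.

    The survival/growth part and the fertility row are kept separate so the
    fertility row can be rescaled per projection year (density-dependent
    recruitment, post-harvest recruitment boosts) without rebuilding.
    """

    survival: np.ndarray  # (2k, 2k) stasis + growth, no reproduction
    fertility: np.ndarray  # (2k,) per-capita contributions to class M1
    scheme: SizeClassScheme
    rates: VitalRates | None = field(default=None, repr=False)

    @property
    def k(self) -> int:
        return self.scheme.n_classes

    @property
    def matrix(self) -> np.ndarray:
        """Full projection matrix A with the fertility row folded in."""
        A = self.survival.copy()
        A[0, :] += self.fertility
        return A


@dataclass
class PopulationState:
    """Per-species stacked (M, UM) tree densities (trees/ha), continuous."""

    densities: dict[str, np.ndarray]
    year: int = 0

    def __post_init__(self) -> None:
        for name, n in self.densities.items():
            n = np.asarray(n, dtype=float)
            if np.any(n < 0):
                raise ValueError(f"negative density for {name}")
            if n.size % 2:
                raise ValueError(f"{name}: stacked (M, UM) vector must have even length")
            self.densities[name] = n

    @property
    def species(self) -> list[str]:
        return list(self.densities)

    def merchantable(self, species: str) -> np.ndarray:
        n = self.densities[species]
        return n[: n.size // 2]

    def unmerchantable(self, species: str) -> np.ndarray:
        n = self.densities[species]
        return n[n.size // 2 :]

    def total(self, species: str | None = None) -> float:
        if species is not None:
            return float(self.densities[species].sum())
        return float(sum(n.sum() for n in self.densities.values()))

    def copy(self) -> "PopulationState":
        return PopulationState(
            {s: n.copy() for s, n in self.densities.items()}, year=self.year
        )


def build_transition_matrix(rates: VitalRates, scheme: SizeClassScheme) -> TransitionMatrix:
    """Assemble the paired M/UM projection matrix.

    Layout per class i (0-based), with k classes per block:

    - stasis: ``A[i, i] = A[k+i, k+i] = S_i - G_i``
    - merchantable upgrowth splits on defect development:
      ``A[i+1, i] = G_i (1 - x_i)`` and ``A[k+i+1, i] = G_i x_i``
    - unmerchantable upgrowth: ``A[k+i+1, k+i] = G_i``
    - fertility: both blocks contribute ``F_i`` per capita to row M1.

    The UM -> M block is structurally zero outside the fertility row: defect
    development is irreversible.
    """
    rates.validate(scheme)
    k = scheme.n_classes
    A = np.zeros((2 * k, 2 * k))
    S, G, x = rates.S, rates.G, rates.x
    for i in range(k):
        stasis = S[i] - G[i]
        A[i, i] = stasis
        A[k + i, k + i] = stasis
        if i < k - 1:
            A[i + 1, i] = G[i] * (1.0 - x[i])
            A[k + i + 1, i] = G[i] * x[i]
            A[k + i + 1, k + i] = G[i]
    fert = np.concatenate([rates.F, rates.F])
    return TransitionMatrix(survival=A, fertility=fert, scheme=scheme, rates=rates)


def project_one_year(
    n: np.ndarray,
    tm: TransitionMatrix,
    extra_recruits: float = 0.0,
    fertility_multiplier: float = 1.0,
) -> np.ndarray:
    """One annual projection step ``n(t+1) = A n(t)`` plus planted recruits.

    ``extra_recruits`` (trees/ha) and all reproduction enter class M1.
    ``fertility_multiplier`` rescales the fertility row (density regulation).
    """
    n = np.asarray(n, dtype=float)
    if n.shape != (tm.survival.shape[0],):
        raise ValueError(
            f"state has {n.shape} entries, matrix is {tm.survival.shape[0]}x{tm.survival.shape[0]}"
        )
    if extra_recruits < 0:
        raise ValueError("extra recruits must be non-negative")
    out = tm.survival @ n
    out[0] += fertility_multiplier * float(tm.fertility @ n) + extra_recruits
    return out


@dataclass(frozen=True)
class EigenSystem:
    """Dominant eigenvalue with right (w) and left (v) eigenvectors.

    w is scaled to sum to 1 (stable stage distribution); v is scaled so that
    <v, w> = 1 (reproductive values), the normalization used by eigenvalue
    sensitivities s_ij = v_i w_j.
    """

    lam: float
    w: np.ndarray
    v: np.ndarray


def spectral_radius(A: np.ndarray | TransitionMatrix) -> float:
    """Largest eigenvalue modulus; robust to reducible/triangular matrices."""
    if isinstance(A, TransitionMatrix):
        A = A.matrix
    return float(np.max(np.abs(np.linalg.eigvals(np.asarray(A, dtype=float)))))


def dominant_eigenvalue(A: np.ndarray | TransitionMatrix) -> EigenSystem:
    """Spectral radius and dominant right/left eigenvectors of a projection matrix."""
    if isinstance(A, TransitionMatrix):
        A = A.matrix
    A = np.asarray(A, dtype=float)
    if np.any(A < 0):
        raise ValueError("projection matrices must be non-negative")
    vals, vecs = np.linalg.eig(A)
    idx = int(np.argmax(np.abs(vals)))
    lam = vals[idx]
    if abs(lam.imag) > 1e-9 * max(1.0, abs(lam.real)):
        raise ValueError("dominant eigenvalue is complex; matrix is not primitive")
    lam = float(lam.real)
    w = np.real(vecs[:, idx])
    if w.sum() < 0:
        w = -w
    w = np.abs(w)
    w = w / w.sum()
    lvals, lvecs = np.linalg.eig(A.T)
    lidx = int(np.argmin(np.abs(lvals - lam)))
    v = np.real(lvecs[:, lidx])
    inner = v @ w
    if abs(inner) < 1e-12:
        raise ValueError(
            "left/right dominant eigenvectors are orthogonal; "
            "matrix is reducible or defective (no simple dominant eigenpair)"
        )
    v = v / inner
    return EigenSystem(lam=lam, w=w, v=v)


def empirical_lambda(n0_total: float, nh_total: float, horizon: int) -> float:
    """Realized annual growth rate over a horizon: (N_H / N_0)^(1/H).

    Totals are summed over classes and merchantability. This is the empirical
    analog of the dominant eigenvalue for a simulated (possibly harvested,
    density-regulated) trajectory.
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    if n0_total <= 0:
        raise ValueError("initial population must be positive")
    return float((nh_total / n0_total) ** (1.0 / horizon))


def trajectory_lambda(totals: np.ndarray) -> float:
    """``empirical_lambda`` over a full yearly trajectory of total densities."""
    totals = np.asarray(totals, dtype=float)
    return empirical_lambda(totals[0], totals[-1], totals.size - 1)


def estimate_defect_transition(merch_proportion_by_class) -> np.ndarray:
    """Back out per-advance defect probabilities from merchantable proportions.

    If the merchantable share declines from ``p_i`` to ``p_{i+1}`` across one
    class advance, the per-advance loss needed is
    ``x_i = max(0, (p_i - p_{i+1}) / p_i)``. Increasing proportions are
    inconsistent with an irreversible transition and clip to 0 with a warning.
    Returns one value per class advance (length ``len(p) - 1``).
    """
    p = np.asarray(merch_proportion_by_class, dtype=float)
    if p.ndim != 1 or p.size < 2:
        raise ValueError("need at least two class proportions")
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("proportions must lie in [0, 1]")
    bad = (p[:-1] == 0) & (p[1:] > 0)
    if np.any(bad):
        raise ValueError(
            "merchantable proportion rises from zero between classes "
            f"{np.flatnonzero(bad).tolist()}; inconsistent with an irreversible transition"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        x = np.where(p[:-1] > 0, (p[:-1] - p[1:]) / np.where(p[:-1] > 0, p[:-1], 1.0), 0.0)
    if np.any(x < 0):
        warnings.warn(
            "merchantable proportion increases with size in some classes; "
            "defect transition clipped to 0",
            stacklevel=2,
        )
    return np.clip(x, 0.0, 1.0)
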