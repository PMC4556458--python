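"""Density-dependent recruitment regulation and carrying-capacity estimation.

Recruitment is regulated by a complemented Weibull function of current stand
density Na: recruitment(Na) = a * exp(-(Na / b)^shape). With the default
shape of 6 the function stays near 1 while the stand is far below carrying
capacity and collapses rapidly as density approaches it. Carrying capacities
are estimated as the maximum density seen by a moving window swept over
stem-mapped plots, and species-specific maxima are rescaled so they sum to
the all-species maximum (distinct species do not peak in the same subplot).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .demography import PopulationState

__all__ = [
    "DensityParams",
    "recruitment_multiplier",
    "estimate_carrying_capacity",
    "scale_species_k",
    "effective_density",
]

DEFAULT_SHAPE = 6.0


@dataclass(frozen=True)
class DensityParams:
    """Parameters of the complemented-Weibull recruitment regulation.

    b defaults to the carrying capacity K, so the multiplier falls to 1/e
    exactly at K and is effectively zero above it. ``a`` is a baseline scale
    carried by the fertility coefficients themselves; the multiplier returned
    by :func:`recruitment_multiplier` is normalized to 1 at Na = 0.
    """

    K: float
    a: float = 1.0
    b: float | None = None
    shape: float = DEFAULT_SHAPE
    mode: str = "per_species"  # or "grouped"

    def __post_init__(self) -> None:
        if self.K <= 0:
            raise ValueError("carrying capacity K must be positive")
        if self.a < 0:
            raise ValueError("a must be non-negative")
        if self.b is not None and self.b <= 0:
            raise ValueError("density scale b must be positive")
        if self.shape <= 0:
            raise ValueError("Weibull shape must be positive")
        if self.mode not in ("per_species", "grouped"):
            raise ValueError("mode must be 'per_species' or 'grouped'")

    @property
    def scale(self) -> float:
        return self.K if self.b is None else self.b


def recruitment_multiplier(na: float, params: DensityParams) -> float:
    """Recruitment regulation factor exp(-(Na/b)^shape), in (0, 1].

    Strictly decreasing in Na; 1 at Na = 0 and 1/e at Na = b.
    """
    if na < 0:
        raise ValueError("stand density must be non-negative")
    return float(np.exp(-((na / params.scale) ** params.shape)))


def estimate_carrying_capacity(
    stems: pd.DataFrame,
    window_m: float = 100.0,
    step_m: float = 10.0,
    extent_m: tuple[float, float] | None = None,
) -> tuple[float, pd.Series]:
    """Maximum windowed stand density (trees/ha) over a stem-mapped plot.

    A ``window_m`` square window is swept on a ``step_m`` grid over the plot;
    the carrying capacity is the largest density (all species combined) any
    placement contains. Raw per-species maxima are computed over the same
    placements and returned for rescaling with :func:`scale_species_k`.

    ``stems`` needs columns ``x_m``, ``y_m`` and ``species``. The plot extent
    defaults to the bounding box of the stems.

    Returns ``(K_all, raw_per_species_max)`` both in trees/ha.
    """
    required = {"x_m", "y_m", "species"}
    if not required.issubset(stems.columns):
        raise ValueError(f"stem table needs columns {sorted(required)}")
    if len(stems) == 0:
        raise ValueError("stem table is empty")
    x = stems["x_m"].to_numpy(dtype=float)
    y = stems["y_m"].to_numpy(dtype=float)
    if extent_m is None:
        extent_m = (float(x.max()), float(y.max()))
    ex, ey = extent_m
    if window_m > ex or window_m > ey:
        raise ValueError("window larger than plot extent")
    if np.any(x < 0) or np.any(y < 0) or np.any(x > ex) or np.any(y > ey):
        raise ValueError("stem coordinates fall outside the plot extent")

    x0s = _placements(ex, window_m, step_m)
    y0s = _placements(ey, window_m, step_m)
    area_ha = window_m * window_m / 1e4

    species = stems["species"].to_numpy()
    names = pd.unique(species)
    best_all = 0
    best_sp = {name: 0 for name in names}
    for x0 in x0s:
        in_x = (x >= x0) & (x < x0 + window_m)
        for y0 in y0s:
            inside = in_x & (y >= y0) & (y < y0 + window_m)
            count = int(inside.sum())
            if count > best_all:
                best_all = count
            if count:
                sp_in = species[inside]
                for name, c in zip(*np.unique(sp_in, return_counts=True)):
                    if c > best_sp[name]:
                        best_sp[name] = int(c)
    raw = pd.Series({name: best_sp[name] / area_ha for name in names}, name="K_raw")
    return best_all / area_ha, raw


def _placements(extent: float, window: float, step: float) -> np.ndarray:
    """Window origins on the step grid, always including the flush-right one."""
    last = extent - window
    xs = np.arange(0.0, last + 1e-9, step)
    if xs.size == 0 or xs[-1] < last - 1e-9:
        xs = np.append(xs, last)
    return xs


def scale_species_k(raw_species_max: pd.Series, overall_max: float) -> pd.Series:
    """Rescale raw per-species window maxima to sum to the all-species maximum.

    The raw maxima come from different subplots; the stand cannot hold all of
    them simultaneously, so K_s = raw_s * overall / sum(raw).
    """
    raw = pd.Series(raw_species_max, dtype=float)
    if overall_max <= 0:
        raise ValueError("overall maximum density must be positive")
    if np.any(raw < 0):
        raise ValueError("raw maxima must be non-negative")
    total = raw.sum()
    if total == 0:
        raise ValueError("all raw species maxima are zero")
    return raw * overall_max / total


def effective_density(
    state: PopulationState, mode: str = "per_species"
) -> dict[str, float]:
    """Density Na regulating each species' recruitment.

    per_species: each species sees its own total density (b tied to its K).
    grouped: every species sees the summed density of all modeled species
    (b tied to the overall K), capturing composition shifts under harvest.
    """
    if mode == "per_species":
        return {s: state.total(s) for s in state.species}
    if mode == "grouped":
        total = state.total()
        return {s: total for s in state.species}
    raise ValueError("mode must be 'per_species' or 'grouped'")
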