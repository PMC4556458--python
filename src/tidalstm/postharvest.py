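"""Post-harvest demographic effects: modified matrices for a fixed window.

For a fixed number of years after each harvest (default 10), surviving trees
follow modified vital rates: juvenile (5-20 cm DBH) upgrowth is scaled by a
per-species factor, adult upgrowth by another (default 1), and fertility by a
recruitment factor (default 1; above 1 only for species with an observed
post-harvest recruitment boost). Mortality is unchanged. A new harvest
restarts the window; with a cutting cycle no longer than the effect duration
the stand is under post-harvest dynamics permanently.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .demography import (
    SizeClassScheme,
    TransitionMatrix,
    VitalRates,
    build_transition_matrix,
)

__all__ = ["PostHarvestEffects", "modified_matrix", "active_matrix"]

#: upper DBH (cm) of the juvenile response group; the class containing this
#: diameter is treated as juvenile.
JUVENILE_MAX_DBH_CM = 20.0


@dataclass(frozen=True)
class PostHarvestEffects:
    duration: int = 10
    juvenile_growth_multiplier: float = 1.0
    adult_growth_multiplier: float = 1.0
    recruitment_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if self.duration < 0:
            raise ValueError("duration must be non-negative")
        for m in (
            self.juvenile_growth_multiplier,
            self.adult_growth_multiplier,
            self.recruitment_multiplier,
        ):
            if m < 0:
                raise ValueError("multipliers must be non-negative")

    @property
    def is_identity(self) -> bool:
        return (
            self.juvenile_growth_multiplier == 1.0
            and self.adult_growth_multiplier == 1.0
            and self.recruitment_multiplier == 1.0
        )


def juvenile_mask(scheme: SizeClassScheme) -> np.ndarray:
    """True for classes in the juvenile response group (5-20 cm DBH).

    The class whose DBH range contains 20 cm counts as juvenile, so the split
    falls on a class boundary: every class with a lower bound <= 20 cm.
    """
    return np.asarray(scheme.lower_bounds) <= JUVENILE_MAX_DBH_CM


def modified_matrix(
    base: TransitionMatrix,
    effects: PostHarvestEffects,
    scheme: SizeClassScheme | None = None,
) -> TransitionMatrix:
    """Post-harvest projection matrix: scaled G (juvenile/adult) and F, same S.

    Scaled upgrowth is clipped (with a warning) wherever it would exceed
    survival, keeping stasis non-negative.
    """
    if base.rates is None:
        raise ValueError("base matrix does not carry its vital rates")
    scheme = scheme or base.scheme
    rates = base.rates
    juv = juvenile_mask(scheme)
    g_mult = np.where(juv, effects.juvenile_growth_multiplier, effects.adult_growth_multiplier)
    g = rates.G * g_mult
    over = g > rates.S
    if np.any(over):
        warnings.warn(
            "post-harvest growth multiplier pushes G above S in classes "
            f"{np.flatnonzero(over).tolist()}; clipped to S",
            stacklevel=2,
        )
        g = np.minimum(g, rates.S)
    new_rates = VitalRates(
        S=rates.S.copy(),
        G=g,
        F=rates.F * effects.recruitment_multiplier,
        x=rates.x.copy(),
    )
    return build_transition_matrix(new_rates, scheme)


def active_matrix(
    year: int,
    harvest_years: list[int] | set[int],
    base: TransitionMatrix,
    modified: TransitionMatrix,
    duration: int = 10,
) -> TransitionMatrix:
    """Matrix in force at a given year: modified within the post-harvest window.

    The window after a harvest at year h spans [h, h + duration); a newer
    harvest restarts the clock rather than stacking effects.
    """
    past = [h for h in harvest_years if h <= year]
    if not past:
        return base
    latest = max(past)
    return modified if year < latest + duration else base
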