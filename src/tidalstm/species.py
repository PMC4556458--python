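"""Per-species parameter bundle tying demography, allometry and regulation."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .demography import (
    SizeClassScheme,
    TransitionMatrix,
    VitalRates,
    build_transition_matrix,
)
from .density import DensityParams
from .harvest import AllometryParams
from .postharvest import PostHarvestEffects, modified_matrix

__all__ = ["SpeciesParameters"]


@dataclass
class SpeciesParameters:
    """Everything the simulator needs to know about one species.

    merch_proportion is the merchantable share per size class used to split
    generated stands into M/UM blocks (and from which the defect-transition
    probabilities x can be estimated). K is the carrying capacity (trees/ha)
    anchoring the density-dependent recruitment scale.
    """

    name: str
    scheme: SizeClassScheme
    rates: VitalRates
    K: float
    merch_proportion: np.ndarray | None = None
    allometry: AllometryParams = field(default_factory=AllometryParams)
    effects: PostHarvestEffects = field(default_factory=PostHarvestEffects)

    def __post_init__(self) -> None:
        self.rates.validate(self.scheme)
        if self.K <= 0:
            raise ValueError("carrying capacity must be positive")
        if self.merch_proportion is not None:
            p = np.asarray(self.merch_proportion, dtype=float)
            if p.shape != (self.scheme.n_classes,):
                raise ValueError("merch_proportion needs one value per class")
            if np.any(p < 0) or np.any(p > 1):
                raise ValueError("merch_proportion must lie in [0, 1]")
            self.merch_proportion = p

    def density_params(self, mode: str = "per_species") -> DensityParams:
        return DensityParams(K=self.K, mode=mode)

    def base_matrix(self) -> TransitionMatrix:
        return build_transition_matrix(self.rates, self.scheme)

    def post_harvest_matrix(self) -> TransitionMatrix:
        return modified_matrix(self.base_matrix(), self.effects, self.scheme)
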