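"""Selective-harvest rules: eligibility, felling, volume caps, residual damage.

A management regime fells a proportion (the harvest intensity) of trees at or
above the minimum cut diameter (MCD), leaving the remainder as seed trees.
Only merchantable trees are ever felled; under "low" seed-tree quality the
intensity is computed over merchantable plus unmerchantable stems (so more
merchantable trees are cut and defective trees are left as seed trees).
Species whose merchantable density above the MCD falls below a minimum
commercial density are skipped. An optional volume cap limits each harvest to
cap x cutting-cycle cubic meters per hectare. After felling, incidental
mortality removes additional trees across all species, classes and
merchantability in proportion to their abundance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .demography import PopulationState, SizeClassScheme

__all__ = [
    "ManagementRegime",
    "DamageParams",
    "AllometryParams",
    "HarvestRecord",
    "ResidualDamageTable",
    "OBSERVED_DAMAGE_TABLE",
    "eligible_harvest",
    "merchantable_volume",
    "apply_volume_cap",
    "apply_residual_mortality",
    "tree_ratio_from_basal_area",
]


@dataclass(frozen=True)
class ManagementRegime:
    """One combination of the six management criteria.

    cutting_cycle: years between harvests; harvest_intensity: proportion of
    the eligibility basis felled; mcd_cm: minimum cut diameter;
    min_commercial_density: trees/ha of merchantable stems >= MCD below which
    a species is not harvested; seed_tree_quality: 'high' (basis counts
    merchantable stems only) or 'low' (basis includes unmerchantable stems);
    volume_cap: m3/ha/yr or None; harvested_species: None means all.
    """

    cutting_cycle: int
    harvest_intensity: float
    mcd_cm: float
    min_commercial_density: float = 0.0
    seed_tree_quality: str = "high"
    volume_cap: float | None = None
    harvested_species: frozenset[str] | None = None

    def __post_init__(self) -> None:
        if self.cutting_cycle <= 0:
            raise ValueError("cutting cycle must be positive")
        if not 0.0 <= self.harvest_intensity <= 1.0:
            raise ValueError("harvest intensity must lie in [0, 1]")
        if self.mcd_cm < 5:
            raise ValueError("MCD below the 5 cm census threshold")
        if self.min_commercial_density < 0:
            raise ValueError("minimum commercial density must be non-negative")
        if self.seed_tree_quality not in ("high", "low"):
            raise ValueError("seed_tree_quality must be 'high' or 'low'")
        if self.volume_cap is not None and self.volume_cap <= 0:
            raise ValueError("volume cap must be positive (or None)")

    def harvests(self, species: str) -> bool:
        return self.harvested_species is None or species in self.harvested_species

    @property
    def volume_allowance(self) -> float:
        """Volume allowed per harvest event (m3/ha), inf when uncapped."""
        if self.volume_cap is None:
            return math.inf
        return self.volume_cap * self.cutting_cycle


def legal_regime(cutting_cycle: int = 30) -> ManagementRegime:
    """The Brazilian legal regime: 90% intensity, 50 cm MCD, MD 0.03,
    low seed-tree quality, 1 m3/ha/yr volume limit."""
    return ManagementRegime(
        cutting_cycle=cutting_cycle,
        harvest_intensity=0.9,
        mcd_cm=50.0,
        min_commercial_density=0.03,
        seed_tree_quality="low",
        volume_cap=1.0,
    )


@dataclass(frozen=True)
class DamageParams:
    """Residual stand mortality: trees incidentally killed per tree harvested."""

    residual_mortality_ratio: float

    def __post_init__(self) -> None:
        if self.residual_mortality_ratio < 0:
            raise ValueError("residual mortality ratio must be non-negative")


@dataclass(frozen=True)
class AllometryParams:
    """Merchantable volume per tree from DBH via a form-factor cylinder.

    volume(dbh) = form_factor * basal_area(dbh) * commercial_height(dbh) with
    commercial height saturating as h_max * dbh / (dbh + h_half). Setting
    h_half = 0 gives a constant commercial height of h_max.
    """

    form_factor: float = 0.7
    h_max_m: float = 25.0
    h_half_cm: float = 15.0

    def __post_init__(self) -> None:
        if not 0 < self.form_factor <= 1:
            raise ValueError("form factor must lie in (0, 1]")
        if self.h_max_m <= 0 or self.h_half_cm < 0:
            raise ValueError("height parameters must be positive")

    def commercial_height(self, dbh_cm: np.ndarray | float) -> np.ndarray | float:
        dbh = np.asarray(dbh_cm, dtype=float)
        return self.h_max_m * dbh / (dbh + self.h_half_cm)

    def tree_volume(self, dbh_cm: np.ndarray | float) -> np.ndarray | float:
        """Merchantable volume (m3) of one tree of the given DBH."""
        dbh = np.asarray(dbh_cm, dtype=float)
        basal_area = np.pi * (dbh / 200.0) ** 2  # m2
        return self.form_factor * basal_area * self.commercial_height(dbh)


@dataclass
class HarvestRecord:
    """Outcome of one harvest event on a 1 ha stand."""

    year: int
    removals: dict[str, np.ndarray]  # per species, trees by merchantable class
    volume_m3: dict[str, float]
    trees_killed: float = 0.0
    cap_binding: bool = False
    skipped_species: list[str] = field(default_factory=list)

    @property
    def total_volume(self) -> float:
        return float(sum(self.volume_m3.values()))

    @property
    def total_trees(self) -> float:
        return float(sum(r.sum() for r in self.removals.values()))


def eligible_harvest(
    state: PopulationState,
    schemes: dict[str, SizeClassScheme],
    regime: ManagementRegime,
) -> tuple[dict[str, np.ndarray], list[str]]:
    """Target removals (merchantable trees by class) for each species.

    For each harvested species: classes with lower bound >= MCD are eligible;
    if the merchantable density in them falls below the minimum commercial
    density the species is skipped; otherwise intensity x basis trees are
    removed (basis per seed-tree quality), drawn from merchantable trees only,
    capped at their availability, allocated across eligible classes
    proportionally to merchantable abundance.

    Returns (removals, skipped_species).
    """
    removals: dict[str, np.ndarray] = {}
    skipped: list[str] = []
    for sp in state.species:
        if not regime.harvests(sp):
            continue
        scheme = schemes[sp]
        elig = scheme.eligible_classes(regime.mcd_cm)
        merch = state.merchantable(sp)
        target = np.zeros_like(merch)
        if elig.size == 0:
            removals[sp] = target
            continue
        merch_elig = merch[elig]
        merch_total = float(merch_elig.sum())
        if merch_total < regime.min_commercial_density:
            skipped.append(sp)
            continue
        basis = merch_total
        if regime.seed_tree_quality == "low":
            basis += float(state.unmerchantable(sp)[elig].sum())
        take = min(regime.harvest_intensity * basis, merch_total)
        if take > 0 and merch_total > 0:
            target[elig] = take * merch_elig / merch_total
        removals[sp] = target
    return removals, skipped


def merchantable_volume(
    removals: np.ndarray, allometry: AllometryParams, scheme: SizeClassScheme
) -> float:
    """Volume (m3/ha) of removed trees, evaluated at class-midpoint DBH."""
    removals = np.asarray(removals, dtype=float)
    if np.any(removals < 0):
        raise ValueError("removals must be non-negative")
    return float(removals @ allometry.tree_volume(scheme.midpoints))


def apply_volume_cap(
    targets: dict[str, np.ndarray],
    volumes: dict[str, float],
    regime: ManagementRegime,
) -> tuple[dict[str, np.ndarray], dict[str, float], bool]:
    """Scale all removals by one factor so total volume meets the cap.

    The allowance per harvest is cap x cutting cycle (m3/ha). Returns the
    (possibly scaled) targets and volumes and whether the cap was binding.
    """
    allowance = regime.volume_allowance
    total = float(sum(volumes.values()))
    if total <= allowance:
        return targets, volumes, False
    factor = allowance / total
    scaled = {sp: t * factor for sp, t in targets.items()}
    scaled_vol = {sp: v * factor for sp, v in volumes.items()}
    return scaled, scaled_vol, True


def apply_residual_mortality(
    state: PopulationState, trees_harvested: float, damage: DamageParams
) -> tuple[PopulationState, float]:
    """Kill ratio x harvested trees, spread proportionally over the residual stand.

    Incidental mortality is indiscriminate of species, size class and
    merchantability: every cell of the post-felling state loses the same
    fraction. Kills are truncated at total availability.

    Returns (new state, trees actually killed).
    """
    if trees_harvested < 0:
        raise ValueError("trees harvested must be non-negative")
    kills = damage.residual_mortality_ratio * trees_harvested
    if kills == 0:
        return state.copy(), 0.0
    total = state.total()
    if total <= 0:
        return state.copy(), 0.0
    frac = min(kills / total, 1.0)
    new = PopulationState(
        {sp: n * (1.0 - frac) for sp, n in state.densities.items()}, year=state.year
    )
    return new, frac * total


@dataclass(frozen=True)
class ResidualDamageTable:
    """Observed basal-area damage ratios (m2 killed : m2 extracted) by tree
    group and cause, with the published per-cause subtotals.

    The printed subtotals carry more precision than the rounded cells (the
    transport cells sum to 0.03 against a printed subtotal of 0.04), so
    aggregate ratios follow the printed marginals.
    """

    cells: dict[str, dict[str, float]]  # group -> cause -> ratio
    cause_subtotals: dict[str, float]

    def total(self) -> float:
        """All-cause basal-area damage ratio (sum of per-cause subtotals)."""
        return float(sum(self.cause_subtotals.values()))

    def group_totals(self) -> dict[str, float]:
        return {g: float(sum(c.values())) for g, c in self.cells.items()}


#: Monitored small-scale extraction: basal area killed per basal area harvested.
OBSERVED_DAMAGE_TABLE = ResidualDamageTable(
    cells={
        "palm": {"tree_fall": 0.17, "transport": 0.03},
        "timber": {"tree_fall": 0.13, "transport": 0.0},
        "other_woody": {"tree_fall": 0.28, "transport": 0.0},
    },
    cause_subtotals={"tree_fall": 0.58, "transport": 0.04},
)


def tree_ratio_from_basal_area(
    ba_ratio: float, mean_ba_harvested_m2: float, mean_ba_killed_m2: float
) -> float:
    """Convert a basal-area damage ratio to a tree-number ratio.

    trees killed per tree harvested = BA ratio x (mean BA of a harvested
    tree) / (mean BA of a killed residual tree). Used to derive the model's
    tree-count mortality ratio from basal-area field observations.
    """
    if mean_ba_harvested_m2 <= 0 or mean_ba_killed_m2 <= 0:
        raise ValueError("mean basal areas must be positive")
    if ba_ratio < 0:
        raise ValueError("basal-area ratio must be non-negative")
    return ba_ratio * mean_ba_harvested_m2 / mean_ba_killed_m2
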