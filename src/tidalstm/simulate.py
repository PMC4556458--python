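"""120-year management-regime simulations on a hypothetical 1 ha stand.

Canonical yearly order of operations (pinned by a regression test):

1. the pre-step state is recorded in the trajectory;
2. if the year is a harvest year (0, c, 2c, ...), felling targets are drawn
   (eligibility, intensity, seed-tree quality), the volume cap applied,
   merchantable trees removed, and residual mortality imposed on everything
   left standing;
3. the projection matrix in force is chosen (post-harvest window);
4. the recruitment-regulation multiplier is evaluated on the current
   (post-felling) density;
5. the state is projected one year, with any compensatory recruits added to
   the first merchantable class.

N_yr0 and N_yr120 of the empirical growth rate are therefore both pre-harvest
densities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .demography import (
    PopulationState,
    TransitionMatrix,
    empirical_lambda,
)
from .density import DensityParams, recruitment_multiplier
from .harvest import (
    DamageParams,
    HarvestRecord,
    ManagementRegime,
    apply_residual_mortality,
    apply_volume_cap,
    eligible_harvest,
    merchantable_volume,
)
from .postharvest import active_matrix
from .species import SpeciesParameters

__all__ = [
    "SimulationResult",
    "simulate_regime",
    "compensatory_recruitment",
    "merchantable_proportion",
]

DEFAULT_HORIZON = 120


@dataclass
class SimulationResult:
    """Trajectory and harvest outcomes of one regime on one stand.

    ``trajectory[sp]`` has shape (horizon + 1, 2k): pre-harvest stacked (M, UM)
    densities at the start of each year.
    """

    trajectory: dict[str, np.ndarray]
    harvests: list[HarvestRecord]
    horizon: int
    regime: ManagementRegime
    skipped: dict[int, list[str]] = field(default_factory=dict)

    @property
    def species(self) -> list[str]:
        return list(self.trajectory)

    def state_at(self, year: int) -> PopulationState:
        return PopulationState(
            {sp: traj[year].copy() for sp, traj in self.trajectory.items()}, year=year
        )

    def totals(self, species: str | None = None) -> np.ndarray:
        """Yearly total density (trees/ha), one species or all combined."""
        if species is not None:
            return self.trajectory[species].sum(axis=1)
        return sum(traj.sum(axis=1) for traj in self.trajectory.values())

    def lambda_h(self, species: str | None = None, horizon: int = DEFAULT_HORIZON) -> float:
        """Empirical growth rate (N_horizon / N_0)^(1/horizon)."""
        horizon = min(horizon, self.horizon)
        totals = self.totals(species)
        return empirical_lambda(float(totals[0]), float(totals[horizon]), horizon)

    def merchantable_proportion(self, species: str) -> np.ndarray:
        return merchantable_proportion(self.trajectory[species])

    def harvest_volumes(self, species: str | None = None) -> np.ndarray:
        """Volume (m3/ha) of each harvest event in order."""
        if species is None:
            return np.array([h.total_volume for h in self.harvests])
        return np.array([h.volume_m3.get(species, 0.0) for h in self.harvests])


def harvest_years(cycle: int, horizon: int) -> list[int]:
    """Harvest at year 0 and every cycle thereafter, strictly inside the horizon."""
    return list(range(0, horizon, cycle))


def simulate_regime(
    stand: PopulationState,
    params: dict[str, SpeciesParameters],
    regime: ManagementRegime,
    horizon: int = DEFAULT_HORIZON,
    damage: DamageParams = DamageParams(0.0),
    density_mode: str = "per_species",
    extra_recruits: dict[str, float] | None = None,
    density_params: dict[str, DensityParams] | None = None,
) -> SimulationResult:
    """Deterministic yearly simulation of one regime over a horizon.

    ``extra_recruits`` plants a constant number of trees/ha/yr into each
    species' first merchantable class (compensatory recruitment).
    ``density_params`` overrides the per-species regulation parameters
    (defaults derive b = K from each species; in grouped mode the scale is
    the summed K of all modeled species).
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    missing = [sp for sp in stand.species if sp not in params]
    if missing:
        raise ValueError(f"no parameters for species {missing}")
    extra = extra_recruits or {}

    base = {sp: params[sp].base_matrix() for sp in stand.species}
    post = {
        sp: (base[sp] if params[sp].effects.is_identity else params[sp].post_harvest_matrix())
        for sp in stand.species
    }
    if density_params is None:
        if density_mode == "grouped":
            k_all = sum(params[sp].K for sp in stand.species)
            density_params = {
                sp: DensityParams(K=k_all, mode="grouped") for sp in stand.species
            }
        else:
            density_params = {sp: params[sp].density_params() for sp in stand.species}
    schemes = {sp: params[sp].scheme for sp in stand.species}

    h_years = set(harvest_years(regime.cutting_cycle, horizon))
    trajectory = {
        sp: np.empty((horizon + 1, stand.densities[sp].size)) for sp in stand.species
    }
    records: list[HarvestRecord] = []
    skipped_log: dict[int, list[str]] = {}
    state = stand.copy()
    past_harvests: list[int] = []

    for t in range(horizon):
        for sp in state.species:
            trajectory[sp][t] = state.densities[sp]
        if t in h_years:
            state, record, skipped = _harvest_event(state, params, schemes, regime, damage, t)
            records.append(record)
            if skipped:
                skipped_log[t] = skipped
            past_harvests.append(t)
        na = _effective_densities(state, density_mode)
        new = {}
        for sp in state.species:
            tm = active_matrix(
                t, past_harvests, base[sp], post[sp], params[sp].effects.duration
            )
            mult = recruitment_multiplier(na[sp], density_params[sp])
            new[sp] = _project(state.densities[sp], tm, extra.get(sp, 0.0), mult)
        state = PopulationState(new, year=t + 1)
    for sp in state.species:
        trajectory[sp][horizon] = state.densities[sp]

    return SimulationResult(
        trajectory=trajectory,
        harvests=records,
        horizon=horizon,
        regime=regime,
        skipped=skipped_log,
    )


def _project(n: np.ndarray, tm: TransitionMatrix, extra: float, mult: float) -> np.ndarray:
    out = tm.survival @ n
    out[0] += mult * float(tm.fertility @ n) + extra
    return out


def _effective_densities(state: PopulationState, mode: str) -> dict[str, float]:
    if mode == "grouped":
        total = state.total()
        return {sp: total for sp in state.species}
    return {sp: state.total(sp) for sp in state.species}


def _harvest_event(
    state: PopulationState,
    params: dict[str, SpeciesParameters],
    schemes,
    regime: ManagementRegime,
    damage: DamageParams,
    year: int,
) -> tuple[PopulationState, HarvestRecord, list[str]]:
    targets, skipped = eligible_harvest(state, schemes, regime)
    volumes = {
        sp: merchantable_volume(t, params[sp].allometry, schemes[sp])
        for sp, t in targets.items()
    }
    targets, volumes, binding = apply_volume_cap(targets, volumes, regime)
    new = state.copy()
    for sp, t in targets.items():
        k = t.size
        merch = new.densities[sp][:k]
        merch -= np.minimum(t, merch)
    trees = float(sum(t.sum() for t in targets.values()))
    new, killed = apply_residual_mortality(new, trees, damage)
    record = HarvestRecord(
        year=year,
        removals=targets,
        volume_m3=volumes,
        trees_killed=killed,
        cap_binding=binding,
        skipped_species=skipped,
    )
    return new, record, skipped


def merchantable_proportion(trajectory: np.ndarray) -> np.ndarray:
    """Yearly merchantable share M / (M + UM); NaN where the species is absent."""
    traj = np.asarray(trajectory, dtype=float)
    k = traj.shape[1] // 2
    merch = traj[:, :k].sum(axis=1)
    total = traj.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(total > 0, merch / total, np.nan)


def compensatory_recruitment(
    stand: PopulationState,
    params: dict[str, SpeciesParameters],
    regime: ManagementRegime,
    horizon: int = DEFAULT_HORIZON,
    tolerance: float = 1e-3,
    damage: DamageParams = DamageParams(0.0),
    density_mode: str = "per_species",
    r_max: float | None = None,
) -> dict[str, float]:
    """Smallest constant yearly planting that holds each species at its
    pre-harvest population after the horizon.

    For each species, finds by bisection the least r (recruits/ha/yr into
    class M1) such that N_horizon >= N_0 under the regime; 0 when the species
    holds its ground unaided. r_max defaults to 10x the species' initial
    class-1 density (plus 1 to cover species starting from an empty first
    class); if even r_max cannot stabilize the species a ValueError reports it.
    """

    def n_ratio(sp: str, r: float) -> float:
        res = simulate_regime(
            stand,
            params,
            regime,
            horizon=horizon,
            damage=damage,
            density_mode=density_mode,
            extra_recruits={sp: r},
        )
        totals = res.totals(sp)
        return float(totals[horizon] - totals[0])

    out: dict[str, float] = {}
    for sp in stand.species:
        if n_ratio(sp, 0.0) >= 0:
            out[sp] = 0.0
            continue
        hi = r_max if r_max is not None else 10.0 * float(stand.densities[sp][0]) + 1.0
        if n_ratio(sp, hi) < 0:
            raise ValueError(
                f"{sp}: even {hi:.3g} recruits/ha/yr cannot stabilize the population; "
                "raise r_max"
            )
        lo = 0.0
        while hi - lo > tolerance:
            mid = 0.5 * (lo + hi)
            if n_ratio(sp, mid) >= 0:
                hi = mid
            else:
                lo = mid
        out[sp] = hi
    return out
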