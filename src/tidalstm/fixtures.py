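"""Synthetic species, stands and stem maps for fully self-contained runs.

No fitted matrices for the study system are published, so these generators
produce parameter sets with the structure the model assumes: asymptotic
growth rates in the realistic 0.99-1.03 band, survival rising and upgrowth
falling with size, fertility proportional to basal area above a reproductive
threshold, merchantable proportions declining with size (yielding the
defect-transition probabilities), and reverse-J stand size distributions.

Three demographic profiles mirror the contrasts the model is meant to
explore: 'fast' (lambda 1.02-1.05, quick stock recovery), 'slow' (lambda
0.99-1.00, declining merchantable share under repeated harvest) and
'pioneer' (near-zero fertility under closed canopy, high juvenile growth,
strong post-harvest recruitment boost). Everything is deterministic given
the seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .demography import (
    PopulationState,
    SizeClassScheme,
    VitalRates,
    build_transition_matrix,
    dominant_eigenvalue,
    estimate_defect_transition,
    spectral_radius,
)
from .harvest import AllometryParams, DamageParams, tree_ratio_from_basal_area
from .postharvest import PostHarvestEffects
from .species import SpeciesParameters

__all__ = [
    "make_species",
    "make_stand",
    "make_stem_map",
    "demo_community",
    "demo_stand",
    "default_damage_params",
    "PROFILES",
]

#: smallest reproductive DBH (cm): fertility is zero below this size
REPRODUCTIVE_DBH_CM = 30.0

#: basal-area damage ratio observed for timber species (m2 killed : m2 cut),
#: converted to the model's tree-number ratio against a concrete stand
TIMBER_BA_DAMAGE_RATIO = 0.13

PROFILES = {
    # lambda target interval, upgrowth scale g0, carrying capacity K,
    # merchantable share of the top class, post-harvest effects
    "fast": dict(
        lam_lo=1.025,
        lam_hi=1.04,
        g0=0.14,
        k_capacity=180.0,
        p_top=0.70,
        effects=PostHarvestEffects(duration=10, juvenile_growth_multiplier=1.3),
    ),
    "slow": dict(
        lam_lo=0.992,
        lam_hi=0.998,
        g0=0.06,
        k_capacity=250.0,
        p_top=0.20,
        effects=PostHarvestEffects(duration=10, juvenile_growth_multiplier=1.15),
    ),
    "pioneer": dict(
        lam_lo=0.986,  # closed-canopy recruitment failure: lambda below 1
        lam_hi=0.992,
        g0=0.20,
        k_capacity=120.0,
        p_top=0.60,
        effects=PostHarvestEffects(
            duration=10, juvenile_growth_multiplier=1.5, recruitment_multiplier=2.0
        ),
    ),
}


def make_species(
    profile: str,
    seed: int,
    max_dbh_cm: float = 70.0,
    name: str | None = None,
) -> SpeciesParameters:
    """Generate one species parameter set for a named demographic profile.

    Fertility is calibrated (Brent root find on the dominant eigenvalue) so
    lambda lands inside the profile's band; the pioneer band sits below 1,
    expressing closed-canopy recruitment failure with a small calibrated
    fertility. Deterministic given the seed.
    """
    if profile not in PROFILES:
        raise ValueError(f"unknown profile {profile!r}; choose from {sorted(PROFILES)}")
    cfg = PROFILES[profile]
    rng = np.random.default_rng(seed)
    scheme = SizeClassScheme.from_max_dbh(max_dbh_cm)
    k = scheme.n_classes
    idx = np.arange(k)

    # high annual survival rising gently with size (canopy trees outlive
    # juveniles), with senescence of the largest classes so the open top
    # class does not accumulate mass against a lambda barely above stasis
    s = 0.973 + 0.012 * idx / (k - 1) + rng.uniform(-0.003, 0.003, k)
    s = np.clip(s, 0.90, 0.988)
    s[-2] -= 0.015
    s[-1] -= 0.035
    g = cfg["g0"] * np.exp(-idx / (k - 1)) * (1 + rng.uniform(-0.1, 0.1, k))
    g = np.minimum(g, s - 0.01)
    g[-1] = 0.0

    # merchantable share: flat across the first advance (class-1 advances keep
    # merchantable status), then declining toward p_top
    p = cfg["p_top"] + (0.95 - cfg["p_top"]) * np.exp(-np.maximum(idx - 1, 0) / (0.45 * k))
    x = np.zeros(k)
    x[: k - 1] = estimate_defect_transition(p)
    x[0] = 0.0

    f_shape = np.where(
        scheme.midpoints >= REPRODUCTIVE_DBH_CM, (scheme.midpoints / 100.0) ** 2, 0.0
    )

    def lam_at(scale: float) -> float:
        rates = VitalRates(S=s, G=g, F=scale * f_shape, x=x)
        return spectral_radius(build_transition_matrix(rates, scheme))

    target = cfg["lam_lo"] + rng.uniform(0.25, 0.75) * (cfg["lam_hi"] - cfg["lam_lo"])
    hi = 0.05
    while lam_at(hi) < target:
        hi *= 2
    f_scale = brentq(lambda c: lam_at(c) - target, 0.0, hi, xtol=1e-10)

    rates = VitalRates(S=s, G=g, F=f_scale * f_shape, x=x)
    return SpeciesParameters(
        name=name or profile,
        scheme=scheme,
        rates=rates,
        K=cfg["k_capacity"],
        merch_proportion=p,
        allometry=AllometryParams(),
        effects=cfg["effects"],
    )


def make_stand(
    species: list[SpeciesParameters],
    total_density: float = 400.0,
    proportions: dict[str, float] | None = None,
    decay: float = 0.82,
    seed: int | None = None,
    structure: str = "reverse_j",
) -> PopulationState:
    """Reverse-J stand: densities fall geometrically with size class and split
    into M/UM by each species' merchantable-proportion curve.

    Sums exactly to ``total_density`` trees/ha. ``proportions`` sets the
    species mix (default equal shares); a seed adds small deterministic
    jitter to the class weights, renormalized so the total is preserved.

    The projection model recruits every new tree as merchantable and creates
    defects only on class advances, so the within-class merchantable shares
    it can hold stationary are the cumulative defect-survival products —
    the species' observed profile rescaled to 1 in the first class. Stands
    are split that way, making the merchantable proportion an invariant of
    unharvested dynamics rather than a relaxation transient.

    ``structure='stable'`` instead places each species at the stable stage
    distribution of its own projection matrix (merchantability split
    included), emulating a stand near demographic equilibrium: without
    harvest, class structure and merchantable proportion then stay constant.
    """
    if total_density < 0:
        raise ValueError("total density must be non-negative")
    if proportions is None:
        proportions = {sp.name: 1.0 / len(species) for sp in species}
    if abs(sum(proportions.values()) - 1.0) > 1e-9:
        raise ValueError("species proportions must sum to 1")
    if structure not in ("reverse_j", "stable"):
        raise ValueError("structure must be 'reverse_j' or 'stable'")
    rng = np.random.default_rng(seed) if seed is not None else None
    densities = {}
    for sp in species:
        k = sp.scheme.n_classes
        if structure == "stable":
            w_full = dominant_eigenvalue(sp.base_matrix()).w
            densities[sp.name] = proportions[sp.name] * total_density * w_full
            continue
        w = decay ** np.arange(k)
        if rng is not None:
            w = w * (1 + rng.uniform(-0.05, 0.0, k))  # keeps weights non-increasing
        n = proportions[sp.name] * total_density * w / w.sum()
        p = sp.merch_proportion if sp.merch_proportion is not None else np.full(k, 0.7)
        p = p / p[0]  # model-consistent shares: recruits are merchantable
        densities[sp.name] = np.concatenate([n * p, n * (1 - p)])
    return PopulationState(densities, year=0)


def scale_to_merchantable_volume(
    stand: PopulationState,
    params: dict[str, SpeciesParameters],
    target_m3: float,
    mcd_cm: float = 50.0,
) -> PopulationState:
    """Rescale all densities so the merchantable volume at or above the MCD
    equals ``target_m3`` (m3/ha); the stand shape is preserved."""
    current = 0.0
    for sp in stand.species:
        scheme = params[sp].scheme
        elig = scheme.eligible_classes(mcd_cm)
        current += float(
            stand.merchantable(sp)[elig]
            @ params[sp].allometry.tree_volume(scheme.midpoints[elig])
        )
    if current <= 0:
        raise ValueError("stand holds no merchantable volume above the MCD")
    factor = target_m3 / current
    return PopulationState(
        {sp: n * factor for sp, n in stand.densities.items()}, year=stand.year
    )


def make_stem_map(
    pattern: str,
    density: float,
    extent_m: tuple[float, float] = (360.0, 360.0),
    seed: int = 0,
    species: tuple[str, ...] = ("fast", "slow", "pioneer"),
) -> pd.DataFrame:
    """Stem-mapped plot table (x_m, y_m, species, dbh_cm, merchantable).

    'uniform' scatters round(density x area) stems uniformly; 'clustered'
    uses a Thomas process (Poisson parents, Gaussian offspring, sd 15 m) so
    local windowed densities exceed the plot mean.
    """
    rng = np.random.default_rng(seed)
    ex, ey = extent_m
    area_ha = ex * ey / 1e4
    n = int(round(density * area_ha))
    if n == 0:
        return pd.DataFrame(columns=["x_m", "y_m", "species", "dbh_cm", "merchantable"])
    if pattern == "uniform":
        x = rng.uniform(0, ex, n)
        y = rng.uniform(0, ey, n)
    elif pattern == "clustered":
        n_parents = max(3, n // 60)
        px = rng.uniform(0, ex, n_parents)
        py = rng.uniform(0, ey, n_parents)
        assign = rng.integers(0, n_parents, n)
        x = np.clip(px[assign] + rng.normal(0, 15.0, n), 0, np.nextafter(ex, 0))
        y = np.clip(py[assign] + rng.normal(0, 15.0, n), 0, np.nextafter(ey, 0))
    else:
        raise ValueError("pattern must be 'uniform' or 'clustered'")
    return pd.DataFrame(
        {
            "x_m": x,
            "y_m": y,
            "species": rng.choice(species, n),
            "dbh_cm": 5.0 + rng.exponential(10.0, n),
            "merchantable": rng.random(n) < 0.7,
        }
    )


def demo_community(seed: int = 0, max_dbh_cm: float = 70.0) -> dict[str, SpeciesParameters]:
    """Three-species community (one per profile), seed-deterministic."""
    return {
        name: make_species(profile, seed=seed * 7919 + offset, max_dbh_cm=max_dbh_cm, name=name)
        for offset, (name, profile) in enumerate(
            [("fast", "fast"), ("slow", "slow"), ("pioneer", "pioneer")]
        )
    }


def demo_stand(
    params: dict[str, SpeciesParameters],
    total_density: float = 420.0,
    seed: int | None = None,
    structure: str = "stable",
) -> PopulationState:
    """Default mixed stand near demographic equilibrium, slow species dominant."""
    shares = {"fast": 0.35, "slow": 0.45, "pioneer": 0.20}
    proportions = {name: shares.get(name, 1.0 / len(params)) for name in params}
    total_share = sum(proportions.values())
    proportions = {k: v / total_share for k, v in proportions.items()}
    return make_stand(
        list(params.values()), total_density, proportions, seed=seed, structure=structure
    )


def default_damage_params(
    stand: PopulationState,
    params: dict[str, SpeciesParameters],
    mcd_cm: float = 50.0,
) -> DamageParams:
    """Tree-number residual-mortality ratio for a concrete stand.

    Converts the observed timber basal-area damage ratio into trees killed
    per tree harvested using the stand's density-weighted mean basal area of
    harvestable merchantable trees (>= MCD) and of all residual stems.
    """
    ba_cut, n_cut, ba_all, n_all = 0.0, 0.0, 0.0, 0.0
    for sp in stand.species:
        scheme = params[sp].scheme
        ba_mid = np.pi * (scheme.midpoints / 200.0) ** 2
        merch = stand.merchantable(sp)
        total = merch + stand.unmerchantable(sp)
        elig = scheme.eligible_classes(mcd_cm)
        ba_cut += float((merch[elig] * ba_mid[elig]).sum())
        n_cut += float(merch[elig].sum())
        ba_all += float((total * ba_mid).sum())
        n_all += float(total.sum())
    if n_cut == 0 or n_all == 0:
        raise ValueError("stand has no harvestable or no residual trees")
    ratio = tree_ratio_from_basal_area(TIMBER_BA_DAMAGE_RATIO, ba_cut / n_cut, ba_all / n_all)
    return DamageParams(residual_mortality_ratio=ratio)
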