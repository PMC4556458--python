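"""Readers/writers for species parameters, stands, regimes, configs, reports.

Tabular data is CSV (UTF-8, full float precision); configuration and regimes
are YAML or JSON. A species CSV carries one row per size class with columns
``species, class_index, dbh_lower_cm, S, G, F, x, merch_proportion,
K_trees_per_ha``; the JSON species format additionally round-trips allometry
and post-harvest effect blocks.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .demography import PopulationState, SizeClassScheme, TransitionMatrix, VitalRates
from .harvest import AllometryParams, ManagementRegime
from .postharvest import PostHarvestEffects
from .species import SpeciesParameters

__all__ = [
    "read_species_params",
    "write_species_params",
    "read_stand",
    "write_stand",
    "read_regime",
    "write_regime",
    "load_config",
    "write_report",
    "write_harvests",
    "write_trajectory",
    "write_matrix",
    "read_matrix",
    "REPORT_COLUMNS",
]

SPECIES_CSV_COLUMNS = [
    "species",
    "class_index",
    "dbh_lower_cm",
    "S",
    "G",
    "F",
    "x",
    "merch_proportion",
    "K_trees_per_ha",
]

REPORT_COLUMNS = [
    "optimized_for",
    "considering",
    "cutting_cycle",
    "harvest_intensity",
    "mcd_cm",
    "min_commercial_density",
    "seed_tree_quality",
    "volume_cap",
    "first_harvest_volume",
    "fifth_harvest_volume",
    "compensatory_recruitment",
    "mean_AY",
]

VALID_CONFIG_KEYS = {
    "grid",
    "horizon",
    "density_mode",
    "damage_ratio",
    "seed",
    "total_density",
}


def write_species_params(params: dict[str, SpeciesParameters], path) -> None:
    """Species parameters to CSV (vital rates, K) or JSON (full fidelity)."""
    path = Path(path)
    if path.suffix == ".json":
        payload = {"species": [_species_to_dict(sp) for sp in params.values()]}
        path.write_text(json.dumps(payload, indent=1))
        return
    rows = []
    for sp in params.values():
        k = sp.scheme.n_classes
        p = sp.merch_proportion if sp.merch_proportion is not None else np.full(k, np.nan)
        for i in range(k):
            rows.append(
                {
                    "species": sp.name,
                    "class_index": i + 1,
                    "dbh_lower_cm": sp.scheme.lower_bounds[i],
                    "S": sp.rates.S[i],
                    "G": sp.rates.G[i],
                    "F": sp.rates.F[i],
                    "x": sp.rates.x[i],
                    "merch_proportion": p[i],
                    "K_trees_per_ha": sp.K,
                }
            )
    pd.DataFrame(rows, columns=SPECIES_CSV_COLUMNS).to_csv(path, index=False)


def read_species_params(path) -> dict[str, SpeciesParameters]:
    """Parse and validate a species parameter file (CSV or JSON)."""
    path = Path(path)
    if path.suffix == ".json":
        payload = json.loads(path.read_text())
        out = {}
        for entry in payload["species"]:
            sp = _species_from_dict(entry)
            out[sp.name] = sp
        return out
    df = pd.read_csv(path)
    missing = {"species", "class_index", "dbh_lower_cm", "S", "G", "F", "K_trees_per_ha"} - set(
        df.columns
    )
    if missing:
        raise ValueError(f"species file lacks columns {sorted(missing)}")
    if "x" not in df.columns:
        warnings.warn("species file has no defect-transition column x; assuming 0")
        df["x"] = 0.0
    out = {}
    for name, grp in df.groupby("species", sort=False):
        grp = grp.sort_values("class_index")
        scheme = SizeClassScheme(tuple(grp["dbh_lower_cm"].to_numpy(dtype=float)))
        rates = VitalRates(
            S=grp["S"].to_numpy(dtype=float),
            G=grp["G"].to_numpy(dtype=float),
            F=grp["F"].to_numpy(dtype=float),
            x=grp["x"].to_numpy(dtype=float),
        )
        merch = None
        if "merch_proportion" in grp.columns and grp["merch_proportion"].notna().all():
            merch = grp["merch_proportion"].to_numpy(dtype=float)
        k_vals = grp["K_trees_per_ha"].unique()
        if len(k_vals) != 1:
            raise ValueError(f"{name}: carrying capacity differs between rows")
        out[str(name)] = SpeciesParameters(
            name=str(name), scheme=scheme, rates=rates, K=float(k_vals[0]), merch_proportion=merch
        )
    return out


def _species_to_dict(sp: SpeciesParameters) -> dict:
    return {
        "name": sp.name,
        "lower_bounds": list(sp.scheme.lower_bounds),
        "S": sp.rates.S.tolist(),
        "G": sp.rates.G.tolist(),
        "F": sp.rates.F.tolist(),
        "x": sp.rates.x.tolist(),
        "merch_proportion": None
        if sp.merch_proportion is None
        else sp.merch_proportion.tolist(),
        "K_trees_per_ha": sp.K,
        "allometry": {
            "form_factor": sp.allometry.form_factor,
            "h_max_m": sp.allometry.h_max_m,
            "h_half_cm": sp.allometry.h_half_cm,
        },
        "effects": {
            "duration": sp.effects.duration,
            "juvenile_growth_multiplier": sp.effects.juvenile_growth_multiplier,
            "adult_growth_multiplier": sp.effects.adult_growth_multiplier,
            "recruitment_multiplier": sp.effects.recruitment_multiplier,
        },
    }


def _species_from_dict(d: dict) -> SpeciesParameters:
    return SpeciesParameters(
        name=d["name"],
        scheme=SizeClassScheme(tuple(d["lower_bounds"])),
        rates=VitalRates(
            S=np.asarray(d["S"]), G=np.asarray(d["G"]), F=np.asarray(d["F"]), x=np.asarray(d["x"])
        ),
        K=float(d["K_trees_per_ha"]),
        merch_proportion=None
        if d.get("merch_proportion") is None
        else np.asarray(d["merch_proportion"]),
        allometry=AllometryParams(**d.get("allometry", {})),
        effects=PostHarvestEffects(**d.get("effects", {})),
    )


def write_stand(stand: PopulationState, path) -> None:
    """Stand to tidy CSV: species, class_index, m_density, um_density."""
    rows = []
    for sp in stand.species:
        m = stand.merchantable(sp)
        um = stand.unmerchantable(sp)
        for i in range(m.size):
            rows.append(
                {"species": sp, "class_index": i + 1, "m_density": m[i], "um_density": um[i]}
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_stand(path) -> PopulationState:
    df = pd.read_csv(path)
    needed = {"species", "class_index", "m_density", "um_density"}
    if not needed.issubset(df.columns):
        raise ValueError(f"stand file needs columns {sorted(needed)}")
    densities = {}
    for name, grp in df.groupby("species", sort=False):
        grp = grp.sort_values("class_index")
        densities[str(name)] = np.concatenate(
            [grp["m_density"].to_numpy(dtype=float), grp["um_density"].to_numpy(dtype=float)]
        )
    return PopulationState(densities, year=0)


_REGIME_KEYS = {
    "cutting_cycle",
    "harvest_intensity",
    "mcd_cm",
    "min_commercial_density",
    "seed_tree_quality",
    "volume_cap",
    "harvested_species",
}


def write_regime(regime: ManagementRegime, path) -> None:
    d = {
        "cutting_cycle": regime.cutting_cycle,
        "harvest_intensity": regime.harvest_intensity,
        "mcd_cm": regime.mcd_cm,
        "min_commercial_density": regime.min_commercial_density,
        "seed_tree_quality": regime.seed_tree_quality,
        "volume_cap": regime.volume_cap,
        "harvested_species": None
        if regime.harvested_species is None
        else sorted(regime.harvested_species),
    }
    _dump_config(d, Path(path))


def read_regime(path) -> ManagementRegime:
    d = _load_mapping(Path(path))
    unknown = set(d) - _REGIME_KEYS
    if unknown:
        raise ValueError(f"unknown regime keys {sorted(unknown)}; valid: {sorted(_REGIME_KEYS)}")
    if d.get("harvested_species") is not None:
        d["harvested_species"] = frozenset(d["harvested_species"])
    return ManagementRegime(**d)


def load_config(path) -> dict:
    """Run configuration: regime grid plus run options, validated keys.

    Without a ``grid`` entry, the config falls back to the legal-regime grid
    (10 or 30 yr cycle, 0.9 intensity, 50 cm MCD, MD 0.03 trees/ha, low
    seed-tree quality, 1 m3/ha/yr volume limit).
    """
    d = _load_mapping(Path(path))
    unknown = set(d) - VALID_CONFIG_KEYS
    if unknown:
        raise ValueError(
            f"unknown config keys {sorted(unknown)}; valid keys: {sorted(VALID_CONFIG_KEYS)}"
        )
    d.setdefault("grid", legal_grid())
    d.setdefault("horizon", 120)
    d.setdefault("density_mode", "per_species")
    grid = d["grid"]
    if not isinstance(grid, dict):
        raise ValueError("config 'grid' must map criteria to value lists")
    return d


def legal_grid() -> dict[str, list]:
    """Grid containing exactly the two Brazilian legal management regimes."""
    return {
        "cutting_cycle": [10, 30],
        "harvest_intensity": [0.9],
        "mcd_cm": [50.0],
        "min_commercial_density": [0.03],
        "seed_tree_quality": ["low"],
        "volume_cap": [1.0],
    }


def full_grid() -> dict[str, list]:
    """The full factorial criteria grid (1200 regimes)."""
    return {
        "cutting_cycle": [10, 20, 30, 40],
        "harvest_intensity": [0.5, 0.6, 0.7, 0.8, 0.9],
        "mcd_cm": [30.0, 40.0, 50.0, 60.0, 70.0],
        "min_commercial_density": [0.0, 0.03, 1.0],
        "seed_tree_quality": ["high", "low"],
        "volume_cap": [None, 1.0],
    }


def _load_mapping(path: Path) -> dict:
    text = path.read_text()
    try:
        if path.suffix == ".json":
            d = json.loads(text)
        else:
            d = yaml.safe_load(text)
    except (json.JSONDecodeError, yaml.YAMLError) as exc:
        raise ValueError(f"malformed config file {path}: {exc}") from exc
    if not isinstance(d, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    return d


def _dump_config(d: dict, path: Path) -> None:
    if path.suffix == ".json":
        path.write_text(json.dumps(d, indent=1))
    else:
        path.write_text(yaml.safe_dump(d, sort_keys=False))


def write_report(rows: pd.DataFrame | list[dict], path) -> None:
    """Regime-table report CSV with a fixed, documented column order."""
    df = pd.DataFrame(rows)
    for col in REPORT_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan if len(df) else None
    df = df[REPORT_COLUMNS] if len(df) else pd.DataFrame(columns=REPORT_COLUMNS)
    df.to_csv(path, index=False)


def write_harvests(harvests, path) -> None:
    """Harvest records as tidy CSV: year, species, trees, volume_m3, killed."""
    rows = []
    for rec in harvests:
        for sp, removal in rec.removals.items():
            rows.append(
                {
                    "year": rec.year,
                    "species": sp,
                    "trees": float(np.sum(removal)),
                    "volume_m3": rec.volume_m3.get(sp, 0.0),
                    "killed_total": rec.trees_killed,
                    "cap_binding": rec.cap_binding,
                }
            )
    pd.DataFrame(
        rows, columns=["year", "species", "trees", "volume_m3", "killed_total", "cap_binding"]
    ).to_csv(path, index=False)


def write_trajectory(result, path) -> None:
    """Yearly trajectory as tidy CSV: year, species, block, class_index, density."""
    frames = []
    for sp, traj in result.trajectory.items():
        k = traj.shape[1] // 2
        years = np.repeat(np.arange(traj.shape[0]), 2 * k)
        blocks = np.tile(np.array(["M"] * k + ["UM"] * k), traj.shape[0])
        classes = np.tile(np.concatenate([np.arange(1, k + 1)] * 2), traj.shape[0])
        frames.append(
            pd.DataFrame(
                {
                    "year": years,
                    "species": sp,
                    "block": blocks,
                    "class_index": classes,
                    "density": traj.ravel(),
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_matrix(tm: TransitionMatrix | np.ndarray, path) -> None:
    A = tm.matrix if isinstance(tm, TransitionMatrix) else np.asarray(tm)
    np.savetxt(path, A, delimiter=",")


def read_matrix(path) -> np.ndarray:
    return np.loadtxt(path, delimiter=",", ndmin=2)
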