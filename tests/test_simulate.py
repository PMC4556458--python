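"""Full regime simulations: reduction cases, a hand-stepped oracle,
merchantable-proportion dynamics and compensatory recruitment."""

import numpy as np
import pytest

from tidalstm.demography import (
    PopulationState,
    SizeClassScheme,
    VitalRates,
)
from tidalstm.density import DensityParams, recruitment_multiplier
from tidalstm.harvest import AllometryParams, DamageParams, ManagementRegime
from tidalstm.postharvest import PostHarvestEffects
from tidalstm.simulate import (
    compensatory_recruitment,
    harvest_years,
    merchantable_proportion,
    simulate_regime,
)
from tidalstm.species import SpeciesParameters

SCHEME = SizeClassScheme.from_max_dbh(15.0)  # 4 classes: 5, 10, 12.5, 15+


def toy_species(f_top=0.4, k_capacity=500.0, effects=None) -> SpeciesParameters:
    return SpeciesParameters(
        name="toy",
        scheme=SCHEME,
        rates=VitalRates(
            S=np.array([0.95, 0.96, 0.96, 0.97]),
            G=np.array([0.12, 0.10, 0.08, 0.0]),
            F=np.array([0.0, 0.0, 0.0, f_top]),
            x=np.array([0.0, 0.1, 0.1, 0.0]),
        ),
        K=k_capacity,
        allometry=AllometryParams(form_factor=0.7, h_max_m=10.0, h_half_cm=0.0),
        effects=effects or PostHarvestEffects(),
    )


def toy_stand(total=100.0) -> PopulationState:
    m = np.array([0.5, 0.25, 0.15, 0.10]) * total * 0.8
    um = np.array([0.5, 0.25, 0.15, 0.10]) * total * 0.2
    return PopulationState({"toy": np.concatenate([m, um])})


class TestHarvestSchedule:
    def test_first_harvest_at_year_zero_then_cycle_multiples(self):
        assert harvest_years(30, 120) == [0, 30, 60, 90]
        assert harvest_years(10, 120) == list(range(0, 120, 10))


class TestReductionCases:
    def test_zero_intensity_equals_pure_projection(self):
        sp = toy_species()
        stand = toy_stand()
        reg0 = ManagementRegime(30, 0.0, 10.0)
        no_harvest = ManagementRegime(30, 0.9, 10.0, harvested_species=frozenset())
        r0 = simulate_regime(stand, {"toy": sp}, reg0, horizon=60)
        r1 = simulate_regime(stand, {"toy": sp}, no_harvest, horizon=60)
        assert np.allclose(r0.trajectory["toy"], r1.trajectory["toy"])
        assert r0.harvest_volumes().sum() == 0.0

    def test_unit_post_harvest_multipliers_change_nothing(self):
        reg = ManagementRegime(20, 0.5, 10.0)
        stand = toy_stand()
        plain = simulate_regime(stand, {"toy": toy_species()}, reg, horizon=60)
        boosted = simulate_regime(
            stand,
            {"toy": toy_species(effects=PostHarvestEffects(duration=10))},
            reg,
            horizon=60,
        )
        assert np.allclose(plain.trajectory["toy"], boosted.trajectory["toy"])


class TestHandSteppedOracle:
    def test_25_year_two_harvest_trajectory_matches_explicit_stepping(self):
        """Independent re-implementation of the yearly loop: harvest at the
        start of years 0 and 20, residual mortality, post-harvest matrix for
        10 years after each harvest, Weibull-regulated fertility, projection."""
        effects = PostHarvestEffects(duration=10, juvenile_growth_multiplier=1.25)
        sp = toy_species(effects=effects)
        stand = toy_stand()
        reg = ManagementRegime(
            cutting_cycle=20,
            harvest_intensity=0.6,
            mcd_cm=12.5,
            seed_tree_quality="low",
            volume_cap=None,
        )
        damage = DamageParams(0.8)
        result = simulate_regime(stand, {"toy": sp}, reg, horizon=25, damage=damage)

        base = sp.base_matrix()
        post = sp.post_harvest_matrix()
        dens = DensityParams(K=sp.K)
        vol_per_tree = sp.allometry.tree_volume(SCHEME.midpoints)

        n = stand.densities["toy"].copy()
        expected = [n.copy()]
        elig = SCHEME.eligible_classes(12.5)  # classes 3 and 4
        for t in range(25):
            if t in (0, 20):
                merch_elig = n[elig]
                basis = merch_elig.sum() + n[4 + elig].sum()
                take = min(0.6 * basis, merch_elig.sum())
                removal = take * merch_elig / merch_elig.sum()
                vol = removal @ vol_per_tree[elig]
                assert vol >= 0
                n[elig] -= removal
                kills = 0.8 * take
                n *= 1 - kills / n.sum()
            tm = post if (t < 10 or t >= 20) else base
            mult = recruitment_multiplier(n.sum(), dens)
            new = tm.survival @ n
            new[0] += mult * (tm.fertility @ n)
            n = new
            expected.append(n.copy())
        assert np.allclose(result.trajectory["toy"], np.array(expected), atol=1e-9)

    def test_reversing_order_of_operations_changes_results(self):
        # regression pin: harvest happens before projection within a year,
        # so the year-1 state of a year-0 harvest differs from a projection
        # of the unharvested stand
        sp = toy_species()
        stand = toy_stand()
        reg = ManagementRegime(30, 0.6, 12.5)
        res = simulate_regime(stand, {"toy": sp}, reg, horizon=2)
        unharvested = sp.base_matrix().matrix @ stand.densities["toy"]
        assert not np.allclose(res.trajectory["toy"][1], unharvested)


class TestMerchantableProportion:
    def test_all_merchantable_gives_one_and_even_split_half(self):
        traj = np.array([[2.0, 1.0, 0.0, 0.0], [1.0, 1.0, 1.0, 1.0]])
        out = merchantable_proportion(traj)
        assert out[0] == 1.0
        assert out[1] == 0.5

    def test_empty_stand_reported_as_missing(self):
        out = merchantable_proportion(np.zeros((2, 4)))
        assert np.all(np.isnan(out))

    def test_harvest_lowers_proportion_immediately(self):
        sp = toy_species()
        stand = toy_stand()
        reg = ManagementRegime(30, 0.9, 12.5, seed_tree_quality="low")
        res = simulate_regime(stand, {"toy": sp}, reg, horizon=40)
        mp = res.merchantable_proportion("toy")
        # year-1 state reflects the year-0 harvest of merchantable trees only
        assert mp[1] < mp[0]


class TestCompensatoryRecruitment:
    def test_zero_when_population_holds_its_ground(self):
        sp = toy_species(f_top=2.0)  # strongly growing
        out = compensatory_recruitment(
            toy_stand(), {"toy": sp}, ManagementRegime(30, 0.1, 15.0), horizon=60
        )
        assert out["toy"] == 0.0

    def test_bisection_matches_grid_search_oracle(self):
        sp = toy_species(f_top=0.25)  # declining under harvest
        stand = toy_stand()
        reg = ManagementRegime(20, 0.9, 12.5, seed_tree_quality="low")
        out = compensatory_recruitment(stand, {"toy": sp}, reg, horizon=60, tolerance=1e-3)
        assert out["toy"] > 0

        def deficit(r):
            res = simulate_regime(stand, {"toy": sp}, reg, horizon=60, extra_recruits={"toy": r})
            totals = res.totals("toy")
            return totals[60] - totals[0]

        grid = np.arange(0.0, 20.0, 0.01)
        feasible = next(r for r in grid if deficit(r) >= 0)
        assert abs(out["toy"] - feasible) <= 0.01 + 1e-3

    def test_monotone_in_harvest_intensity(self):
        sp = toy_species(f_top=0.25)
        stand = toy_stand()
        needs = []
        for intensity in (0.5, 0.7, 0.9):
            reg = ManagementRegime(20, intensity, 12.5, seed_tree_quality="low")
            needs.append(
                compensatory_recruitment(stand, {"toy": sp}, reg, horizon=60)["toy"]
            )
        assert needs[0] <= needs[1] <= needs[2]


class TestLambdaH:
    def test_lambda_h_uses_start_and_horizon_totals(self):
        sp = toy_species()
        res = simulate_regime(toy_stand(), {"toy": sp}, ManagementRegime(30, 0.0, 10.0), horizon=120)
        totals = res.totals("toy")
        assert res.lambda_h("toy") == pytest.approx((totals[120] / totals[0]) ** (1 / 120))
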