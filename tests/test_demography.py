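"""Construction and analysis of the paired M/UM projection matrices."""

import numpy as np
import pytest

from tidalstm.demography import (
    PopulationState,
    SizeClassScheme,
    VitalRates,
    build_transition_matrix,
    dominant_eigenvalue,
    empirical_lambda,
    estimate_defect_transition,
    project_one_year,
    spectral_radius,
)

from conftest import random_primitive_matrix


class TestSizeClassScheme:
    def test_first_class_is_5_to_10_then_2p5_steps(self):
        s = SizeClassScheme.from_max_dbh(20.0)
        assert s.lower_bounds == (5.0, 10.0, 12.5, 15.0, 17.5, 20.0)
        assert s.midpoints[0] == 7.5
        assert s.midpoints[-1] == 21.25  # open class given one standard width

    @pytest.mark.parametrize(
        "bounds",
        [(5.0,), (6.0, 10.0, 12.5), (5.0, 12.5), (5.0, 10.0, 13.0)],
    )
    def test_invalid_schemes_rejected(self, bounds):
        with pytest.raises(ValueError):
            SizeClassScheme(bounds)

    def test_eligible_classes_by_lower_bound(self):
        s = SizeClassScheme.from_max_dbh(55.0)
        elig = s.eligible_classes(50.0)
        assert all(s.lower_bounds[i] >= 50.0 for i in elig)
        assert len(elig) == 3  # 50, 52.5, 55


class TestBuildTransitionMatrix:
    def test_no_growth_no_death_gives_identity(self):
        scheme = SizeClassScheme((5.0, 10.0))
        rates = VitalRates(S=[1, 1], G=[0, 0], F=[0, 0], x=[0, 0])
        A = build_transition_matrix(rates, scheme).matrix
        assert np.allclose(A, np.eye(4))

    def test_defect_split_of_upgrowth(self):
        # an advance out of class 2 with G=0.2 splits 0.15 merchantable /
        # 0.05 newly unmerchantable when x2 = 0.25
        scheme = SizeClassScheme((5.0, 10.0, 12.5))
        rates = VitalRates(S=[0.9, 0.9, 0.9], G=[0.1, 0.2, 0.0], F=[0, 0, 0], x=[0, 0.25, 0])
        A = build_transition_matrix(rates, scheme).matrix
        k = 3
        assert A[2, 1] == pytest.approx(0.2 * 0.75)  # M3 <- M2
        assert A[k + 2, 1] == pytest.approx(0.2 * 0.25)  # UM3 <- M2
        assert A[k + 2, k + 1] == pytest.approx(0.2)  # UM3 <- UM2

    def test_full_three_class_layout_matches_hand_construction(self, toy_rates, toy_scheme):
        A = build_transition_matrix(toy_rates, toy_scheme).matrix
        expected = np.array(
            [
                # M1     M2        M3    UM1    UM2    UM3
                [0.85, 0.000, 0.50, 0.00, 0.000, 0.50],
                [0.10, 0.880, 0.00, 0.00, 0.000, 0.00],
                [0.00, 0.072, 0.97, 0.00, 0.000, 0.00],
                [0.00, 0.000, 0.00, 0.85, 0.000, 0.00],
                [0.00, 0.000, 0.00, 0.10, 0.880, 0.00],
                [0.00, 0.008, 0.00, 0.00, 0.080, 0.97],
            ]
        )
        assert np.allclose(A, expected)

    def test_um_to_m_block_structurally_zero(self, community):
        # defect development is irreversible: no path back to merchantable
        for sp in community.values():
            A = sp.base_matrix().matrix
            k = sp.scheme.n_classes
            block = A[1:k, k:]  # UM -> M, fertility row excluded
            assert np.all(block == 0)

    def test_column_outflow_never_exceeds_survival(self, community):
        for sp in community.values():
            tm = sp.base_matrix()
            k = sp.scheme.n_classes
            outflow = tm.survival.sum(axis=0)
            S2 = np.concatenate([sp.rates.S, sp.rates.S])
            assert np.all(outflow <= S2 + 1e-12)

    @pytest.mark.parametrize(
        "bad",
        [
            dict(S=[1.2, 1.0], G=[0, 0], F=[0, 0], x=[0, 0]),  # S > 1
            dict(S=[0.9, 0.9], G=[0.95, 0], F=[0, 0], x=[0, 0]),  # G > S
            dict(S=[0.9, 0.9], G=[0.1, 0.1], F=[0, 0], x=[0, 0]),  # top class grows
            dict(S=[0.9, 0.9, 0.9], G=[0.1, 0, 0], F=[0, 0, 0], x=[0, 0, 0]),  # wrong k
        ],
    )
    def test_invalid_rates_rejected(self, bad):
        scheme = SizeClassScheme((5.0, 10.0))
        with pytest.raises(ValueError):
            build_transition_matrix(VitalRates(**{k: np.array(v, float) for k, v in bad.items()}), scheme)


class TestProjection:
    def test_identity_matrix_preserves_state(self, toy_scheme):
        rates = VitalRates(S=[1, 1, 1], G=[0, 0, 0], F=[0, 0, 0], x=[0, 0, 0])
        tm = build_transition_matrix(rates, toy_scheme)
        n = np.array([3.0, 2.0, 1.0, 0.5, 0.25, 0.1])
        assert np.allclose(project_one_year(n, tm), n)

    def test_extra_recruits_enter_first_merchantable_class(self, toy_scheme):
        rates = VitalRates(S=[0, 0, 0], G=[0, 0, 0], F=[0, 0, 0], x=[0, 0, 0])
        tm = build_transition_matrix(rates, toy_scheme)
        out = project_one_year(np.ones(6), tm, extra_recruits=4.5)
        assert out[0] == 4.5
        assert np.all(out[1:] == 0)

    def test_matches_elementwise_matrix_vector_product(self, toy_matrix):
        rng = np.random.default_rng(42)
        n = rng.uniform(0, 10, 6)
        A = toy_matrix.matrix
        by_hand = np.array([sum(A[i, j] * n[j] for j in range(6)) for i in range(6)])
        assert np.allclose(project_one_year(n, toy_matrix), by_hand, atol=1e-12)

    def test_conservation_with_full_survival_and_no_reproduction(self, toy_scheme):
        rates = VitalRates(S=[1, 1, 1], G=[0.3, 0.2, 0.0], F=[0, 0, 0], x=[0, 0.5, 0])
        tm = build_transition_matrix(rates, toy_scheme)
        n = np.array([5.0, 4.0, 3.0, 2.0, 1.0, 0.5])
        for _ in range(50):
            n = project_one_year(n, tm)
        assert n.sum() == pytest.approx(15.5, rel=1e-12)

    def test_dimension_mismatch_raises(self, toy_matrix):
        with pytest.raises(ValueError):
            project_one_year(np.ones(4), toy_matrix)


class TestEigen:
    def test_two_by_two_with_known_unit_eigenvalue(self):
        eig = dominant_eigenvalue(np.array([[0.0, 2.0], [0.5, 0.0]]))
        assert eig.lam == pytest.approx(1.0)
        assert eig.w.sum() == pytest.approx(1.0)
        assert eig.v @ eig.w == pytest.approx(1.0)

    def test_matches_power_iteration_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            A = random_primitive_matrix(rng)
            n = np.ones(5)
            lam = 0.0
            for _ in range(2000):
                n = A @ n
                lam = n.sum()
                n = n / lam
            eig = dominant_eigenvalue(A)
            assert eig.lam == pytest.approx(lam, abs=1e-10)
            assert np.allclose(eig.w, n / n.sum(), atol=1e-8)

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError):
            dominant_eigenvalue(np.array([[1.0, -0.1], [0.2, 0.5]]))

    def test_spectral_radius_on_triangular_matrix(self):
        A = np.diag([0.3, 0.9, 0.7])
        A[1, 0] = 0.5
        assert spectral_radius(A) == pytest.approx(0.9)


class TestEmpiricalLambda:
    def test_constant_population_gives_one(self):
        assert empirical_lambda(100.0, 100.0, 120) == 1.0

    def test_doubling_over_120_years(self):
        assert empirical_lambda(100.0, 200.0, 120) == pytest.approx(2 ** (1 / 120))

    def test_zero_initial_population_rejected(self):
        with pytest.raises(ValueError):
            empirical_lambda(0.0, 10.0, 120)

    def test_converges_to_dominant_eigenvalue_with_horizon(self):
        # transient structure decays, so the realized rate approaches the
        # asymptotic one; error shrinks roughly as 1/horizon
        rng = np.random.default_rng(11)
        for _ in range(5):
            A = random_primitive_matrix(rng, lam_scale=1.0)
            lam = dominant_eigenvalue(A).lam
            n0 = rng.uniform(0.1, 5.0, 5)
            errs = []
            for horizon in (120, 1200):
                n = n0.copy()
                for _ in range(horizon):
                    n = A @ n
                errs.append(abs(empirical_lambda(n0.sum(), n.sum(), horizon) - lam))
            assert errs[1] < errs[0]
            assert errs[1] < 1e-3


class TestDefectTransition:
    def test_constant_proportions_mean_no_defect_development(self):
        assert np.allclose(estimate_defect_transition([0.8, 0.8, 0.8]), [0.0, 0.0])

    def test_declining_proportions_recover_per_advance_rates(self):
        assert np.allclose(estimate_defect_transition([1.0, 0.75, 0.6]), [0.25, 0.2])

    def test_increasing_proportions_clip_to_zero_with_warning(self):
        with pytest.warns(UserWarning):
            x = estimate_defect_transition([0.5, 0.6])
        assert x[0] == 0.0

    def test_rise_from_zero_is_inconsistent(self):
        with pytest.raises(ValueError):
            estimate_defect_transition([0.0, 0.3])

    def test_roundtrip_with_matrix_entries(self, toy_scheme):
        # proportions -> x -> matrix reproduces the advance split implied
        p = np.array([0.9, 0.9, 0.54])
        x = np.zeros(3)
        x[:2] = estimate_defect_transition(p)
        rates = VitalRates(S=[0.95, 0.95, 0.95], G=[0.1, 0.1, 0.0], F=[0, 0, 0], x=x)
        A = build_transition_matrix(rates, toy_scheme).matrix
        assert A[2, 1] == pytest.approx(0.1 * (0.54 / 0.9))


class TestPopulationState:
    def test_totals_and_blocks(self):
        st = PopulationState({"a": np.array([1.0, 2.0, 3.0, 4.0])})
        assert st.total() == 10.0
        assert np.all(st.merchantable("a") == [1.0, 2.0])
        assert np.all(st.unmerchantable("a") == [3.0, 4.0])

    def test_negative_density_rejected(self):
        with pytest.raises(ValueError):
            PopulationState({"a": np.array([1.0, -0.5])})
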