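"""Tests for the Y-N curve model: fits, projections, comparison model."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ynstand import allometry, regression, yn_growth
from ynstand.yn_growth import GrowthModelParams


class TestCumulativeCurve:
    def test_sort_and_cumulate(self):
        pairs = yn_growth.cumulative_curve([3.0, 1.0, 2.0])
        assert pairs.tolist() == [[1, 3], [2, 5], [3, 6]]

    def test_singleton(self):
        assert yn_growth.cumulative_curve([5.0]).tolist() == [[1, 5]]

    def test_total_conservation(self):
        rng = np.random.default_rng(0)
        m = rng.lognormal(0, 1, 100)
        pairs = yn_growth.cumulative_curve(m)
        assert pairs[-1, 1] == pytest.approx(m.sum(), rel=1e-12)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            yn_growth.cumulative_curve([])


class TestYNValue:
    def test_substitutions(self):
        assert yn_growth.yn_value(0.01, 0.1, 10) == pytest.approx(50.0)
        assert yn_growth.yn_value(0.01, 0.1, 1) == pytest.approx(100 / 11)

    def test_large_n_limit_is_ymax(self):
        assert yn_growth.yn_value(0.01, 0.1, 1e9) == pytest.approx(100.0, rel=1e-6)

    def test_derivative_identity_with_individual_biomass(self):
        # M(N) = dY/dN, spot-checked numerically at 100 points
        a, b = 0.003, 0.2
        n = np.linspace(0.5, 300, 100)
        eps = 1e-6
        numeric = (yn_growth.yn_value(a, b, n + eps) - yn_growth.yn_value(a, b, n - eps)) / (
            2 * eps
        )
        analytic = yn_growth.individual_biomass(a, b, n)
        assert np.allclose(numeric, analytic, rtol=1e-6)

    def test_finite_difference_midpoint(self):
        a, b = 0.01, 0.1
        diff = yn_growth.yn_value(a, b, 10) - yn_growth.yn_value(a, b, 9)
        mid = yn_growth.individual_biomass(a, b, 9.5)
        assert diff == pytest.approx(mid, rel=1e-3)


class TestFitYN:
    def test_exact_recovery(self):
        n = np.arange(1, 51, dtype=float)
        y = yn_growth.yn_value(0.01, 0.1, n)
        fit = yn_growth.fit_yn(np.column_stack([n, y]))
        assert fit.converged
        assert fit.A == pytest.approx(0.01, rel=1e-8)
        assert fit.B == pytest.approx(0.1, rel=1e-8)
        assert fit.r2 == pytest.approx(1.0, abs=1e-10)

    def test_noisy_recovery_within_10pct(self):
        rng = np.random.default_rng(4)
        n = np.arange(1, 51, dtype=float)
        y = yn_growth.yn_value(0.01, 0.1, n) * np.exp(rng.normal(0, 0.02, 50))
        fit = yn_growth.fit_yn(np.column_stack([n, y]))
        assert abs(fit.A - 0.01) / 0.01 < 0.1

    def test_underdetermined(self):
        with pytest.raises(ValueError):
            yn_growth.fit_yn([[1, 3], [2, 5]])


class TestRankInversion:
    def test_round_trip(self):
        assert yn_growth.rank_from_biomass(2.5, 0.01, 0.1) == pytest.approx(10.0)
        m = yn_growth.individual_biomass(0.01, 0.1, 37.2)
        assert yn_growth.rank_from_biomass(m, 0.01, 0.1) == pytest.approx(37.2, rel=1e-12)

    def test_limits(self):
        # M -> 1/B from below: rank -> 0
        assert yn_growth.rank_from_biomass(1 / 0.1 - 1e-9, 0.01, 0.1) < 1e-2

    def test_above_mmax_errors(self):
        with pytest.raises(ValueError):
            yn_growth.rank_from_biomass(1 / 0.1 + 1e-9, 0.01, 0.1)

    def test_individual_biomass_small_rank_limit(self):
        assert yn_growth.individual_biomass(0.01, 0.1, 1e-9) == pytest.approx(10.0, rel=1e-6)


class TestProjection:
    def test_identity_projection(self):
        for m0 in [0.01, 1.0, 9.9]:
            assert yn_growth.project_biomass(m0, 0.01, 0.1, 0.01, 0.1) == pytest.approx(
                m0, rel=1e-12
            )

    def test_rank_inversion_oracle_example(self):
        # rank of M0=2.5 under (0.01, 0.1) is 10; rank 10 under (0.005, 0.05) weighs 5
        assert yn_growth.project_biomass(2.5, 0.01, 0.1, 0.005, 0.05) == pytest.approx(5.0)

    def test_largest_maps_to_largest(self):
        assert yn_growth.project_biomass(1 / 0.1, 0.01, 0.1, 0.005, 0.05) == pytest.approx(
            1 / 0.05, rel=1e-12
        )

    def test_scaled_form_equals_explicit_b(self):
        p = GrowthModelParams(A0=0.01, AT=0.005, K3=10, c=1, K4=0.2, delta_t=5)
        assert yn_growth.project_biomass_scaled(2.5, p) == pytest.approx(5.0, rel=1e-12)

    @given(
        st.floats(min_value=-4, max_value=-1),  # log10 A0
        st.floats(min_value=0.5, max_value=0.99),  # AT/A0
        st.floats(min_value=0.5, max_value=2.0),  # c
        st.floats(min_value=0.5, max_value=50.0),  # K3
        st.floats(min_value=0.001, max_value=0.999),  # M0 as fraction of 1/B0
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_scaled_and_explicit_forms_agree(self, log_a0, ratio, c, k3, frac):
        a0 = 10.0**log_a0
        at = a0 * ratio
        b0, bt = k3 * a0**c, k3 * at**c
        m0 = frac / b0
        explicit = yn_growth.project_biomass(m0, a0, b0, at, bt)
        p = GrowthModelParams(A0=a0, AT=at, K3=k3, c=c, K4=0.06, delta_t=1.0)
        assert yn_growth.project_biomass_scaled(m0, p) == pytest.approx(explicit, rel=1e-12)


class TestProjectDiameter:
    PARAMS = GrowthModelParams(A0=0.01, AT=0.005, K3=10, c=1, K4=0.2, delta_t=5)

    def test_identity_params_no_growth(self):
        p = GrowthModelParams(A0=0.01, AT=0.01, K3=10, c=1, K4=0.2, delta_t=5)
        d0 = np.array([0.5, 1.0, 2.0])
        dt, _ = yn_growth.project_diameter(d0, p)
        assert np.allclose(dt, d0, rtol=1e-12)
        assert np.allclose(yn_growth.growth_rate_curve(d0, p), 0.0, atol=1e-14)

    def test_composed_oracle_example(self):
        d0 = allometry.biomass_to_diameter(2.5, 0.2)
        dt, dt23 = yn_growth.project_diameter(d0, self.PARAMS)
        assert dt == pytest.approx((5.0 / 0.2) ** (3 / 8), rel=1e-9)  # ≈3.344
        assert dt23 == pytest.approx((5.0 / 0.2) ** 0.25, rel=1e-9)  # ≈2.236
        assert yn_growth.growth_rate_curve(d0, self.PARAMS) == pytest.approx(
            (dt - d0) / 5, rel=1e-12
        )

    def test_monotone_and_order_preserving(self):
        d0 = np.linspace(0.05, 0.98 * self.PARAMS.max_initial_diameter(), 500)
        dt, dt23 = yn_growth.project_diameter(d0, self.PARAMS)
        assert np.all(np.diff(dt23) > 0)
        assert np.all(np.diff(dt) > 0)

    def test_rate_curve_single_peaked(self):
        p = GrowthModelParams(A0=0.02, AT=0.008, K3=20, c=1.2, K4=0.06, delta_t=5)
        d0 = np.linspace(0.02, 0.99, 400) * p.max_initial_diameter()
        rate = yn_growth.growth_rate_curve(d0, p)
        sign_changes = np.sum(np.diff(np.sign(np.diff(rate))) != 0)
        assert sign_changes <= 1  # rises then falls (convex single-peaked curve)

    def test_domain_violation_errors(self):
        with pytest.raises(ValueError):
            yn_growth.project_diameter(self.PARAMS.max_initial_diameter() * 1.01, self.PARAMS)


class TestABScaling:
    def test_two_point_exact_solve(self):
        fit = yn_growth.fit_ab_scaling([(0.01, 0.1), (0.005, 0.05)])
        assert fit.c == pytest.approx(1.0, rel=1e-12)
        assert fit.K3 == pytest.approx(10.0, rel=1e-12)

    def test_zero_residual_recovery(self):
        a = 0.01 * 0.8 ** np.arange(6)
        b = 10 * a**1.2
        fit = yn_growth.fit_ab_scaling(list(zip(a, b)))
        assert fit.c == pytest.approx(1.2, rel=1e-12)
        assert fit.K3 == pytest.approx(10.0, rel=1e-10)

    def test_noisy_c_within_ci(self):
        rng = np.random.default_rng(12)
        a = 0.01 * 0.8 ** np.arange(10)
        b = 10 * a**1.2 * np.exp(rng.normal(0, 0.05, 10))
        fit = yn_growth.fit_ab_scaling(list(zip(a, b)))
        lo, hi = fit.fit.slope_ci95
        assert lo < 1.2 < hi

    def test_single_point_errors(self):
        with pytest.raises(ValueError):
            yn_growth.fit_ab_scaling([(0.01, 0.1)])


class TestEnquist:
    def test_projection_substitution(self):
        assert yn_growth.enquist_project(1.0, 0.5) == pytest.approx(1.5**1.5)
        assert yn_growth.enquist_project(7.3, 0.0) == pytest.approx(7.3)

    def test_matches_ode_integration(self):
        from scipy.integrate import solve_ivp

        beta, T = 0.4, 10.0
        for d0 in [1.0, 5.0, 20.0]:
            sol = solve_ivp(
                lambda t, y: beta * y ** (1 / 3), [0, T], [d0], rtol=1e-10, atol=1e-12
            )
            closed = yn_growth.enquist_project(d0, (2 / 3) * beta * T)
            assert sol.y[0, -1] == pytest.approx(closed, rel=1e-6)

    def test_rate_fit_hand_solution(self):
        # beta = (1*1 + 2*2) / (1 + 4) = 1
        assert yn_growth.fit_enquist_rate([[1, 1], [8, 2]]).beta == pytest.approx(1.0)

    def test_rate_fit_exact_data(self):
        d0 = np.array([1.0, 3.0, 10.0, 30.0])
        em = yn_growth.fit_enquist_rate(np.column_stack([d0, 0.4 * d0 ** (1 / 3)]))
        assert em.beta == pytest.approx(0.4, rel=1e-12)

    def test_closed_form_matches_nls(self):
        rng = np.random.default_rng(14)
        d0 = rng.uniform(1, 40, 80)
        g = 0.3 * d0 ** (1 / 3) + rng.normal(0, 0.05, 80)
        closed = yn_growth.fit_enquist_rate(np.column_stack([d0, g])).beta
        nls = regression.nls_fit(lambda p, x: p[0] * x ** (1 / 3), d0, g, [1.0])
        assert closed == pytest.approx(nls.params[0], rel=1e-8)
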