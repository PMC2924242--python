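"""Analytic traveling-wave machinery: tail rates, S profile, speed selection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.linalg import solve_banded

from chemopulse.reference import reference_params
from chemopulse.wave import (
    NoTravelingPulseError,
    asymmetry_factor,
    chemo_profile_in_frame,
    nutrient_profile_in_frame,
    rho_max_from_mass,
    solve_speed,
    speed_residual,
    tail_rates,
)

from conftest import closed_form_asymmetry, closed_form_speed


class TestTailRates:
    def test_symmetric_when_sigma_equals_u_N(self):
        p = reference_params(u_S=2.0, u_N=0.5, D_rho=1.0)
        assert tail_rates(p, 0.5) == pytest.approx((2.0, 2.0))

    def test_cluster_limit(self):
        p = reference_params(u_S=2.0, u_N=0.0, D_rho=1.0)
        assert tail_rates(p, 0.0) == pytest.approx((2.0, 2.0))

    def test_bracket_violation_raises(self):
        p = reference_params(u_S=2.0, u_N=0.5, D_rho=1.0)
        with pytest.raises(NoTravelingPulseError):
            tail_rates(p, 3.0)  # faster than u_S + u_N: back tail grows

    def test_mass_normalization_exact(self):
        p = reference_params()
        lb, lf = tail_rates(p, 1.0)
        rho_max = rho_max_from_mass(p, 1.0)
        assert rho_max * (1 / lb + 1 / lf) == pytest.approx(p.M, rel=1e-14)


class TestChemoProfile:
    def test_no_secretion_means_no_signal(self):
        p = reference_params(beta=0.0)
        c = chemo_profile_in_frame(p, 1.0)
        z = np.linspace(-500, 500, 101)
        assert np.max(np.abs(c.S(z))) == 0.0

    def test_symmetric_cluster_has_flat_top(self):
        p = reference_params(u_N=0.0)
        c = chemo_profile_in_frame(p, 0.0)
        assert c.dS(0.0) == pytest.approx(0.0, abs=1e-12 * abs(c.S(0.0)))
        z = np.linspace(1.0, 400.0, 50)
        assert np.allclose(c.S(z), c.S(-z), rtol=1e-10)

    def test_profile_matches_independent_bvp_solve(self):
        """Finite-difference boundary-value solve as an independent oracle."""
        p = reference_params()
        sigma = 1.3
        c = chemo_profile_in_frame(p, sigma)
        # dense FD solve of -D_S S'' - sigma S' + alpha S = beta rho on a
        # domain wide enough that Dirichlet-zero ends are exact to roundoff
        z = np.linspace(-6000.0, 6000.0, 24001)
        dz = z[1] - z[0]
        rho = c.rho(z)
        n = z.size
        ab = np.zeros((3, n))
        ab[0, 1:] = -p.D_S / dz**2 - sigma / (2 * dz)
        ab[1, :] = 2 * p.D_S / dz**2 + p.alpha
        ab[2, :-1] = -p.D_S / dz**2 + sigma / (2 * dz)
        rhs = p.beta * rho
        ab[1, 0] = ab[1, -1] = 1.0
        ab[0, 1] = ab[2, -2] = 0.0
        rhs[0] = rhs[-1] = 0.0
        S_fd = solve_banded((1, 1), ab, rhs)
        interior = np.abs(z) < 2000
        err = np.max(np.abs(S_fd[interior] - c.S(z[interior]))) / np.max(
            np.abs(c.S(z))
        )
        assert err < 1e-5

    def test_continuity_at_peak(self):
        p = reference_params()
        c = chemo_profile_in_frame(p, 0.9)
        assert c.S(-1e-12) == pytest.approx(c.S(1e-12), rel=1e-9)
        assert c.dS(-1e-12) == pytest.approx(c.dS(1e-12), rel=1e-6)


class TestSpeedResidual:
    def test_zero_speed_solution_without_nutrient(self):
        p = reference_params(u_N=0.0)
        assert speed_residual(p, 0.0) == pytest.approx(0.0, abs=1e-18)

    def test_sign_change_on_bracket(self, ref_params):
        p = ref_params
        lo = max(0.0, p.u_N - p.u_S) + 1e-6
        hi = p.u_N + p.u_S - 1e-6
        assert speed_residual(p, lo) * speed_residual(p, hi) < 0

    def test_scales_linearly_with_mass(self, ref_params):
        r1 = speed_residual(ref_params, 1.0)
        r2 = speed_residual(ref_params.replace(M=2 * ref_params.M), 1.0)
        assert r2 == pytest.approx(2 * r1, rel=1e-12)

    @pytest.mark.parametrize("u_N,alpha", [(2.4, 0.0243), (1.0, 0.01), (0.5, 0.1)])
    def test_unique_sign_change_on_bracket(self, u_N, alpha):
        """The residual crosses zero exactly once on the admissible bracket,
        supporting uniqueness of the selected speed.  (The raw residual is
        not strictly monotone -- it carries a positive sigma-dependent
        amplitude factor -- but its sign pattern is.)"""
        p = reference_params(u_N=u_N, alpha=alpha)
        lo = p.u_N - p.u_S
        hi = p.u_N + p.u_S
        span = hi - lo
        sigmas = np.linspace(lo + 1e-4 * span, hi - 1e-4 * span, 200)
        signs = np.sign([speed_residual(p, s) for s in sigmas])
        assert np.count_nonzero(np.diff(signs)) == 1


class TestSolveSpeed:
    def test_reference_set_reproduces_calibrated_speed(self, ref_params):
        assert solve_speed(ref_params).sigma == pytest.approx(1.8, rel=1e-9)

    def test_zero_nutrient_pull_gives_zero_speed(self):
        assert solve_speed(reference_params(u_N=0.0)).sigma == 0.0

    def test_mass_independence_exact(self, ref_params):
        s1 = solve_speed(ref_params)
        s2 = solve_speed(ref_params.replace(M=10 * ref_params.M))
        assert s2.sigma == pytest.approx(s1.sigma, rel=1e-10)
        assert s2.asymmetry == pytest.approx(s1.asymmetry, rel=1e-10)

    @given(
        u_S=st.floats(1.0, 5.0),
        ratio=st.floats(0.05, 0.95),
        alpha=st.floats(1e-3, 0.2),
        D_S=st.floats(200.0, 2000.0),
        sign=st.sampled_from([1.0, -1.0]),
    )
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_matches_closed_form_oracle(self, u_S, ratio, alpha, D_S, sign):
        p = reference_params(u_S=u_S, u_N=sign * ratio * u_S, alpha=alpha, D_S=D_S)
        sol = solve_speed(p)
        assert sol.sigma == pytest.approx(closed_form_speed(p), rel=1e-8, abs=1e-12)
        assert sol.asymmetry == pytest.approx(
            closed_form_asymmetry(p, sol.sigma), rel=1e-8
        )

    def test_speed_independent_of_cell_diffusivity(self, ref_params):
        sol1 = solve_speed(ref_params)
        sol2 = solve_speed(ref_params.replace(D_rho=3 * ref_params.D_rho))
        assert sol2.sigma == pytest.approx(sol1.sigma, rel=1e-9)

    def test_rejects_dominant_nutrient_pull(self):
        with pytest.raises(NoTravelingPulseError):
            solve_speed(reference_params(u_N=5.0, u_S=3.0))


class TestAsymmetry:
    def test_unity_when_sigma_equals_u_N(self):
        p = reference_params(u_S=2.0, u_N=0.5)
        assert asymmetry_factor(p, 0.5) == pytest.approx(1.0)

    def test_direct_formula_value(self):
        p = reference_params(u_S=2.0, u_N=0.0, D_rho=1.0)
        # lambda_front/lambda_back = (2 - 0 + 1)/(2 + 0 - 1) = 3
        assert asymmetry_factor(p, 1.0) == pytest.approx(3.0)

    def test_invariant_under_mass_rescaling(self, ref_params):
        a1 = asymmetry_factor(ref_params, 1.2)
        a2 = asymmetry_factor(ref_params.replace(M=7 * ref_params.M), 1.2)
        assert a1 == a2


class TestNutrientProfile:
    def test_monotone_increasing_and_bounded(self, ref_params):
        sol = solve_speed(ref_params)
        z = np.linspace(-3000, 3000, 2001)
        N = nutrient_profile_in_frame(ref_params, sol, z)
        assert np.all(np.diff(N) >= -1e-9 * ref_params.N0)
        assert N[-1] == pytest.approx(ref_params.N0)
        assert np.all(N >= -1e-12 * ref_params.N0)
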