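"""Response functions, transport coefficients and parameter records."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

from chemopulse.core import (
    KineticParams,
    PhysicalParams,
    ResponseFunction,
    VelocitySet,
    chemotactic_slope,
    evaluate_response,
    flux_from_gradient,
    macroscopic_diffusion,
    stiff_flux,
    stiff_flux_magnitude,
)
from chemopulse.reference import reference_params


class TestResponseFunction:
    def test_stiff_is_negative_sign_with_zero_tiebreak(self):
        phi = ResponseFunction(kind="stiff")
        assert evaluate_response(phi, 3.2) == -1.0
        assert evaluate_response(phi, -0.7) == 1.0
        assert evaluate_response(phi, 0.0) == 0.0

    def test_smooth_family_is_scaled_tanh(self):
        phi = ResponseFunction(kind="smooth", delta=1.0)
        y = np.linspace(-5, 5, 101)
        assert np.max(np.abs(evaluate_response(phi, y) + np.tanh(y))) == 0.0

    @given(
        y=st.floats(-1e6, 1e6, allow_nan=False),
        delta=st.floats(1e-3, 1e3),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_bounded_odd_decreasing(self, y, delta):
        phi = ResponseFunction(kind="smooth", delta=delta)
        v = evaluate_response(phi, y)
        assert -1.0 <= v <= 1.0
        assert evaluate_response(phi, -y) == pytest.approx(-v, abs=1e-12)
        assert evaluate_response(phi, y + 1.0) <= v

    def test_slope_at_origin_is_inverse_delta(self):
        phi = ResponseFunction(kind="smooth", delta=0.25)
        h = 1e-7
        slope = (evaluate_response(phi, h) - evaluate_response(phi, -h)) / (2 * h)
        assert slope == pytest.approx(-1 / 0.25, rel=1e-5)


class TestDiffusion:
    def test_two_point_closed_form(self):
        kin = KineticParams(c=20.0, psi0=1.0, epsilon=0.0)
        assert macroscopic_diffusion(kin) == pytest.approx(400.0)

    def test_unit_circle_halves_mean_square(self):
        kin = KineticParams(
            c=20.0, psi0=1.0, epsilon=0.0, velocity_set=VelocitySet.unit_circle
        )
        assert macroscopic_diffusion(kin) == pytest.approx(200.0)

    def test_scaling_in_psi0(self):
        k1 = KineticParams(c=17.0, psi0=1.3, epsilon=0.0)
        k2 = KineticParams(c=17.0, psi0=2.6, epsilon=0.0)
        assert macroscopic_diffusion(k2) == pytest.approx(
            macroscopic_diffusion(k1) / 2
        )


class TestFlux:
    def test_zero_gradient_gives_zero(self):
        kin = KineticParams(c=20.0, psi0=1.0, epsilon=0.09)
        for phi in (ResponseFunction(kind="stiff"), ResponseFunction.from_delta(0.5)):
            assert flux_from_gradient(kin, phi, 0.0) == 0.0

    def test_two_point_stiff_saturation(self):
        kin = KineticParams(c=20.0, psi0=1.0, epsilon=0.09)
        phi = ResponseFunction(kind="stiff")
        # brute-force average over V = {-c, +c}
        expected = -kin.epsilon * 0.5 * (
            kin.c * (-1.0) + (-kin.c) * (+1.0)
        )
        assert expected == pytest.approx(1.8)
        assert flux_from_gradient(kin, phi, 0.37) == pytest.approx(1.8)
        assert flux_from_gradient(kin, phi, -0.37) == pytest.approx(-1.8)

    def test_unit_circle_stiff_saturation_is_two_over_pi(self):
        kin = KineticParams(
            c=20.0, psi0=1.0, epsilon=0.09, velocity_set=VelocitySet.unit_circle
        )
        phi = ResponseFunction(kind="stiff")
        assert flux_from_gradient(kin, phi, 5.0) == pytest.approx(
            0.09 * 20.0 * 2 / math.pi
        )

    @pytest.mark.parametrize("g", [1e-3, 0.02, 0.3, 5.0])
    def test_unit_circle_smooth_matches_quadrature(self, g):
        kin = KineticParams(
            c=20.0, psi0=1.0, epsilon=0.12, velocity_set=VelocitySet.unit_circle
        )
        phi = ResponseFunction.from_delta(0.3)
        # independent quadrature of -eps <v phi(v g)> on the circle
        val, _ = quad(
            lambda th: -kin.epsilon
            * kin.c
            * math.cos(th)
            * (-math.tanh(kin.c * math.cos(th) * g / phi.delta)),
            0,
            2 * math.pi,
        )
        assert flux_from_gradient(kin, phi, g) == pytest.approx(
            val / (2 * math.pi), abs=1e-8
        )

    @given(g=st.floats(-100, 100, allow_nan=False))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_bounded_by_epsilon_c_and_odd(self, g):
        kin = KineticParams(c=25.0, psi0=2.0, epsilon=0.12)
        phi = ResponseFunction.from_delta(0.1)
        f = flux_from_gradient(kin, phi, g)
        assert abs(f) <= kin.epsilon * kin.c + 1e-12
        assert flux_from_gradient(kin, phi, -g) == pytest.approx(-f, abs=1e-12)

    @pytest.mark.parametrize("delta", [1e-2, 1e-3])
    def test_stiff_limit_convergence(self, delta):
        kin = KineticParams(c=25.0, psi0=2.0, epsilon=0.12)
        phi = ResponseFunction.from_delta(delta)
        g = 0.05
        assert flux_from_gradient(kin, phi, g) == pytest.approx(
            stiff_flux_magnitude(kin), rel=0.01
        )

    def test_linear_regime_slope(self):
        kin = KineticParams(c=25.0, psi0=2.0, epsilon=0.12)
        delta = 0.4
        phi = ResponseFunction.from_delta(delta)
        h = 1e-9
        fd = (flux_from_gradient(kin, phi, h) - flux_from_gradient(kin, phi, -h)) / (
            2 * h
        )
        assert fd == pytest.approx(chemotactic_slope(kin, delta), rel=1e-5)


class TestStiffFlux:
    def test_values_and_tiebreak(self):
        assert stiff_flux(2.0, -0.1) == -2.0
        assert stiff_flux(2.0, 0.0) == 0.0
        assert stiff_flux(0.0, 7.0) == 0.0
        with pytest.raises(ValueError):
            stiff_flux(-1.0, 0.1)


class TestParamRecords:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            KineticParams(c=20.0, psi0=1.0, epsilon=1.0)
        with pytest.raises(ValueError):
            reference_params(D_rho=-1.0)
        with pytest.raises(ValueError):
            reference_params(u_S=0.0)

    def test_config_round_trip(self, tmp_path):
        p = reference_params()
        for name in ("p.yaml", "p.json"):
            path = tmp_path / name
            p.to_file(path)
            assert PhysicalParams.from_file(path) == p
        k = KineticParams(c=25.0, psi0=2.0, epsilon=0.12)
        path = tmp_path / "k.yaml"
        k.to_file(path)
        assert KineticParams.from_file(path) == k

    def test_chemical_range_accessor(self):
        p = reference_params(D_S=800.0, alpha=0.02)
        assert p.l_S == pytest.approx(200.0)
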