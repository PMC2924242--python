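"""Analytic traveling-pulse theory in the stiff-response limit.

In a frame ``z = x - sigma t`` moving with the pulse, and for a step response
(only the *sign* of the chemical gradients matters), the density equation
integrates once to a piecewise-exponential profile

    rho(z) = rho_max * exp(lambda_back * z)   (z < 0, behind the peak)
           = rho_max * exp(-lambda_front * z) (z > 0, ahead of it)

    lambda_back  = (u_S + u_N - sigma) / D_rho
    lambda_front = (u_S - u_N + sigma) / D_rho

because the chemoattractant drift points toward the peak on both sides
(+u_S behind, -u_S ahead) while the nutrient drift is the constant +u_N
(fresh nutrient ahead of the pulse).  The chemoattractant profile solves

    -D_S S'' - sigma S' + alpha S = beta rho(z)

with decay at infinity.  The pulse speed is selected by the requirement that
S peaks exactly at the density peak, i.e. ``S'(0) = 0``: faster waves leave
their own secretion behind, slower ones run into it.  ``speed_residual``
evaluates S'(0) and ``solve_speed`` finds its root by bracketing; the root
does not depend on the total cell number M (the residual is proportional to
``rho_max``) nor on the cell diffusivity D_rho (only the *ratio* of tail
rates enters).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .core import PhysicalParams

__all__ = [
    "NoTravelingPulseError",
    "SCoeffs",
    "TravelingWaveSolution",
    "tail_rates",
    "rho_max_from_mass",
    "chemo_profile_in_frame",
    "speed_residual",
    "solve_speed",
    "asymmetry_factor",
]


class NoTravelingPulseError(ValueError):
    """Raised when no decaying traveling-pulse profile exists."""


def tail_rates(params: PhysicalParams, sigma: float) -> tuple[float, float]:
    """Exponential decay rates (lambda_back, lambda_front) of the pulse tails.

    Both must be positive for a localized pulse; otherwise the parameter
    regime admits no traveling pulse at this speed and
    :class:`NoTravelingPulseError` is raised.
    """
    lam_back = (params.u_S + params.u_N - sigma) / params.D_rho
    lam_front = (params.u_S - params.u_N + sigma) / params.D_rho
    if lam_back <= 0 or lam_front <= 0:
        raise NoTravelingPulseError(
            f"no decaying pulse at sigma={sigma}: rates "
            f"({lam_back:.3g}, {lam_front:.3g}) must both be positive"
        )
    return lam_back, lam_front


def rho_max_from_mass(params: PhysicalParams, sigma: float) -> float:
    """Peak density from mass normalization, integral of rho(z) dz = M."""
    lb, lf = tail_rates(params, sigma)
    return params.M * lb * lf / (lb + lf)


@dataclass
class SCoeffs:
    """Piecewise-exponential representation of the wave-frame S profile.

    ``S(z) = A_back e^{lambda_back z} + C_back e^{mu_plus z}`` for z < 0 and
    ``A_front e^{-lambda_front z} + C_front e^{mu_minus z}`` for z > 0, with
    ``mu_+ > 0 > mu_-`` the decaying homogeneous roots of the operator
    ``-D_S d_zz - sigma d_z + alpha``.
    """

    A_back: float
    C_back: float
    A_front: float
    C_front: float
    mu_plus: float
    mu_minus: float
    lambda_back: float
    lambda_front: float
    rho_max: float

    def S(self, z):
        z = np.asarray(z, dtype=float)
        back = self.A_back * np.exp(self.lambda_back * z) + self.C_back * np.exp(
            self.mu_plus * z
        )
        front = self.A_front * np.exp(-self.lambda_front * z) + self.C_front * np.exp(
            self.mu_minus * z
        )
        out = np.where(z < 0, back, front)
        return float(out) if out.ndim == 0 else out

    def dS(self, z):
        z = np.asarray(z, dtype=float)
        back = self.A_back * self.lambda_back * np.exp(
            self.lambda_back * z
        ) + self.C_back * self.mu_plus * np.exp(self.mu_plus * z)
        front = -self.A_front * self.lambda_front * np.exp(
            -self.lambda_front * z
        ) + self.C_front * self.mu_minus * np.exp(self.mu_minus * z)
        out = np.where(z < 0, back, front)
        return float(out) if out.ndim == 0 else out

    def rho(self, z):
        z = np.asarray(z, dtype=float)
        out = self.rho_max * np.where(
            z < 0, np.exp(self.lambda_back * z), np.exp(-self.lambda_front * z)
        )
        return float(out) if out.ndim == 0 else out


@dataclass
class TravelingWaveSolution:
    """Traveling pulse: speed, tail rates, peak density and asymmetry."""

    sigma: float
    lambda_back: float
    lambda_front: float
    rho_max: float
    asymmetry: float
    S_coeffs: SCoeffs

    def to_dict(self) -> dict:
        return {
            "sigma": self.sigma,
            "lambda_back": self.lambda_back,
            "lambda_front": self.lambda_front,
            "rho_max": self.rho_max,
            "asymmetry": self.asymmetry,
        }


def _homogeneous_roots(params: PhysicalParams, sigma: float) -> tuple[float, float]:
    if params.alpha <= 0:
        raise ValueError("wave-frame chemoattractant profile requires alpha > 0")
    disc = math.sqrt(sigma**2 + 4.0 * params.D_S * params.alpha)
    mu_plus = (-sigma + disc) / (2.0 * params.D_S)
    mu_minus = (-sigma - disc) / (2.0 * params.D_S)
    return mu_plus, mu_minus


def chemo_profile_in_frame(
    params: PhysicalParams, sigma: float, rho_max: float | None = None
) -> SCoeffs:
    """Solve the wave-frame chemoattractant equation for the exponential pulse.

    Returns the coefficients of the unique bounded C^1 solution of
    ``-D_S S'' - sigma S' + alpha S = beta rho(z)`` with the two-sided
    exponential source.  ``rho_max`` defaults to the mass-normalized peak.
    """
    lb, lf = tail_rates(params, sigma)
    if rho_max is None:
        rho_max = rho_max_from_mass(params, sigma)
    mu_p, mu_m = _homogeneous_roots(params, sigma)

    # particular-solution denominators; perturb near resonance with the
    # homogeneous roots (measure-zero parameter coincidence)
    def _den_back(lam):
        return params.alpha - sigma * lam - params.D_S * lam**2

    def _den_front(lam):
        return params.alpha + sigma * lam - params.D_S * lam**2

    scale = params.alpha + abs(sigma) * lb + params.D_S * lb**2
    if abs(_den_back(lb)) < 1e-12 * scale:
        warnings.warn("tail rate resonant with homogeneous root; perturbing")
        lb *= 1.0 + 1e-9
    scale = params.alpha + abs(sigma) * lf + params.D_S * lf**2
    if abs(_den_front(lf)) < 1e-12 * scale:
        warnings.warn("tail rate resonant with homogeneous root; perturbing")
        lf *= 1.0 + 1e-9

    A_b = params.beta * rho_max / _den_back(lb)
    A_f = params.beta * rho_max / _den_front(lf)

    # continuity of S and S' at z = 0
    r1 = A_f - A_b
    r2 = -lf * A_f - lb * A_b
    det = mu_p - mu_m
    C_b = (-mu_m * r1 + r2) / det
    C_f = (r2 - mu_p * r1) / det

    return SCoeffs(
        A_back=A_b,
        C_back=C_b,
        A_front=A_f,
        C_front=C_f,
        mu_plus=mu_p,
        mu_minus=mu_m,
        lambda_back=lb,
        lambda_front=lf,
        rho_max=rho_max,
    )


def speed_residual(params: PhysicalParams, sigma: float) -> float:
    """S'(0) of the wave-frame chemoattractant profile (conc/um).

    A root in sigma is a traveling-pulse speed: there the chemoattractant
    peak coincides with the density peak so that S' changes sign exactly
    once, as required for the stiff drift to point toward the peak on both
    sides.  The residual scales linearly with rho_max, hence its root does
    not depend on the cell number M.
    """
    coeffs = chemo_profile_in_frame(params, sigma)
    return coeffs.lambda_back * coeffs.A_back + coeffs.mu_plus * coeffs.C_back


def solve_speed(params: PhysicalParams, rtol: float = 1e-12) -> TravelingWaveSolution:
    """Pulse speed and profile by bracketed root-finding on ``speed_residual``.

    The admissible bracket is ``u_N - u_S < sigma < u_N + u_S`` (both tails
    decay); monotonicity of the residual gives a unique speed, positive for
    u_N > 0.  Raises :class:`NoTravelingPulseError` when the residual does
    not change sign on the bracket.
    """
    if params.u_S <= 0:
        raise ValueError("u_S must be positive")
    if abs(params.u_N) >= params.u_S:
        raise NoTravelingPulseError(
            "pulse theory requires |u_N| < u_S (nutrient pull weaker than "
            "self-attraction)"
        )
    if params.u_N == 0:
        sigma = 0.0
    else:
        lo = params.u_N - params.u_S
        hi = params.u_N + params.u_S
        span = hi - lo
        lo += 1e-9 * span
        hi -= 1e-9 * span
        f_lo = speed_residual(params, lo)
        f_hi = speed_residual(params, hi)
        if f_lo == 0.0:
            sigma = lo
        elif f_hi == 0.0:
            sigma = hi
        elif f_lo * f_hi > 0:
            raise NoTravelingPulseError(
                "no traveling pulse in this regime: speed residual does not "
                f"change sign on ({lo:.4g}, {hi:.4g})"
            )
        else:
            sigma = brentq(
                lambda s: speed_residual(params, s),
                lo,
                hi,
                rtol=max(rtol, 4 * np.finfo(float).eps),
                xtol=1e-14 * max(1.0, span),
            )
    lb, lf = tail_rates(params, sigma)
    rho_max = rho_max_from_mass(params, sigma)
    coeffs = chemo_profile_in_frame(params, sigma, rho_max)
    return TravelingWaveSolution(
        sigma=sigma,
        lambda_back=lb,
        lambda_front=lf,
        rho_max=rho_max,
        asymmetry=asymmetry_factor(params, sigma),
        S_coeffs=coeffs,
    )


def asymmetry_factor(params: PhysicalParams, sigma: float) -> float:
    """Front-over-back ratio of the tail rates, lambda_front / lambda_back.

    Equals 1 iff sigma = u_N (symmetric pulse); for the selected speed
    (sigma < u_N) the back tail is the stiffer one and the factor is < 1.
    Independent of the cell number M.
    """
    lb, lf = tail_rates(params, sigma)
    return lf / lb


def nutrient_profile_in_frame(
    params: PhysicalParams,
    sol: "TravelingWaveSolution",
    z: np.ndarray,
) -> np.ndarray:
    """Wave-frame nutrient profile on the given z grid (numeric).

    Solves the linear equation ``D_N N'' + sigma N' = gamma rho(z) N`` with
    zero slope at the left edge and N = N0 at the right edge; N increases
    monotonically across the pulse (fresh nutrient ahead), which is the
    standing assumption of the stiff-limit wave construction.
    """
    z = np.asarray(z, dtype=float)
    n = z.size
    dz = z[1] - z[0]
    rho = sol.S_coeffs.rho(z)
    main = np.empty(n)
    lower = np.empty(n - 1)
    upper = np.empty(n - 1)
    a = params.D_N / dz**2
    b = sol.sigma / (2.0 * dz)
    main[:] = -2.0 * a - params.gamma * rho
    lower[:] = a - b
    upper[:] = a + b
    rhs = np.zeros(n)
    # left: N'(z0) = 0  ->  ghost N_{-1} = N_1
    main[0] = -2.0 * a - params.gamma * rho[0]
    upper[0] = 2.0 * a
    # right: Dirichlet N = N0
    main[-1] = 1.0
    lower[-1] = 0.0
    rhs[-1] = params.N0
    ab = np.zeros((3, n))
    ab[0, 1:] = upper
    ab[1, :] = main
    ab[2, :-1] = lower
    from scipy.linalg import solve_banded

    return solve_banded((1, 1), ab, rhs)
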