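"""Stationary clusters (zero-speed pulses) and linear stability in the
stiffness parameter.

Without nutrient the stiff-response system admits stationary clusters: the
zero-speed limit of the traveling pulse, a symmetric two-sided exponential

    rho(z) = rho_max exp(-(u_S / D_rho) |z|),   rho_max = M u_S / (2 D_rho)

whose width ``2 D_rho / u_S`` does not depend on the number of trapped
cells -- the size-independence observed for self-organized E. coli
aggregates.

For a *smooth* response (stiffness delta > 0) the drift is linear in small
gradients with slope ``chi = eps <v^2> / delta`` and the model coincides
with a Keller-Segel system near the uniform state ``rho0``.  With the
chemoattractant slaved to the slow cell dynamics, the growth rate of a
perturbation ``cos(k x)`` (zero-flux channel modes ``k = n pi / L``) is

    rate(k) = -D_rho k^2 + chi rho0 beta k^2 / (D_S k^2 + alpha)

Instability (cluster formation) occurs for delta below a critical stiffness
``delta_c``; the uniform state is linearly stable for delta > delta_c.  The
threshold grows with rho0 and shrinks with the degradation rate alpha
(shorter chemical range ``l_S = sqrt(D_S / alpha)``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .core import KineticParams, PhysicalParams, chemotactic_slope
from .wave import SCoeffs, chemo_profile_in_frame

__all__ = [
    "ClusterSolution",
    "DispersionResult",
    "cluster_profile",
    "linear_growth_rate",
    "dispersion_curve",
    "stability_threshold",
]


@dataclass
class ClusterSolution:
    """Zero-speed stationary pulse (no nutrient)."""

    lam: float  # tail rate u_S / D_rho (1/um)
    width: float  # 2 D_rho / u_S (um)
    rho_max: float  # M lam / 2 (cells/um)
    S_coeffs: SCoeffs

    def rho(self, z):
        z = np.asarray(z, dtype=float)
        out = self.rho_max * np.exp(-self.lam * np.abs(z))
        return float(out) if out.ndim == 0 else out


@dataclass
class DispersionResult:
    """Dispersion relation of the uniform state on a zero-flux channel."""

    wavenumbers: np.ndarray  # 1/um
    growth_rates: np.ndarray  # 1/s
    delta_c: float | None
    l_S: float  # chemical range sqrt(D_S/alpha) (um)


def cluster_profile(params: PhysicalParams) -> ClusterSolution:
    """Closed-form stationary cluster for a stiff response, u_N = 0.

    The even two-sided exponential of rate u_S / D_rho; its chemoattractant
    profile is the sigma = 0 wave-frame solution, symmetric with S'(0) = 0.
    """
    p0 = params.replace(u_N=0.0)
    lam = p0.u_S / p0.D_rho
    rho_max = p0.M * lam / 2.0
    coeffs = chemo_profile_in_frame(p0, 0.0, rho_max)
    return ClusterSolution(
        lam=lam, width=2.0 * p0.D_rho / p0.u_S, rho_max=rho_max, S_coeffs=coeffs
    )


def linear_growth_rate(
    k,
    rho0: float,
    params: PhysicalParams,
    kin: KineticParams,
    delta: float | None = None,
) -> float | np.ndarray:
    """Growth rate (1/s) of a cos(k x) perturbation of the uniform state.

    Requires a smooth response (delta > 0; the linearization is undefined
    for the step response).  ``delta`` defaults to ``params.delta``.  The
    k = 0 mode is neutral (mass conservation) and rates fall off as
    ``-D_rho k^2`` at large k.
    """
    delta = params.delta if delta is None else delta
    if delta <= 0:
        raise ValueError("linear stability requires a smooth response (delta > 0)")
    chi = chemotactic_slope(kin, delta)
    k = np.asarray(k, dtype=float)
    rate = -params.D_rho * k**2 + chi * rho0 * params.beta * k**2 / (
        params.D_S * k**2 + params.alpha
    )
    return float(rate) if rate.ndim == 0 else rate


def stability_threshold(
    rho0: float,
    params: PhysicalParams,
    kin: KineticParams,
    L: float | None = None,
    delta_range: tuple[float, float] = (1e-8, 1e6),
) -> float:
    """Critical stiffness delta_c on a sealed channel of length L.

    The most unstable admissible mode is the lowest one, k1 = pi / L; the
    growth rate at k1 is monotone decreasing in delta, so delta_c is its
    unique root, found by bracketed root-finding.  Raises with the scanned
    bound if no threshold lies in ``delta_range``.
    """
    L = params.L if L is None else L
    k1 = np.pi / L

    def rate_at_k1(delta: float) -> float:
        return float(linear_growth_rate(k1, rho0, params, kin, delta=delta))

    lo, hi = delta_range
    f_lo, f_hi = rate_at_k1(lo), rate_at_k1(hi)
    if f_lo <= 0:
        raise ValueError(
            f"uniform state already stable at delta = {lo}: delta_c below scan range"
        )
    if f_hi >= 0:
        raise ValueError(
            f"uniform state still unstable at delta = {hi}: delta_c above scan range"
        )
    return float(brentq(rate_at_k1, lo, hi, rtol=1e-12))


def dispersion_curve(
    rho0: float,
    params: PhysicalParams,
    kin: KineticParams,
    k: np.ndarray | None = None,
    L: float | None = None,
) -> DispersionResult:
    """Dispersion relation over the channel modes plus the critical stiffness."""
    L = params.L if L is None else L
    if k is None:
        k = np.arange(0, 41) * np.pi / L
    k = np.asarray(k, dtype=float)
    rates = linear_growth_rate(k, rho0, params, kin)
    try:
        delta_c = stability_threshold(rho0, params, kin, L)
    except ValueError:
        delta_c = None
    return DispersionResult(
        wavenumbers=k, growth_rates=np.asarray(rates), delta_c=delta_c, l_S=params.l_S
    )
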