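"""Parameter records, tumbling-response functions and kinetic-derived transport
coefficients.

The macroscopic model describes a population of run-and-tumble bacteria by its
density ``rho(t, x)`` coupled to a self-secreted chemoattractant ``S`` and a
consumed nutrient ``N``::

    d_t rho = d_x ( D_rho d_x rho - rho * (u_S(d_x S) + u_N(d_x N)) )
    d_t S   = D_S d_xx S + beta * rho - alpha * S
    d_t N   = D_N d_xx N - gamma * rho * N

The chemotactic drifts are not postulated (as in the classical Keller-Segel
model) but derived from the individual run-and-tumble process: a cell runs at
speed ``c``, tumbles at rate ``psi0 * (1 + eps * phi(v * d_x S))`` and picks a
fresh velocity uniformly on the admissible velocity set.  In the parabolic
(drift-diffusion) limit this yields a diffusivity ``<v^2>/psi0`` and a drift

    u(g) = -eps * < v * phi(v * g) >_V ,

which is *bounded* by ``eps * c`` however large the chemical gradient -- the
feature that allows stable traveling pulses instead of blow-up.

``phi`` is an odd, decreasing response with values in [-1, 1]; the smooth
one-parameter family used here is ``phi_delta(y) = -tanh(y / delta)`` whose
slope at the origin is ``-1/delta``; ``delta -> 0`` gives the all-or-none step
response ``-sign(y)``.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np
import yaml
from scipy.integrate import quad

__all__ = [
    "VelocitySet",
    "PhysicalParams",
    "KineticParams",
    "ResponseFunction",
    "evaluate_response",
    "mean_square_velocity",
    "macroscopic_diffusion",
    "flux_from_gradient",
    "stiff_flux",
    "stiff_flux_magnitude",
    "chemotactic_slope",
    "normalized_drift",
]


class VelocitySet(str, enum.Enum):
    """Admissible velocity sets of the kinetic model.

    ``two_point`` is {-c, +c} (the 1D idealization, default); ``unit_circle``
    is {c * (cos t, sin t)} projected on the channel axis.  Macroscopic
    conclusions do not depend on this choice, only the numerical constants do.
    """

    two_point = "two_point"
    unit_circle = "unit_circle"


@dataclass
class PhysicalParams:
    """Macroscopic parameters of the drift-diffusion system.

    Units: lengths in micrometers, times in seconds, chemical concentrations
    in arbitrary units (only gradients relative to the response stiffness
    ``delta`` matter), cell counts in cells.

    Attributes
    ----------
    D_rho : float
        Effective cell diffusivity (um^2/s).
    D_S, D_N : float
        Molecular diffusivities of chemoattractant and nutrient (um^2/s).
    alpha : float
        Chemoattractant degradation rate (1/s).
    beta : float
        Chemoattractant secretion rate per unit cell density (conc * um / s).
    gamma : float
        Nutrient consumption rate per unit cell density (um / (cell * s));
        consumption term is ``-gamma * rho * N``.
    u_S : float
        Saturated (stiff-limit) chemotactic speed toward the chemoattractant
        (um/s), positive.
    u_N : float
        Saturated chemotactic speed toward the nutrient (um/s); may be signed.
    delta : float
        Stiffness of the response function; 0 means a step response.
    M : float
        Total cell number (conserved; no division on the experimental
        timescale).
    L : float
        Channel length (um).
    N0 : float
        Initial (uniform) nutrient level (arb. units).
    """

    D_rho: float
    D_S: float
    D_N: float
    alpha: float
    beta: float
    gamma: float
    u_S: float
    u_N: float
    delta: float
    M: float
    L: float
    N0: float

    def __post_init__(self) -> None:
        for name in ("D_rho", "D_S", "D_N"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("alpha", "beta", "gamma", "N0"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.u_S <= 0:
            raise ValueError("u_S must be > 0")
        if self.delta < 0:
            raise ValueError("delta must be >= 0")
        if self.M <= 0 or self.L <= 0:
            raise ValueError("M and L must be > 0")

    @property
    def l_S(self) -> float:
        """Range of action of the chemical signal, sqrt(D_S / alpha) (um)."""
        if self.alpha == 0:
            return math.inf
        return math.sqrt(self.D_S / self.alpha)

    def replace(self, **kwargs) -> "PhysicalParams":
        d = asdict(self)
        d.update(kwargs)
        return PhysicalParams(**d)

    # -- flat key-value config round trip -------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        with open(path, "w") as fh:
            if path.suffix == ".json":
                json.dump(self.to_dict(), fh, indent=2)
            else:
                yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "PhysicalParams":
        return cls(**{k: float(d[k]) for k in cls.__dataclass_fields__})

    @classmethod
    def from_file(cls, path: str | Path) -> "PhysicalParams":
        d = _load_config(path)
        return cls.from_dict(d)


@dataclass
class KineticParams:
    """Individual-cell (kinetic) parameters.

    ``c`` is the run speed (um/s), ``psi0`` the basal tumbling rate (1/s) and
    ``epsilon`` the (small) modulation amplitude of the tumbling rate, which
    in the parabolic scaling is also the ratio of collective to individual
    speed.  ``0 <= epsilon < 1`` keeps the tumbling rate positive.
    """

    c: float
    psi0: float
    epsilon: float
    velocity_set: VelocitySet = VelocitySet.two_point

    def __post_init__(self) -> None:
        if self.c <= 0 or self.psi0 <= 0:
            raise ValueError("c and psi0 must be > 0")
        if not 0 <= self.epsilon < 1:
            raise ValueError("epsilon must be in [0, 1)")
        self.velocity_set = VelocitySet(self.velocity_set)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["velocity_set"] = self.velocity_set.value
        return d

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        with open(path, "w") as fh:
            if path.suffix == ".json":
                json.dump(self.to_dict(), fh, indent=2)
            else:
                yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "KineticParams":
        return cls(
            c=float(d["c"]),
            psi0=float(d["psi0"]),
            epsilon=float(d["epsilon"]),
            velocity_set=VelocitySet(d.get("velocity_set", "two_point")),
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "KineticParams":
        return cls.from_dict(_load_config(path))


def _load_config(path: str | Path) -> dict:
    path = Path(path)
    with open(path) as fh:
        if path.suffix == ".json":
            return json.load(fh)
        return yaml.safe_load(fh)


@dataclass
class ResponseFunction:
    """Signal-response function phi of the tumbling rate.

    Odd, decreasing, with values in [-1, 1].  ``stiff`` is the two-valued
    step ``-sign(y)`` (with phi(0) = 0 as symmetric tie-break); ``smooth`` is
    ``-tanh(y / delta)`` with slope ``-1/delta`` at the origin.
    """

    kind: str = "stiff"  # "stiff" | "smooth"
    delta: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("stiff", "smooth"):
            raise ValueError("kind must be 'stiff' or 'smooth'")
        if self.kind == "smooth" and self.delta <= 0:
            raise ValueError("smooth response requires delta > 0")

    def __call__(self, y):
        return evaluate_response(self, y)

    @classmethod
    def from_delta(cls, delta: float) -> "ResponseFunction":
        """Stiff response for delta == 0, else the smooth tanh family."""
        if delta == 0:
            return cls(kind="stiff")
        return cls(kind="smooth", delta=delta)


def evaluate_response(phi: ResponseFunction, y):
    """Evaluate phi at the perceived signal derivative ``y = v * d_x S``.

    Total function with values in [-1, 1]; stiff kind returns -sign(y).
    """
    y = np.asarray(y, dtype=float)
    if phi.kind == "stiff":
        out = -np.sign(y)
    else:
        out = -np.tanh(y / phi.delta)
    return out if out.ndim else float(out)


def mean_square_velocity(kin: KineticParams) -> float:
    """Mean square of the axial velocity component over the velocity set."""
    if kin.velocity_set is VelocitySet.two_point:
        return kin.c**2
    if kin.velocity_set is VelocitySet.unit_circle:
        return kin.c**2 / 2.0
    raise ValueError(f"unsupported velocity set {kin.velocity_set}")


def macroscopic_diffusion(kin: KineticParams) -> float:
    """Cell diffusivity of the parabolic limit, ``<v^2> / psi0`` (um^2/s).

    This is the time integral of the velocity autocorrelation of the
    unbiased (epsilon = 0) velocity-jump process with uniform resampling.
    """
    return mean_square_velocity(kin) / kin.psi0


def stiff_flux_magnitude(kin: KineticParams) -> float:
    """Saturation value of the chemotactic drift for a step response.

    ``eps * c`` for the two-point set; ``eps * c * 2/pi`` on the unit circle
    (the mean of |cos|).
    """
    if kin.velocity_set is VelocitySet.two_point:
        return kin.epsilon * kin.c
    if kin.velocity_set is VelocitySet.unit_circle:
        return kin.epsilon * kin.c * 2.0 / math.pi
    raise ValueError(f"unsupported velocity set {kin.velocity_set}")


def flux_from_gradient(kin: KineticParams, phi: ResponseFunction, g) -> float:
    """Chemotactic drift speed ``-eps * < v phi(v g) >_V`` (um/s).

    Odd in the gradient ``g`` and bounded by ``eps * c`` in magnitude; for a
    step response it saturates at ``stiff_flux_magnitude`` for any g != 0.
    """
    g_arr = np.asarray(g, dtype=float)
    scalar = g_arr.ndim == 0
    g_arr = np.atleast_1d(g_arr)
    c, eps = kin.c, kin.epsilon
    if kin.velocity_set is VelocitySet.two_point:
        # <v phi(v g)> over {-c, +c} = c * phi(c g) by oddness of phi
        out = -eps * c * np.asarray(evaluate_response(phi, c * g_arr))
    elif kin.velocity_set is VelocitySet.unit_circle:
        if phi.kind == "stiff":
            out = stiff_flux_magnitude(kin) * np.sign(g_arr)
        else:
            out = np.empty_like(g_arr)
            for i, gi in enumerate(g_arr):
                val, _ = quad(
                    lambda th: math.cos(th)
                    * math.tanh(c * math.cos(th) * gi / phi.delta),
                    0.0,
                    2.0 * math.pi,
                )
                # -eps <v phi> with phi = -tanh: + eps/(2 pi) * integral
                out[i] = eps * c * val / (2.0 * math.pi)
    else:
        raise ValueError(f"unsupported velocity set {kin.velocity_set}")
    return float(out[0]) if scalar else out


def stiff_flux(u: float, g) -> float:
    """Stiff-limit drift ``u * sign(g)`` with the tie-break 0 at g = 0."""
    if u < 0:
        raise ValueError("u must be >= 0")
    g_arr = np.asarray(g, dtype=float)
    out = u * np.sign(g_arr)
    return float(out) if out.ndim == 0 else out


def chemotactic_slope(kin: KineticParams, delta: float) -> float:
    """Small-gradient slope chi of the drift, ``u(g) ~ chi * g``.

    For the tanh family ``chi = eps * <v^2> / delta``; this is the
    chemosensitivity of the coinciding Keller-Segel model in the linear
    regime, and the quantity entering the dispersion relation of the uniform
    state.
    """
    if delta <= 0:
        raise ValueError("linear slope undefined for a step response")
    return kin.epsilon * mean_square_velocity(kin) / delta


def normalized_drift(phi: ResponseFunction, c: float, g):
    """Drift response normalized to saturate at +-1.

    The macroscopic solver multiplies this by the free macroscopic speeds
    ``u_S`` / ``u_N``, so that the saturated drift equals the configured
    stiff-limit speed regardless of the kinetic normalization constant.
    For the two-point set this is ``tanh(c g / delta)`` (smooth) or
    ``sign(g)`` (stiff).
    """
    g_arr = np.asarray(g, dtype=float)
    if phi.kind == "stiff":
        out = np.sign(g_arr)
    else:
        out = np.tanh(c * g_arr / phi.delta)
    return float(out) if out.ndim == 0 else out
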