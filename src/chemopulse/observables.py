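"""Macroscopic observables, parameter inversion and synthetic fixtures.

The three observables of a traveling pulse that an experiment (or a
simulation) yields are the pulse speed ``sigma`` (linear regression of the
peak position against time) and the two exponential tail rates
``lambda_back``, ``lambda_front`` (log-linear fits of the profile on each
side of the peak).  Inverting the stiff-wave constitutive relations gives
the microscopic parameters that are hard to measure directly:

    u_S   = D_rho (lambda_back + lambda_front) / 2
    u_N   = sigma + D_rho (lambda_back - lambda_front) / 2
    alpha = the degradation rate at which the wave-frame chemoattractant
            peak sits exactly on the density peak at the observed speed
            (root of the speed residual in alpha).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .core import PhysicalParams
from .pde import FieldState, Grid1D, Trajectory
from .wave import TravelingWaveSolution, nutrient_profile_in_frame, solve_speed, speed_residual

__all__ = [
    "PulseTrack",
    "ProfileFit",
    "EstimatedParams",
    "track_peak",
    "refine_peak",
    "fit_tails",
    "invert_parameters",
    "make_fixture",
]


@dataclass
class PulseTrack:
    """Peak positions vs time and their least-squares speed."""

    times: np.ndarray
    positions: np.ndarray
    speed: float
    intercept: float
    residual_rms: float
    boundary_flagged: bool = False  # peak touched the domain boundary


@dataclass
class ProfileFit:
    """Log-linear tail fits of a pulse profile."""

    lambda_back: float
    lambda_front: float
    r2_back: float
    r2_front: float
    peak_position: float
    peak_height: float
    window: tuple[float, float] = (0.10, 0.60)


@dataclass
class EstimatedParams:
    """Microscopic parameters inverted from pulse observables."""

    u_S: float
    u_N: float
    alpha: float | None
    alpha_bracket: tuple[float, float] | None = None
    provenance: dict = field(default_factory=dict)


def refine_peak(x: np.ndarray, y: np.ndarray) -> tuple[float, float, bool]:
    """Argmax refined by a 3-point quadratic fit.

    Returns (position, height, at_boundary).  At a boundary node no
    refinement is possible and the flag is set.
    """
    i = int(np.argmax(y))
    if i == 0 or i == len(y) - 1:
        return float(x[i]), float(y[i]), True
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom == 0:
        return float(x[i]), float(y1), False
    shift = 0.5 * (y0 - y2) / denom
    shift = float(np.clip(shift, -1.0, 1.0))
    dx = x[1] - x[0]
    height = y1 - 0.25 * (y0 - y2) * shift
    return float(x[i] + shift * dx), float(height), False


def track_peak(
    traj: Trajectory, window: tuple[float, float] | None = None
) -> PulseTrack:
    """Fit the peak position against time by ordinary least squares.

    ``window`` restricts to snapshot times t in [t0, t1].  Snapshots whose
    peak sits on a domain boundary are flagged (pulse not yet detached) but
    still included; callers normally choose a window past detachment.
    """
    x = traj.grid.x
    times, pos = [], []
    flagged = False
    for s in traj.states:
        if window is not None and not (window[0] <= s.t <= window[1]):
            continue
        p, _, at_boundary = refine_peak(x, s.rho)
        flagged |= at_boundary
        times.append(s.t)
        pos.append(p)
    if len(times) < 3:
        raise ValueError("need at least 3 snapshots in the window")
    times = np.asarray(times)
    pos = np.asarray(pos)
    speed, intercept = np.polyfit(times, pos, 1)
    resid = pos - (speed * times + intercept)
    return PulseTrack(
        times=times,
        positions=pos,
        speed=float(speed),
        intercept=float(intercept),
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        boundary_flagged=flagged,
    )


def _fit_side(z: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Log-linear fit; returns (decay rate, R^2). z measured from the peak."""
    if len(z) < 5:
        raise ValueError("tail window shorter than 5 points")
    logy = np.log(y)
    slope, intercept = np.polyfit(z, logy, 1)
    pred = slope * z + intercept
    ss_res = float(np.sum((logy - pred) ** 2))
    ss_tot = float(np.sum((logy - np.mean(logy)) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return float(slope), r2


def fit_tails(
    state: FieldState | tuple[np.ndarray, np.ndarray],
    grid: Grid1D | None = None,
    window: tuple[float, float] = (0.10, 0.60),
) -> ProfileFit:
    """Fit the exponential tails of a pulse profile.

    Accepts a :class:`FieldState` plus its grid, or a raw ``(x, rho)`` pair.
    On each side of the (refined) peak the fit uses the contiguous stretch
    where rho is within ``window`` (fractions of the peak height) -- close
    enough to the peak to stay above any noise floor, far enough to avoid
    the peak curvature.
    """
    if isinstance(state, FieldState):
        if grid is None:
            raise ValueError("grid required with a FieldState")
        x, rho = grid.x, state.rho
    else:
        x, rho = state
        x = np.asarray(x, float)
        rho = np.asarray(rho, float)
    peak_pos, peak_height, at_boundary = refine_peak(x, rho)
    if at_boundary:
        raise ValueError("peak at domain boundary: pulse not separated")
    lo, hi = window[0] * peak_height, window[1] * peak_height
    i_peak = int(np.argmax(rho))
    if min(i_peak, len(x) - 1 - i_peak) < 10:
        raise ValueError("peak too close to boundary for tail fits")

    rates, r2s = [], []
    for side in (-1, +1):
        idx = []
        j = i_peak
        while 0 <= j < len(x):
            if rho[j] < lo:
                break
            if rho[j] <= hi:
                idx.append(j)
            j += side
        idx = np.asarray(idx)
        if len(idx) < 5:
            raise ValueError("tail window shorter than 5 points")
        slope, r2 = _fit_side(x[idx] - peak_pos, rho[idx])
        rates.append(side * -slope if side == 1 else slope)
        r2s.append(r2)
    lam_back, lam_front = rates[0], rates[1]
    if lam_back <= 0 or lam_front <= 0:
        raise ValueError("fitted tail rates must be positive")
    return ProfileFit(
        lambda_back=lam_back,
        lambda_front=lam_front,
        r2_back=r2s[0],
        r2_front=r2s[1],
        peak_position=peak_pos,
        peak_height=peak_height,
        window=window,
    )


def invert_parameters(
    fit: ProfileFit,
    track: PulseTrack,
    D_rho: float,
    D_S: float,
    beta: float,
    M: float,
    alpha_scan: tuple[float, float] = (1e-6, 10.0),
) -> EstimatedParams:
    """Invert pulse observables to (u_S, u_N, alpha).

    u_S and u_N follow in closed form from the tail rates and the speed;
    alpha is recovered as the root, over ``alpha_scan``, of the wave-frame
    speed residual evaluated at the observed speed.  If the residual does
    not change sign on the scanned range the bracket is reported instead.
    """
    lb, lf = fit.lambda_back, fit.lambda_front
    sigma = track.speed
    u_S = D_rho * (lb + lf) / 2.0
    u_N = sigma + D_rho * (lb - lf) / 2.0

    def resid(alpha: float) -> float:
        p = PhysicalParams(
            D_rho=D_rho,
            D_S=D_S,
            D_N=D_S,
            alpha=alpha,
            beta=beta,
            gamma=0.0,
            u_S=u_S,
            u_N=u_N,
            delta=0.0,
            M=M,
            L=1.0,
            N0=0.0,
        )
        return speed_residual(p, sigma)

    alphas = np.geomspace(alpha_scan[0], alpha_scan[1], 200)
    vals = np.array([resid(a) for a in alphas])
    sign_change = np.nonzero(np.diff(np.sign(vals)) != 0)[0]
    prov = {
        "observables": {"sigma": sigma, "lambda_back": lb, "lambda_front": lf},
        "fixed": {"D_rho": D_rho, "D_S": D_S, "beta": beta, "M": M},
    }
    if len(sign_change) == 0:
        return EstimatedParams(
            u_S=u_S, u_N=u_N, alpha=None, alpha_bracket=alpha_scan, provenance=prov
        )
    i = int(sign_change[0])
    alpha = brentq(resid, alphas[i], alphas[i + 1], rtol=1e-12)
    return EstimatedParams(u_S=u_S, u_N=u_N, alpha=float(alpha), provenance=prov)


def make_fixture(
    true_params: PhysicalParams,
    noise_level: float,
    seed: int,
    grid: Grid1D | None = None,
    times: np.ndarray | None = None,
    start_fraction: float = 0.25,
) -> tuple[Trajectory, dict]:
    """Synthetic pulse trajectory with known ground truth.

    Samples the analytic traveling wave (profile + speed of
    :func:`chemopulse.wave.solve_speed`) on a grid at several times and
    applies seeded multiplicative log-normal noise ``rho * exp(eta Z)`` with
    ``eta = noise_level`` -- the fluorescence-like noise model.  Returns the
    trajectory and a ground-truth record.
    """
    sol: TravelingWaveSolution = solve_speed(true_params)
    if grid is None:
        grid = Grid1D.for_channel(true_params.L, 1001)
    if times is None:
        times = np.linspace(0.0, 0.3 * grid.length / max(abs(sol.sigma), 1e-9), 6)
    rng = np.random.default_rng(seed)
    x = grid.x
    x_start = grid.x0 + start_fraction * grid.length
    z_grid = x - x_start
    N_frame = nutrient_profile_in_frame(true_params, sol, z_grid)
    traj = Trajectory(
        grid=grid,
        provenance={
            "kind": "synthetic_fixture",
            "noise_level": noise_level,
            "seed": seed,
            "params": true_params.to_dict(),
        },
    )
    for t in np.asarray(times, float):
        z = x - x_start - sol.sigma * t
        rho = sol.S_coeffs.rho(z)
        if noise_level > 0:
            rho = rho * np.exp(noise_level * rng.standard_normal(rho.shape))
        traj.states.append(
            FieldState(
                t=float(t),
                rho=rho,
                S=sol.S_coeffs.S(z),
                N=np.interp(z, z_grid, N_frame),
            )
        )
    truth = {
        "sigma": sol.sigma,
        "lambda_back": sol.lambda_back,
        "lambda_front": sol.lambda_front,
        "rho_max": sol.rho_max,
        "asymmetry": sol.asymmetry,
        "u_S": true_params.u_S,
        "u_N": true_params.u_N,
        "alpha": true_params.alpha,
    }
    return traj, truth
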