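"""Stochastic run-and-tumble agents: the kinetic model made empirical.

Each agent runs at constant speed (velocity drawn from the two-point set
{-c, +c} or from the unit circle projected on the channel axis), and
tumbles -- redraws its velocity uniformly, independently of the old one --
at the state-dependent rate

    psi(v) = psi0 * (1 + eps_S phi(v dS/dx) + eps_N phi(v dN/dx))

so runs up a favourable gradient last longer.  Signals integrate linearly;
the nutrient bias amplitude is slaved to the macroscopic speed ratio,
``eps_N = eps_S * u_N / u_S``, which keeps the agent population and the
drift-diffusion solver describing the same physics.  Tumbles are scheduled
by per-step thinning (probability ``1 - exp(-rate dt)``), accurate for
``rate * dt <= 0.1`` (enforced).

In ``self_consistent`` coupling the chemical fields evolve on a grid by the
same semi-implicit reaction-diffusion steps as the macroscopic solver, with
the binned agent density (scaled to total mass M) as secretion/consumption
source.  In ``imposed_field`` coupling the fields are frozen -- the
configuration used to validate the drift-diffusion limit against the
closed-form diffusivity ``<v^2>/psi0`` and drift ``-eps <v phi(v g)>``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import (
    KineticParams,
    PhysicalParams,
    ResponseFunction,
    VelocitySet,
    evaluate_response,
)
from .pde import FieldState, Grid1D, Trajectory, update_chemicals
from .observables import refine_peak

__all__ = [
    "AgentEnsemble",
    "TumbleLog",
    "AgentRunResult",
    "tumble_rate",
    "simulate_agents",
    "tumbling_frequency_map",
]


@dataclass
class AgentEnsemble:
    """Positions (um) and axial velocities (um/s) of the agents at time t."""

    positions: np.ndarray
    velocities: np.ndarray
    t: float
    seed: int
    angles: np.ndarray | None = None  # unit_circle only

    def __post_init__(self) -> None:
        if self.positions.shape != self.velocities.shape:
            raise ValueError("positions and velocities must have the same shape")

    @property
    def n(self) -> int:
        return self.positions.size


@dataclass
class TumbleLog:
    """Position- and direction-binned tumbling statistics.

    ``events[i, d]`` counts tumbles in spatial bin i of agents moving left
    (d = 0) or right (d = 1); ``occupancy[i, d]`` is the corresponding
    agent-time (agent-seconds).  The empirical tumbling frequency is their
    ratio.  ``frame`` records whether positions are absolute ("lab") or
    relative to the instantaneous density peak ("pulse").
    """

    bin_edges: np.ndarray
    events: np.ndarray
    occupancy: np.ndarray
    psi0: float
    frame: str = "lab"

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def total_events(self) -> int:
        return int(self.events.sum())


@dataclass
class AgentRunResult:
    """Output bundle of :func:`simulate_agents`."""

    ensemble: AgentEnsemble
    tumble_log: TumbleLog
    density: Trajectory
    times: np.ndarray
    mean_displacement: np.ndarray
    msd: np.ndarray
    provenance: dict = field(default_factory=dict)


def tumble_rate(
    v,
    gradS,
    kin: KineticParams,
    phi: ResponseFunction,
    gradN=0.0,
    eps_N: float = 0.0,
):
    """Tumbling rate psi0 (1 + eps phi(v gS) + eps_N phi(v gN)) (1/s).

    Strictly positive whenever ``eps + eps_N < 1``; averaged over a
    symmetric velocity set at fixed gradient it equals psi0 (phi odd).
    """
    v = np.asarray(v, dtype=float)
    bias = kin.epsilon * np.asarray(evaluate_response(phi, v * gradS))
    if eps_N != 0.0:
        bias = bias + eps_N * np.asarray(evaluate_response(phi, v * np.asarray(gradN)))
    out = kin.psi0 * (1.0 + bias)
    return float(out) if out.ndim == 0 else out


def _draw_velocities(
    n: int, kin: KineticParams, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray | None]:
    if kin.velocity_set is VelocitySet.two_point:
        v = kin.c * rng.choice((-1.0, 1.0), size=n)
        return v, None
    theta = rng.uniform(0.0, 2.0 * math.pi, size=n)
    return kin.c * np.cos(theta), theta


def _sample_exponential_wall(
    n: int, decay_length: float, x0: float, x1: float, rng: np.random.Generator
) -> np.ndarray:
    x = x0 + rng.exponential(decay_length, size=n)
    while True:
        bad = x > x1
        n_bad = int(bad.sum())
        if n_bad == 0:
            return x
        x[bad] = x0 + rng.exponential(decay_length, size=n_bad)


def simulate_agents(
    n_agents: int,
    kin: KineticParams,
    params: PhysicalParams,
    grid: Grid1D,
    dt: float,
    T: float,
    seed: int,
    coupling: str = "self_consistent",
    phi: ResponseFunction | None = None,
    initial: str | AgentEnsemble = "wall",
    imposed: tuple[np.ndarray, np.ndarray] | None = None,
    cadence: float | None = None,
    log_frame: str = "lab",
    log_bin_width: float | None = None,
) -> AgentRunResult:
    """Run the agent simulator for time T.

    Parameters
    ----------
    coupling : "self_consistent" or "imposed_field"
        Whether S and N evolve with the binned agent density as source, or
        stay frozen at their initial (or ``imposed``) values.
    initial : "wall", "wave", or an AgentEnsemble
        "wall" samples positions from the left-wall exponential and sets
        S = 0, N = N0; "wave" samples the analytic traveling-pulse state
        centered at 0.3 L.
    imposed : optional (S, N) node arrays for imposed_field coupling.
    log_frame : "lab" or "pulse"
        Bin tumble events by absolute position, or by position relative to
        the instantaneous peak of the binned density (for pulse-frame
        tumbling-frequency maps).

    Reproducible: identical seeds give identical trajectories.
    """
    if n_agents < 100:
        raise ValueError("need at least 100 agents")
    if coupling not in ("self_consistent", "imposed_field"):
        raise ValueError(f"unknown coupling {coupling!r}")
    if phi is None:
        phi = ResponseFunction.from_delta(params.delta)
    eps_N = (
        kin.epsilon * params.u_N / params.u_S if params.u_N != 0.0 else 0.0
    )
    max_rate = kin.psi0 * (1.0 + kin.epsilon + abs(eps_N))
    if max_rate * dt > 0.1:
        raise ValueError(
            f"thinning accuracy requires max-rate * dt <= 0.1, got {max_rate * dt:.3g}"
        )

    rng = np.random.default_rng(seed)
    x_nodes = grid.x
    x_lo, x_hi = x_nodes[0], x_nodes[-1]
    dx = grid.dx

    # --- initial ensemble and fields -----------------------------------
    if isinstance(initial, AgentEnsemble):
        x = initial.positions.astype(float).copy()
        v = initial.velocities.astype(float).copy()
        theta = None if initial.angles is None else initial.angles.copy()
        S = np.zeros(grid.n) if imposed is None else imposed[0].astype(float).copy()
        N = (
            np.full(grid.n, params.N0)
            if imposed is None
            else imposed[1].astype(float).copy()
        )
    elif initial == "wall":
        x = _sample_exponential_wall(n_agents, 500.0, x_lo, x_hi, rng)
        v, theta = _draw_velocities(n_agents, kin, rng)
        S = np.zeros(grid.n)
        N = np.full(grid.n, params.N0)
    elif initial == "wave":
        from .wave import nutrient_profile_in_frame, solve_speed

        sol = solve_speed(params)
        center = x_lo + 0.3 * grid.length
        u = rng.random(n_agents)
        w_back = sol.lambda_front / (sol.lambda_back + sol.lambda_front)
        z = np.where(
            u < w_back,
            np.log(np.clip(u / w_back, 1e-300, None)) / sol.lambda_back,
            -np.log(np.clip((1.0 - u) / (1.0 - w_back), 1e-300, None))
            / sol.lambda_front,
        )
        x = np.clip(center + z, x_lo, x_hi)
        v, theta = _draw_velocities(n_agents, kin, rng)
        S = sol.S_coeffs.S(x_nodes - center)
        N = nutrient_profile_in_frame(params, sol, x_nodes - center)
    else:
        raise ValueError(f"unknown initial {initial!r}")
    if imposed is not None:
        S = imposed[0].astype(float).copy()
        N = imposed[1].astype(float).copy()

    x_init = x.copy()
    mass_per_agent = params.M / n_agents

    # --- logging setup -------------------------------------------------
    if log_bin_width is None:
        log_bin_width = 4.0 * dx
    if log_frame == "pulse":
        half = 0.5 * grid.length
        log_edges = np.arange(-half, half + log_bin_width, log_bin_width)
    elif log_frame == "lab":
        log_edges = np.arange(x_lo, x_hi + log_bin_width, log_bin_width)
    else:
        raise ValueError("log_frame must be 'lab' or 'pulse'")
    n_log_bins = len(log_edges) - 1
    events = np.zeros((n_log_bins, 2))
    occupancy = np.zeros((n_log_bins, 2))

    if cadence is None:
        cadence = max(dt, T / 50.0)
    snap_every = max(1, int(round(cadence / dt)))
    n_steps = int(round(T / dt))

    hist_edges = np.concatenate(([x_lo - 0.5 * dx], x_nodes + 0.5 * dx))

    def binned_density(xp: np.ndarray) -> np.ndarray:
        counts, _ = np.histogram(xp, bins=hist_edges)
        return counts * (mass_per_agent / dx)

    density = Trajectory(grid=grid, provenance={"kind": "agent_binned_density"})
    times = [0.0]
    mean_disp = [0.0]
    msd = [0.0]
    rho = binned_density(x)
    density.states.append(FieldState(t=0.0, rho=rho, S=S.copy(), N=N.copy()))

    def _reflect(x: np.ndarray, v: np.ndarray, theta) -> None:
        low = x < x_lo
        if low.any():
            x[low] = 2.0 * x_lo - x[low]
            v[low] = -v[low]
            if theta is not None:
                theta[low] = math.pi - theta[low]
        high = x > x_hi
        if high.any():
            x[high] = 2.0 * x_hi - x[high]
            v[high] = -v[high]
            if theta is not None:
                theta[high] = math.pi - theta[high]

    gradS = np.gradient(S, dx)
    gradN = np.gradient(N, dx)
    t = 0.0
    for istep in range(1, n_steps + 1):
        # perceived gradients and tumbling decision
        gS_a = np.interp(x, x_nodes, gradS)
        bias = kin.epsilon * np.asarray(evaluate_response(phi, v * gS_a))
        if eps_N != 0.0:
            gN_a = np.interp(x, x_nodes, gradN)
            bias = bias + eps_N * np.asarray(evaluate_response(phi, v * gN_a))
        rate = kin.psi0 * (1.0 + bias)
        tumbling = rng.random(x.size) < -np.expm1(-rate * dt)

        # occupancy (agent-seconds) by position bin and run direction
        peak_pos = 0.0
        if log_frame == "pulse":
            peak_pos, _, _ = refine_peak(x_nodes, rho)
        bins = np.clip(
            ((x - peak_pos - log_edges[0]) / log_bin_width).astype(int),
            0,
            n_log_bins - 1,
        )
        right = (v > 0).astype(int)
        np.add.at(occupancy, (bins, right), dt)

        # event-driven flight within the step: successive exponential
        # waiting times with velocity-dependent rates (gradients frozen at
        # the step-start position), iterated until the step is exhausted.
        # This samples the velocity-jump process exactly up to the O(dt)
        # spatial variation of the gradients over one step's flight.
        x[~tumbling] += v[~tumbling] * dt
        active = np.nonzero(tumbling)[0]
        if active.size:
            remaining = np.full(active.size, dt)
            r_act = rate[tumbling]
            # first tumble time, conditioned on falling inside the step
            tau = -np.log1p(rng.random(active.size) * np.expm1(-r_act * dt)) / r_act
            while active.size:
                x[active] += v[active] * tau
                remaining = remaining - tau
                # log every tumble event at its position, with the
                # pre-tumble run direction
                ev_bins = np.clip(
                    ((x[active] - peak_pos - log_edges[0]) / log_bin_width).astype(
                        int
                    ),
                    0,
                    n_log_bins - 1,
                )
                np.add.at(events, (ev_bins, (v[active] > 0).astype(int)), 1.0)
                v_new, th_new = _draw_velocities(active.size, kin, rng)
                v[active] = v_new
                if theta is not None:
                    theta[active] = th_new
                bias_a = kin.epsilon * np.asarray(
                    evaluate_response(phi, v_new * gS_a[active])
                )
                if eps_N != 0.0:
                    bias_a = bias_a + eps_N * np.asarray(
                        evaluate_response(phi, v_new * gN_a[active])
                    )
                r_act = kin.psi0 * (1.0 + bias_a)
                tau = rng.exponential(1.0, size=active.size) / r_act
                done = tau >= remaining
                if done.any():
                    x[active[done]] += v[active[done]] * remaining[done]
                    keep = ~done
                    active = active[keep]
                    remaining = remaining[keep]
                    tau = tau[keep]
                    r_act = r_act[keep]
        _reflect(x, v, theta)

        t = istep * dt
        rho = binned_density(x)
        if coupling == "self_consistent":
            S, N = update_chemicals(S, N, rho, params, dt, dx)
            gradS = np.gradient(S, dx)
            gradN = np.gradient(N, dx)

        if istep % snap_every == 0 or istep == n_steps:
            times.append(t)
            disp = x - x_init
            mean_disp.append(float(disp.mean()))
            msd.append(float((disp**2).mean()))
            density.states.append(FieldState(t=t, rho=rho, S=S.copy(), N=N.copy()))

    ensemble = AgentEnsemble(positions=x, velocities=v, t=t, seed=seed, angles=theta)
    log = TumbleLog(
        bin_edges=log_edges,
        events=events,
        occupancy=occupancy,
        psi0=kin.psi0,
        frame=log_frame,
    )
    return AgentRunResult(
        ensemble=ensemble,
        tumble_log=log,
        density=density,
        times=np.asarray(times),
        mean_displacement=np.asarray(mean_disp),
        msd=np.asarray(msd),
        provenance={
            "n_agents": n_agents,
            "dt": dt,
            "T": T,
            "seed": seed,
            "coupling": coupling,
            "eps_N": eps_N,
        },
    )


def tumbling_frequency_map(log: TumbleLog, min_occupancy: float = 0.0):
    """Relative tumbling frequencies by position bin and run direction.

    Returns a pandas DataFrame with, per bin: the empirical frequency of
    leftward- and rightward-movers normalized by the basal rate psi0
    (``rel_left``, ``rel_right``), the same normalized by the local mean
    rate over both directions (``relmean_left``, ``relmean_right``), and
    the occupancy.  Bins with occupancy at or below ``min_occupancy``
    agent-seconds are reported as NaN (missing), not zero.
    """
    import pandas as pd

    if log.total_events == 0:
        raise ValueError("empty tumble log")
    occ = log.occupancy
    ev = log.events
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(occ > min_occupancy, ev / np.where(occ > 0, occ, np.nan), np.nan)
        rel = freq / log.psi0
        local_mean = (ev.sum(axis=1)) / np.where(
            occ.sum(axis=1) > 0, occ.sum(axis=1), np.nan
        )
        relmean = freq / local_mean[:, None]
    return pd.DataFrame(
        {
            "position": log.bin_centers,
            "rel_left": rel[:, 0],
            "rel_right": rel[:, 1],
            "relmean_left": relmean[:, 0],
            "relmean_right": relmean[:, 1],
            "occupancy_left": occ[:, 0],
            "occupancy_right": occ[:, 1],
        }
    )
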