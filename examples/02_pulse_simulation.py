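"""Full macroscopic simulation: a pulse detaches from the wall and travels.

Integrates the coupled density/chemoattractant/nutrient system from the
centrifuged initial condition (cells piled at the left wall) with the
reference stiffness delta = 0.1, then measures speed and tail rates and
compares them with the analytic stiff-limit wave.
"""

from chemopulse import (
    Grid1D,
    ResponseFunction,
    fit_tails,
    reference_kinetics,
    reference_params,
    simulate,
    solve_speed,
    track_peak,
)

p = reference_params()
kin = reference_kinetics()
grid = Grid1D.for_channel(p.L, 1001)
phi = ResponseFunction.from_delta(p.delta)

print(f"integrating {grid.n} nodes for 2500 s (dt = 0.5 s) ...")
traj = simulate(p, kin, phi, grid, dt=0.5, T=2500.0, cadence=100.0)

track = track_peak(traj, window=(1000.0, 2500.0))
fit = fit_tails(traj.states[-1], grid)
sol = solve_speed(p)

print()
print(f"measured pulse speed   = {track.speed:.3f} um/s "
      f"(analytic {sol.sigma:.3f}, residual RMS {track.residual_rms:.1f} um)")
print(f"tail rate back/front   = {fit.lambda_back:.5f} / {fit.lambda_front:.5f} 1/um "
      f"(analytic {sol.lambda_back:.5f} / {sol.lambda_front:.5f})")
print(f"fit quality R^2        = {fit.r2_back:.4f} (back), {fit.r2_front:.4f} (front)")
print(f"mass conservation      = {traj.states[-1].mass(grid.dx) / p.M - 1:+.2e} relative")
print()
print("The pulse keeps a constant speed and an asymmetric two-sided")
print("exponential shape, steeper at the back -- the collective signature")
print("of run-and-tumble chemotaxis with a bounded flux.")
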