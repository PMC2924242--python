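"""Stationary clusters without nutrient, and when the uniform state clusters.

The zero-speed pulse (cluster) has width 2 D_rho / u_S independent of the
number of trapped cells.  For a smooth response the uniform state is
unstable below a critical stiffness delta_c: sensitive cells aggregate,
insensitive ones disperse.
"""

import numpy as np

from chemopulse import (
    cluster_profile,
    dispersion_curve,
    reference_kinetics,
    reference_params,
)

p = reference_params()
kin = reference_kinetics()

cl = cluster_profile(p)
print(f"cluster tail rate  = {cl.lam:.4f} 1/um")
print(f"cluster width      = {cl.width:.0f} um  (2 D_rho / u_S; mass-independent)")
print(f"peak density       = {cl.rho_max:.0f} cells/um at M = {p.M:.0e}")
print(f"  at 10x the mass the width is {cluster_profile(p.replace(M=10*p.M)).width:.0f} um")
print()

rho0 = p.M / p.L  # channel filled uniformly
disp = dispersion_curve(rho0, p, kin)
print(f"uniform state rho0 = {rho0:.1f} cells/um on a {p.L:.0f} um channel")
print(f"chemical range l_S = {disp.l_S:.0f} um")
print(f"critical stiffness delta_c = {disp.delta_c:.3f}")
print(f"  reference delta = {p.delta}  ->  "
      f"{'UNSTABLE: clusters form' if p.delta < disp.delta_c else 'stable: stays uniform'}")
print()
print("growth rate of the first channel modes (1/s):")
for k, r in zip(disp.wavenumbers[:6], disp.growth_rates[:6]):
    print(f"  k = {k:.5f} 1/um   rate = {r:+.3e}")
print("(k = 0 is the neutral mass mode; large k are damped by diffusion)")
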