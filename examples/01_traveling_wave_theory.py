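"""Analytic traveling-pulse theory on the reference parameter set.

Solves the stiff-limit wave: the speed selected by the condition that the
chemoattractant peak rides exactly on the density peak, the two exponential
tail rates, and the asymmetry factor.
"""

from chemopulse import reference_params, solve_speed

p = reference_params()
sol = solve_speed(p)

print("reference parameters:")
print(f"  u_S = {p.u_S} um/s (self-attraction), u_N = {p.u_N} um/s (nutrient pull)")
print(f"  alpha = {p.alpha} 1/s, D_S = {p.D_S} um^2/s, D_rho = {p.D_rho} um^2/s")
print()
print(f"pulse speed sigma        = {sol.sigma:.4f} um/s")
print(f"tail rate behind peak    = {sol.lambda_back:.4f} 1/um  (decay length {1/sol.lambda_back:.0f} um)")
print(f"tail rate ahead of peak  = {sol.lambda_front:.4f} 1/um  (decay length {1/sol.lambda_front:.0f} um)")
print(f"asymmetry (front/back)   = {sol.asymmetry:.4f}")
print(f"peak density             = {sol.rho_max:.1f} cells/um for M = {p.M:.0e} cells")
print()
print("The profile decays faster behind the peak than ahead of it (the")
print("experimentally observed asymmetry); the speed is independent of the")
print("cell number M and of the cell diffusivity D_rho:")
sol10 = solve_speed(p.replace(M=10 * p.M))
print(f"  sigma at 10x mass       = {sol10.sigma:.4f} um/s")
solD = solve_speed(p.replace(D_rho=3 * p.D_rho))
print(f"  sigma at 3x diffusivity = {solD.sigma:.4f} um/s")
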