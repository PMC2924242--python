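"""Reference parameter set used throughout the examples and tests.

The set mirrors a sealed PDMS/glass channel experiment with *E. coli*:
individual run speed ~25 um/s, basal tumbling ~2 /s, effective cell
diffusivity 300 um^2/s, molecular diffusivities 800 um^2/s, a centimetre-long
channel and ~1e5 cells.  The effective chemotaxis speeds and the
chemoattractant degradation rate are fixed the way they are obtained
experimentally: from the macroscopic observables of the traveling pulse
(speed sigma = 1.8 um/s, rear tail rate lambda_back = 0.012 /um, front tail
rate lambda_front = 0.008 /um) through the constitutive relations of the
stiff-response wave,

    u_S   = D_rho (lambda_back + lambda_front) / 2        = 3.0  um/s
    u_N   = sigma + D_rho (lambda_back - lambda_front)/2  = 2.4  um/s
    alpha = (s^2 - sigma^2) / (4 D_S),  s = sigma u_S / (u_N - sigma)
                                                          = 0.0243 /s

so the analytic wave speed of this set is exactly 1.8 um/s.  The secretion
rate ``beta`` sets the (arbitrary) concentration unit of S; it is chosen so
the perceived signal derivative ``c * d_x S`` across the pulse is of order
one, which places the stiffness values 1e-1 (clustering/pulse regime) and 10
(dispersal regime) on opposite sides of the response transition.  ``gamma``
is chosen, within the physically expected order of magnitude (nutrient
substantially consumed during one pulse passage), so that the three
collective regimes are realized at stiffness 1e-1: a single traveling pulse
at abundant nutrient (N0 = 1e3), and a trapped stationary cluster
coexisting with a smaller traveling pulse at low nutrient (N0 = 1e2).
"""

from __future__ import annotations

from .core import KineticParams, PhysicalParams, VelocitySet

__all__ = ["reference_params", "reference_kinetics"]


def reference_params(**overrides) -> PhysicalParams:
    """Reference macroscopic parameter set (see module docstring)."""
    base = dict(
        D_rho=300.0,   # um^2/s
        D_S=800.0,     # um^2/s
        D_N=800.0,     # um^2/s
        alpha=0.0243,  # 1/s
        beta=2.0e-3,   # conc um / s per cell
        gamma=4.0e-4,  # um / (cell s)
        u_S=3.0,       # um/s
        u_N=2.4,       # um/s
        delta=0.1,     # response stiffness
        M=1.0e5,       # cells
        L=1.0e4,       # um
        N0=1.0e3,      # arb. units
    )
    base.update(overrides)
    return PhysicalParams(**base)


def reference_kinetics(**overrides) -> KineticParams:
    """Kinetic parameters consistent with the macroscopic reference set.

    ``eps * c = u_S`` and ``c^2 / psi0 = D_rho`` hold exactly, so agent
    simulations and the macroscopic solver describe the same population.
    """
    base = dict(
        c=25.0,            # um/s
        psi0=25.0 / 12.0,  # 1/s  (c^2 / D_rho)
        epsilon=0.12,      # u_S / c
        velocity_set=VelocitySet.two_point,
    )
    base.update(overrides)
    return KineticParams(**base)
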