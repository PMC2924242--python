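# Methods

## Model and assumptions

The package describes a population of run-and-tumble bacteria in a sealed
1D channel by its density ρ(t,x), coupled to a self-secreted
chemoattractant S (secretion β per cell, degradation α, diffusion D_S) and
a consumed nutrient N (consumption −γρN, diffusion D_N). Cell division is
neglected (short experimental timescale), signal integration is linear (the
two chemical contributions to the tumbling bias add), and there is no
memory kernel: a cell reacts to the instantaneous directional derivative of
the signal along its trajectory, v·∂xS. The channel is sealed, so all
fields carry zero-flux boundaries and the total cell number M is conserved.

The tumbling rate is ψ0(1 + ε φ(v ∂xS) + ε_N φ(v ∂xN)) with φ odd,
decreasing, |φ| ≤ 1. Published variants of this rate differ by affine
conventions (a non-negative decreasing φ inside 1 ± εφ); any of them maps
onto ours by rescaling (ε, ψ0), and our normalization makes the positivity
condition simply ε + ε_N < 1. The smooth family is φ_δ(y) = −tanh(y/δ)
(slope −1/δ at the transition); δ = 0 is the step response −sign(y), with
φ(0) = 0 as the symmetric tie-break. In the drift–diffusion (parabolic)
limit — valid because the collective speed is an order of magnitude below
the individual speed — the macroscopic coefficients are D_ρ = ⟨v²⟩/ψ0 and
u(g) = −ε⟨v φ(v g)⟩_V, bounded by εc.

Two velocity sets are supported: the two-point set {−c, +c} (default; the
1D idealization) and the unit circle projected on the channel axis. All
qualitative conclusions are identical; only constants change (⟨v²⟩ = c² vs
c²/2, stiff drift εc vs εc·2/π).

In the macroscopic solver the drifts are written u_S·r(∂xS) + u_N·r(∂xN),
where r is the response normalized to saturate at ±1 (r = tanh(cg/δ) for
the two-point smooth case). u_S and u_N are free macroscopic parameters;
their kinetic consistency u = εc is *checked* in tests, not enforced, so
that estimated and literature values can be used directly.

## Reference parameter set

Units: µm, s, cells; chemical concentrations are arbitrary units.

| parameter | value | why |
|---|---|---|
| D_ρ | 300 µm²/s | effective diffusivity of swimming *E. coli* |
| D_S = D_N | 800 µm²/s | small-molecule diffusion in water |
| c | 25 µm/s | individual run speed |
| ψ0 | c²/D_ρ = 25/12 s⁻¹ | kinetic consistency with D_ρ |
| ε | u_S/c = 0.12 | kinetic consistency with u_S; "small bias" regime |
| u_S | 3.0 µm/s | from observables, see below |
| u_N | 2.4 µm/s | from observables, see below |
| α | 0.0243 s⁻¹ | from observables, see below; l_S = √(D_S/α) ≈ 181 µm |
| β | 2×10⁻³ conc·µm/s | sets the S unit so c·∂xS = O(1) across the pulse |
| γ | 4×10⁻⁴ µm/(cell·s) | see "regime calibration" below |
| δ | 0.1 | reference stiffness (effectively stiff at the pulse scales) |
| M | 10⁵ cells | typical pulse population; results are M-independent |
| L | 10⁴ µm | centimetre channel |
| N0 | 10³ (arb.) | abundant-nutrient condition |

u_S, u_N and α are not directly measurable; they are fixed the same way an
experiment fixes them — by inverting the macroscopic observables of the
pulse through the constitutive relations of the stiff wave. The observables
used are speed σ = 1.8 µm/s and tail rates λ₋ = 0.012 µm⁻¹ (back),
λ₊ = 0.008 µm⁻¹ (front): back steeper than front, decay lengths 83/125 µm,
a channel-scale pulse. The inversion (u_S = D_ρ(λ₋+λ₊)/2,
u_N = σ + D_ρ(λ₋−λ₊)/2, α from the wave-speed condition) gives the values
above exactly, so the analytic speed of the reference set is exactly
1.8 µm/s by construction and every simulated number can be referred to it.

Regime calibration: β and γ only enter the dynamics through the *scale* of
the perceived signal derivatives relative to δ (in the strict stiff limit
they drop out entirely). β is chosen so the chemoattractant argument
c·∂xS is O(1) at the pulse, which places δ = 0.1 and δ = 10 on the stiff
and smooth sides of the response — the clustering vs dispersal dichotomy.
γ is chosen, once, inside its physical order of magnitude (nutrient
substantially consumed during one pulse passage) such that the three
collective regimes occur at their nominal conditions: a single persistent
pulse at (δ=0.1, N0=10³), dispersal at δ=10, and a population split —
trapped stationary cluster plus smaller traveling pulse — at (δ=0.1,
N0=10²). The split mechanism is a finite-stiffness effect: where nutrient
is deeply depleted the argument c·∂xN falls below the response threshold
and the forward pull disengages; lowering N0 by 10× moves that
disengagement boundary forward past a large part of the initial pile.

A consequence worth knowing: with a *pure* step response (δ = 0) the
wall-attached initial pile never detaches — sign(∂xN) = +1 gives a uniform
pull u_N < u_S that cannot beat the self-attraction, so the wall cluster is
an exact steady state. The finite threshold of δ = 0.1 is what lets the
pulse escape. Stiff-limit (δ = 0) runs are therefore validated as
*translation* tests initialized from the analytic wave, while the
detachment scenario always uses δ = 0.1.

## Traveling-wave machinery

In the wave frame the density equation integrates once to the two-sided
exponential with rates λ₋ = (u_S+u_N−σ)/D_ρ, λ₊ = (u_S−u_N+σ)/D_ρ. The
chemoattractant profile solves −D_S S″ − σS′ + αS = βρ(z); we assemble the
bounded C¹ solution from the two decaying homogeneous roots μ± and
piecewise particular solutions, guarding the (measure-zero) resonance
λ = μ with a 1e−9 relative perturbation and a warning. The speed residual
is S′(0); its root — found by bracketed root-finding (Brent) on
(u_N−u_S, u_N+u_S) to 1e−12 relative — is the selected speed. The residual
is proportional to ρ_max, hence the root is independent of M; eliminating
the rates shows it is also independent of D_ρ and satisfies
σ(u_S+s) = u_N s with s = √(σ²+4D_Sα), which the test suite uses as an
independent oracle for the constructive implementation. The raw residual
is *not* monotone in σ (it carries a positive σ-dependent amplitude), but
its sign changes exactly once on the bracket, which is what uniqueness
requires; the property test asserts precisely that. Signed u_N is
accepted (the pulse then travels left, mirror-symmetrically).

Cluster solutions are the σ = 0, u_N = 0 case: rate u_S/D_ρ, width
2D_ρ/u_S, peak Mλ/2, all mass-independent. The wave-frame nutrient profile
(needed for initializing translation tests and agent runs) solves the
linear ODE D_N N″ + σN′ = γρN numerically on a tridiagonal stencil with
N′ = 0 behind and N = N0 ahead.

## Macroscopic solver

Operator splitting, first order in time: (1) explicit advection of ρ by
the total drift evaluated at half-nodes from one-sided gradients;
(2) implicit cell diffusion; (3) chemoattractant: implicit diffusion +
implicit decay with explicit secretion source; (4) nutrient: implicit
diffusion + pointwise-implicit consumption (keeps N ≥ 0). All implicit
stages are tridiagonal solves in flux form with zero column sums, so the
discrete cell mass is conserved to roundoff (measured drift ~1e−12
relative over 10⁴ steps). The only stability restriction is the advection
CFL max|u|·dt ≤ dx (checked every step); since the drift is bounded by
u_S+|u_N|, the default dt is 0.4× that bound.

Advection uses minmod-limited second-order upwind reconstruction rather
than plain donor-cell. The reason is specific to this problem: the drift
magnitude differs strongly between the two sides of the peak (u_S+u_N
behind vs u_S−u_N ahead), so first-order numerical diffusion is strongly
asymmetric and measurably distorts the profile and speed (3–8% speed bias
at 5–10 µm resolution); the limited scheme removes most of it while
remaining monotone and positivity-preserving at the enforced CFL. Measured
bias of the stiff translation test at dx = 5 µm, dt = 0.25 s is below 1%
for pulses whose shorter tail spans ≳ 15 cells; the oracle-equivalence
checks use parameter sets in that resolved regime, and the reference
wall-IC run changes by < 1% under halving dx and dt.

Standard resolutions used throughout tests and the acceptance script:
n = 1001–2001 nodes on the 10⁴ µm channel (dx = 10/5 µm), dt = 0.5/0.25 s,
horizons 600–3000 s; each such run takes seconds, chosen so the entire
suite completes in minutes on one core.

## Agent simulator

Agents carry positions and velocities from the chosen velocity set. Each
step: gradients are sampled at agent positions by linear interpolation of
the node-centered gradient; agents flagged by thinning
(p = 1−exp(−rate·dt), validity rate·dt ≤ 0.1 enforced) perform
*event-driven* tumbling inside the step — successive exponential waiting
times with velocity-dependent rates, gradients frozen at the step start —
which samples the velocity-jump process exactly up to the O(dt) spatial
variation of the gradients over one step's flight (≤ 1 µm at the default
dt = 0.035 s). Plain one-tumble-per-step thinning was measured to bias the
stationary drift by ψ0·dt/2 (≈ 4% at practical dt, matching the analytic
value for the discretized two-state chain) and is therefore not used.
Walls reflect position and reverse the axial velocity. The nutrient bias
amplitude is slaved to the macroscopic ratio, ε_N = ε·u_N/u_S, keeping
agents and PDE consistent by construction.

In self-consistent coupling, S and N evolve on the grid with the binned
agent density (scaled to mass M) as source, reusing the macroscopic
solver's reaction–diffusion stages. Tumble events and direction-resolved
occupancy are accumulated in position bins, either in the lab frame or
relative to the instantaneous density peak ("pulse" frame, used for
tumbling-frequency maps); empirical frequencies are reported normalized by
ψ0 and by the local mean rate, and empty bins are NaN, not zero. Runs are
reproducible given the seed.

## Linear stability

Around the uniform state ρ0 with a smooth response, the drift is linear
with slope χ = ε⟨v²⟩/δ (where the model coincides with Keller–Segel).
Treating S as quasi-steady on the slow cell timescale (rate separation
≈ 40× at the parameters used; the seeded-mode PDE check agrees within 10%)
gives the growth rate of the zero-flux channel mode cos(kx):

    rate(k) = −D_ρ k² + χ ρ0 β k² / (D_S k² + α).

k = 0 is neutral (mass conservation); the most unstable admissible mode is
k₁ = π/L; the critical stiffness δ_c solves rate(k₁) = 0, is found by
bracketed root-finding (monotone in δ), scales linearly in ρ0 and
decreases with α. The stability of the *nonlinear* cluster state is not
analysed; the package provides numerical evidence only (relaxation tests).

## Observables and estimation

Peak positions are grid argmax refined by 3-point quadratic interpolation;
speed is ordinary least squares on (t, position); peaks on the boundary
are flagged as "not yet detached". Tail rates are log-linear fits on each
side over the window where ρ ∈ [10%, 60%] of the peak — close enough to
dominate any noise floor, far enough to avoid peak curvature — with R²
reported per side. Inversion: u_S = D_ρ(λ₋+λ₊)/2, u_N = σ + D_ρ(λ₋−λ₊)/2;
α is recovered as the root in α of the wave-frame speed residual at the
observed σ, scanned over a log grid (bracket reported if no sign change).

Synthetic fixtures sample the analytic wave (profile + speed) on a grid at
several times with seeded multiplicative log-normal noise ρ·exp(ηZ), a
fluorescence-like noise model. They emulate the *shape and kinematics* of
a clean detached pulse; they do not emulate detachment transients, camera
background, bleaching drift, or spatially correlated noise, so estimator
performance on fixtures bounds, but does not guarantee, performance on raw
experimental movies. Noiseless fixtures round-trip the generating
(u_S, u_N, α) to ~1e−15; at 5% noise the u_S error is ≈1% on average over
20 seeds.

## Known limitations

- 1D only; no channel cross-section effects, no hydrodynamic interactions.
- First-order-in-time splitting; the limiter makes advection second order
  in space but the scheme is not formally second order overall.
- The smooth-response traveling wave has no closed form; it is reached
  only numerically.
- Internal signalling (CheY dynamics, receptor competition, adaptation
  memory) is outside the model: stiffness δ is a phenomenological stand-in
  for the cell's response sharpness.
- The trapped-fraction boundary in the low-nutrient split regime is a
  threshold phenomenon and is sensitive to β, γ and the initial pile
  width; the package fixes one representative calibration.
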