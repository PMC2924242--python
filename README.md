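# chemopulse

Traveling pulses of chemotactic bacteria: a kinetic-derived macroscopic
model, its analytic wave theory, and a run-and-tumble agent validator.

## The problem

Suspensions of motile *E. coli* confined in a sealed microchannel and
centrifuged to one end form a sharp concentration pulse that travels down
the channel at constant speed with a remarkably conserved, asymmetric
profile — steeper behind the peak than ahead of it. Classical Keller–Segel
descriptions struggle here: their chemotactic flux grows without bound with
the chemical gradient, which promotes blow-up instead of stable pulses.

`chemopulse` implements an alternative macroscopic description whose
chemotactic flux is *derived* from the individual run-and-tumble process
and is therefore bounded by the cells' own swimming speed. The package is
for modellers of bacterial collective motion who want to simulate the
system, compare against the closed-form wave theory, check the macroscopic
limit against stochastic agents, and invert measured pulse observables into
microscopic parameters.

## The model

Cell density ρ(t,x), self-secreted chemoattractant S and consumed nutrient
N on a 1D channel:

    ∂t ρ = ∂x ( D_ρ ∂x ρ − ρ [u_S(∂x S) + u_N(∂x N)] )
    ∂t S = D_S ∂xx S + β ρ − α S
    ∂t N = D_N ∂xx N − γ ρ N

Individual cells run at speed c and tumble at rate
ψ0 (1 + ε φ(v ∂x S)), with φ odd, decreasing, |φ| ≤ 1 (smooth family
φ_δ(y) = −tanh(y/δ); δ → 0 is the step response). The parabolic
(drift–diffusion) limit of this velocity-jump process gives

    D_ρ = ⟨v²⟩/ψ0,   u(g) = −ε ⟨v φ(v g)⟩_V,   |u| ≤ ε c.

For a step response the drifts saturate at ±u_S, ±u_N and the traveling
pulse is solvable in closed form in the wave frame z = x − σt:

    ρ(z) = ρ_max · exp(λ₋ z)  (z<0),  ρ_max · exp(−λ₊ z)  (z>0),
    λ₋ = (u_S + u_N − σ)/D_ρ,   λ₊ = (u_S − u_N + σ)/D_ρ,

with the speed σ selected by the condition that the chemoattractant peak
rides exactly on the density peak (S′(0) = 0), equivalent to

    σ (u_S + s) = u_N s,   s = √(σ² + 4 D_S α).

σ is independent of the cell number M and of D_ρ; the asymmetry factor is
λ₊/λ₋ = (s − σ)/(s + σ). Without nutrient the same theory gives stationary
clusters of width 2 D_ρ/u_S, independent of M, and a linear-stability
threshold δ_c in the response stiffness below which a uniform population
aggregates.

## Worked example

```
$ python examples/01_traveling_wave_theory.py
pulse speed sigma        = 1.8000 um/s
tail rate behind peak    = 0.0120 1/um  (decay length 83 um)
tail rate ahead of peak  = 0.0080 1/um  (decay length 125 um)
asymmetry (front/back)   = 0.6667
peak density             = 480.0 cells/um for M = 1e+05 cells
  sigma at 10x mass       = 1.8000 um/s
  sigma at 3x diffusivity = 1.8000 um/s
```

The reference parameter set travels at 1.8 µm/s with a back decay length of
83 µm against 125 µm at the front — the observed back-steep asymmetry — and
the speed is insensitive to how many cells ride the pulse. Running the full
PDE from the centrifuged initial condition reproduces this from raw
dynamics:

```
$ python examples/02_pulse_simulation.py
measured pulse speed   = 1.753 um/s (analytic 1.800, residual RMS 0.9 um)
tail rate back/front   = 0.01096 / 0.00780 1/um (analytic 0.01200 / 0.00800)
mass conservation      = -3.83e-13 relative
```

and the stochastic agents close the loop on the kinetic side:

```
$ python examples/04_run_and_tumble_agents.py
1. diffusivity: measured 298 um^2/s, theory <v^2>/psi0 = 300 um^2/s
2. drift in gradient 0.02: measured 2.97 um/s, flux formula 3.00 um/s
3. ... binned agent density travels at 1.81 um/s, macroscopic sigma = 1.80 um/s
```

The other examples cover cluster formation and the stiffness threshold
(`03`) and parameter estimation from noisy profiles (`05`). A thin CLI
(`chemopulse simulate|wave-speed|stability|agents|estimate|fixtures`)
exposes the same pipelines for shell use; see `--help`.

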