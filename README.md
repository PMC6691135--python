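# spinedyn

Spatio-temporal dynamics of second messengers (Ca²⁺, IP₃, cAMP) in
idealized dendritic-spine geometries with an internal spine apparatus.

Dendritic spines are sub-micron signaling compartments whose shape — and
the shape and size of the endoplasmic-reticulum organelle inside them (the
spine apparatus, SA) — shapes how fast a pulse of second messenger
localizes and homogenizes. `spinedyn` simulates the reaction–diffusion
dynamics of a messenger concentration C(**x**, t),

    ∂C/∂t + C/τ = D ∇²C            (linear degradation), or
    ∂C/∂t + V_max·C/(K_M + C) = D ∇²C   (Michaelis–Menten),

inside spherical shells, oblate spheroidal shells and mushroom-like heads,
driven by time-dependent membrane fluxes:

- plasma membrane (PM): a biexponential pulse
  `J_PM(t) = |γ|(e^(−t/α) − e^(−t/β))`,
- spine-apparatus membrane (ER): a delayed, scaled copy
  `J_ER(t) = ζ·J_PM(t − t_ER)`,
- spine neck: a concentration-proportional (Robin) outlet
  `J_N = K_N·C` on a small cap opposite the pole,
- optional localization of the PM influx to a PSD-like pole cap, a side
  band, or anti-periodic influx/efflux caps.

From the solved field it computes the gradient magnitude ‖∇C‖, the extent
of gradient `Ψ(t) = ‖∇C‖_mean(t) / max_t ‖∇C‖_mean`, and the gradient
lifetime `τ_Ψ` — the time from which Ψ stays below a threshold (default
25%), i.e. when the spine has become well mixed — plus the pure-diffusion
estimate `τ_theory = L²/6D` with `L = πR_o√((e_o² + ρ²)/2)`.

All geometries are axisymmetric: domains are meshed in the meridian
half-plane and solved with P1 finite elements under the 2πr revolution
weight (backward Euler in time, per-step mass-balance accounting).
Semi-analytical eigenfunction solutions (spherical-Bessel / Legendre
modes) for the uniformly driven shell and the anti-periodic solid sphere
serve as independent correctness oracles for the numerical solvers.

## Worked example

Pole-localized (PSD-like) influx into a spheroidal head with a large spine
apparatus (ρ=0.9, e_o=0.8, e_i=0.1, R_o=250 nm, D=10 µm²/s, τ=50 ms,
K_N=1 µm/s):

```sh
$ spinedyn simulate --preset pole_influx
{
  "tau_psi_ms": 27.763350307025767,
  "tau_theory_ms": 7.453607490406028,
  "psi_threshold": 0.25,
  "grad_mean_peak_uM_per_um": 1.1534499709985132e-06,
  "mass_residual_max": 7.882073785711275e-13
}
```

The concentration gradient created by the synaptic pulse (and re-created
by the delayed ER release at t_ER = 20 ms) persists for ≈28 ms — nearly
4× the bare diffusion estimate — because the large spine apparatus acts
as a diffusion barrier between the pole and the neck. The mass-balance
residual confirms discrete conservation to solver roundoff. The same run
is two library calls:

```python
from spinedyn import preset, run_scenario
solution, metrics = run_scenario(preset("pole_influx"))
print(metrics.summary())
```

Eigenvalues of the uniformly driven shell (dimensionless roots of the
transcendental characteristic function, here for ρ = 0.5):

```sh
$ spinedyn eigen --rho 0.5 --n 4
{
  "rho": 0.5,
  "roots_dimensionless": [6.572013199016393, 12.721356347418018,
                          18.954392095852526, 25.211779236236573],
  "tolerance": 1e-09
}
```

Config-driven runs (`spinedyn simulate --config scenario.yaml`) accept
blocks `geometry`, `layout`, `flux`, `kinetics`, `solver`, `metrics`,
`output`; `spinedyn sweep --config sweep.yaml` executes geometry grids and
writes a long-format lifetime table (CSV) with per-run error codes and a
resume cache. See `docs/methods.md` for the model, parameter meanings,
defaults and numerical choices.

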