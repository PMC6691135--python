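# Model and methods

## The physical model

A single diffusible second messenger with concentration C(**x**, t) (µM)
evolves in the spine-head cytosol according to

    ∂C/∂t + f(C) = D ∇²C,

where D is the diffusion coefficient and f(C) a cytosolic sink that lumps
buffering/degradation: linear, f = C/τ, or saturating Michaelis–Menten,
f = V_max·C/(K_M + C) with the convention V_max = C_ref/τ so both kinds
share the same time constant at a reference concentration C_ref. The
domain is the volume between the plasma membrane (PM, outer boundary) and
the spine-apparatus membrane (ER, inner boundary); the spine neck is not
resolved geometrically but represented as an outlet boundary condition on
a small cap of the outer membrane opposite the pole.

Boundary conditions (all fluxes positive when mass enters the cytosol,
at both membranes):

- PM influx `J_PM(t) = |γ|(e^(−t/α) − e^(−t/β))`, a biexponential pulse
  standing in for receptor/channel activity after a synaptic event;
- ER influx `J_ER(t) = ζ·J_PM(t − t_ER)`, clamped to zero before the
  delay t_ER (the biexponential diverges for negative arguments, and
  causality demands the clamp);
- neck outlet `J_N = K_N·C|_neck` (Robin), with K_N a velocity;
- zero flux on the remaining outer membrane when the influx is localized.

Spatial localization options for the PM influx: the whole membrane
(optionally minus the neck cap), a PSD-like polar cap, a band on the side
of the head, or anti-periodic caps (influx +J_PM at the top cap,
prescribed efflux −J_PM at the antipodal cap) used in the semi-analytical
sphere analysis.

### Geometries

All domains are solids of revolution about the z-axis:

- `sphere_shell`: concentric spheres R_i = ρ·R_o;
- `oblate_shell`: outer spheroid with semi-axes (a_o, b_o = e_o·a_o),
  inner spheroid (a_i = ρ·a_o, b_i = e_i·a_i); an eccentricity of 1 is a
  sphere, small values flatten the body;
- `mushroom`: the oblate shell minus its intersection with a flat
  spheroid centered at (0, b_o) with semi-axes (a_o, b_o/10), which caves
  in the top of the head;
- `sphere_solid`: a full sphere (no spine apparatus).

Validity requires the inner spheroid strictly inside the outer
(e_i·ρ < e_o, positive gap everywhere; a gap under 10⁻³·R_o — sub-nanometer
at physiological sizes — counts as degenerate), and the mushroom cut must
not reach the inner spheroid (b_i < 0.9·b_o). Sweep grids may contain
invalid combinations; they are reported with error codes, never silently
dropped.

## Parameters, units, defaults

Canonical internal units are µm, ms, µM; configs accept the literature
units (D in µm²/s, K_N in µm/s) and convert at the boundary of the
package (D = 10 µm²/s ≡ 0.01 µm²/ms).

| parameter | meaning | default |
|---|---|---|
| R_o (= a_o) | outer radius / major semi-axis | 0.25 µm |
| ρ, e_i, e_o | SA size ratio, inner/outer eccentricity | scenario-specific |
| D | diffusion coefficient | 10 µm²/s (crowded cytosol) |
| τ | linear decay constant | 50 ms |
| α, β | flux pulse time constants | 2.5 ms, 2 ms |
| \|γ\| | flux amplitude | 1.14×10⁻⁶ µM·µm/ms |
| ζ | ER/PM amplitude ratio | 0.2 |
| t_ER | ER release delay | 20 ms |
| K_N | neck outlet velocity | 1 µm/s |
| cap diameters | PSD / neck chord diameter | 0.2 µm at R_o = 0.25 µm |
| Ψ_th | gradient-lifetime threshold | 25% |
| C_ref, K_M | MM reference peak and constant | 4 µM, 2 µM |

Membrane patch sizes are specified by chord diameter (the rim circle of
the cap) and converted internally to polar-angle extents; the side band
is specified by its center polar angle (default π/3) and meridian arc
length. Because PSD area scales with head size, cap diameters default to
0.2 µm × (R_o / 0.25 µm) when the head is scaled; explicit values
override this. Under linear kinetics every reported metric (Ψ, τ_Ψ) is
invariant to |γ| (verified to machine precision in the tests), so the
amplitude only matters for Michaelis–Menten runs, where the comparison
preset raises |γ| until peak concentrations reach the µM range that
actually exercises the saturation.

## Numerical solvers

**Axisymmetric finite elements.** The meridian half-plane is meshed by a
structured ray construction (all supported domains are star-shaped about
the origin): n_φ+1 polar angles × n_s+1 points from the inner to the
outer boundary, split into triangles, with boundary facets tagged
{PM_influx, PM_efflux, PM_neck, PM_inert, ER, axis}. P1 elements are
assembled with the 2πr revolution weight (exact integration of the
linear-in-r factor); the Robin outlet contributes a boundary mass matrix,
the symmetry axis carries the natural zero-flux condition. Time stepping
is backward Euler with a lumped (row-sum) mass matrix; the system matrix
is constant and factorized once per run. The Michaelis–Menten sink is
evaluated lagged (previous step) — at the default Δt = 0.05 ms the sink
time scales (≥ 25 ms) are resolved by three orders of magnitude.
Defaults: n_s = 16 (≥ 10 elements across the thinnest gap in the standard
scenarios), n_φ = 96, Δt = 0.05 ms, horizon T = 100 ms — these resolve
the pulse constants (2–2.5 ms) and the lifetime scales (8–45 ms); the
reported lifetimes change by well under 1% when mesh and step are halved.

**Radial scheme.** For the uniformly driven spherical shell a 1D P1
scheme on [R_i, R_o] with the r² weight provides an independent fast
solver; it agrees with the 2D solver to ~0.01% and with the eigenfunction
series to ~0.2% relative L2.

**Mass balance.** Every step records the residual of
d/dt∫C dV = ∮J dA − ∮K_N C dA − ∫f(C) dV in the discrete quadrature;
because load, Robin and sink terms use the same quadrature as the mass
matrix the residual is solver roundoff (~10⁻¹²).

**Negativity gate.** Concentrations are asserted non-negative rather than
clipped (clipping would hide flux-sign errors). Sharply localized influx
on anisotropic mapped cells produces benign P1 undershoots up to ~10⁻⁴ of
the eventual peak in the earliest frames, so the gate is relative: abort
if C < −5×10⁻² of the running maximum during the run or below −5×10⁻⁴ of
the global maximum at the end. A sign error drives C negative at order
one and is caught by either gate. The anti-periodic configuration
legitimately produces negative (relative) concentrations and is exempt.

## Semi-analytical series solutions

Two configurations admit eigenfunction expansions used as oracles.

**Uniformly driven shell.** With a reference function w(r, t) — quadratic
in r, constructed directly from the two boundary-derivative conditions
D∂w/∂r|_{R_o} = +J_PM and D∂w/∂r|_{R_i} = −J_ER (the sign at the inner
membrane follows from the outward normal pointing into the organelle) —
the remainder v = C − w satisfies homogeneous Neumann conditions and is
expanded in radial modes u_n(r) = α_n j₀(k_n r) + β_n y₀(k_n r). The
dimensionless wavenumbers λ_D = k R_o are the roots of

    p(λ_D) = (λ_D²ρ + 1)·sin(λ_D(1−ρ)) + λ_D(ρ−1)·cos(λ_D(1−ρ)),

found by scanning with half the asymptotic spacing π/(1−ρ) (guaranteeing
a sign-change bracket for every root; p has a triple zero at the origin,
so the scan starts just above it) and polishing with Brent's method.
Projections use the r² Sturm–Liouville weight of the spherical radial
operator, under which the combined modes are orthogonal (j₀ and y₀
separately are not), and the source projections are evaluated through
Green's identity, which converts the Laplacian term into boundary-flux
values. Coefficients obey Ṫ_n + (Dk_n² + 1/τ)T_n = q_n(t) and are
integrated exactly per grid interval with an exponential-trapezoid rule
(q piecewise-linear; robust at the t_ER kink). The λ=0 constant mode is
tracked separately.

**Anti-periodic solid sphere.** Modes j_m(k_mn r)·P_m(cos φ) with odd
Legendre order m (the anti-symmetric boundary data project onto odd
orders only) and radial wavenumbers at the roots of dj_m/dx. The
coefficient ODEs are driven by the boundary-flux projection
q_mn ∝ J_PM(t)·j_m(x_mn)·∫_{cos φ₀}^1 P_m dx, with the Legendre cap
integral in closed form. The rectangle-function reference profile of this
configuration is discontinuous in φ at interior points, so the
concentration is reconstructed by direct modal projection of C itself —
identical in exact arithmetic, but the L2-optimal truncation, free of
Gibbs oscillation. At 21 odd orders × 16 radial roots the series agrees
with the finite-element solution to ~1.3% relative L2 (the residual is
dominated by the FEM discretization of the cap edges).

## Gradient metrics

`grad_mean(t)` is the volume-weighted average of the per-cell gradient
magnitude, using the same quadrature as the solver. Ψ(t) normalizes it by
its own temporal peak, per run — each run's Ψ therefore peaks at exactly
1, and normalization is not shared across sweep members. τ_Ψ is read as
the **final** down-crossing of Ψ_th after the global peak, linearly
interpolated between frames: the delayed ER release routinely pushes Ψ
back above threshold near t_ER + 2 ms, and the lifetime should report
when the spine is well mixed *for good*. For single-transient histories
this reduces to the first post-peak crossing. If Ψ ends the horizon above
threshold the lifetime is a NaN sentinel with a warning to extend T.

`τ_theory = L²/6D` with L = πR_o√((e_o²+ρ²)/2) (the semi-perimeter of the
ellipse spanning the inner major and outer minor semi-axes) is the bare
diffusion estimate; simulated lifetimes exceed it because they
additionally carry the flux time constants, their localization and the
decay kinetics.

### What the lifetime does and does not measure

Two regimes emerged clearly from the simulations. (1) When no late
transient re-crosses the threshold, τ_Ψ is floored by the flux envelope:
the biexponential pulse itself falls below 25% of its peak near 8 ms,
and with D = 10 µm²/s every geometric relaxation mode in a 0.5 µm head
decays in 3–6 ms, so uniform-influx lifetimes cluster at 8.6–10 ms
across the whole (ρ, e_o) plane. (2) When the delayed ER transient (or a
localized influx interacting with the SA barrier) lifts Ψ above
threshold again, the lifetime jumps to the decay of that second
transient, 25–37 ms. The boundary between the regimes is controlled by
the ER/PM amplitude ratio ζ: at the default ζ = 0.2 the uniform-influx
resurgence peaks at ~0.15 of the global maximum and regime (2) is
reached only by localized influx or thin-gap geometries. Reported
lifetimes should therefore be read together with the Ψ(t) history, which
the metrics CSV always contains.

## Workflow and reproducibility

`run_scenario` validates the config (all problems reported at once),
meshes, solves, computes metrics, and writes metrics CSV + summary JSON +
a manifest with a config hash and version. `run_sweep` executes geometry
grids, records one row per combination with an error code
(ok / not_reached / invalid_geometry / error) and caches completed rows
by config hash for resumability. `compare_kinetics` pairs linear and
Michaelis–Menten runs on the identical mesh and time grid and reports the
maximum relative divergence of the mean-concentration trajectories before
and after 10 ms. There is no randomness anywhere; identical configs give
bitwise-identical outputs.

Sweep grids in the acceptance script use 3 points per axis
(3×3×3 with invalid combinations skipped), which keeps the full
recomputation around a minute on one CPU; grid densities are free
parameters of `SweepSpec` for denser surfaces.

## Known limitations

- Idealized geometries only; no reconstructed spine meshes, no resolved
  neck, no non-axisymmetric boundary data (the "side" influx is an
  axisymmetric band, the closest revolution-symmetric analogue of a
  lateral PSD patch).
- The flux laws are phenomenological envelopes, not mechanistic channel
  or pump models; buffering is lumped into τ.
- Oblate-spheroidal wave functions are not evaluated explicitly;
  spheroidal geometries are validated numerically against the radial and
  sphere oracles plus conservation/invariance properties.
- First-order time stepping: accuracy is gained by step refinement, and
  reported lifetimes should be checked with a halved Δt when configs
  leave the tested regime (a 2% τ_Ψ drift under halving is the accuracy
  gate used here).
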