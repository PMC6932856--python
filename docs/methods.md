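# Methods

## Scope and model

`ventriflow` simulates the blood flow inside a beating left ventricle (LV)
with a flow-driven mitral valve (MV), and quantifies mitral regurgitation
and blood washout.  The pipeline couples four models:

1. **Prescribed ventricular kinematics.**  The endocardium is a closed
   parametric surface X(θ, s, t) whose enclosed volume follows a prescribed
   physiological waveform V(t).  Wall motion is an input, not an output:
   the solver answers how blood moves inside a ventricle whose contraction
   pattern is given.
2. **Incompressible Navier–Stokes** (ν = 0.04 cm²/s, Newtonian blood) on a
   fixed staggered Cartesian grid, with the moving surfaces imposed by a
   cut-cell immersed-boundary method: every cell crossed by a surface is an
   impermeable no-slip element carrying the local surface velocity.
3. **Asymptotic two-degree-of-freedom valve dynamics.**  Each MV leaflet has
   one opening angle φᵢ ∈ [0, π/2] interpolating between imaged-like closed
   and open configurations.  The angle rates minimize, in the least-squares
   sense over the leaflet surfaces, the mismatch between fluid and valve
   normal velocity, giving a 2×2 linear system M φ̇ = b per step.  The model
   carries no tissue elasticity; the chordae are replaced by the constraint
   that the valve cannot open toward the atrium (clamp at φ = 0).
4. **Passive-scalar transit tracking.**  A concentration C ∈ [0, 1] marks
   blood present in the LV at end systole; its advection-diffusion
   (Schmidt number 1 by default) yields the residual volume and the
   old-blood fraction of the regurgitant jet.

Units are cm / s / cm³ throughout (1 ml = 1 cm³).

## Synthetic geometry

No clinical meshes ship with the package; the generator emulates the study
conditions:

* **LV presets.**  Truncated prolate spheroid, long axis along z, base at
  high z.  `healthy`: EDV 113.47, ESV 46.52 cm³ (EF 59 %); `dilated`:
  EDV 199.31, ESV 142.50 cm³ (EF 29 %).  A single amplitude α(t) drives the
  deformation: the short semi-axes contract with a weight tanh(3s) that
  vanishes on the annulus ring (which therefore stays exactly stationary —
  a deliberate simplification that keeps the basal measurement plane fixed)
  and the long axis shortens with a 10 % gain.  α is calibrated sample-by-
  sample against the discrete surface-quadrature volume (Brent root find,
  1e-12 tolerance) and interpolated by a periodic cubic spline, so node
  velocities are analytic and the cavity volume tracks V(t) to ~1e-5·SV.
* **Volume waveform.**  Period 1 s; a single raised-cosine systolic
  ejection of 0.35 s; diastole split into an E-wave (0.25 s) and an A-wave
  (0.15 s) raised cosine carrying the stroke volume 2:1, with a diastasis
  between them.  Systole is defined as the contiguous window with dV/dt < 0.
* **MV presets.**  Two independent leaflets (anterior/posterior) spanning a
  circular annulus in the basal plane; annulus areas 6.20 / 4.83 /
  4.26 cm² for `healthy` / `P3like` / `P2like`.  The closed state coapts
  along a commissure-to-commissure curve sagging 0.55 cm below the annulus.
  A coaptation defect of adjustable `severity` retracts the posterior free
  edge toward its annulus and lifts it toward the atrium over one scallop:
  central for P2like, posteromedial for P3like, and a broad shallow slit
  for the healthy preset (physiological valves close with ~1 % residual
  orifice).  The defect is deliberately compact and wide rather than a long
  hairline slit, so the orifice stays resolvable on coarse flow grids at
  matched area; the closed-state orifice area grows continuously (and
  monotonically) with severity, and `severity_for_eoa` inverts the map.
* **Domain assembly.**  A basal plate closes the LV annulus minus the two
  orifices; straight tube surrogates of the atrium and aorta extend both
  orifices to the top box face (they only keep inflow and outflow separated
  outside the ventricle).  The aortic orifice area is 3.46 cm² (radius
  1.05 cm), a typical adult aortic valve, placed just inside the annulus
  rim opposite the MV.

## Numerics

* **Grid/discretization.**  Uniform MAC grid; second-order central
  differences; advection in skew-symmetric form (divergence form minus half
  the face-interpolated velocity divergence), which stays energy-neutral
  where the boundary-cell layer makes the field slightly non-solenoidal.
* **Time stepping.**  Explicit SSP-RK3 with adaptive dt (CFL_max 0.5
  against Σ|vᵢ|/hᵢ, dt_max 2 ms); the valve angles advance inside the same
  Runge–Kutta combinations.
* **Pressure projection.**  Periodic in x/y; along z a wall at the bottom
  and an open (p = 0) top face where the tubes vent — mirrored reading
  switchable via `grid.z_mode`.  The unmasked Poisson operator diagonalizes
  by FFT in x/y and a DCT-IV in z.  Inside the immersed geometry a *masked*
  projection is used: divergence is enforced on fluid cells only and the
  pressure correction acts only across fluid–fluid faces, so prescribed
  wall velocities are Neumann boundaries of the projection and the volume
  displaced by the walls must exit through the orifices.  The masked system
  is solved by conjugate gradients preconditioned with the FFT solver
  (warm-started; relative tolerance 3e-4 on intermediate RK stages, 1e-7 on
  the final stage).  A fluid component sealed off from the open face (both
  valves momentarily closed) has the incompatible mean source removed — the
  discrete analogue of the pressure spike in a sealed chamber.
* **Discrete geometric conservation.**  The staircase wall formed by cut
  cells does not automatically sweep the same volume rate as the smooth
  surface it represents (an O(h) defect, ~8 % at desk resolution).  The
  ventricle-wall boundary velocities are therefore rescaled each retag by a
  single factor so their discrete face flux into the fluid equals −dV/dt
  exactly; diastolic inflow then balances the stroke volume to well under
  1 %.
* **Grid-scale regularization.**  The orifice jets are marginally resolved
  at desk-scale grids (cell Reynolds numbers in the hundreds), which a
  purely central scheme cannot sustain.  A fourth-difference low-pass
  filter (ε = 0.01, damping ∝ (kh)⁴, i.e. only near-grid wavelengths) is
  applied to the provisional velocity once per step, before the final
  projection, so the filtered field is also solenoidal.  This is a
  numerical filter, not a turbulence model: its action on resolved scales
  is negligible (the Taylor–Green decay test runs unfiltered/filtered with
  indistinguishable results).
* **Valve coupling regularization.**  The inertia-free valve model coupled
  to an explicit solver flutters, because the leaflet samples fluid that
  its own forcing just set.  Three measures keep the coupling faithful and
  stable: (i) the fluid velocity entering M, b is sampled off the leaflet
  (±1.5h and ±2.5h along the local normal), using only samples that land
  in genuine fluid cells; (ii) rates are under-relaxed 50 % against the
  previous step and capped at 60 rad/s (a full swing in ~30 ms, the
  physiologic closure scale); (iii) during systole rates are clamped
  non-positive (a ratchet): the model carries no transvalvular pressure
  force, and it is ventricular pressure — not local velocity matching —
  that pins a closed valve shut against the regurgitant jet's
  recirculation.  Closure itself remains fully flow-driven.  A leaflet held
  at a stop is tagged with zero surface velocity.
* **Aortic valve.**  A simple orifice: it opens when the MV is closed and
  the mean normal velocity at the orifice points toward the aorta; once
  open it closes only on flow reversal (hysteresis — closure of the real
  valve is flow-reversal driven, and this keeps sub-tolerance flutter of
  the mitral angles from sealing the chamber mid-ejection).  When closed,
  the orifice is tagged as a static wall patch.
* **Scalar scheme.**  Flux-form upwind-biased second order with
  monotonized-central limited slopes (the harmonic limiter drifts a rotating
  blob several cells per revolution; MC keeps it within a hundredth of a
  cell), explicit central diffusion with zero flux through non-fluid faces,
  values clipped to [0, 1].  Boundary cells receive the mean neighbouring
  fluid concentration before each step so wall faces advect the local
  concentration (discrete impermeability).

## Measurement protocol

`run_report_case` simulates a startup cycle from quiescent end diastole
(systole then diastole), marks all ventricular blood at end systole, and
continues through the next systole.  Regurgitation metrics integrate over
that flow-developed second systole; the residual volume is evaluated at its
end, exactly one cycle after marking, normalized by the discrete cavity
volume at marking time (so the marker integral is exact at any resolution).
Severity sweeps use single-systole runs from quiescent end diastole.

Metric definitions: MVO(t) integrates the trailing-edge gap along the
midline between the paired edges (stations paired by parametric index,
which keeps them registered when the prolapse stretches one edge); EOA is
the MVO of the closed configuration; QMV averages the fluid velocity over
five Gauss points per gap segment, subtracts the mean edge velocity (the
literal half-difference rate is available via a switch), projects on the
station normal and integrates gap-weighted along the midline; QMVa and QLV
are discrete staggered-face fluxes through the mitral-annulus disk and the
LV-annulus disk in the basal plane (the exact flux the solver transports);
QMVold weights the QMV integrand by the sampled concentration.  Regurgitant
(atrium-ward) flow is positive in QMV/QMVa; QLV is positive into the
ventricle.  Vreg_false = Vreg_MVa − Vreg holds identically by construction.

## Default problem sizes

Desk-scale defaults, chosen once as this package's study conditions: flow
grid 24×24×36 over a box 1.3× the LV bounding box for the heartbeat
analyses (the config accepts any size), LV surface mesh 40×33, leaflet
meshes 33×13, verification problems at 32³–64³.  Severity sweeps use
`P2like` at severities 0.3–0.9 (closed-orifice areas 6–21 % of the valve
area).

## What the synthetic data do and do not show

The generator reproduces the volumes, valve areas, orifice-area range,
timing and transit physics of the study conditions, so passing tests show
that the method — solver, valve model, marker transport and the
quantification suite — behaves correctly and reproduces the *relations*
(regurgitant volume proportional to orifice area, washout contrast between
normal and dilated ventricles, false regurgitation from leaflet closure).
They do not certify patient-specific accuracy: real ventricles are not
spheroids, real leaflets are not two rigid-ish cusps, desk-scale grids
under-resolve the regurgitant jet (which biases Vreg/SV low against
EOA/MVA, visible as a proportionality slope below one), and the scalar
diffusivity matches ν rather than a physical marker diffusivity.

## Known limitations

* No tissue mechanics, no papillary muscles/chordae geometry, no
  aortic/atrial pressure coupling (both tube ends vent at p = 0; the
  regurgitant fraction therefore arises from conductance splitting rather
  than from a systemic afterload).
* Cut-cell forcing is first order at the wall; metrics that depend on flow
  structure within 1–2 cells of the leaflets (EOA is geometric and exact,
  but QMV is not) converge slowly with grid refinement.
* Single-cycle marking only; multi-cycle residence-time statistics are out
  of scope.
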