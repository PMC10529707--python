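# Methods

This note documents the models, numerical choices and their rationale, the
synthetic-data design, and the limits of what the tests demonstrate.

## Governing model

Blood is treated as an incompressible Newtonian fluid (kinematic viscosity
ν = 0.04 cm²/s, density 1 g/cm³; pressure is stored per unit density).  The
Navier–Stokes equations are solved on a fixed uniform Cartesian box with
free-slip outer boundaries; the moving atrial wall is imposed with a
direct-forcing immersed-boundary method, so no body-fitted mesh exists and
the chamber interior/exterior are both part of the computational domain.  The
mitral valve is a flat impermeable immersed surface while the left ventricle
ejects (dV_LV/dt ≤ 0) and an open orifice into the box exterior while it
fills; the exterior acts as the reservoir that sinks mitral outflow and
sources the pulmonary-vein buffers.  Flow is driven entirely by (a) the
prescribed wall motion and (b) the PV inflow imposed in buffer regions
upstream of each inlet cap, where the velocity is forced to
`v_t = (Q_i/A_i) n̂` along the inward cap normal.  Mass conservation of the
moving chamber fixes the total inflow, `Q_PV = dV_LA/dt + Q_MV`, with
`dV_LA/dt` evaluated *exactly* from the Fourier wall motion (divergence
theorem differentiated in time), so the boundary data are consistent with the
wall the solver actually sees.

Residence time obeys `∂T_R/∂t + v·∇T_R = 1`, is zero at the start of a run
and is reset to zero over the whole inflow buffer of every vein (the reset
region includes one cell beyond the buffer so inflowing blood enters with
zero age).  At the mitral orifice characteristics leave the chamber and no
condition is imposed.  Exterior cells carry T_R too but are excluded from all
statistics by the region masks.

## Synthetic anatomy

The generator stands in for a registered 4D-CT segmentation pipeline.  The
surface is *star-shaped*: a radial support function on sampling directions
(uniform angles in 2D; an icosphere, subdivision 5, in 3D) taking the soft
maximum (log-sum-exp, 0.08 cm fillet scale) of

* a seeded ellipsoidal chamber (relative axes (1, 0.85, 0.75) in 3D,
  (1, 0.92) in 2D) with a smooth random shape perturbation (four
  quadratic-form bumps, 2 % amplitude, seeded RNG);
* one cylindrical stub per pulmonary vein and for the mitral orifice, ending
  in an exactly planar cap (cap vertices satisfy x·d = L analytically; the
  soft maximum perturbs planarity by < 2·10⁻³ cm, the stated tolerance);
* a capsule (cylinder + spherical tip) for the appendage.

This construction is watertight by construction and exposes every labeled
patch the pipeline needs.  Wall motion scales the chamber support (and the
sac radius) by time factors found by Brent root-finding so that the enclosed
body volume (everything on the atrial side of the ostium plane) tracks the LA
waveform and the beyond-ostium volume tracks the LAA waveform; the resulting
frames (32 samples/cycle) are least-squares projected onto K = 8 temporal
harmonics per vertex.  Enclosed volumes at the cycle markers match the
requested V_min/V_max/V_preA within 2 % (typically < 0.2 %).

Volume waveforms are sums of raised-cosine *rate lobes* (reservoir rise
during ventricular systole, E-wave fall, diastasis, atrial-kick fall), which
hit the markers exactly and have analytic derivatives.  The chamber targets
are band-limited to the mesh's K harmonics before the motion solve: driving
the wall toward spectral content it cannot represent would leave ringing in
dV_LA/dt and hence in Q_PV.  The LV waveform stays in closed lobe form — its
rate sign defines the valve state and no mesh ever realizes it.  The AF-like
variant enlarges the chamber, nearly removes the atrial kick (booster EF
≈ 0.05, monophasic mitral filling) and reduces the LAA emptying fraction to
≈ 0.21.

What the generator does *not* emulate: real anatomical irregularity (trabeculae,
LAA lobes and morphotypes), vein ostium motion (the inlet caps are static, see
below), registration noise, or inter-frame segmentation inconsistencies.
Passing tests therefore demonstrate the pipeline's correctness and its
qualitative physics on idealized geometry, not quantitative patient-specific
accuracy.

A consequence of static inlet caps: the per-vein flow-rate waveforms under
every split are exact scalar multiples of Q_PV(t), and the flow-rate
correlation factor — a per-vein cosine similarity without mean subtraction —
is then exactly 1 for every scenario pair.  Values slightly below 1 in the
source experiments arise from time-varying inlet areas.  The velocity-field
correlation factors are unaffected and carry the sensitivity analysis here.

The correlation factors are implemented verbatim as normalized inner
products (cosine similarity).  A Pearson-style variant with mean subtraction
would measure waveform *shape* similarity instead; we note the alternative
but do not adopt it.

## Discretization

* **Grid**: staggered (MAC); velocity components on faces, pressure and T_R
  at cell centers; uniform spacing h in all directions.
* **Time**: three-stage low-storage Runge–Kutta, γ = (8/15, 5/12, 3/4),
  ζ = (0, −17/60, −5/12); constant Δt chosen as
  `Δt = 0.24 h / (1.8 v_peak)` where v_peak is the peak boundary-condition
  velocity over the cycle and all scenarios (schedule targets, transmitral
  velocity, wall-normal speed); the factor 1.8 covers local accelerations
  (inlet vena contracta reaches ≈ 1.7× the plug velocity) so the CFL stays
  below the hard 0.3 guard, which aborts the run if violated.
* **Advection**: second-order centered, convective form.
* **Viscosity**: Crank–Nicolson inside each substep, implemented as a
  direction-factorized tridiagonal solve.  When the diffusion number
  ν Δt/h² < 0.05 (always true at study scale) the run-level default switches
  to an explicit viscous update — at those parameters CN adds cost and no
  accuracy; the scheme is config-selectable (`"cn"`/`"explicit"`/`"auto"`).
* **Projection**: exact discrete divergence removal each substep via a
  type-II cosine-transform Poisson solve consistent with the free-slip box.
* **Immersed boundary**: direct forcing with the three-point regularized
  delta kernel; markers are boundary vertices subsampled to 0.75 h spacing
  (2D) or wall-face centroids with area weights (3D).  Marker velocity is the
  *wall-normal projection* of the parameterized vertex velocity: the
  synthetic anatomy prescribes shape, and the tangential sliding of a radial
  parameterization is not material motion.  Forcing and projection are
  interleaved twice per substep, which is what keeps the thin immersed walls
  nearly impermeable under the transvalvular pressure difference; delivered
  PV flux matches the schedule within ~15 % at 96² (an O(h) interface
  property).  Static "duct extension" walls continue each PV tube through its
  buffer so the forced inflow column is confined as it would be inside the
  vein.
* **Buffers**: 3 cells deep immediately upstream of each inlet cap,
  re-forced to the target velocity every substep.
* **Valve transitions**: the cap forcing weight ramps smoothly with
  `clip(−dV_LV/dt / (0.05 max|dV_LV/dt|), 0, 1)`, a ≈ 10 ms ramp that avoids
  impulsive forcing at the zeros of dV_LV/dt.
* **Residence time**: dimension-by-dimension WENO3 upwinding
  (Hamilton–Jacobi form) with SSP-RK3, one scalar step per flow step using
  the end-of-step velocity.  The smoothness regularization defaults to the
  grid-scaled ε = 10 h², which preserves the design order at smooth extrema
  (observed order 2.5–2.8) while fronts stay essentially non-oscillatory
  (overshoot < 0.1 % of a jump).  Verification problems use periodic ghosts;
  production runs use zero-gradient ghosts at the box.
* **Warm-up**: runs start from rest, integrate `warmup_cycles` heartbeats on
  a 2× coarser grid, interpolate linearly to the nominal grid, re-project,
  and continue; the final `cycles` heartbeats form the averaging window.

## The flow-split experiment

One anatomy is simulated under all four splits with the same grid and time
step (chosen from the scenario-wide peak velocity), so snapshot times
coincide and velocity fields are comparable point by point.  Region masks are
recomputed at each snapshot phase (instantaneous MV plane by total least
squares on the orifice boundary; the KE/correlation decomposition uses the
cycle-mean plane); the LAPV/LAb cut is ξ = 0.25 — any fixed fraction
reproduces the mechanism and the value is config-exposed.  Statistics pool
cell values over all snapshots of the averaging window; box plots use the
{9, 25, 50, 75, 91} percentile set; z-scores average over unordered scenario
pairs.  The ρ integrals use trapezoidal quadrature at the snapshot cadence.
"The region near the PVs" excluded from body correlations is identified with
the LAPV mask.

Default study conditions: planar anatomy, 128² grid on an 8×8 cm box
(h = 0.0625 cm), heart rate 60 min⁻¹, two coarse warm-up plus three averaged
heartbeats, 32 snapshots per cycle, ≈ 4300 time steps per heartbeat.  These
problem sizes are the package's desk-scale operating point; the nominal
patient-scale configuration (256³, Δt = 5·10⁻⁵ s, 10 + 5 heartbeats) is
accepted by the config but is not what the tests exercise.  The planar model
uses one vein per side (areas giving an equal-velocity split of 55/45 L/R, a
left-shifted counterpoint to the right-dominant splits) with chamber areas
(9.6–14.4 cm², LVSV analogue 8 cm²) chosen so ejection-fraction profiles and
peak velocities (≈ 30 cm/s at the mitral orifice and veins) are
physiological; the impaired variant reduces global EF to ≈ 0.19 and LAA EF to
≈ 0.215.

## Degenerate inputs and tie-breaks

Infeasible anatomy parameters (markers out of order, an appendage the chamber
cannot host, overlapping feature cones, volumes the chamber radii cannot
bracket) raise with a diagnostic.  Zero-area inlets are rejected by the
splitters; zero-norm waveforms/fields are rejected by the correlation
factors; identical-mean zero-variance pairs give z = 0 while unequal means
with zero variance raise (infinite z).  The valve state is open exactly where
dV_LV/dt > 0, so diastasis counts as closed for the forcing but lies inside
the diastolic window used by the phase-volume integrals (diastole = the span
from first opening to last closure).  The atrial-kick onset is detected as
the last local minimum of Q_MV inside diastole that is followed by a rise;
monophasic filling leaves E/A undefined and flagged.  PVa integrates reverse
flow over that window from raw (unrounded) durations.

## Known limitations

* The immersed wall is O(h) accurate: it leaks a few percent of the imposed
  flux and smears the boundary layer over ~2 cells; regional statistics
  within one cell shell of the wall inherit that uncertainty.
* 3D wall markers inherit the direction-sampling anisotropy of the icosphere
  (stretched faces along the tube walls), so the 3D solver path is exercised
  only on small verification problems; the quantitative study runs in 2D.
* Three averaged heartbeats after two coarse warm-up beats do not reach the
  fully periodic residence-time state (the source experiments run 15): mean
  appendage T_R is still close to the elapsed time in both anatomies, so
  regional orderings (LAA vs body) are already robust but *across-split*
  appendage-T_R differences have not yet emerged from the common start-up
  growth.  The across-split z-score of appendage T_R consequently does not
  yet rank the impaired anatomy above the normal one at this scale, even
  though the flow half of that mechanism (systematically lower velocity
  correlation factors for the impaired anatomy) is reproduced.
* LA sphericity is not computed (no standard definition at this geometry
  level); the printed cohort value is carried as data only.
* Whether per-vein rates should be clipped at zero during atrial-kick
  reversal is not specified by the split definitions; the common sign of
  Q_PV propagates to every vein.
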