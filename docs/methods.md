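# Methods

This note documents the models, numerical choices and limitations of the
aneuchip pipeline: parametric/voxelized geometry → volume-penalized
incompressible flow → wall shear stress (WSS) → low/high-shear sites →
microfluidic-chip operating points.

## Geometry representation

All geometry lives on a uniform, isotropic Cartesian grid as a binary
indicator χ, **1 in solid, 0 in fluid** — the support of the Brinkman
penalization term. This is the opposite of the "occupancy" convention of
many voxelization tools and is stated prominently in the code. Cell
centers sit at `origin + (index + ½)·spacing`; everything dimensional is
SI.

Two parametric generators provide the synthetic stand-ins for segmented
patient imaging, which is not publicly deposited for cases like this:

- `make_straight_vessel`: a plane channel (2-D) or circular cylinder
  (3-D) of the vessel diameter (default 4 mm);
- `make_sidewall_aneurysm` (2-D): channel plus a circular sac placed so
  the chord it cuts in the wall line has exactly the requested neck
  width. Defaults (1.6 mm sac radius, 1.28 mm neck) are plausible for a
  small sidewall aneurysm; the actual patient dimensions of the
  motivating case are not published, so these are surrogates, not
  patient-matched values. A sphere-on-cylinder 3-D sac is not offered:
  its neck is not well defined by a single chord width, and the flow
  solver is 2-D (below).

Watertight STL surfaces are voxelized by even–odd ray-crossing parity
along the z axis; the ray grid carries a fixed sub-nanometer
perturbation so degenerate edge hits cannot occur and results are
bit-reproducible. Non-watertight input is rejected with the open-edge
count. Voxel masks can be refined (block replication — exactly
volume-preserving and compositional) and smoothed (morphological closing
then opening of the solid with a disk/ball element, the voxel analogue
of the mesh smoothing usually applied to segmented imagery; the domain
border is padded by 3 radii so border erosion can never reach the real
domain). Every generator output must pass the mask invariants: strict
{0,1} values, non-empty disjoint inlet/outlet port labels on the domain
boundary, and a single connected fluid component (flood fill from the
inlet).

The domain box always keeps ≥ 2 solid padding layers on non-port faces
so penalization handles every wall uniformly.

## Flow solver

Nondimensionalization: lengths by the vessel diameter D (taken from the
mask's inlet opening unless overridden), velocities by the mean inlet
speed U, time by D/U; the single physical parameter is Re = U·D/ν
(≈ 246 at the reference conditions U = 0.2 m/s, D = 4 mm,
ν = 3.25 × 10⁻⁶ m²/s).

Spatial discretization is a second-order finite-volume scheme on a
staggered (MAC) grid — face-normal velocities, cell-centered pressure —
which excludes pressure checkerboard modes without stabilization terms.
Advective fluxes are central second order; one time step is:

1. **Advection + diffusion**, explicit second-order Adams–Bashforth
   (forward Euler on the first step). The time step is fixed per run
   from the CFL condition against a conservative speed bound
   (2·(1+α)·max inlet speed) and the explicit viscous limit h²/(4ν),
   scaled by the configured Courant number (default 0.5); an actual CFL
   violation aborts with an instability error.
2. **Penalization**, implicit with its exact integrating factor
   u ← u/(1 + Δt·χ/η) on faces adjacent to solid cells — the stiffness
   of η = 10⁻⁸ forbids explicit treatment.
3. **Projection**: a pressure Poisson solve over the fluid cells (5-point
   symmetric Laplacian, homogeneous Neumann at penalized and port faces,
   nullspace removed by pinning one fluid cell) followed by the velocity
   correction on interior fluid–fluid faces. The system is factorized
   once per run with a sparse direct solver, so the post-projection
   divergence sits at round-off (~10⁻¹²), far below the nominal
   tolerance. Before the solve, the zero-gradient outlet profile
   receives a uniform flux correction that makes the Neumann problem
   exactly compatible — as a byproduct, global inlet/outlet mass balance
   holds to ~10⁻¹² at steady state.

**Wall placement.** Plain face penalization zeroes the tangential
velocity at the first *solid face row*, half a cell inside the wall; the
effective channel is then wider by one cell and a 32-cell channel
recovers only 1.4545·U instead of 1.5·U on the centerline. The solver
therefore treats deep-solid faces adjacent to fluid faces as mirror
ghosts (value = − adjacent fluid value) inside the diffusion stencil,
which places the no-slip wall exactly on the fluid/solid interface face.
With this closure the 32-cell channel recovers the centerline to 0.2%
and the wall stress 6μU/H to 0.3%. Normal velocity components need no
such treatment: they live exactly on the interface faces, where
penalization acts directly.

**Inlet/outlet.** The inlet carries a parabolic (or plug) profile over
the fluid opening, normalized so the *discrete* mean is exactly the
waveform value; the outlet is zero-gradient plus the compatibility flux
correction. Pulsatile runs use u_in(t) = U(1 + α·sin 2πt/T) — a
sinusoid is the minimal heartbeat surrogate; α = 0.3 is a typical
relative pulsatility for cerebral arteries. The first period is
transient; snapshots of the final period feed the time-averaged and peak
WSS fields. Quasi-periodicity at the 1% level is reached within ~4
periods for the channel cases tested; exact periodicity to the
steadiness tolerance would need many more periods than a desk-scale run
warrants.

**Determinism.** Zero initial velocity, fixed Δt, direct sparse solves,
no randomness anywhere: a given mask + configuration reproduces bitwise
identical fields across runs.

**Penalization parameter.** η is nondimensional, default 10⁻⁸.
Penalization theory bounds the spurious solid-region velocity by
C·√η; with the implicit discrete treatment used here the measured
steady max solid-cell speed decays even faster, essentially ∝ η
(measured 1.9 × 10⁻⁴ → 1.9 × 10⁻⁸ over η = 10⁻⁴ → 10⁻⁸ in a 32-cell
channel) — comfortably inside the √η envelope and monotone in η.

**Scope.** The solver is two-dimensional. The refined patient-scale 3-D
runs this pipeline emulates use 30–40 grid cells per mm over centimeters
of vasculature — a cluster-scale problem. A 2-D section exercises the
same discretization, penalization and WSS extraction at desk scale; the
geometry module nevertheless supports full 3-D masks (cylinders, STL
voxelization, refinement, smoothing) for resolution studies and future
extension.

## Grid-convergence quantification

`estimate_convergence_order` implements the resolution-comparison
procedure: solutions at spacings h, h/2, h/4 on nested grids give the
observed order log₂(‖u_h − u_{h/2}‖ / ‖u_{h/2} − u_{h/4}‖). Probes sit
at interior *grid corners* of the coarse grid (eroded 3 cells from the
wall): corners are shared by every nested refinement, so bilinear
sampling there is the plain 2ᵈ-cell average whose consistency error
scales with h² like the solution error itself — sampling at cell
centers instead injects an interpolation error of the same order as the
signal and corrupts the ratio. If both differences sit at round-off the
estimate is flagged "converged" rather than returning a number.

On a channel triple (16/32/64 cells across) with walls face-aligned at
every level the observed order is ≈ 1.99. With walls deliberately
misaligned, staircase quantization makes the ratio erratic (the
voxelized wall can land on the same face at two levels and jump at the
third) — an inherent property of staircase immersed boundaries worth
knowing before interpreting any single Richardson number.

## Wall shear stress and sites

Wall faces are the fluid cells with ≥ 1 solid face-neighbor. Outward
normals are the normalized gradient of the one-cell-smoothed indicator
(fallback: mean solid-neighbor direction for degenerate thin features).
The WSS magnitude uses a one-sided first-order gradient: tangential
cell-center velocity divided by the h/2 wall-normal distance, times
1/Re. The staircase boundary does not support robust higher-order
one-sided stencils, so this is the dominant error term of the pipeline
(≈ h/2H relative in a channel of height H). Dimensional stress is
τ = ρU²·τ_nd (the nondimensional stress carries the 1/Re factor, so the
dynamic pressure is the correct scale; for a channel this reproduces
6μU/H exactly). Blood density defaults to ρ = 1060 kg/m³ — the flow
model itself is specified through ν only, so ρ is a documented default
rather than a fitted quantity.

Sites of extreme shear are connected wall regions (diagonal-including
adjacency) below the 5th / above the 95th percentile of τ, keeping
regions with ≥ 3 faces, ranked by the distance of the region median
from the field median. The median is the representative statistic
(robust against staircase outliers); the mean is reported alongside.
Thresholding is strict, so a constant field yields no sites. For
pulsatile runs the time-averaged field feeds site extraction by
default, with the peak field available — which temporal statistic best
matches any given experimental protocol is a modeling choice left to
the user.

For the default synthetic sidewall aneurysm at Re = 250 (steady,
256 × 128), the top high-shear site sits ~1.2 neck widths from the
downstream sac–vessel rim where the neck shear layer impinges
(~1.2 Pa), and the top low-shear site sits on the sac dome
(~0.007 Pa) — the same qualitative topology reported for patient
sidewall aneurysms, with stress magnitudes bracketing typical high/low
chip culture conditions.

## Chip translation

The parallel-plate formulas γ = 6Q/(h²w), τ = γμ and the inverse
Q = τh²w/(6μ) are implemented verbatim as the primary mapping — they are
the design convention of shallow-channel perfusion experiments — with an
optional exact rectangular-duct series correction behind a flag, OFF by
default (at the default aspect ratio h/w = 1/12 the difference is
below ~10%; a penalized-solver run through the chip cross-section at the
mapped Q reproduces the 1.5 Pa target to 0.2%). The default chip is
56 × 1.2 × 0.1 mm with μ = 7 × 10⁻⁴ Pa·s (water at 37 °C, the
culture-medium surrogate — deliberately a different fluid from the
blood used in the CFD stage; both are configuration keys).

Each operating point carries the channel Reynolds number
ρ·(Q/hw)·D_h/μ with D_h = 2hw/(h+w) and warnings for Re ≥ 2000
(laminarity) and h/w > 0.25 (parallel-plate validity). When a user
supplies both τ and Q, they are checked against the formula and a > 5%
disagreement is surfaced as a warning — published operating pairs are
never silently "corrected". (One widely used low-shear pair,
0.03 Pa at 8.67 × 10⁻¹⁰ m³/s on this chip, disagrees with the formula
by exactly 10×; the package reports the formula value, 0.30 Pa, and
warns.)

## Problem sizes and tolerances

Defaults: η = 10⁻⁸, CFL 0.5, steadiness tolerance 10⁻⁶ on the velocity
change rate ‖Δu‖∞/Δt, percentiles 5/95, minimum region size 3 faces.
The test-suite and acceptance problem sizes are desk-scale by design:
32-cell channels for Poiseuille recovery and the penalization sweep,
a 16/32/64 triple for grid convergence, and a 256 × 128 section
(64 cells per diameter, steadiness 10⁻⁵) for the Re = 250 aneurysm —
each solves in seconds to a couple of minutes on one CPU.

## What the synthetic data does and does not show

The generators emulate the geometric features that control the shear
topology — a supply vessel at the physiological Reynolds number and a
sidewall sac with a finite neck — so tests of the solver, WSS extraction
and site logic carry over to real voxelized lumens. They do **not**
emulate vessel curvature and tapering, branch vessels, 3-D swirl in the
sac, non-Newtonian rheology, wall compliance, or a measured cardiac
waveform; absolute WSS magnitudes from the 2-D section should not be
read as patient predictions, only the relative low/high-site structure
and the verified numerics. The chip formulas are exact algebra given
their parallel-plate assumption; their accuracy for a physical chip is
bounded by the aspect-ratio correction discussed above.

## Known limitations

- 2-D flow solver (3-D masks supported in the geometry stage only).
- Staircase walls limit WSS accuracy to first order at the boundary;
  refine the grid rather than trusting a single-resolution stress value.
- Steady and sinusoidally pulsatile inflow only; no measured waveforms.
- No turbulence model (irrelevant at Re ≈ 250), no fluid–structure
  interaction, no non-Newtonian rheology.
- Oscillatory shear index and WSS-gradient metrics are out of scope.
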