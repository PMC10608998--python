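# Methods

## Geometry and coordinates

The channel planform is parameterized by the upstream/downstream width `w_u`,
minimum contraction width `w_c`, contraction length `L_c`, depth `h`, and
straight inlet/outlet lengths `L_in`, `L_out`. `x` is axial with origin at
the contraction entrance, `y` transverse from the centerline, `z` along the
depth from the midplane; configuration I/O is in micrometers, all internal
computation in SI.

The contraction profile is the standard hyperbolic design, `1/w(x)` affine in
`x`:

    w(x) = w_u w_c L_c / (w_c L_c + (w_u - w_c) x),   0 <= x <= L_c.

This is the unique profile for which the width-mean (and in practice the
centerline) velocity grows linearly with `x`, so the extensional strain rate
is constant through the contraction. The physical mold's exact hyperbola is
not published; any profile with the same endpoints and near-affine `1/w` is
equivalent at the accuracy of this model. The expansion at `x = L_c` is an
instantaneous step back to `w_u`.

### Grid

A boundary-fitted tensor-product grid: nonuniform axial stations `x_i` and a
transverse coordinate `eta in [-1, 1]` scaled by the local half-width
(`y = eta w(x)/2`). `ny` must be even so a node row lies exactly on the
centerline. Two clustering choices matter numerically:

- **Wall clustering.** `eta` nodes are cosine-clustered toward the side
  walls. The Brinkman side-wall layer has thickness `h/sqrt(12)` (17 um for
  `h = 60` um); uniform spacing at `ny = 64` under-resolves it (~2% error vs
  the closed form), clustering brings the straight-channel solve within 0.2%.
- **Expansion regularization.** A discontinuous width cannot be carried by a
  boundary-fitted map (the mapping metrics blow up), so the step is replaced
  by a cosine ramp of length 20 um centered on `x = L_c`. The ramp is
  area-neutral by symmetry, so the grid-area invariant against the analytic
  planform area still holds to < 0.1%. The ramp gets its own uniformly fine
  grid segment; outlet stations then grow geometrically. Consequence: the
  "contraction" of the discrete device ends 10 um early, and the elliptic
  operator feels the expansion upstream over a couple of screening lengths —
  centerline monotonicity is therefore guaranteed only up to ~50 um before
  the throat.

Axial stations inside the contraction are spaced uniformly in `log w`
(denser toward the throat where the cells shrink); the default production
grid is 512x128, and the refinement ladder {64x16, 128x32, 256x64, 512x128}
mirrors a four-mesh refinement study procedurally.

## Flow model

The full 3D incompressible Stokes problem is reduced to the depth-averaged
Stokes-Brinkman equations on the planform,

    mu lap(u_bar) - (12 mu / h^2) u_bar = grad p,    div u_bar = 0,

valid for Re = rho Q/(2 h mu) << 1 (<= 0.15 at the largest study flow rate;
the solver warns, but does not refuse, above Re = 1; note the study's printed
Re-per-flow-rate coefficient is an order of magnitude below what its own
definition gives — we always evaluate the definition). The `12/h^2` drag is
the parabolic-depth closure; the retained in-plane Laplacian restores the
side-wall layers, so in a straight duct the solution is the classical
Brinkman profile

    u(y) = A [1 - cosh(sqrt(12) y/h) / cosh(sqrt(12) W/(2h))],

which doubles as the solver's closed-form oracle.

Discretization: streamfunction-vorticity splitting (`lap psi = q`,
`mu lap q = (12 mu/h^2) q`) with second-order finite differences on the
mapped rectangle; cross-derivative and first-derivative metric terms arise
from the `y = eta w(x)/2` map. End rows of the 1D derivative operators are
4-point one-sided (third order): the same rows serve as the wall no-slip
closure and the wall velocity reconstruction, and their order controls the
near-wall accuracy of the whole solve. Boundary conditions: uniform inflow
(`psi` linear in `y`, `q = 0`), wall `psi = +-Q/(2h)` with `d psi/d eta = 0`,
and outlet zero-gradient implemented as a two-point column copy (which makes
the outlet inherit the wall no-slip exactly). The uniform-inflow profile is
incompatible with no-slip at the two inlet corners; this inconsistency is
inherited from the original study's boundary conditions and decays within a
screening length.

The assembled system mixes O(1) Dirichlet rows with O(1/dx^2) operator rows;
it is row/column equilibrated to unit max-norms, factorized with sparse LU,
and polished with two iterative-refinement passes (without refinement,
localized residuals of ~1e-3 relative appear near the steepest metric
gradients). The reported residual is the normwise backward error
(~1e-16; tolerance 1e-8). Pressure is a diagnostic, recovered by integrating
the centerline momentum balance from the outlet gauge.

Stokes linearity is exact, so the pipeline solves once per grid at the
largest flow rate and rescales fields to the others.

### Midplane conversion

Tracked cells sit near the focal midplane, so comparisons use midplane
velocities: `u_mid(x, y) = r(w(x)/h) u_bar(x, y)`, where `r` is the ratio of
midplane-centerline to depth-averaged-centerline velocity of a developed
rectangular duct at the local aspect ratio, evaluated from the duct Fourier
series (100 odd terms; overflow-safe sech). Limits: `r -> 3/2` for a wide
slot (parabolic depth profile), `r -> 1` for a deep narrow slot (plug-like
depth profile); the series also reproduces the square-duct peak-to-mean
factor 2.096, its independent check. The conversion assumes locally
developed depth profiles, which holds because the depth relaxation length
(~`h/sqrt(12)`) is small compared to the contraction length.

## Particle model

Rigid spheres, one-way coupled (1% hematocrit is dilute):

    du_p/dt = (u - u_p)/tau_r + g (rho_p - rho)/rho_p + F/m_p,

with the Stokes-drag relaxation time `tau_r = rho_p d_p^2/(18 mu)` (0.85 us
for the 8 um, 1080 kg/m^3 cell surrogate; particle Reynolds number << 1) and
`F = 0`: no lift, Magnus or wall forces, mirroring the rigid-sphere
simplification of the original model. RBC deformability is deliberately out
of scope. Gravity acts along the depth (horizontal chip); its in-plane
component is zero and the quasi-steady settling offset
`tau_r g (rho_p - rho)/rho_p ~ 0.26 um/s` is tracked only as a diagnostic
(nanometers per transit).

Integration: the linear drag is integrated exactly over each step
(exponential update), with the carrier velocity taken as the average of its
values at the departure point and at a predictor endpoint; positions advance
trapezoidally. The corrector matters: with the step policy
`dt = min(0.1 cell-crossing, 10 tau_r)`, a plain one-point sampling incurs
O(strain rate x dt) ~ 1.5e-3 relative velocity error, above the physical
Stokes-number lag of ~1.5e-4; the corrector reduces the scheme error to
O((strain rate x dt)^2) so the particle-fluid velocity gap is governed by
physics and stays under 1e-3 at the largest flow rate.

Particle spin relaxes toward half the local vorticity with the creeping-flow
rotational drag `T = 8 pi mu (d_p/2)^3 Omega` (time constant
`rho_p d_p^2/(60 mu)`). The published force balance leaves the rotational
drag coefficient unspecified; the Stokes closure is adopted since the
rotational Reynolds number is << 1. Spin is a diagnostic and does not feed
back on translation.

Default release protocol: `x_0 = -100 um`, `y_0 in {0, +-25, +-50, +-100} um`,
initial velocity equal to the local fluid velocity, initial spin equal to
half the local vorticity. The release positions of the original simulations
are not published; this sweep reconstructs the reported off-axis comparison
qualitatively.

## Synthetic tracking data

The generator emulates a manual-tracking export from high-speed video: it
samples each trajectory at the frame interval, quantizes positions to the
pixel grid, adds isotropic Gaussian localization noise, and crops to the
axial field of view. Defaults: pixel size 0.5 um/px and localization sigma
0.25 um — free parameters of the emulator (neither is published), chosen
sub-cell-diameter; frame rate 4800 fps for the two slower flow rates and
13000 fps for the fastest, matching the published camera range; three
near-axis particles per flow rate (`y_0 in {-5, 0, +5} um`), matching the
three tracked cells per flow rate of the published table. Tracks are 2D
(x, y) only, as the imaging acquires no depth information. Everything is
deterministic given the acquisition seed; identical config + seed gives
byte-identical CSV.

What the emulator does *not* model: point-spread blur, motion blur, tracking
gaps and misassociations, cell-depth jitter about the midplane, and cell
deformation. Passing recovery tests therefore show that the analysis chain
is unbiased against this noise model, not that manual tracking of real cells
is. In particular, at the lowest flow rate the per-frame displacement is
sub-pixel, so frame-pair velocities are noise-dominated and the synthetic
per-track R^2 is far below the published experimental values — consistent
with the real analysis having used longer effective baselines than single
frame pairs.

## Velocimetry and statistics

Frame-pair velocities by central differences (one-sided at track ends) —
exact for linear velocity variation; strain rate as the OLS slope of axial
velocity vs axial position inside the fit window, with the standard R^2. The
default window is [0, 500 um] from the contraction entrance (configurable up
to the full contraction). Per-flow-rate statistics: arithmetic mean of the
per-particle slopes; relative errors as 100 |value - reference|/reference
with the experimental mean as reference (the mesh-refinement table instead
references the designated reference grid — both conventions are reproduced
as printed). Transverse profiles from tracks: linear interpolation of each
track's station crossing, frame-pair velocity at the crossing, then y-binned
means.

## Known limitations

- The 2D reduction plus duct-series conversion reproduces developed-duct
  physics to ~1% but treats depth development quasi-statically; fully 3D
  corner effects near the throat (where w < h) are approximated.
- The regularized expansion smears the velocity drop over ~20 um.
- The midplane assumption is the main source of disagreement with tracked
  cells: real cells are distributed over depth, and a depth-sampled velocity
  average sits ~20% below the midplane value in this geometry. The package's
  midplane strain rate at the highest flow rate (~173 1/s on the default
  window) is consistent with its own duct-series oracle (~176) and with the
  published mesh-study strain rate (~150, different fit window), but sits
  well above the published tracked-cell means (~121) — users comparing
  against PTV data averaged over depth should expect this systematic offset.
- Newtonian carrier only; no cell-cell interaction, no two-way coupling, no
  cell-free layer physics.
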