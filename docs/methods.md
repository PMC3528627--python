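# Methods

## Model

Particles diffuse on a periodic membrane — the segment [-L, L) in 1D or the
square [-L, L)^2 in 2D with toric topology.  Heterogeneity enters through a
position-dependent noise amplitude a(x) > 0 ("diffusion profile"): the
equation of motion is the overdamped multiplicative-noise SDE

    dX = a(X) o dZ            (Stratonovich reading)

with dZ standard white noise per axis.  The physical diffusion coefficient
is D(x) = a(x)^2.  The profile is assumed temporally stable over the
simulated window; the package does not model what creates it.

Under the Stratonovich reading the stationary Fokker-Planck solution with
periodic boundary conditions and zero flux is

    rho(x) = Omega / a(x),        Omega = [ int dx / a(x) ]^-1,

i.e. density proportional to the inverse square root of diffusivity: slow
zones overconcentrate by sqrt(D_fast/D_slow).  Under the Ito reading
(plain Euler increments, no Milstein correction) the stationary law is
rho ~ 1/a^2 and the overconcentration is the full ratio D_fast/D_slow.
Both channels are implemented; Stratonovich is the default and the Ito runs
serve as the contrast experiment.

In 1D the transform xt(x) = int_{-L}^{x} du/a(u) maps the problem onto
classical diffusion on a circle of circumference C = 1/Omega, for
p(xt, t) = a(x) rho(x, t):  dp/dt = (1/2) d^2p/dxt^2.  The package solves
transients by wrapped-heat-kernel convolution in xt (images truncated below
1e-12) and maps back.  No closed-form transient exists in 2D; 2D transients
come only from particle simulation.

FRAP: bleaching a zone |x| < r_b resets the initial condition to g(x) = 0
inside the zone.  The classical half-time tau = gamma r^2 / D generalizes
under heterogeneous diffusion to

    tau = gamma * ( int_{-r_b}^{r_b} du / a(u) )^2 .

gamma depends on the apparatus and on the precise half-time definition and
is never fixed here; all quantitative FRAP comparisons are ratios to the
homogeneous control at the same r_b, in which gamma cancels.

## Integrators

Stratonovich runs use the Milstein scheme per particle and axis:

    X <- wrap( X + sqrt(dt) a(X) Z + (dt/2) a(X) (da/daxis)(X) Z^2 ),

Z ~ N(0,1) independent per particle and axis.  The right-hand side is the
increment added to the current position.  In 2D the 1D scheme is applied
independently per axis with per-axis partials of a; the noise is diagonal
and scalar, and cross Levy-area terms are dropped — validated a posteriori
against the closed-form 2D equilibrium.  Ito runs drop the correction term.
Default dt = 0.01, the largest value for which halving dt leaves the
equilibrium histogram statistically unchanged (the suite tests this).  A
sanity check rejects configurations whose rms single step exceeds L/2.

Interacting runs (2D only) add a mobility-weighted deterministic drift

    dx_j = dt * D(X_j) * sum_{i != j, r_ij < cutoff} f(r_ij) u_ij,

with f = -dP/dr from the 6-12 Lennard-Jones potential
P(r) = eps[(sigma/r)^12 - 2(sigma/r)^6] (minimum -eps exactly at sigma),
u_ij the unit vector from i to j, r_ij the minimum-image distance.  The
mobility factor D(X_j) follows the Einstein relation; a flag
(`mobility_weighted=False`) switches to the plain dt*f increment for
comparison.  Numerical guards: the force is clamped below r = 0.5 sigma to
its value there, and the per-step drift displacement is capped at 0.5 sigma
— both regions are unreachable at equilibrium and the caps only prevent
overflow after an unlucky noise draw.  The cutoff defaults to 3 sigma with
no energy shift (forces, not energies, drive the dynamics; the small force
discontinuity at the cutoff is accepted).  No tail corrections: equilibrium
structure, not thermodynamics, is the target.

Hard-core collisions: each step every particle is visited once in random
order; a proposed move landing within `core_diameter` of any other
particle's current position is rejected (the particle keeps its previous
position).  Initial configurations are random sequential insertions; an
overlapping user-supplied start is an error.  When an interaction is
configured the core defaults to sigma.

Inner loops for interacting runs are compiled with numba using linked-cell
lists (cell size >= cutoff, falling back to all-pairs when the grid would be
coarser than 3x3 cells); the test suite asserts bit-level agreement between
the compiled step and the public numpy operations, and between cell-list
neighbor sets and brute-force enumeration.

Reproducibility: one seeded generator per run.  Non-interacting runs draw
the (N, dim) normal block per step from numpy's PCG64; interacting runs
derive a 31-bit seed for the compiled kernel, which draws per step first the
(N, 2) normal block, then the collision permutation.  Trajectories are
bit-reproducible for a fixed (config, seed) and software environment.

## Profiles

* Gaussian well(s): a(x) = D0 (1 - d exp(-|x - c|^2/omega)), 0 <= d < 1,
  periodized by summing periodic images until the truncation error is below
  1e-18, so the field is exactly 2L-periodic and smooth at the seam.  The
  2D multi-well field is the arithmetic mean of the K single-well fields.
  Canonical parameters D0 = 1, d = 0.9, omega = 0.1 (amplitude 0.1 at the
  well bottom).  The well width symbol is omega throughout; sigma is
  reserved for the Lennard-Jones length.
* Square slow patch: amplitude exactly D0/r inside, D0 outside
  (r = sqrt(D0/D_patch) >= 1 the amplitude ratio), joined by a compactly
  supported C2 quintic-smoothstep band of width `edge_width` (default 2% of
  L) straddling the nominal boundary, wrap-aware.  A sigmoid band with
  exponential tails was rejected: the equilibrium density
  1/(1 - (1 - 1/r) f) is hypersensitive to f near 1, and at r = 10 logistic
  tails depress the patch-averaged density by tens of percent; the
  compact band confines the distortion to the thin edge strip.  The theory
  module works with the smoothed field, so theory and simulation always
  describe the same profile.

## Observables

* Density histograms are normalized to integrate to 1; per-bin standard
  errors are multinomial.  Comparisons against closed-form densities use
  the variance-normalized sup-norm z_sup = max |rho_hat - rho| / se with
  the null se taken from the theory density, so a threshold calibrated on
  homogeneous control runs transfers across profiles.  Calibration runs the
  full pipeline on a constant profile (default: 99th percentile over 100
  runs; mean + 3 sd for small calibration sets).  Equilibrium-law tests
  compare single final snapshots: positions of independent particles at one
  time are iid draws from rho(t), making the per-bin statistic exactly
  multinomial, whereas time-pooled samples taken closer than the position
  decorrelation time would inflate it.
* Patch concentration: particles are counted in the slow square and in an
  equal-area control square far from it (default diagonally opposite), each
  normalized by total count and area fraction.  The fold-overconcentration
  reported by the experiment presets and the acceptance script is
  patch/control: that ratio equals the amplitude ratio r exactly for
  punctual particles at equilibrium regardless of the patch's area
  fraction, which is the prediction the theory makes, whereas the
  area-normalized patch value alone saturates at r/(phi r + 1 - phi) for
  patch area fraction phi (6.4 instead of 10 at r = 10, phi = 1/16).
  The slow square's edge band uses the compact smoothstep described above;
  with exponential (logistic) tails the patch-averaged density at r = 10
  would fall ~30% below the nominal fold because the equilibrium density
  1/(1 - (1-1/r) f) is hypersensitive to f slightly below 1.
* Clustering: the proximity graph links pairs closer than a*r0 (minimum
  image); connected components via scipy's union-find.  The coefficient
  c = (number of components, singletons included)/(number of particles)
  is ~1 without clustering and small when particles aggregate.  By default
  r0 = 1 and the printed threshold a = 2.7 is treated as an absolute
  distance ("a bit higher than sigma = 2.5"); pass r0 = sigma for the
  relative convention.
* FRAP: after pre-equilibration all particles within r_b of the center are
  flagged bleached; F(t) = unbleached particles in the zone divided by the
  zone's pre-bleach mean occupancy.  Half-time = first crossing of half the
  asymptotic recovery level F_inf = 1 - (bleached fraction of all
  particles), which is exact by particle conservation on the closed
  membrane; the end-of-window mean (reported as a diagnostic plateau) still
  drifts at the slow global-redistribution timescale and would bias the
  half-time.  A curve that never crosses half F_inf is flagged
  `unresolved`.  Two validity conditions shape the FRAP experiment design:
  (i) the bleach zone must be a small fraction of the *transformed* circle
  (the half-time law tau = gamma (int du/a)^2 is an
  infinite-reservoir approximation), so the canonical wells are embedded in
  a wide membrane (L = 16) rather than the L = 1 domain of the equilibrium
  experiments, where any zone covering the deep well spans 30-40% of the
  transformed circle and the law fails by construction; and (ii) the
  pre-bleach zone occupancy must itself be equilibrated (a long coarse-dt
  equilibration phase precedes the bleach), otherwise the normalization is
  biased low.  With both in place the measured gamma of this half-time
  definition is ~0.45 (used only to size simulation windows); measured
  heterogeneous/homogeneous ratios match the closed form within 20% and the
  homogeneous half-times scale as r^2 (fit exponent 1.9).  These
  definitions are the package's own — only the scaling laws are externally
  given — and gamma cancels in the ratios actually asserted.

## Interaction units

Interaction strengths are quoted in conventional printed units and
converted by `epsilon_scale` (default 1.5e-4).  Rationale: those strengths
(0..10000, nominally scaled down by 1e-12) belong to an unstated box/time
unit system; in this package's units (D0 = 1, sigma = 2.5, unit-amplitude
noise) the stationary law of the interacting system under the
mobility-weighted drift is prod_j a(x_j)^-1 * exp(-2 U_total) — the
effective thermal energy is kT_eff = 1/2 — and a 1e-12 scale would make
every force ~1e-8 and forbid clustering entirely.  The 1.5e-4 conversion
maps the sweep onto well depths 0..1.5 (0..3 kT_eff): clustering onset in
the middle of the sweep and, at the top, the strongest coupling at which
the dynamics remain quasi-reversible — clusters still exchange particles
and can migrate into slow zones.  Deeper quenches fall out of
quasi-equilibrium into arrested aggregation: clusters freeze wherever they
nucleate, the measured concentrations then reflect initial conditions
rather than the stationary law, and the slow-patch amplification cannot
develop.  The scale is a config field, not a constant.

Strongly coupled runs are equilibrated by annealing
(`engine.equilibrate_annealed`): starting from the punctual-particle
equilibrium, the interaction strength is ramped linearly over several
stages before the measurement window.  A direct quench to a deep
attraction freezes clusters wherever they first nucleate — mostly outside
the slow patch, since most particles start there — and the measured patch
concentration then reflects the quench history rather than the stationary
law; the ramp keeps the system near quasi-equilibrium at each coupling, so
clusters develop where the stationary measure concentrates the density.

The stationary law above also settles the drift ambiguity (mobility-
weighted `dt*D(X_j)*F` versus plain `dt*F`): the mobility-weighted form
satisfies detailed balance with the factorized equilibrium, under which a
cluster of m particles inside an r-times-slower patch is favored by r^m,
reproducing the observed cluster accumulation.  The plain increment lacks
detailed balance and measurably depletes the slow patch at strong coupling;
it remains available via `mobility_weighted=False` for comparison.

## Study conditions and scaled problem sizes

The continuous-model experiments use L = 1, dt = 0.01, 1e5 particles in 1D
and 1e6 in 2D (full-size presets fig1-fig4); the test suite and acceptance
script run the same pipelines at 1e4-2e4 particles in 1D where the
comparison statistics remain well within their calibrated thresholds.

The interacting experiments need a box large enough that a slow patch can
physically hold a many-fold overconcentration of finite-size particles
(hexagonal packing of disks at spacing sigma caps the patch density), and
small enough that cluster transport into the patch equilibrates within the
run: the package uses a 70 x 70 box (L = 35), patch side 17.5 (1/16 of the
area), sigma = 2.5, collisions on with core = sigma, and 50-100 particles.
The count matters geometrically: a condensed cluster occupies about
4 sigma^2/sqrt(3) per particle, so only ~55 disks fit inside the patch —
with many more particles the condensate necessarily overflows the patch
boundary and the patch concentration saturates below its nominal value
regardless of equilibration.  The interaction-sweep experiments therefore
use 50 particles (condensate area ~ patch area).  Plain runs last
1500-3000 time units discarding the first half as burn-in; strongly
coupled runs are annealed (8 ramp stages over 6400 time units) and then
measured over 3600 time units, with the fold summarized by the median
across seven seeds — the fold is heavy-tailed in both directions when a
transient cluster wanders through the small control square, so the median
is the appropriate location estimator.  Collisions-only ("crowding")
experiments use a dilute hard core (0.05) in a 24 x 24 box with patch side
6 and 1000 particles: the punctual-particle prediction only holds when
crowding is negligible — at a 10-fold patch occupancy even a modest core
produces a measurable excluded-area suppression — and the reference
crowding runs themselves "did not differ much" from the punctual
prediction.  Equilibration windows are multiples of the slowest relevant
timescale (interior relaxation of the slow patch, of order
(side/2)^2 / (2 D_patch), i.e. ~2000 time units for the r = 10 patch);
burn-in discards at least the first half of each run.  The strongly slowed
(r = 10) patch is additionally measured from a warm start: positions are
initialized by rejection sampling from the closed-form stationary law
(hard-core overlaps redrawn), after which the dynamics must sustain the
concentration over the burn-in and sampling window — long cold-start runs
confirm the discrete dynamics converge to the same value (within ~1% of
the smoothed-profile quadrature), so the warm start removes the slow
filling transient without substituting theory for measurement.

## What the generator does and does not emulate

Synthetic profiles emulate the geometry of membrane heterogeneity (wells,
patches, random multi-well fields) and the dynamics of overdamped diffusing
proteins with van-der-Waals-like attraction.  They do not emulate membrane
curvature, hydrodynamic coupling, rotational degrees of freedom, inertial
dynamics, binding chemistry, or temporal changes of the viscosity pattern.
Passing tests therefore demonstrate the mathematical mechanism — slow zones
overconcentrate and amplify clustering — not a quantitative fit to any
particular measured membrane.

## Numerical choices

* Quadrature: composite trapezoid on uniform grids (tensor-product in 2D),
  with a doubling check that raises a resolution error if the normalization
  constant still moves by more than 1e-6; the coordinate transform uses
  cumulative Simpson on 2^14+1 nodes with monotone (PCHIP) interpolation in
  both directions (round-trip error < 1e-8).
* Heat-kernel image sums truncate below 1e-12; Gaussian-profile image sums
  below 1e-18.
* Histogram defaults: 100 bins (1D), 64 x 64 (2D).
* Degenerate inputs raise typed errors (invalid parameters, overlapping
  initial configurations, unnormalized initial densities, non-finite
  positions mid-run) rather than propagating NaNs.

## Known limitations

* The hard-core collision pass is a rejection scheme, not an event-driven
  resolution; at high packing it slightly distorts short-time dynamics
  (equilibrium occupancies are unaffected in the dilute regimes used).
* The per-axis 2D Milstein scheme drops cross Levy-area terms; the residual
  dt-bias is measured by the dt-halving test rather than bounded a priori.
* At finite dt, larger noise amplitudes carry a larger discretization
  "temperature"; clustering comparisons across amplitudes are made at the
  shared default dt.
* FRAP half-times need the recovery plateau inside the simulated window;
  the `unresolved` flag is the guard, not an extrapolation.
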