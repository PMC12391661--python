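# Methods

This note documents the models implemented in `porehull`, the assumptions
behind them, the defaults and why they were chosen, and what the synthetic
data used in the test suite does and does not establish about real
tracking data.

## Physical picture

A fluorescent bead embedded in a hydrogel pore performs Brownian motion
until it collides with the pore walls. Over an acquisition long compared to
the cage-exploration time, the bead's position cloud fills the accessible
region of the pore, and the convex hull of that cloud is a solid model of
the cavity. Two independent size estimates follow: a per-pore one (hull
Feret diameter) and an ensemble one (the MSD diffusion length). The
nanometre-scale mesh between polymer crosslinks is a separate quantity,
estimated from equilibrium swelling, and is three orders of magnitude
smaller than the micron-scale pores treated here.

## Brownian simulator (`simulate.py`)

Free diffusion is an independent Gaussian walk per bead with per-axis step
variance 2·D·Δt, D = k_B·T/(6π·η·r). k_B is fixed at 1.38×10⁻²³ J/K, the
precision used throughout the downstream analysis; at the default assay
conditions (T = 300 K, η = 0.001 Pa·s, r = 0.5 µm) D = 0.439 µm²/s.

Confined diffusion keeps the bead *centroid* inside the geometry eroded
inward by one bead radius, since that is what a tracking algorithm reports.
Overshooting steps are folded back across the boundary:

- for planar walls (boxes, polyhedron facets) the fold is exact specular
  reflection across the offset plane, iterated for multi-facet overshoots;
- for spherical and cylindrical walls the *radial coordinate* is folded by
  a triangle wave into [0, R−r]. This is the small-step approximation to
  specular reflection off a curved wall; it preserves the step-length
  distribution and, because a shell just outside the wall maps onto a
  thinner shell just inside, its curvature bias slightly overweights the
  near-wall region. That bias is conservative for the quantities measured
  here (it cannot deflate hull diameters or the MSD plateau). Validation:
  the plateau MSD of an equilibrated ensemble in an 18 µm sphere with 1 µm
  beads matches the uniform-pair value 1.2·R² = 86.7 µm² to a few percent,
  and the hull Feret diameter converges to the accessible diameter 17 µm.

Initial positions are uniform in the accessible region. All randomness
derives from one integer seed via `numpy.random.SeedSequence`; panels spawn
per-well child seeds so each element is reproducible in isolation.
Optional observation effects, both off by default because they are
instrument-specific: additive Gaussian localization noise (a typical choice
is half a pixel, 0.23 µm at the 0.46 µm pixel size of the reference assay)
and z-quantization to 1 µm steps emulating confocal stacks.

The simulator makes no attempt at hydrodynamic wall coupling, anomalous
diffusion beyond geometric confinement, or polymer-network elasticity.
Tests passing on its output therefore establish the correctness of the
*analysis chain* under ideal confined-Brownian statistics, not robustness
to adsorption, drift, or localization error in real data.

## MSD analysis (`msd.py`)

The MSD is the displacement-from-origin ensemble average
MSD(t) = (1/N_t)·Σ‖pᵢ(t) − pᵢ(0)‖², *not* the lag-time-averaged MSD of
micro-rheology. Tracks of unequal length contribute wherever they have
data (N_t varies). For planar data z ≡ 0 enters the same formula.

**Diffusion length.** For confined ensembles the curve saturates; a line is
fitted by OLS along the plateau and extrapolated to t = 0, and the square
root of the intercept is the diffusion length. The plateau window is
auto-detected as the longest trailing window whose local log-log slope
stays below 0.1, with the local slope measured between octave-binned MSD
means (mean over [T/2, T] against [T/4, T/2], extending backwards octave by
octave). Binning is essential: pointwise slopes at late lag times divide
shrinking log-t increments into correlated ensemble wander and are pure
noise. The window must span at least 20% of the usable points. A curve
whose final octaves still rise (slope ≥ 0.1) raises a non-confined error
rather than returning a meaningless intercept. Note the plateau of a
*from-origin* MSD is the mean squared distance between two independent
draws from the cage's stationary distribution — for a sphere of accessible
radius R this is 1.2·R², so the diffusion length is ~0.54× the accessible
diameter. It is a consistent *proxy* for pore size, not an unbiased
estimate of it.

**Diffusion exponent.** The slope of ln MSD vs ln t (t = 0 excluded) over
the whole curve by default, following the convention MSD = 6·D·tⁿ. The
prefactor 6 is kept for planar data too; this affects only the recovered
effective D, never n. Regime classification uses a tolerance of 0.05
around n = 1.

For ensembles pooled across samples versus per-sample fits, the functions
operate on whatever TrackSet they are given; pooling is the default
workflow and per-sample analysis is a caller-side split.

## Pore models (`pores.py`)

Hulls come from `scipy.spatial.ConvexHull`. 2D hull vertices are
canonicalized to a closed counterclockwise ring starting at the lowest
(y, x) vertex so that downstream shoelace centroids are reproducible. 3D
models carry triangulated facets. Degenerate clouds (coplanar/collinear)
are skipped with a recorded reason, never silently projected down.

The Feret diameter is the maximum pairwise distance among hull vertices
(which equals the maximum over all cloud points, since extreme points are
hull vertices). The reported diameter adds the bead diameter: tracked
centroids cannot approach a wall closer than one radius, so the raw hull
underestimates the cavity by one bead diameter across. Volume and surface
area are reported *uncorrected* — the proper correction would be a
Minkowski dilation by the bead radius, which is out of scope; treat
volumes/areas as lower bounds with an O(r/R) relative bias.

Minimum track length for hull building defaults to 10 localizations:
shorter clouds grossly under-sample the cavity. Short tracks remain
available for MSD analysis. An optional z-limits flag excludes tracks that
touch the imaging-volume boundary (off by default, as the reference
workflow does not state such a filter).

`pooled_pore_model` pools all tracks in a set into one hull. It is the
right estimator when all beads probe the *same* cavity — the microwell
validation uses it, because a single bead cannot traverse a 250 µm well
within a realistic acquisition, while twenty drop-cast beads sample it
densely. For gels, where each track sits in its own pore, per-track models
are the correct unit.

## Simulated SEM sections (`sem.py`)

To compare tracking-derived 3D pores with planar micrographs on equal
footing, pores are sampled uniformly at random without replacement until
the next pore would push the summed volume over the budget (default
300 000 µm³ — a greedy "equal or a little less" rule, seeded). Selected
pores are flattened by deleting z from the hull vertices and re-hulling in
the plane. Flattening is a projection, so every 2D Feret diameter is ≤ its
3D parent; medians of flattened populations fall below the corrected 3D
medians, which is the mechanism behind cross-sectional imaging
underestimating pore size. The resolution filter removes pores below a
diameter floor (no default — it must come from the reference micrographs)
and below 10 µm² area (the smallest pore detectable in the reference
imaging). Distributions are compared by a two-sided Mann–Whitney U test;
a Bonferroni helper covers families of comparisons.

The flattening axis is fixed to z, matching the cross-sectioning
convention; a random-plane variant was considered and left out of the
default paths to keep the pipeline deterministic and minimal.

## Layouts and packing (`layout.py`)

Polygon centroids use the signed shoelace formulas on closed CCW rings;
orientation violations raise rather than being silently fixed, because a
clockwise ring would negate the area and corrupt the centroid.

The packed layout places one placeholder circle per pore, with diameter
equal to the pore's planar Feret diameter (the diameter definition used
everywhere else in the package; an equivalent-area diameter would pack
tighter but mix conventions). Packing is a deterministic front-chain
algorithm: each circle is placed tangent to two circles of the advancing
front, the front is scanned for collisions and re-anchored at the pair
closest to the packing centre. Input order is preserved because the
algorithm is order-sensitive. Contracts, enforced by property tests over
seeded random panels: no pairwise overlap beyond 1e-9 µm, and every circle
after the second tangent to at least one predecessor. Pores are moved onto
their circles by pure translation (no rotation — the pore's spatial
orientation is part of the measurement), so area, perimeter and diameter
are preserved to 1e-9.

Rendering draws outlines with matplotlib at a stated µm-per-pixel scale
with a scale bar; SVG or PNG by file extension.

## Flory–Rehner calculator (`swelling.py`)

The chain Q_m → Q_v → υ → M_c → ξ follows the printed equations exactly:
Q_m = (m_wet − m_dry)/m_dry and Q_v = 1 + (ρ_p/ρ_s)(Q_m − 1). Note this
pair is a *convention*: with Q_m defined as above (solvent mass per polymer
mass), the textbook volume relation would not subtract 1; the implemented
form is the one the downstream constants were calibrated against, and the
calculator is internally consistent under it. ῡ = 1/ρ_p in cm³/g against
V₁ in mL/mol is dimensionally consistent (cm³ = mL). The logarithm in the
mixing term is evaluated exactly. The 2/M_n term uses the molecular weight
of the polymer *before* crosslinking (the quantity sometimes conflated
with M_c in writeups of the method). Defaults are the PEG/PBS constants
ρ_p = 1.125 g/cm³, ρ_s = 1.011 g/cm³, V₁ = 18 mL/mol, χ₁ = 0.426,
M_r = 44 g/mol, l = 0.15 nm, Cₙ = 4.

Failure modes surface as errors, not numbers: Q_v ≤ 1 (no net solvent
uptake) and nonpositive 1/M_c (swelling inconsistent with the network
model) both raise. Only mass ratios matter, verified by a scale-invariance
property test. The end-to-end chain is pinned against a stepwise
hand-computed oracle (M_c = 2847.448 g/mol, ξ = 9.5813 nm on the reference
input set) frozen before the implementation was written.

## Problem sizes and numerical choices

Test and acceptance runs use ensembles sized so each check is decisive yet
quick: 1000 beads × 180 steps for the free-diffusion exponent (the fit's
Monte-Carlo spread is well inside ±0.05), 20 beads × 2000 steps per
microwell across 9–250 µm wells, 10⁴ steps for single-track sphere
recovery, and 100 random panels of up to 200 circles for the packing
audit. Hull containment and rigidity tolerances are 1e-9 µm; the packing
overlap slop is 1e-10 µm internally (above double-precision noise at
100 µm coordinates, below the 1e-9 contract). Degenerate inputs (too few
points, collinear/coplanar clouds, empty track sets, open or clockwise
rings, nonpositive physical parameters) raise typed errors from
`porehull.errors`.

## Known limitations

- Pores smaller than the bead are invisible; pore sizes are conditioned on
  bead accessibility.
- Convex hulls cannot represent concave cavities or pore connectivity;
  volumes/areas are uncorrected for the bead radius (lower bounds).
- The from-origin MSD plateau estimates pore size only up to a
  geometry-dependent factor (~0.54 for spheres).
- The simulator's idealizations (no adsorption, no localization error by
  default, no hydrodynamic wall drag) mean green tests bound algorithmic
  correctness, not experimental robustness.
- The radial-fold reflection is approximate for curved walls at step sizes
  comparable to the radius of curvature; its bias direction is documented
  above.
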