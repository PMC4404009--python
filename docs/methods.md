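# Methods

## The shell model

A planispiral shell is generated by an ellipse revolving about a coiling
axis while its distance from the axis grows exponentially:
`r(θ) = W^(θ/2π)` in units of the outer radius at the aperture.  In the
half-plane at angle θ the aperture is an ellipse spanning the radial
interval `[D, 1]`: center `c = (1+D)/2`, radial semi-axis `a = (1−D)/2`,
axial (width) semi-axis `b = S·a`.  All outputs are dimensionless ratios;
because the shell is self-similar, every per-angle integrand is a pure
power of `r` and ratios of integrands are independent of position along
the spiral and of absolute size.

Successive whorls interpenetrate when `W < 1/D` (the whorl laid down one
revolution earlier spans `[D/W, 1/W]`, overlapping the new section's
inner part).  Beyond that curve shells are gyroconic (whorls never touch).

## Internal-volume to shell-material ratio

The economy performance is the ratio of two per-radian integrands:

- **internal volume**: the radial first moment of the aperture section,
  `∫∫ ρ dA = π a b c` (the solid-of-revolution volume element; the whole
  tube counts — chambers plus body);
- **shell material**: wall thickness × the radial-moment arc integral of
  the wall being built, `t·√(ab) · ∫ ρ ds` over the section boundary.

Conventions, all explicit keyword options with these defaults:

- **Thickness scale** (`thickness_fraction`, default 0.077): thickness is
  a fixed fraction of the *local whorl-section radius* `√(ab)` (the
  geometric mean of the semi-axes).  This is the only scaling under which
  the ratio is constant on the gyroconic region at fixed `S` — for
  circular sections it equals `1/(2·0.077) = 6.49` at every `(D, W)` with
  `W > 1/D` — and the `√(ab)` mean (rather than `a` or `b`) makes the
  gyroconic value, and with it the 3-D optimum, symmetric in `S ↔ 1/S`
  with its maximum at circular openings.
- **Already-built wall** (`cover`, default `"sections"`): the part of the
  new section's boundary lying inside any previously laid whorl section
  (union over all earlier revolutions, with a continuous-scale envelope —
  the tangent cone `|y| ≤ bρ/√D` — standing in for whorls deeper than the
  explicit union, which matters only as `W → 1` where the discrete scales
  become dense).  Alternatives implemented for sensitivity analysis:
  `"circle"` (everything within distance `1/W` of the coiling center) and
  `"halfplane"` (everything below radius `1/W`).
- **Shared-wall cost** (`shared_wall_weight`, default 0.5): a wall between
  two adjoining whorls is built once and serves both, so each whorl's
  material bill carries half of it.  `0` treats shared walls as free,
  `1` ignores sharing entirely (and makes the ratio constant everywhere).
- **Internal area** (`internal_area`, default `"full"`): the full section
  area counts as internal volume.  The `"net"` option instead counts only
  the part of the section outside previously built whorls (the newly
  enclosed space); it sends the ratio to zero as `W → 1` and moves the
  economy optimum into the grid interior (`D ≈ 0.9, W ≈ 1.1`).

Under the defaults the economy surface is the gyroconic constant right of
`W = 1/D`, rises through a ridge running from the involute low-`W` corner
toward high-`W`/low-`D` shells, and is maximised at the boundary corner of
the default grid (`D = 0.95`, `W → 1`): the more tightly a shell coils,
the larger the fraction of its wall that is shared.  The optimum's exact
location is therefore a statement about the wall-accounting convention and
the grid bounds as much as about geometry — analyses of this kind that
report an interior economy optimum depend on details of their overlap
accounting, and the options above are provided precisely so such
alternatives can be explored.  The growth optimum and the `S ≈ 1.0`
coordinate of the 3-D economy optimum are, by contrast, stable across all
conventions we examined.

`surface_to_volume` uses the same integrands (exposed wall per internal
volume).  Its `normalized` form `surface / volume^(1/2)` is symmetric
under `S ↔ 1/S` and minimal at `S = 1`; the raw per-radius ratio falls
monotonically with `S` simply because the section area grows, so
globularity comparisons should use the normalised form.

## Performance surfaces and optima

- **Economy**: wraps the volume ratio (above).
- **Growth**: a shell's material production is taken proportional to its
  body volume; accumulating the reciprocal diameter over growth gives the
  penalty `P = W / (Ratio(D, W) · log W · (1 + √W))` with `Ratio`
  evaluated at `S = 1` by default.  The performance is `1/P`: zero at
  `W → 1` (the penalty diverges with `1/log W`) and peaked at
  `(D, W) ≈ (0.166, 4.33)` under the default ratio conventions.  The
  surface is extremely flat near its peak (within 1% over
  `D ∈ [0.1, 0.2] × W ∈ [4.2, 4.6]`), so the argmax location is far less
  certain than the peak value.
- **Drag**: only two facts are used downstream — drag rises monotonically
  with `D`, `W` and `S`, and the hydrodynamic optimum is the low corner.
  The default surface is the documented stand-in `−(D + S/2 + W)`;
  measured drag tables (CSV columns `D,S,W,cd`) are interpolated linearly
  inside their convex hull and by nearest neighbour outside.

Grids: `D` 101 points on `[0, 0.95]`, `W` 101 points on `[1+1e-6, 5]`
(`[1+1e-6, 6]` for growth), `S` 36 points on `[0.1, 3.5]`.  `W = 1` is a
singular closed-circle limit and is approached, never evaluated.  Grid
argmaxes break ties toward lexicographically smallest `(D, S, W)` and are
polished by Nelder–Mead clipped to the grid box; optima on a box edge are
flagged as boundary optima.

Quadrature: fixed 256-node Gauss–Legendre for all section integrals
(~1e-12 on smooth arcs, ~1e-7 on the square-root-edged area integrand);
the exposed/shared wall split is resolved to O(1/256) of the arc, well
below the spread among the overlap conventions themselves.

## Pareto fronts

A grid point survives iff no other point is at least as good at every
task and strictly better at one; ties are kept so symmetric inputs are
preserved.  The implementation sorts by total performance (a dominator
always has a strictly larger sum) and checks candidates blockwise; it is
exact, matches the quadratic-time definition on every tested instance,
and handles the default grids in seconds.  Fronts are computed on grids,
not by contour-tangency geometry; with smooth single-peaked tasks the
front converges to the convex hull of the task optima, with a one-to-two
grid-cell fringe near the optima where contours flatten.

## Polytope fitting

Both fitters standardise traits to zero mean and unit variance (the trait
ranges differ by an order of magnitude) and map results back; RMS errors
are reported in standardised units.

**Minimum-volume soft-enclosing simplex** (`fit_simplex`): minimises
`volume + outside_penalty · Σ hinge(point outside)` over the `d+1`
vertices, where the hinge is the maximum outward facet margin (zero
inside, a lower bound on Euclidean distance outside).  The default
penalty 200 effectively encloses everything (fraction inside 1.0 on ≤2%
noise data).  Initialisation is deterministic: the maximal-volume simplex
over convex-hull vertices, inflated 10% about its centroid; further
seeded jittered restarts guard against local minima.  Two systematic
biases are inherent to enclosing fits and visible in the tests: an
outward offset of order the penalty/volume equilibrium (~1e-3 standardised
on noise-free data) and an apex overshoot of order noise/sin(apex angle)
on noisy data (~0.1 of the trait range at 2% noise for the thin growth
apex).

**PCHA** (`fit_pcha`): archetypes are convex combinations of data rows
(`delta`-relaxed if requested; default `delta = 0`), data rows are convex
combinations of archetypes, and the Frobenius reconstruction error is
minimised by block alternating projected gradient — eight inner gradient
steps per block with adaptive backtracking step sizes, exact sorted-based
simplex projections, convergence at relative improvement < 1e-8.  The
first restart seeds archetypes at FurthestSum extreme points, the rest at
random rows; 20 seeded restarts by default, best kept, all seeds
recorded.  `rms_profile` warm-starts each `k` from the best `k−1`
solution plus a point-mass archetype on the worst-reconstructed row,
which makes the error profile non-increasing in `k` by construction.

Identifiability caveat: archetypes can only be recovered where the data
actually approach them.  With strongly interior sampling (Dirichlet
concentration ≳ 0.5) the optimal archetypes sit well inside the true
vertices — that is a property of the estimand, not a solver failure — so
recovery experiments use corner-reaching sampling (concentration ≈ 0.25).

## Randomisation statistics

- **t-ratio**: convex-hull area of the data over fitted-triangle area;
  1 for perfectly polygonal data.  The polygonality null permutes each
  trait column independently (preserving marginals exactly) and refits
  the triangle per replicate by default; a fixed-triangle variant exists
  and is calibrated only when the columns are independent.
- **Triangle similarity**: intersection-over-union by exact polygon
  clipping; the null draws both triangles' vertices i.i.d. uniform on a
  rectangle.  The ratio is invariant under per-axis scaling applied to
  both triangles, so the rectangle's shape is irrelevant.
- **Size enrichment**: Euclidean distance to an archetype in
  standardised trait space, ten equal-count bins (ties broken by stable
  sort), least-squares slope through the bin means, two-sided permutation
  p-value.  The slope convention is value-versus-distance: shells that are
  *large near* an archetype give a *negative* slope.
- All Monte-Carlo p-values are floored at `1/n_null`, never zero.

## Westermann projection

No unique published formula exists for the ternary mapping, so the
package uses a documented affine-then-normalise construction: scores
`(D, (W−1)/(w_ref−1), S/s_ref)` with `w_ref = 5`, `s_ref = 3.5`,
normalised to barycentric coordinates.  The qualitative structure this
must (and does) reproduce: three archetypes near distinct corners, the
depressed-involute archetype near an edge, and severe distortion near the
all-scores-small corner, quantified by mapping a ball of 5% of each
trait's span and summarising the planar spread of its image.  Points with
all three scores zero have no defined image and are rejected/counted.

## Synthetic data generator

`make_dataset` emulates an era-partitioned genus table: eras of 113, 386
and 392 genera (the three intervals between the Frasnian–Famennian,
Devonian–Mississippian and Permian–Triassic extinctions), traits drawn as
Dirichlet-weighted combinations of the five default archetypes plus
isotropic Gaussian noise (sd 0.02 trait units), and diameters from a
multiplicative model `base · Π effect_v^weight_v · lognormal(0.4)` with
default effects (1, 1.8, 1.6, 0.4, 0.5) planting large shells near the
drag/growth archetypes and small ones near the compact archetypes.  The
default Dirichlet concentration 0.8 fills the pyramid the way the fossil
clouds look (mass toward faces, sparse corners).

What the generator does *not* emulate: phylogenetic autocorrelation
between genera, survivorship through extinctions, measurement error
structure of real fossil compilations, or era-to-era differences in
occupancy.  Passing tests therefore demonstrate that the estimators
recover known geometric/statistical structure from idealised tables of
the study's size — not that real compilations have that structure.

## Problem sizes

Default analysis sizes, chosen to resolve each quantity comfortably on a
single CPU: 101×101 trait grids (101×36×101 in 3-D) with local
refinement; 10,000-replicate similarity nulls; 200-replicate polygonality
nulls in the pipeline (10,000 is the study-scale value; the p-value floor
scales accordingly); PCHA with 8–20 restarts and n up to ~1000.

## Known limitations

- The economy optimum's location is convention- and boundary-dependent
  (see above); report it together with the wall-accounting options used.
- Enclosing-simplex vertices are biased outward by noise; PCHA archetypes
  are biased inward wherever corners are sparsely populated.
- The growth model ignores the `S`-dependence of growth beyond its effect
  through the volume ratio, and the drag default encodes monotonicity
  only — supply measured tables for anything quantitative.
- The Westermann construction is one reasonable reconstruction; only its
  qualitative statements are meaningful.
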