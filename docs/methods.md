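# Methods

This note documents the models and procedures implemented in
`betascape`, the defaults they ship with, and the reasoning behind the
design choices that were genuinely open.

## Dissimilarity index

Compositional turnover between two sites with abundance vectors x, y is
measured by the Horn–Morisita dissimilarity

    d(x, y) = 1 − 2 Σᵢ xᵢyᵢ / ((Σᵢxᵢ²/X² + Σᵢyᵢ²/Y²) · X · Y)

with X = Σx, Y = Σy.  The index derives from the probability that two
individuals drawn one from each site are conspecific.  It is symmetric,
bounded in [0, 1], defined for non-integer abundances, and invariant to
proportional rescaling of either community — the property that makes it
usable on ad hoc occurrence data with wildly unequal sampling effort.
The classical Morisita form (integer counts, unbiased Simpson
denominators) is available behind a flag for comparison; note it is not
zero on identical communities and can go negative, which is why the
Horn form is the default.  Both totals must be positive; empty
communities are an error, never a silent zero.

## Site formation (Markov clustering)

Occurrence coordinates are grouped into sites with the Markov Cluster
algorithm on a similarity graph: records within `edge_radius` degrees
(Euclidean on decimal degrees, matching the upstream distance
computation; haversine is available behind a flag) are joined with
Gaussian-kernel weights exp(−d²/2h²) plus unit self-loops.  The
column-stochastic flow matrix is iterated through one optional
pre-inflation, then expansion (matrix square) and inflation
(element-wise power, renormalize) with pruning of entries below
`prune_threshold`, until the matrix change falls below
`convergence_tol`.  Clusters are the connected components of the
thresholded, symmetrized limit matrix.  Column sums stay within 1e-9 of
1 after every normalization (asserted in tests via the iteration
trace).

Defaults follow the reference implementation of the algorithm:
inflation 2.0, no pre-inflation, prune 1e-5.  The graph-construction
parameters (radius 0.5°, bandwidth 0.1°) bound cluster reach so that
continental-scale sites cannot form; the packaged small-world
configuration widens them to 0.8°/0.3° because its pixels are a full
degree across.  Inflation and pre-inflation are exposed in the run
configuration since appropriate values are data-dependent.

## Boundary removal

Records are binned by coordinates rounded to one decimal place (0.1°
cells, roughly 5 km half-width at mid-latitudes).  A bin is a boundary
bin when the region-class grid disagrees across the bin's four corners
and center (default, record-independent and deterministic), or — behind
the `record_pixels` switch — when the classes under the bin's own
records disagree.  All records in boundary bins are removed, so mixed
communities straddling two regions cannot blur the class contrasts.  In
the pipeline, boundary removal runs before site clustering so that site
centroids are computed from retained records only.

## Sparsity filters

Species observed at fewer than `min_sites_per_species` sites and sites
with fewer than `min_obs_per_site` records are removed **iteratively to
a fixed point**: dropping a site can push a species back below
threshold and vice versa, and a single pass can leave the stated
invariant violated.  Library defaults are 30 sites/species and 300
records/site, appropriate for snapshots with tens of millions of
records; the packaged 20k-record world scales them to 2 and 3.  The
result is checked against a brute-force fixed-point oracle and is
invariant to the order the two criteria are applied within a pass.

## Raster extraction

Grids are north-up with half-open pixel intervals: pixel (0,0) is the
northwest corner, a point on an internal edge belongs to the
pixel east/south of the edge, so every in-extent point maps to exactly
one pixel.  Extraction reads the containing pixel; if it is nodata the
grid is coarsened by nearest-neighbour resampling at integer factors
2, 3, … up to `max_fallback_factor` (default 8) and the first valid
value is taken, with the factor recorded as provenance.  The coarse
pixel's value is that of the valid fine pixel nearest the block center
(row-major on ties), so coarse values are always a subset of fine
values and a block with any valid pixel yields data.  A point still on
nodata at the maximum factor is flagged missing and its site excluded —
never silently filled.  Multi-year vegetation layers are composited
per-pixel by the median over valid years (even counts: mean of the two
central values).

Real-data products tie fallback steps to metric pixel sizes
(e.g. 250 m → 2,000 m); the integer-factor generalization covers that
case through configuration while remaining meaningful for grids in
degrees.  Each layer is sampled independently at the site centroid;
no attempt is made to reconcile native resolutions across layers.

## MRM and the Mantel test

Distance matrices violate the independence assumptions of ordinary
regression, so inference is by permutation: the response matrix's rows
and columns are permuted simultaneously (the matrix analogue of
permuting observations) while predictor matrices stay fixed.  The test
is one-sided (greater) with the add-one correction
p = (1 + #{statistic_perm ≥ statistic_obs}) / (n_perm + 1).  The
overall MRM p-value uses the permutation null of R²; per-coefficient
p-values use |t| nulls.  Environmental predictor matrices are absolute
per-variable differences |eᵢ − eⱼ|; predictors are z-standardized on
the unfolded scale by default so coefficients are comparable (raw scale
behind a flag).  Matrix triangles are always unfolded row-major over
i < j so vectors align bit-identically across modules.  Calibration is
tested: under a true null both tests reject at 0.05 with frequency
inside [0.03, 0.07] across 500 simulations.

## Generalized dissimilarity model

Each predictor x (latitude and longitude entered separately, plus each
environmental variable) is expanded in monotone I-splines: integrals of
order-2 M-splines, i.e. piecewise-quadratic curves rising 0 → 1 over
the predictor's range.  With the default 3 basis functions the knots
sit at the 0/50/100 percentiles of the predictor's site values — the
de-facto standard for this model family.  The linear predictor and
link are

    η = β₀ + Σₚ Σₖ β_pk |I_pk(x_pi) − I_pk(x_pj)|,   μ = 1 − exp(−η)

with all coefficients constrained ≥ 0, so predicted dissimilarity is
monotone in every gradient and saturates over long gradients.  The fit
minimizes the weighted continuous-binomial deviance

    D = 2 Σ w_ij [ d ln(d/μ) + (1−d) ln((1−d)/(1−μ)) ]

(0·ln 0 = 0; observed d = 1 is nudged to 1 − 1e-9 to keep logs finite)
by iteratively reweighted least squares with a non-negative
least-squares inner solve.  The weighted LS subproblem is reduced to
its k×k normal equations (Cholesky) before the NNLS call, which makes
permutation refits cheap; a step-halving guard keeps the deviance
monotone.  The deviance is convex in β under this link, so the
constrained optimum is unique — verified against random search (10⁴
feasible draws) and a generic box-constrained optimizer with restarts.
Convergence is a relative deviance change below 1e-8, with the scale
floored so a perfect fit (deviance → 0) also converges; non-convergence
raises with the deviance trace.

Site pairs are weighted by richness, w_ij = (Sᵢ + Sⱼ)/(2 max S), which
damps poorly sampled sites.  A predictor's **magnitude** is the sum of
its fitted coefficients — the plateau height of its I-spline, i.e. the
maximum partial ecological distance attributable to that gradient.
Significance is tested by permuting the predictor's site values across
sites, rebuilding pairs and refitting (default 100 permutations in the
library, fewer in the fast fixture configuration); the p-value compares
permuted percent-deviance-explained against the observed.  This
permutation scheme mirrors standard variable-importance practice for
the model family; the null deviance comes from an intercept-only fit
under the same link and weights, and percent deviance explained for
reporting uses the full-predictor fit rather than a re-fit on the
significant subset.

## Beta-diversity maps

Rasters of kept predictors are transformed pixel-wise to partial
ecological distance f_p(x) = Σₖ β_pk I_pk(x) (bounded by [0,
magnitude_p]; nodata propagates).  PCA over valid pixels reduces the
transformed stack; the first three components are min–max scaled to
[0, 255] and assigned to red, green, blue.  Component signs are fixed
so each loading vector's largest-magnitude entry is positive, making
colors reproducible across reruns; with fewer than three layers the
stack is padded with zero layers and a warning raised.

## Synthetic worlds

The generator emulates the study's input structure with known ground
truth.  Environmental surfaces are low-pass-filtered Gaussian noise
blended (weight 0.4) with a monotone latitudinal gradient, scaled to
[0, 100]; the region-class map partitions the grid by k-means over
spatial position and smoothed environment.  Species follow a Gaussian
niche times a hard circular dispersal range,

    λ_s(pixel) = I_s exp(−Σ_v (e_v − o_sv)²/2b_sv²) · 1[|p − c_s| ≤ r_s],

the simplest model realizing both environmental filtering and dispersal
limitation.  Pool defaults: optima uniform inside observed ranges,
breadths 15–60% of each variable's range, radii 35–90% of the extent
half-diagonal, lognormal intensities (σ = 0.5).  Sampling draws pixels
from an effort-weighted multinomial over total expected abundance,
species from the pixel's composition, and jitters coordinates uniformly
within the pixel so records are never grid-aligned.  The default effort
surface is a two-patch 10:1 west/east split emulating regional database
bias.  The packaged test world uses a 24×24 grid over a 24°×24° extent
(1° square pixels), 5 environmental variables, 3 region classes, 40
species and 20,000 records — large enough for several hundred sites
after clustering, small enough that the full chain runs in about a
minute on one CPU.

`true_pair_dissimilarity` evaluates Horn–Morisita on the *expected*
(noise-free) abundance vectors of two cells, giving an exact oracle for
parameter-recovery experiments.

What the generator does **not** emulate: taxonomic error and synonymy,
temporal dynamics, species interactions, spatially autocorrelated
observation error, and the heavy-tailed species-abundance distributions
of real insect data.  Passing tests therefore demonstrate correctness
of the statistical machinery and recoverability of planted structure,
not performance on real occurrence snapshots.

## Numerical conventions

- Distance-matrix triangles unfold row-major over i < j everywhere.
- Permutation p-values always use the add-one correction, so p ∈
  (0, 1] and is never zero.
- All generators and tests are seeded; the pipeline expands one
  top-level seed per stage via `SeedSequence(seed, spawn_key=(k,))`.
- Degenerate inputs raise informative errors rather than warn: empty
  communities, zero-variance predictors, constant knots, all-nodata
  extraction, rank-deficient MRM designs, empty filter fixed points.

## Known limitations

- MCL on very dense graphs (radius ≫ typical nearest-neighbour
  distance) is memory-hungry because expansion fills in 2-hop
  neighbourhoods; choose `edge_radius` near the intended site scale.
- The GDM permutation test refits the full model per permutation and
  per predictor; cost grows linearly in both.  The fixture
  configuration uses 20 permutations (resolution p ≥ 1/21), the library
  default 100.
- Geographic distance is Euclidean on decimal degrees by default for
  consistency with the site-clustering metric; at continental scales
  this distorts east–west distances (haversine is available).
- GeoTIFF I/O writes ModelPixelScale/ModelTiepoint/GDAL-nodata tags
  only (no full CRS key directory); text rasters use the ESRI ASCII
  grid format, which requires square pixels.
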