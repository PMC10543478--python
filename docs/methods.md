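# Methods

## Idealized grid-cell model

A grid cell's firing-rate field is the sum of three planar cosine gratings
whose stripe directions are θ, θ+60° and θ+120° with wavevector magnitude
4π/(√3·λ).  With that magnitude the maxima of the summed gratings form a
hexagonal (triangular) lattice with nearest-neighbor distance λ along the
directions θ + k·60°.  The sum ranges over [−1.5, 3] and is rescaled
affinely to [0, `peak_rate`]; there is no thresholding or rectification, so
fields are smooth cosine bumps peaking at lattice points.  The peak rate is
not constrained by the phenomena being modeled; the default is 10 Hz,
typical of entorhinal grid cells, and configurable everywhere.

A module (`make_module`) draws spacing and orientation per cell from normal
distributions — defaults λ ~ N(45, sd²) cm, θ ~ N(14.9, sd²)° with sd = 0,
the reference comodular configuration; realistic variability is about 5 cm
and 3° — and draws each cell's 2D phase uniformly over its lattice unit-cell
parallelogram, which is the correct uniform distribution over distinct
lattice translations.

Environments are an open circular arena (radius 75 cm by default) and an
annular track (outer radius 75 cm, width 15 cm, i.e. inner radius 60 cm),
both binned at 1 cm.  Track responses are the literal slice of the arena
field: rates outside the annulus are zeroed and marked unvisited.

Trajectories are synthetic foraging paths: in the arena a heading random
walk (diffusion 1.5 rad/√s) reflected at the wall; on the track noisy
angular progression at ~15 cm/s with radial jitter and direction reversals
(probability 0.001 per 20-ms step — animals on the real track were free to
turn around).  A deterministic `n_laps` variant produces steady clockwise
laps for lap-stability analyses.  Spikes are an inhomogeneous Poisson
process: the rate is held constant over each 20-ms trajectory interval, the
count per interval is Poisson(rate·Δt) and times are uniform within the
interval; time-rescaled inter-spike intervals pass a KS test against Exp(1).

What the generator does *not* emulate: theta modulation, firing-rate
adaptation, head-direction conjunctive tuning, lattice shear/ellipticity,
boundary-driven deformations, out-of-field noise spikes, or lap-to-lap
field drift.  Passing tests therefore demonstrate that the analysis
recovers lattice structure from undersampled but ideal hexagonal inputs;
they do not certify behavior under every distortion present in real
recordings (the field-shuffle and spike-shuffle nulls cover the "no
structure" alternative, not intermediate ones).

## Rate-map estimation

The average rate at x is the kernel ratio
λ(x) = Σᵢ g(sᵢ−x) / Σₜ g(y(t)−x)·Δt with unnormalized Gaussian kernel
g(r) = exp(−|r|²/2σ²), σ = 3 cm (any normalization constant cancels).
Spike positions sᵢ interpolate the path linearly at spike times; the time
integral is a Riemann sum over trajectory samples with Δt the median
inter-sample interval.  Kernels are truncated at 7σ (relative error
< 3·10⁻¹¹, verified against an untruncated brute-force oracle).  Bins more
than 3 cm from every recorded position are unvisited and set to 0 (exact
nearest-neighbor query, not a rasterized approximation).

Linearization maps the path to cumulative signed angular distance about the
track center (clockwise positive, configurable) times a linearization
radius.  The per-bin rate in 1-cm bins is spikes/timestamps/Δt.  Two radius
conventions are plausible for a 60–75-cm annulus — the outer radius
(circumference 471 cm) and the midline (424 cm); the outer-radius value is
the default and both are supported, since either appears in common use and
the choice rescales the lag axis only.

## Autocorrelograms

The per-lag Pearson autocorrelation is computed for every integer-bin lag
from sliding sums obtained by FFT convolution (verified to 10⁻⁹ against an
explicit double loop).  Three modes:

- `zero_fill_pearson` (default): unvisited bins count as rate 0 and the
  correlation runs over the overlap of the two square extents.  This
  reproduces the artifacts the environment geometry itself contributes — a
  binary track map yields a central peak plus an outer ring near the track
  diameter — which is the behavior the analysis tradition expects.
- `masked_pearson`: only bins visited in both shifted copies enter; lags
  with fewer than 20 shared bins are invalid.  Carrying no zeros, it is
  free of geometry artifacts.
- `raw`: unnormalized sliding inner product.

A **support mask** option restricts the zero-fill window to the
environment's bounding disc.  The square window is anisotropic: at equal
lag magnitude, diagonal lags retain larger overlap windows than
axis-aligned ones, which on sparse track maps biases inner-ring peak angles
by ~6° toward the diagonals.  A disc window is isotropic in lag direction
and removes the bias while keeping the off-track zeros (hence the track
artifacts); the pipeline uses it for circular environments.

The population autocorrelation is the plain elementwise sum of per-cell
correlograms, with no renormalization; cells whose correlograms carry more
surviving structure therefore weigh more, by design.  A lag is valid in the
sum if valid in at least one input.  Pearson correlograms of constant maps
have no valid lags (flagged, not NaN-propagated into downstream sums).

## Annulus extraction, gridness and lattice inference

M(r), the mean correlation on concentric rings of integer radius, decreases
from the central peak to a trough and rises to the center of the innermost
peak ring.  r_min is the first local minimum of M beyond 2 bins and r_max
the **first** local maximum beyond it (the global maximum can sit on the
track-diameter geometry ring, which would be wrong); the extracted annulus
spans [r_min, 2·r_max − r_min], clipped to the correlogram half-extent.
If no minimum/maximum pair exists, or the rise M(r_max) − M(r_min) is below
2% of M(0), the profile is treated as structureless and the fallback
annulus (25, 40) cm is used and flagged.  The 2% floor was set so that the
shallowest clearly-hexagonal profile in the reference configurations (the
20-cell track population, whose rise is ≈4.6% of M(0)) is comfortably above
it while flat noise profiles fall below.

The rotational correlation ρ(φ) correlates annulus bins with bilinear
interpolations of the correlogram at the back-rotated positions, dropping
pairs whose rotated sample leaves the valid region.  Gridness is
min{ρ(60°), ρ(120°)} − max{ρ(30°), ρ(90°), ρ(150°)} ∈ [−2, 2]; a 3°-step
ρ(φ) profile is available for diagnostics.  A radially symmetric annulus
scores 0, a square lattice negative, an ideal hexagonal lattice ≈1.5.

Peaks are located on the upper half-annulus (0°–180° from the positive
x-axis) by iterative argmax, excluding ±35° (mod 180°, via point symmetry)
around each found peak, three iterations; argmax ties resolve to the lowest
(row, column) index and peak coordinates are bin centers (no subpixel
refinement — 1-cm bins are two orders below the spacing).  Spacing is the
mean peak radius, orientations are the three peak angles.

On a track the central peak can obscure the inner ring and the detected
ring may be the *second* hexagonal ring, at radius √3·λ rotated 30°; the
caller interprets which ring was found.  `second_ring_features` searches
the radial band (1.37, 1.87)·λ — the geometric midpoints between the
consecutive ring radii λ, √3λ and 2λ — with the same three-peak procedure.
For track data this measurement is performed on the masked-mode population
autocorrelation: in zero-fill modes the track's inner-diameter artifact
ring (120 cm) and the 2λ ring overlap and swamp the √3λ ring, while masked
mode recovers it cleanly (112.7 cm for λ = 65, offset 30.0°).

## Null models and significance

Field-shuffle surrogates: starting at threshold 0 (as a fraction of the map
maximum), firing fields are 8-connected components of suprathreshold bins.
Fields are placed in decreasing area order, uniformly at random among *all*
anchor positions where the footprint lies on free environment bins
(enumerated exactly by FFT cross-correlation of the free mask with the
footprint — placement failure is exact infeasibility, not sampling bad
luck).  If any field exceeds the area cap (1000 cm² arena, 500 cm² track)
or a placement is impossible, the threshold rises by 1% of the maximum and
everything restarts.  Finally the subthreshold values are randomly permuted
onto the remaining environment bins, so the value multiset over the
environment is preserved exactly; field count and per-field value multisets
are conserved by construction (touching placed fields can merge under
*re*-detection, conserving total area).

The permutation p-value of a population gridness is the plain fraction of
control replicates scoring at least the observed value — it can be exactly
0, understating the p-value by at most 1/n_controls; the +1-corrected
estimate is a one-line change if preferred.  The joint two-environment test
counts simultaneous dominance (both components ≥ observed, inclusive),
which is bounded above by either marginal.  Spike-time shuffles redraw all
spike times i.i.d. uniform over the session.

## 1D lap-periodicity peak

The linearized population autocorrelation of ideal simulations is richer
than a single circumference peak: it also carries within-lap
field-interval satellites (near λ and 471±λ), low-prominence wiggles on the
main peak's flank, lap harmonics at k·471 cm of comparable prominence, and
unstable values at extreme lags where the overlap shrinks.  The peak
detector therefore searches lags between a floor (the track diameter, below
which only within-lap field structure lives) and half the lag extent,
keeps local maxima with prominence ≥ 20% of the window's most prominent
peak, and returns the smallest lag whose height reaches 75% of the tallest
candidate.  Each constant neutralizes one artifact class above; with them
the detector returns the circumference within ±3 cm across all pilot seeds.

## Module partitioning and cross-environment correlations

Cells are partitioned by agglomerative clustering with average linkage
(mean Euclidean distance between all cross-cluster pairs) on the z-scored
feature vector (spacing, three orientation angles).  The tree is cut at the
smallest k ≥ n_modules for which exactly n_modules clusters have ≥ 2
members; singletons at that cut are outliers.  The plain linear z-scores
are the literal procedure despite the 60°-circularity of orientations; a
wraparound-aware embedding (each angle as a point on the 60°-period circle)
ships behind `circular_orientations=True`, off by default.

Cross-environment similarity uses the annulus the environments share.  The
protocol's stated annulus radii of 120 and 150 cm exceed the 75-cm arena
and are read as diameters — radii 60 and 75 cm, exactly the track annulus;
both are overridable.  Annulus rates are mean-subtracted over visited bins
(removing exploration bias), unvisited bins set to 0, flattened in a fixed
raster order, and compared with Pearson correlation; same-cell coefficients
are tested against all ordered distinct-cell pairs with a right-tailed
Mann-Whitney U test.  A common lattice phase shift between environments
drives same-cell correlations down to the cross-cell level even when
spacing and orientation are preserved — the signature that distinguishes a
phase shift from remapping.

## Problem sizes, determinism, degenerate inputs

Every stochastic operation takes an explicit integer seed (or Generator);
there is no global random state, and reruns are bit-reproducible.  The
validation suite uses 20-cell modules on the 150-cm arena/track for the
lattice analyses, 100 paired repeats for the shuffle-discrimination check,
and a reduced null-calibration setting (25-cm arena, 3 cells with 3 compact
fields each, 100 controls × 200 runs) chosen to keep the permutation
machinery exercised end to end at desk scale.  Degenerate inputs are
defined errors: empty trajectories, spikes outside the session, trajectories
through the track center, constant maps in Pearson modes (invalid lags),
all-identical features with n_modules > 1, annuli too narrow for three
peaks.

## Known limitations

- The square-window diagonal bias is removed only when a support disc is
  supplied; bare `zero_fill_pearson` on sparse maps retains it.
- Inferred spacing on the track reads ~10% low for the inner ring (annulus
  clipping); orientations are unaffected.
- Grid spacing approaching the track's inner diameter leaves the √3λ ring
  entangled with geometry artifacts except in masked mode; spacing above
  the inner diameter is outside the method's domain.
- The field-shuffle kernel is not exactly idempotent (touching fields merge
  on re-detection), so twice-shuffled maps differ slightly in distribution
  from once-shuffled ones; with compact well-separated fields the effect is
  negligible and the permutation test calibrates correctly.
- No shear/ellipticity correction and no automatic selection of the number
  of modules.
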