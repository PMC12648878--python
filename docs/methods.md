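# Methods

## Model and assumptions

The package treats residential exposure to land cover as a property of where
people live rather than of the administrative polygon they are aggregated
into. Each postcode point stands for a cluster of dwellings; its 300 m disc
is taken as the immediate residential environment; the number of domestic
delivery addresses is the population weight. The unit-level exposure is then
the delivery-weighted mean of per-buffer fractional covers. Implicit
assumptions:

- the postcode point adequately locates its dwellings (it is the delivery
  point nearest the mean position of the postcode's addresses);
- a fixed circular neighbourhood is a reasonable exposure support — no
  distance decay within the disc, no road-network shape, no time-activity;
- delivery counts are proportional to resident population.

The whole-unit ("typical") method is implemented with identical denominator
conventions so that differences between the two tables reflect the method,
not bookkeeping.

### Denominator convention

Sea and estuaries are ordinary cover classes and stay **inside** the
denominator — a coastal buffer can legitimately be 40% sea. Only the
out-of-country exclusion layer is removed from the denominator, for buffers
and for whole units alike. A buffer (or unit) entirely inside the exclusion
is flagged unusable/missing, never treated as zero exposure.

### Zero-weight postcodes

Postcodes with zero domestic delivery addresses carry zero weight and
contribute nothing; a unit whose postcodes are all zero-weight becomes a
*missing* row rather than a row of zeros, since weighting by addresses
implies no residents there.

### Residual class

The composite keeps any frame area covered by no input layer as an explicit
`residual` class, and per-buffer covers assign any area outside the composite
(e.g. a buffer poking past the mapped frame) to `residual` as well. This is
what makes the sum-to-100 invariant checkable on every row. The national
habitat map's own "unclassified" habitat is a map class and is never used as
a gap filler.

## Composite assembly

Layer precedence is habitats > estuaries > exclusion > sea: each added layer
is clipped by the union of everything already placed, so no two classes
overlap beyond a relative tolerance of 1e-6 of the smaller feature. The sea
layer is derived, not supplied: the merged land is buffered outward by 500 m
and the land subtracted, leaving a coastal ring. Slivers below 1e-4 m² are
discarded (with a logged count). Invalid polygons are repaired by zero-width
buffering; geometries invalid beyond that are rejected.

All computation happens in a single projected metre-based CRS. Layers
declaring a geographic CRS — or, lacking a declaration, with coordinates that
fit in the lon/lat envelope — are rejected rather than reprojected, because a
silent degree/metre confusion would corrupt every buffer radius.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| buffer radius | 300 | m | accessible-greenspace policy distance (≈ 5-min walk) |
| sea buffer | 500 | m | width of derived coastal ring; exceeds the buffer radius so coastal buffers stay on the map |
| segments per quadrant | 64 | — | disc polygonization; area error < 0.05% of πr² |
| size-class edges | 0.5, 5, 50 | km² | logarithmic bins with the smallest class split off, as most units fall there; configurable |
| delivery-count law | median 12, mean 17 | dwellings | see below |
| overlap tolerance | 1e-6 | relative | cross-class overlap allowed in a composite |
| sliver cutoff | 1e-4 | m² | discarded during merging |

Percentages are computed in double precision with no intermediate rounding;
CSV output is fixed at 6 decimals for byte-stable diffs (the published
tables' rounding is not stated, so this is a package choice).

## Statistics

- **Kolmogorov–Smirnov** (two-sample, two-sided): D = sup |ECDF₁ − ECDF₂|
  with the asymptotic p-value.
- **Kendall's tau-b** with tie correction and the normal-approximation
  p-value; chosen over tau-a because habitat covers contain many tied zeros.
  Constant vectors leave tau undefined (NaN, flagged); at n = 2 the single
  pair gives tau = ±1 with no meaningful p-value.
- **Mann–Whitney U** two-sided with tie-corrected normal approximation;
  U = #{a_i > b_j} + ½·#{a_i = b_j}. An exact permutation option exists for
  small samples (full enumeration is infeasible beyond ~15 per group, where a
  seeded randomized permutation test takes over); the asymptotic form is the
  default and the one used in reports.
- p-values are reported raw, with no multiple-testing correction, and coded
  with conventional stars at 0.05 / 0.01 / 0.001.
- Differences are `typical − proposed` everywhere, so a negative value means
  the buffer-weighted method assigned more of that class.

The **GAM smoother** for method-vs-method scatter is a visualization aid: a
penalized cubic B-spline (default 10 basis functions, curvature penalty
α = 1). Gaussian identity-link smoothing has a closed-form penalized
least-squares solution, which is solved directly on the statsmodels B-spline
basis; the penalty null space contains all linear functions, so exactly
linear data are reproduced to machine precision regardless of α.

## Synthetic data

The generators emulate the *shape* of the real inputs, not their geography:

- **striped landscapes** tile a rectangular frame with vertical class
  stripes, giving closed-form buffer covers (sums of circular segments via
  `(acos(u) − u√(1−u²))/π`) to test exact overlay against;
- **variable unit grids** grow square-cell size geometrically across bands,
  spanning the ~4 orders of magnitude of real unit areas; cells below 1 km²
  are flagged urban, and West/East regions are assigned by centroid;
- **clustered postcodes** fall uniformly within each unit with counts
  Poisson in unit area (minimum one), so point density tracks the unit-size
  gradient;
- **delivery counts** are rounded lognormal with μ = ln 12 and
  σ = √(2 ln(17/12)), the unique lognormal with median 12 and mean 17 — the
  published per-postcode dwelling summary. Only these two moments are
  calibrated; the true count distribution is not public. Integer rounding
  shifts the mean by well under 1%.

What these scenes do **not** emulate: real settlement clustering within
units, coastline shapes, probability-surface habitat uncertainty, or
spatial autocorrelation between neighbouring units' covers. Passing tests
demonstrate the correctness of the geometry, weighting, and statistics — not
that the synthetic landscapes are statistically faithful to England.

The Monte-Carlo oracle estimates buffer covers by uniform rejection sampling
(≥ 1000 points) with binomial standard errors, points in the exclusion layer
removed from the denominator and unclaimed points counted as residual. Tests
compare exact overlay against the oracle within 3 SEs computed from the
exact fraction (so a class that is truly absent yields a zero-width band
consistently on both routes).

## Numerical choices and degenerate inputs

- Buffer polygonization makes analytic-vs-exact comparisons agree to ~1e-4
  absolute fraction at 64 segments/quadrant; analytic tests use 1e-3 bands.
- Region assignment uses the unit centroid; a centroid exactly on a shared
  edge breaks the tie to the lexicographically first region name, and a
  centroid in no region yields `"unassigned"` with a warning.
- Size-class intervals are lower-inclusive half-open, so 0.5 km² falls in
  the second class.
- Postcode→unit membership is taken from the input attribute; a
  point-in-polygon utility exists with a first-by-sorted-unit-id tie-break
  for points on shared boundaries.
- Tiny negative residual fractions from overlay noise are clipped and the
  cover vector renormalized.

## Problem sizes

The test suite runs synthetic scenes of order 10–200 units and 10²–10³
postcodes, Monte-Carlo sweeps of 50 random scenes at 10⁵ points per buffer,
and statistics oracles over hundreds of short vectors — small enough to run
the whole suite in well under a minute while exercising every code path at
full precision.

## Known limitations

- Vector I/O is GeoJSON + CSV; GeoPackage/Shapefile are not read or written.
- No reprojection: all layers must already share one projected metre CRS.
- Single-process; national-scale inputs would need external tiling/chunking.
- The proposed method inherits the postcode point's location error and does
  not model within-buffer distance decay, network access, or time spent
  away from home.
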