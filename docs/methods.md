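# Methods

This note documents the models implemented in `ecosec`, the defaults and
why they were chosen, the numerical conventions, and the limits of what
the synthetic test scenarios demonstrate.

## Assessment units and quadrants

The landscape is a categorical raster of eight land-use classes —
woodland; high (>50%), medium (20–50%) and low (5–20%) coverage
grassland; water; farmland; construction land; saline-alkali and other
unused land — the first five counting as ecological land, the last three
as non-ecological. Analysis runs on a square tessellation of
`unit_size_m` (default 1 000 m, the common basic-unit choice for
landscape assessment at this extent). Per-unit class areas `A_ki` come
from exact cell counting, so unit sums reconcile with whole-raster
tallies to the last cell; blocks truncated at the raster edge are kept
with their true smaller area, which keeps the ratios `A_ki/A_k` well
defined without discarding boundary landscape. Units are additionally
labelled with one of eight 45° azimuth sectors (N, NE, … NW; azimuth
clockwise from grid north, N = [−22.5°, +22.5°), a centroid coincident
with the center maps to N) for directional summaries.

## DPSIR composite index

Eleven indicators in five weighted dimensions (weights below are the
shipped defaults and are fully configurable):

| dim | w | indicator | w | polarity | scope |
|----|----|----|----|----|----|
| D | 0.05 | D1 urbanization growth intensity (city Δurbanization / national Δurbanization) | 0.5 | + | city |
| D | | D2 per-capita GDP | 0.5 | + | city |
| P | 0.20 | P1 resource curse coefficient (city share of national resource production ÷ city share of secondary industry) | 0.5 | + | city |
| P | | P2 environmental performance index (mean city-vs-nation consumption/pollution intensity per unit GDP) | 0.5 | + | city |
| S | 0.20 | S1 grassland degradation intensity K₁ | 0.25 | − | unit |
| S | | S2 grassland restoration intensity K₂ | 0.25 | + | unit |
| S | | S3 proportion of non-ecological land | 0.5 | − | unit |
| I | 0.50 | I1 ecological risk index ERI | 0.5 | − | unit |
| I | | I2 ecological resilience ECO | 0.25 | + | unit |
| I | | I3 ecosystem service value ESV | 0.25 | + | unit |
| R | 0.05 | R1 ecological-construction investment / GDP | 1.0 | + | city |

D, P and R derive from citywide statistics and are constant across units
within a year; S and I vary per unit through land-use state. Interval
indicators (D1, S1, S2) describe the step ending at the reported year and
are undefined for the first year.

* `K₁` counts grassland moving to lower-coverage grassland, construction
  or saline-alkali land, divided by the initial grassland area and the
  interval length; `K₂` counts moves to higher-coverage grassland, water
  or woodland. Conversion to farmland counts in neither direction. The
  coverage ordering is saline < low < medium < high. A unit without
  grassland has undefined (not zero) intensities.
* `ERI = Σᵢ (A_ki/A_k)·Eᵢ·Fᵢ` with per-class interference `Eᵢ` and
  vulnerability `Fᵢ`; it is a convex combination of the per-class `E·F`
  products.
* `ECO = Σᵢ Aᵢ·Pᵢ/Cᵢ` with elasticity `Pᵢ` and fragmentation
  `Cᵢ = Nᵢ/Aᵢ` (patch count over area, 8-connected components by
  default). Patch density is the simplest fragmentation index consistent
  with the resilience formula; any alternative can be plugged in because
  `C` enters only through `PatchStats`.
* `ESV = Σᵢ Aᵢ·VCᵢ` with per-km² value coefficients `VCᵢ`.

The shipped coefficient tables (`E`, `F`, `P`, `VC`) are **synthetic
stand-ins** ordered by ecological intuition — construction and
saline-alkali land most disturbing, most vulnerable and least elastic;
water and woodland most valuable — and are clearly marked as such in the
config schema. Applications with calibrated regional tables should
override them.

Normalization is linear min-max with polarity (negative polarity reverses
the scale), pooled over **all units and years jointly** per indicator so
index values are comparable across time; a degenerate pooled range maps
to 0.5 with a warning. The composite index is the doubly weighted sum,
bounded in [0, 1] and monotone in every indicator. Missing indicators
renormalize the remaining weights within their dimension (and missing
dimensions renormalize across dimensions) instead of biasing the index
toward 0.

Pairwise-comparison weighting is supported through `ahp_weights`:
normalized principal eigenvector of a positive reciprocal matrix,
consistency ratio `CR = ((λ_max − n)/(n − 1))/RI(n)` against Saaty's
random index, warning above the conventional 0.1; 2 × 2 matrices are
consistent by construction (CR = 0).

### S3 and the pressure polarities

The non-ecological proportion S3 counts farmland + construction +
saline-alkali area (the ecological/non-ecological split of the
classification system), not merely "non-construction" land, and carries
negative polarity. The positive polarities on P1/P2 look
counter-intuitive (more pressure raising the index); they are retained as
the shipped default but are ordinary config entries — flip them in
`IndicatorConfig.polarity` if your interpretation differs.

## Spatial autocorrelation

Global Moran's I uses the classical double-sum form with binary adjacency
weights, expected value `E[I] = −1/(n−1)`, the standard randomization
(S1/S2/b2) variance, and a permutation pseudo p-value
`(#{|I_perm| ≥ |I_obs|} + 1)/(permutations + 1)` (999 permutations,
seeded, two-sided by default; one-sided alternatives available). A
constant field raises an explicit undefined-statistic error (the `S² = 0`
division failure).

Getis–Ord Gi* uses self-inclusive neighborhoods and the standard
denominator `S·√[(n Σw² − (Σw)²)/(n−1)]` with the population standard
deviation `S`; the statistic is a z-score. Seven-grade classification is
by normal confidence thresholds — |z| ≥ 2.58 high, ≥ 1.96 middle,
≥ 1.65 low, boundaries inclusive upward, the sign giving hot/cold — or
alternatively by 7-class Jenks natural breaks (exact Fisher–Jenks dynamic
program) for a "spatial fracture point" rendering.

The **optimized hotspot** variant profiles the global Moran z-score over
candidate distance bands (default 1–8 unit spacings), selects the band at
the first local peak (falling back to the maximum), computes Gi* at that
band and applies Benjamini–Hochberg FDR at level 0.05 before grading;
significant units below the 1.65 threshold grade as low intensity.

Two defaults deserve explanation:

* **Pipeline weights: fixed distance band, 2 × unit size, binary.** The
  per-year analyses default to a fixed-distance-band neighborhood rather
  than rook/queen contiguity. Narrow, strip-shaped anomalies — exactly
  the geometry of an oilfield belt — lose most of their edge units under
  queen contiguity because diagonal neighbors reach into background; a
  2-km band on 1-km units keeps the neighborhood majority inside a
  4-km-wide strip while behaving identically on spatially unstructured
  fields. Rook, queen and arbitrary bands remain one config field away,
  and the Moran summary reports the scheme used.
* **FDR-corrected per-year grading.** The pipeline grades per-year Gi*
  fields after Benjamini–Hochberg correction (`hotspot_correction:
  "fdr"`). With hundreds of units tested simultaneously, the raw
  |z| ≥ 1.65 threshold flags ≈10% of null units by chance, which would
  manufacture restoration zones on perfectly homogeneous landscapes.
  The standalone `getis_ord_gistar` function keeps `correction="none"`
  as its default, matching the conventional single-map usage.

## Time–space overlay and MCR zoning

The overlay rule table maps (first-year sign, second-year grade,
optimized sign) to a zone; the shipped default covers all 63
combinations:

* hot in both years → **core protection**, promoted to **bottom-line
  protection** when the unit's dominant class is water;
* hot in the second year only → **ideal protection**;
* not significant both years but optimized-hot → **ecological
  potential**;
* cold in both years, by second-year intensity: low → **risk
  prevention**, middle → **key restoration**, high → **core
  restoration**;
* cold in the second year only → **risk supervisory**;
* anything else → unzoned (**other**).

The table is an explicit config artifact; a user-supplied table must
cover every occurring triple or the uncovered triples are reported.

The resistance surface is `0.5·R_landuse + 0.5·R_zone` with ranks
water 1 · woodland 2 · high grass 3 · medium grass 4 · low grass 5 ·
farmland 6 · saline-alkali 7 · construction 8, and core/bottom-line
protection 1 · ecological potential 2 · ideal protection 3 · other 4 ·
risk supervisory 5 · risk prevention 6 · key restoration 7 · core
restoration 8 — values in [1, 8] wherever land use is defined.

Cost distance is exact multi-source Dijkstra on the 8-connected cell
graph with step cost = mean of the two cells' resistance × step length
(cell size, ×√2 diagonal) — the standard cost-distance semantics; the
outer `f` of the MCR formulation is taken as the identity since only
orderings and thresholds matter. Core sources are the core and
bottom-line protection cells, potential sources the ecological-potential
cells. Cells under the core threshold (default 30 000 resistance-metres)
or the potential threshold (default 14 000), united with ideal-protection
zones, form the protection area; inside it, previously unzoned
construction land and farmland become **ecological conflict** and the
unzoned remainder **ecological buffer**. Warning zones are never
overwritten — the protection area grows into unallocated space only,
which is what allows warning and protection partitions to coexist on one
map. Thresholds are configurable; zero is a valid limit (protection =
sources ∪ ideal), negative values are rejected.

## Synthetic scenarios

The generator produces what the assessment assumes about a resource-city
fringe, not real geography:

* spatially autocorrelated 8-class mosaics via rank-order thresholding of
  Gaussian-smoothed noise (exact class proportions up to one cell; the
  generation path compares only ranks, with ties broken by cell index,
  so fixed seeds are platform-stable);
* a rectangular "oilfield strip" with its own class mix, where each
  grassland cell converts directly to saline-alkali land with per-step
  probability `degradation_rate` (so after `t` steps a fraction
  `1 − (1−rate)^t` of the initial grassland is saline) and surviving
  grassland steps one coverage level down with probability
  `coverage_downgrade_rate`;
* post-policy restoration: outside the strip, farmland converts to
  high-coverage grassland at `restoration_rate` per step once the step
  ends after `policy_year`;
* a socio-economic table with a Gaussian rise-then-decline oil production
  curve (strictly increasing before the peak year, decreasing after),
  smooth GDP/population/urbanization growth, and a late-ramping
  ecological-investment series; a `flat` economy preset holds every
  column constant.

Three presets freeze the study conditions used by the test and
acceptance suites: 160 × 160 cells of 100 m (256 one-km units — a
deliberately scaled-down scene that keeps the full pipeline under half a
minute), years 1980/1990/2000/2010/2017, and

* `stable` — fine-grained homogeneous mosaic (300-m patches), no strip,
  no change;
* `degrade_only` — a 10 × 4 km grassland-dominated strip salinizing at
  0.35 per step with 0.2 coverage downgrade;
* `degrade_then_restore` — the same plus 0.25 farmland restoration after
  2000.

The background patch scale (300 m) is deliberately below the unit size so
the far field is statistically homogeneous at the analysis scale: the
planted strip is then the *only* structural anomaly, which is what makes
recovery assertable. What passing tests show, and what they do not: the
pipeline recovers a planted, strongly contrasted anomaly and stays quiet
on null landscapes; they say nothing about power on weak or diffuse
degradation gradients, about landscapes whose background has real
unit-scale structure (where genuine secondary clusters will and should be
flagged), or about the fidelity of the stand-in coefficient tables to any
real region. Real-data use requires calibrated coefficients and a
sensitivity check of the weights scheme.

## Numerical conventions

* Integer class codes end to end in generation; no float comparisons
  decide a class.
* All randomness flows through `numpy.random.Generator(PCG64(seed))`;
  per-year Moran permutation seeds derive linearly from the scenario
  seed; identical configs reproduce every output byte for byte.
* Missing values propagate as NaN, never as 0; degenerate normalization
  ranges map to 0.5 with a warning; constant fields raise
  `UndefinedStatisticError` rather than returning 0.
* Jenks breaks use the exact O(k·n²) dynamic program (fine for the
  few-hundred-unit fields this package targets).
* ESRI ASCII grid is the raster interchange format (text, exact for
  integer rasters); unit tables export to CSV/GeoJSON.

## Known limitations

* No CRS handling or reprojection: inputs must be co-registered.
* Fragmentation is patch density only; richer landscape metrics must be
  supplied externally through the pluggable `PatchStats` table.
* The optimized hotspot scale search covers discrete bands derived from
  unit spacing, not a continuous optimum, and implements no locational
  outlier trimming or incident aggregation.
* City-level (D, P, R) indicators shift the index uniformly within a
  year; spatial contrasts rest entirely on the S and I indicators.
* Cost-distance thresholds are in resistance-metres and scale with scene
  size; the shipped defaults suit the preset extent and real scenes need
  rescaled thresholds.
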