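# Methods

## Scope and workflow

`nicheshift` implements a seven-stage presence-only species distribution
workflow for marine species: (i) occurrence cleaning and spatial thinning,
(ii) environmental variable selection, (iii) vessel-traffic / MPA / EEZ layer
preparation, (iv) pseudoabsence ensemble niche modeling, (v) projection onto
warmed climate stacks with per-pixel range-change accounting, (vi)
multi-species hotspot identification and protection-gap analysis, and (vii)
co-occurrence of richness change with high-intensity shipping.  Every stage is
a pure function of its inputs and a seed; the pipeline orchestrator derives
all stage seeds from a single root seed via `numpy` seed sequences, so a full
run is reproducible bit for bit (the run manifest records SHA-256 checksums).

## Grids and geometry

All layers live on one plate-carrée lon/lat grid (EPSG:4326 semantics), row 0
at the northern edge.  Points are assigned to cells by the containing-cell
rule `floor((coord − origin) / cell_size)` with half-open `[low, high)` cells,
so boundary coordinates resolve deterministically.  Cell areas use the
spherical-cap formula `R² · Δλ · (sin φ_top − sin φ_bottom)` with
R = 6371 km: over a domain spanning tens of degrees of latitude, flat
`cell_size²` scaling would misstate areas by several percent, which matters
for km² protection totals.  Rasters are serialized as ESRI ASCII grids (a
plain-text single-band format readable by any GIS) with a JSON manifest per
multi-layer stack.

## Occurrence QC

Filters run in a fixed order — duplicates → suspicious → land → thinning —
and each logs its removal count so the provenance log reconciles exactly with
input/output sizes.

- Duplicates: identical coordinates after rounding to 6 decimals; first
  instance kept.
- Suspicious: identical longitude and latitude, (0, 0), out-of-range
  coordinates, and imprecise records.  "Imprecise" is operationalized as both
  coordinates expressible with fewer than 2 decimal places (~1 km at the
  equator); the cutoff is configurable since no standard value exists.
- Land: records whose containing cell is land (or outside the grid, logged
  separately) are dropped.
- Thinning to a 5.5 km minimum great-circle distance (haversine), matching a
  0.05° model grid at the equator.  The algorithm greedily removes the record
  with the most neighbours inside the radius (seeded random tie-break), then
  re-adds any removed record whose neighbourhood was itself entirely removed.
  The result provably satisfies the distance constraint and is maximal — no
  removed record can be re-added.  Stochastic-search thinners retain slightly
  more points on some configurations; the greedy variant is deterministic and
  within a few points of them on random clouds (tested against random
  feasible subsets).

## Variable selection

Candidate predictors are screened by model-based permutation importance: for
each fitted learner, importance of a variable is `1 − mean Pearson r` between
predictions on the original design and on designs with that variable's column
shuffled (3 shuffles), clipped to [0, 1]; importances are averaged across the
learner family.  Selection is greedy by mean importance under a pairwise
correlation cap: a variable is admitted only if `|r| < 0.70` against every
already-admitted variable, stopping at k = 6.  The cap is applied to |r|
because strongly negative correlation is equally redundant.  Correlations are
computed over the modeling domain (presence + pseudoabsence cells), not the
whole grid, since that is the sample the learners see.  Screening uses one
pseudoabsence replicate; the shuffle repetitions provide the averaging.

## Ensemble modeling

- Pseudoabsences: uniform draws without replacement over valid sea cells
  excluding presence cells (no exclusion buffer), 5000 per replicate, 3
  replicates.  Requesting more than the eligible cell count is an error,
  never silent replacement sampling.
- Splits: five independent stratified 75/25 train/test splits plus one final
  full-data pseudo-fold ("5 + 1"), per pseudoabsence replicate.
- Learners: (a) `glm` — logistic regression on standardized linear +
  quadratic terms (unimodal response curves); (b) `sre` — rectilinear range
  envelope at presence quantiles [0.025, 0.975] (suitability 1 inside the
  box, 0 outside); (c) `gbm` — gradient-boosted shallow trees (xgboost,
  histogram method, 100 trees, depth 3, single thread for determinism).
  Constant training variables are dropped with a warning.
- Evaluation: ROC AUC by the rank (Mann–Whitney) formulation (exactly the
  pairwise-concordance probability with ties as ½) and TSS maximized over the
  midpoints between consecutive distinct scores plus the two degenerate
  extremes; ties break toward the smallest maximizing threshold.
- Ensemble: members with held-out TSS > 0.75 are weighted by raw TSS
  (normalized to sum 1).  The ensemble's binarization threshold is
  TSS-optimized on its weighted-average scores over the pooled held-out rows
  of all replicates and folds.  Binarization uses the ≥ convention at the
  threshold.  The evaluated fold models themselves serve as the committee for
  projection, keeping members, weights, and maps mutually consistent; the
  full-data pseudo-fold fits are produced and persisted but are not part of
  the weighted committee, since they carry no held-out skill estimate.

Open choices made here (weighting by raw TSS rather than ranks; splitting
within each pseudoabsence replicate rather than pooling first) follow the
simplest reading of standard ensemble-SDM practice and are recorded in the
run configuration echo.

## Projection and change accounting

Binary maps under each scenario are compared cell-wise with the current map:
lost (1→0), stable (1→1), gained (0→1), with percentages relative to the
current presence count (so gains can exceed 100%); an empty current range
reports percentages as not available rather than dividing by zero.  Net
richness change per pixel is (# species gained) − (# species lost); a cell
with equal numbers is 0.  Latitudinal density tables use half-open 1° bands
tiling [−90, 90).  Dispersal is implicitly unlimited — a cell that becomes
suitable is counted as gained regardless of distance from the current range.

## Hotspots and overlays

Continuous (not binarized) ensemble suitabilities are summed across species,
min-max standardized to [0, 1] over valid sea cells, and thresholded strictly
at 0.80.  Each scenario is standardized against its own min/max; this is the
one reading of "standardize then threshold" that never leaves a scenario
without a hotspot ceiling, but it means cross-scenario area comparisons are
relative, not absolute — flagged prominently because a scenario with uniformly
lower summed suitability still gets standardized to [0, 1].  Overlap reports
are area-weighted (spherical cell areas): total / protected / unprotected
hotspot km², percent protected, and a per-EEZ breakdown with high seas as
zone 0.  Vessel density is square-root transformed and the high-traffic mask
keeps cells strictly above the mean of the square-root values over valid sea
cells (the mean-of-sqrt reading; the raw-mean alternative is one flag away in
`shipping_transform`).

## The synthetic world

The generator produces the statistical structure the analysis assumes, with
every ground truth known:

- Environmental fields: a temperature layer `T = 30 − 0.5·lat` plus smoothed
  white noise (moving-average kernel, s.d. 0.5 °C), and auxiliary layers
  (chlorophyll, salinity, oxygen, …) as constant base levels plus independent
  smoothed-noise fields.  Smoothed white noise is the simplest field with
  tunable spatial autocorrelation.
- Scenarios: spatially uniform additive warming applied to temperature only
  (defaults approximate the warming levels of the three standard pathways:
  +0.9/+1.8, +1.35/+2.7, +2.2/+4.4 °C for 2050/2100).  Uniform warming on a
  linear gradient makes the expected poleward shift analytic:
  shift = Δ / slope.
- Species: independent Gaussian responses multiplied across variables —
  differentiable, with analytically tractable optimum and shift, standard in
  niche theory.  The seven default species span thermal optima 27–17 °C
  (optimal latitudes 6–26° on the default basin) with σ_T = 0.8 °C and a
  chlorophyll response (σ = 1.2 against a field s.d. of 3).  Niches are
  deliberately sharp so held-out ensemble skill lands in the high-TSS regime
  (≈0.9) that the TSS > 0.75 gate presumes; with broader niches the
  presence-proportional sampling model itself caps attainable TSS near the
  gate.
- Occurrences: cell probabilities proportional to true suitability, uniform
  jitter within the cell, plus flagged contaminants (exact duplicates, (0,0)
  records, points on land cells, 1-decimal rounded coordinates) appended at
  configurable rates (defaults 10/2/5/5% of the clean count).  Contaminant
  labels travel in a hidden sidecar that QC never reads, giving tests a
  recall oracle without leaking labels.
- Zones: a contiguous wavy land band on the eastern edge; MPA patches grown
  from random sea seeds and trimmed to exactly the requested fraction of sea
  cells; EEZ labels partitioning a 12-cell coastal buffer into latitudinal
  strips (0 = high seas).
- Shipping: straight-line lanes with Gaussian cross-sections, log-normal
  amplitudes, and multiplicative log-normal speckle — a heavy-tailed field
  concentrated along corridors, zero on land.

Default problem size: a 100 × 200 cell basin at 0.5° (lat 0–50°N), 7 species,
500 presences each, 5000 × 3 pseudoabsences — chosen so a complete run
finishes in well under a minute on one CPU while keeping ≥17,000 sea cells
for map-level statistics.

What the synthetic world does **not** emulate: ocean dynamics, currents,
bathymetry realism, inter-model climate spread, monthly climatologies,
sampling bias fields, or spatially autocorrelated observation error.  Passing
tests therefore demonstrate the correctness of the pipeline's accounting and
its ability to recover known niches under the stated sampling model — not
predictive skill on real occurrence data.

## Numerical conventions and degenerate inputs

- ROC AUC and TSS require both classes; single-class labels raise.
- A constant layer in the correlation sample gets correlations 0 with a
  warning (undefined Pearson r).
- Constant summed suitability cannot be min-max standardized and raises.
- Thresholds for binarization must lie in (0, 1).
- Empty hotspot masks and empty current ranges report percentages as
  not-available (`None`), never NaN arithmetic.
- Permutation importance treats an unchanged prediction vector as r = 1
  (importance 0) and a degenerate-variance prediction as r = 0.

## Known limitations

- The learner family is three algorithms, not the ten of full biomod2-style
  ensembles; the family spans parametric / envelope / boosted classes but
  narrower model diversity inflates weight concentration.
- Greedy thinning is near-optimal, not optimal, on pathological point
  configurations.
- Single-species runs skip the hotspot/overlay stages (hotspots are defined
  across ≥2 species).
- Per-scenario hotspot standardization (see above) precludes absolute
  cross-scenario suitability comparisons.
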