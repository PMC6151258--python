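# Methods

This note documents the models, defaults, and numerical choices behind
gapstack, and what the synthetic benchmark does and does not demonstrate.

## The pipeline in one paragraph

Occurrence records from four sources are reduced to "effective records" by
detection-independence and deduplication rules, species with enough records
are modeled with a five-technique presence/pseudo-absence ensemble selected
and weighted by the true skill statistic (TSS), the binarized per-species
maps are stacked into scenario richness rasters, richness fractions are
classified into priority (≥ 80% of the scenario's species), important
(≥ 50%) and normal cells, and the classes are overlaid on reserve zoning
plus a 1-km outward margin ring to quantify protection gaps.

## Synthetic landscape and community

The generator produces the study conditions every test runs under:

* **Grid.** 60 × 60 cells at 200 m (144 km²), planar meters, north-up.
  This matches the scale of a mid-size montane reserve (~142 km²) while
  keeping a full model run near 20 s on one CPU; tests that need the exact
  142.47 km² total construct it explicitly.
* **Relief.** Gaussian white noise smoothed by an isotropic kernel
  (length scale 2.5 km) and rescaled exactly to 375–2,118 m.  Slope comes
  from central differences.  The smoothing kernel is the simplest
  controllable form of spatial autocorrelation; no hydrology is modeled.
* **Climate.** Seven layers in annual/summer/winter groups, each an affine
  function of elevation (e.g. mean temperature at −0.0065 °C/m) plus
  smoothed noise with layer-specific σ.  With elevation and slope this
  gives the canonical nine-variable stack of two topography + seven climate
  variables.  Seasonal groups are independent layers rather than derived
  from monthly series.
* **Zoning.** Cells sorted by distance from the landscape center are
  assigned core, then buffer, then experimental zone; default fractions
  keep the emulated reserve's 37.95 : 24.04 : 80.48 km² proportions scaled
  to 60% of the landscape so an outside region and margin ring exist.
  Requested areas are met within one cell.
* **Roads.** Polylines crossing the outer band that pick the
  lowest-elevation crossing at each station — valley roads skirting the
  reserve, mirroring the empirical pattern that human infrastructure sits
  at low elevation while most of the community lives at mid elevation.
* **Virtual species.** Suitability is a product of Gaussian responses
  exp(−(x − opt)²/2b²) over elevation plus one season-appropriate climate
  layer; truth is suitability ≥ 0.5.  Elevation optima sit in the
  0.25–0.70 quantile band of the relief and breadths of 6–14% of the
  relief span, calibrated so per-species true ranges fall in the
  ~5–50 km² band (mean ≈ 25 km²) reported for communities at this reserve
  scale.  Eight species in four phenology groups (2 mammal, 3 resident
  bird, 2 summer bird, 1 winter bird) form the default community.
* **Sampling.** Records are drawn from true-presence cells with weight
  ∝ exp(−bias · distance-to-road); the default bias is 1/1000 m⁻¹ (an
  e-folding of 1 km), a free parameter since field protocols quantify the
  effect only qualitatively.  Camera records snap to a fixed jittered-grid
  site design whose minimum spacing (≥ 0.7 × 600 m) honours the > 400 m
  block-design rule; timestamps fall in each group's seasonal window;
  interviews and specimens carry no timestamp.

What the generator does **not** emulate: detection failure (all records are
true presences), taxonomic error, spatial error in interview geocoding,
multi-year dynamics, and village-avoidance bias beyond the single
distance-to-road kernel.  Passing tests therefore demonstrate that the
statistical machinery recovers known niches under honest sampling noise —
not that any field dataset meets these assumptions.

## Record filters

* Camera rule: a record is retained iff ≥ 30 min elapsed since the last
  *retained* record of that species at that site (the first is always
  retained).  Elapsed time exactly 30 min retains, the standard camera-trap
  convention.  Rows are ordered by timestamp with coordinate tie-breaks, so
  the result is invariant to input order.
* Transect rule: greedy scan in survey order; a record is dropped iff
  strictly closer than 30 m to an already-retained record of the same
  species.  Exactly 30 m keeps both.  The rule is applied per species over
  all records (the radius is configurable; whether it should reset per
  transect visit is left to the caller's preprocessing).
* Interview cross-validation: retained iff the species has at least one
  effective camera or transect record.  Specimens pass unfiltered.
* Records flagged invalid (conflicting metadata) are dropped before any
  filter; every dropped row is written to an audit table naming the rule.

All filters are idempotent and can only shrink the record set.

## Variable screening

VIF_j = 1/(1 − R²_j) with R²_j from an ordinary least-squares regression of
column j on the remaining columns plus intercept.  Perfect collinearity
(R² ≥ 1 − 1e−12) is reported as +inf.  Backward elimination drops the
largest VIF until all survive below 10, breaking ties toward the later
layer in stack order for determinism.  The regression sample is the
species' presences plus the background pool, so different species can keep
different variables.  If fewer than two variables survive, the survivors
are returned with a warning.

## Ensemble modeling

All techniques consume the same design matrix and return suitability in
[0, 1]; they differ in basis and regularization:

| technique | model |
|---|---|
| glm | logistic regression on linear + quadratic terms (C = 10) |
| gam | logistic regression on per-feature cubic B-spline bases (5 quantile knots) |
| mars | hinge pairs at 5 quantile knots per feature, pruned by L1 logistic regression |
| rf | 100-tree random forest, probability output, min leaf 2 |
| maxent | class-balanced regularized logistic on linear + quadratic terms; C ∈ {0.1, 1, 10} picked by held-out TSS on an internal 70/30 split |

The MaxEnt entry is the standard infinitely-weighted-logistic approximation
of the presence/background exponential model, with a small fixed
regularization sweep in place of a full hyperparameter grid.  Constant
feature columns are masked at fit time; if everything is constant the fit
returns the class prevalence.

Evaluation: 10 stratified 70/30 splits (fraction chosen as common practice;
the protocol this emulates does not state it); each technique is scored on
the held-out part by TSS at the cut-off maximizing TSS over all unique
predicted scores (ties → smallest cut-off).  5 × 10 = 50 TSS values per
species.  Member selection is conjunctive: mean per-technique TSS must reach
the mean of all 50 values *and* exceed a 0.40 quality floor (the
"fair-or-good" convention); if nothing qualifies, the single best technique
is used with a warning.  Selected techniques are refit on all data and
combined as a mean weighted by mean TSS.  The binarization cut-off *P* and
the reported ensemble TSS come from the pooled held-out ensemble scores;
binarization is strictly above *P*.

## Hotspots and gaps

Richness is an exact integer sum of binary maps.  Class thresholds compare
richness/n as exact rationals (0.8 parsed as 8/10), so boundary cells carry
no floating-point artifacts; ≥ 80% is inclusive.  Elevation profiles use
half-open 100 m bands with area-weighted mean richness per band, and the
area–richness relation is summarized by Pearson correlation.

Zone overlay counts integer cells first and converts to areas and
percentages last.  The margin ring relabels outside cells whose center lies
within 1 km of the nearest reserve cell center (Euclidean distance
transform).  Coverage denominators are per class ("x% of the priority area
lies in zone z"); empty classes report NaN, not 0.  Cross-scenario summaries
use simple (unweighted) means over scenarios, reported alongside the
per-scenario values.

## Reproducibility

A single master seed fans out through
`SeedSequence([master, stage_index, item_index])` into per-stage,
per-species sub-seeds (all < 2³¹), so stages are independently reproducible
and a rerun of the full pipeline is bit-identical — the test suite checks
file hashes.  All artifacts are text: ASCII-grid rasters, CSV tables,
GeoJSON roads, JSON reports with config hash and seed.

## The recovery benchmark

`gapstack.recovery_trial(master_seed)` runs one truth-recovery experiment
under the default reserve with unbiased sampling (150 presences, road bias
0, noiseless climate layers), cycling the evaluated species through the
four phenology groups across seeds.  Two scores are reported: pooled
held-out TSS against pseudo-absences, and Jaccard overlap between the
binarized prediction and the known truth raster.  TSS systematically
understates skill here because part of the road-buffer background falls in
truly suitable cells (label noise that grows with range size); Jaccard is
the direct truth comparison.  Across ten master seeds the suite requires
TSS ≥ 0.7 *and* Jaccard ≥ 0.5 in at least eight.

## Known limitations

* Real mode (reading field CSVs and external rasters) shares all I/O
  schemas but the orchestration currently implements the synthetic study
  only.
* No spatial block cross-validation; random splits overestimate
  transferability under spatial autocorrelation.
* No AUC, no complementarity/irreplaceability scoring — hotspots are pure
  overlap fractions.
* The MaxEnt approximation and the fixed C sweep are desk-scale stand-ins
  for a full presence-background tuning grid.
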