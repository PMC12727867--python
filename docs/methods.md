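# Methods

This note documents the models and procedures implemented in `tropirep`,
the defaults they use, the synthetic study system the tests run on, and the
numerical choices made where the design was genuinely open.

## Citation allocation and habitat filtering

Each article row carries a total citation count and one or more geocoded
sampling locations.  Influence is attributed per location as
`allocated_citations = total_citations / n_locations`, an equal-split rule
that conserves article totals exactly (checked to 1e-9 relative).  Articles
must have at least one citation; locations carry 1–3 habitat labels from a
nine-term vocabulary (forest, grassland, wetland, desert, rocky,
agricultural, urban, lake, river), normalized case-insensitively with a
small synonym table ("rocky area" → "rocky").

The natural-habitat filter removes a location if *any* of its habitats is
excluded (default: urban, agricultural).  This conservative reading of
"natural" is a design choice: a site labeled both forest and agricultural is
treated as human-influenced.  After filtering (and likewise after the domain
clip), citations are by default re-allocated over an article's *remaining*
locations, so filtered citation totals still represent whole-article
influence; the alternative — keeping the original denominators, so dropped
locations take their citation share with them — is available via
`reallocate=False` because either convention is defensible.  Articles left
without locations are dropped.  The filter is idempotent and monotone in all
three counts.

## Study domain and zonal statistics

The domain core is the union of the biome polygons; the buffered domain
dilates it by `buffer_km` (default 100 km).  Buffering is done in a local
sinusoidal projection centred on the domain (x = R·λ·cosφ, y = R·φ, in km)
so that the distance is kilometre-true at all latitudes rather than a
constant number of degrees; at tropical latitudes the projection's shear is
negligible relative to a 100 km buffer.  Polygon areas are computed on a
sphere of radius 6371 km (authalic radius, a standard reproducible choice)
by an equal-area shoelace in (λ, sin φ) after densifying edges to 0.1°;
this is exact for edges along meridians and parallels and convergent
otherwise.

Locations are assigned point-in-polygon with boundary points counting as
inside; where units overlap, the earliest unit in layer order wins
(deterministic tie-break).  Points in the buffer but outside every unit are
labeled "Extra-tropical other"; points outside the buffered domain are
dropped and counted in a clip report (kept + dropped = input always).

The biome summary reports, per biome: area (km²), % of domain area, location
and citation counts, % shares, densities per 10⁵ km², and the
citation:sampling ratio = pct_citations / pct_locations.  Percentages are
computed before rounding; displayed ratios round half-away-from-zero to one
decimal.  Coarse density grids (default 3° cells) divide per-cell weight
sums by the spherical land area of the domain within each cell; cells with
no domain land are nodata and pre-division totals are conserved.

## Covariate stack

Eight aligned geographic grids: MAT (°C), MAP (mm), their projected changes
ΔMAT/ΔMAP (future minus baseline, computed cell-wise with nodata
propagation), LAI (m² m⁻², may contain gaps), SOC (upper 2 m stock), plant
species richness (per 1000 m² plot) and combined bird+mammal richness.
Co-registration is validated on construction; resampling is out of scope.

LAI gaps are filled by a focal mean over a centred window (default 19×19,
matching the processing convention for gappy satellite LAI composites) in a
**single pass**: valid cells are never altered, and freshly filled values do
not feed later fills in the same call.  Single-pass filling is deterministic
and order-independent; an iterated variant could fill larger holes but would
couple the result to sweep order, so it is not the default.

Point extraction uses pure index arithmetic (`floor((x − x0)/dx)`), returns
rows in input order, and flags out-of-extent points; background sampling
draws n (default 100,000) distinct domain pixels uniformly without
replacement with a fixed seed (if the domain is smaller than n, all pixels
are taken with a warning).

## Environmental-space histograms

For each covariate pair, three 2-D histograms share edges derived from the
pooled background ∪ location range, expanded by 0.1% so extremes fall inside
the closed outer bins: occurrence (unit weight per background pixel),
sampling (unit weight per location) and citations (allocated citations as
weights).  Bins are right-open with the last bin closed; rows with missing
covariates or out-of-range values are dropped and their count and weight
reported, so histogram mass plus dropped weight equals input weight to 1e-9.
Defaults: 50 bins per axis and the pairs (MAT, MAP), (ΔMAT, ΔMAP),
(LAI, SOC), (plant, animal richness) — both are configuration, not
substance, since binning only affects display resolution.

## Representativeness model

Presences are the (filtered) sampling locations; pseudo-absences are drawn
uniformly without replacement from domain pixels with complete covariates,
in the same number as the presences.  By default absence pixels may not
contain a presence — allowing overlap would create contradictory labels for
identical covariate rows — but an overlap-allowed mode is available.
Presences on missing covariates are dropped before the absence draw so class
parity is exact.

The default covariates are MAT, MAP, SOC, LAI, plant and animal richness.
The collinearity screen computes pairwise Pearson correlations and, while
any |r| ≥ 0.70, drops the member of the worst pair with the larger mean
absolute correlation to all other retained covariates (ties: the later
column); constant columns are dropped with a warning.  The iterative
mean-correlation rule is a standard way to make "keep correlations < 0.70"
deterministic.

Three members are fitted on identical rows:

* **Smooth additive logistic model** — per-covariate cubic B-spline bases
  (8 knots, constant extrapolation beyond the training range so full-map
  prediction cannot blow up) combined additively in a ridge-penalized
  logistic regression (C = 1).  This is the GAM-type member: smooth,
  additive, probabilistic.
* **Random forest** — 500 trees, default feature subsampling.
* **Gradient-boosted trees** — 1000 trees, learning rate 0.01, depth 3.

All hyperparameters are exposed and recorded; the tree counts follow common
SDM practice.  The ensemble prediction is the element-wise **median** of the
three member probabilities (for three members: the middle value, hence
always bounded by the member envelope).  Mapping applies the fitted ensemble
to every domain pixel with complete covariates; covered area sums spherical
cell areas where probability is **strictly** greater than the threshold
(default 0.5), so a uniform-0.5 map has zero coverage.

Validation: ROC AUC (probability that a random presence outscores a random
absence, ties counted half) over 99 repeated random 70/30 train/test splits.
Splits are stratified by label — the unstratified alternative can produce
single-class test sets on small tables — and each split refits the full
ensemble and scores the held-out 30% with the ensemble median.

## Synthetic study system

The generator provides the three inputs with known structure:

* **Stack** — eight smooth fields (Gaussian-smoothed white noise,
  correlation length 6 cells) on a 0.5° grid spanning 120° × 50° of a
  tropical belt.  The latent fields are orthonormalized and mixed with the
  Cholesky factor of a target correlation matrix, so requested pairwise
  correlations are achieved exactly before a deterministic latitudinal
  gradient (e.g. MAT −0.12 °C per degree |lat|) is added; a
  non-positive-definite target raises.  Layers are then scaled to realistic
  units (MAT ≈ 27 ± 2 °C, MAP ≈ 1600 ± 600 mm, LAI clipped to [0, 7] …).
  LAI receives a configurable fraction (default 5%) of random nodata gaps.
* **Biomes** — a smooth latent field thresholded at quantiles into n classes;
  each connected component becomes one ecoregion polygon (merged cell
  rectangles), classes are biomes.  The partition covers the grid exactly.
* **Literature** — article locations drawn from a point process with
  intensity ∝ exp(Σ βᵢ·zᵢ) over domain cells (z domain-standardized;
  default β = 0.7 on LAI and 0.3 on MAT, a moderate bias toward warm,
  densely vegetated cells emulating the concentration of field effort
  around forest research stations).  400 articles by default, 1–8 locations
  each (uniform), citations from a discretized lognormal (μ = 2.8,
  σ = 1.2, minimum 1 — mean ≈ 33 citations/article with a heavy tail; a
  lognormal was chosen because a few heavily cited sites dominate real
  citation distributions).  Natural habitat labels are drawn conditionally
  on local LAI; independently per location, with probability 0.36 the
  location also carries an urban or agricultural label — the default
  fraction matches the share of human-dominated sampling locations reported
  for tropical literature at large.  The generator returns a truth record
  (β, seeds, intensity summary) for bias-recovery tests.

What the synthetic system does **not** emulate: real geography and
coastlines, the empirical value distributions of the source climate/soil
products, spatially clustered LAI gaps (gaps are i.i.d.), within-article
spatial clustering of sites, and citation–location dependence.  Passing
tests therefore demonstrate correctness of the algorithms and the
recoverability of a known bias under controlled conditions, not the
magnitude of any real-world result.

## Problem sizes and determinism

The test suite and the acceptance script run at desk scale as a deliberate
design choice: grids of 100×240 cells, hundreds of articles, background
samples of 2,000–20,000 pixels, and CV ensembles with 150-tree forests and
200-tree boosters (learning rate 0.05).  Chance-level calibration,
separability recovery and conservation identities are size-invariant, so
these scales test the same properties the full-size configuration would.
All randomness flows from one master seed through named `SeedSequence`
sub-streams (background, pseudo-absence, model, CV), recorded in the run
manifest; two runs with the same configuration and seed produce
byte-identical summary outputs.

## Known limitations

* Geodesy is spherical (authalic radius); ellipsoidal areas differ by up to
  ~0.3%.  Buffering through the sinusoidal projection is accurate in the
  tropics but degrades poleward of ~60°.
* The equal-split citation allocation is a convention; citation counts are a
  coarse and time-lagged proxy for influence.
* Pseudo-absences are environmental, not geographic, absences: the model
  describes representativeness of *conditions*, and spatial autocorrelation
  is not modeled (no spatial-block CV).
* AUC on pseudo-absence data measures discrimination against the background
  sample, not absolute accuracy.
* The observed count of presences passed to the model is taken as-is from
  the filtered table; no deduplication of coincident coordinates is applied
  (duplicates are legitimate repeat sampling).
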