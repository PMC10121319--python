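# Methods

This note documents the models, the synthetic study system, the parameter
defaults, and the numerical choices behind `enmstack`, in the order the
pipeline runs them.

## 1. The niche model

Each species' model is a Gibbs distribution over a finite background cell
set, the classic presence-only maximum-entropy formulation: minimising
relative entropy to the uniform distribution subject to feature-expectation
constraints is dual to maximising the L1-penalised log-likelihood

ℓ(λ) = (1/m) Σ_{i∈train} λ·f(x_i) − log Σ_{x∈B} exp(λ·f(x)) − Σ_j β_j|λ_j|.

Assumptions inherited from this formulation:

* presences are an (effort-biased) sample of where the species occurs;
  the background represents available environment *including that bias*
  when the target-group background is used;
* only the ordering of the output matters downstream — we therefore report
  the raw relative occurrence rate (ROR, normalised to sum to 1 over the
  background) and never a logistic/cloglog transform, which would require a
  prevalence assumption without changing any binary map.

**Features.**  Every non-constant layer is min-max scaled to [0, 1] on the
background and contributes a linear and a quadratic feature; when the
training sample has ≥ 15 cells, hinge features are added at the nine
background deciles of each layer.  This coarsely emulates the automatic
feature rules of the widely used Maxent implementation without reproducing
it bit-for-bit (product, threshold and categorical features, clamping and
extrapolation controls are deliberately out of scope).

**Regularisation.**  β_j = β₀·s_j/√m with s_j the background feature
standard deviation, m the number of presences and β₀ = 1.0 by default — the
sample-size scaling that makes small-sample models smoother.

**Optimisation.**  The objective is convex.  We split λ = λ⁺ − λ⁻ with
λ⁺, λ⁻ ≥ 0, which turns the L1 kink into a smooth bound-constrained problem,
and solve with L-BFGS-B (gradient tolerance 10⁻⁶, iteration cap 10⁴).
Non-convergence raises an error carrying the final projected-gradient norm;
a property test verifies the fitted objective dominates random weight
perturbations.

**Thresholding.**  The 10-percentile training-presence threshold τ is the
value at 0-based index ⌊0.1·n⌋ of the ascending training RORs (the lower
value at non-integer ranks).  This convention makes the guarantee exact:
training omission is ⌊0.1·n⌋/n ≤ 10%, and exactly 10% when n ≡ 0 (mod 10)
with distinct values.  Cells with missing layer values binarise to
*unsuitable* (conservative; prevents NA propagation into stacking).

## 2. Curation

Records are kept only if their kind is specimen or observation; native-range
polygons, when supplied, drop records outside a species' range.  Remaining
records collapse to spatially unique grid cells, dropping cells with any
missing layer value.  Record-count categories: ≤ 6 unique cells — excluded
from everything downstream; 7–99 — all cells train, evaluated on training
omission; ≥ 100 — random 70/30 train/test split (|train| = round(0.7 n), no
spatial blocking).  The background is the union of all modelled species'
presence cells within the guild (target-group background), topped up with
uniform valid cells to `min_background` (default 1000) on sparse rosters.

## 3. Stacking and evaluation

Flora rectangles are snapped outward to cell edges to form bounding boxes
(cell membership is center-in-box, half-open on the max edges, so adjacent
boxes never double-count).  A species is predicted present in a flora when
at least `min_suitable_cells` (default 1 — the most permissive rule, and the
one consistent with strong overprediction) suitable cells fall in its box.
Binary maps are thresholded once globally per species, never re-thresholded
locally.

Statistics (all logarithms base 10; z itself is base-invariant):

* **z coefficient** per flora; NA when either richness is 0 or the areas
  coincide, and NA floras are excluded from z summaries.
* **Regressions** of predicted on reported richness, overall and per size
  class.  The orientation is predicted-on-reported; the companion ratio
  table reports both S_pred/S_rep and its reciprocal so the reverse reading
  is available.  Floras with S_rep = 0 stay in regressions (they anchor the
  intercept) but are excluded from z and ratio computations.
* **Fisher intervals** tanh(atanh r ± z_{α/2}/√(n−3)), truncated below at 0.
* **Confusion matrices** per flora over the modelled roster of the guild
  being evaluated; sensitivity a/(a+c) is NA for floras with no reported
  presences, specificity d/(b+d) is NA when every modelled species is
  reported.
* **Overprediction factor**: the headline is the mean over floras (with both
  richnesses > 0) of S_pred/S_rep; the pooled ratio ΣS_pred/ΣS_rep is also
  emitted since mean-of-ratios and ratio-of-sums can differ materially.

## 4. The synthetic world

The generator produces a study system with the statistical structure the
analysis assumes, with complete ground truth:

* **Landscape**: a flat grid of square cells (default 200×200 cells of
  100 ha; the cell area is a free parameter), partitioned into three equal
  vertical basins that act purely as sampling strata.
* **Environment**: L = 22 Gaussian random fields (white noise smoothed at
  scale 8 cells, standardised), mixed by the symmetric square root of an
  AR(1)-style correlation target ρ^|i−j| with ρ = 0.6 — emulating the strong
  collinearity of bioclim-style predictor stacks.  Positive-semidefinite
  targets are accepted (perfectly correlated layers become affine copies);
  indefinite ones are rejected.
* **Species**: product-Gaussian niches on 4 layers shared within a guild
  (families respond to common climatic axes).  The *narrow* guild (66
  species in the default world) has breadth 0.5 (in standardised layer
  units), optima confined to the 0.7–0.97 quantile corner of its niche
  layers — a specialist clade concentrated in one climatic region — and
  dispersal fraction 0.5.  The *broad* guild (60 species) has breadth 1.0,
  optima across the whole gradient, and full dispersal.  Suitability cutoff
  0.2 defines the suitable set; the occupied range is a seeded flood-fill
  subset of round(dispersal_fraction · |suitable|) cells, keeping ranges
  contiguous the way dispersal limitation does.
* **Occurrences**: each species draws its target record count (a mixture of
  sparse 3–6, moderate 20–99 and well-sampled 120–400 regimes, weighted
  10/40/50) from occupied cells with probability proportional to a smooth
  collection-bias field, jittered within cells; 90% of records are
  specimens/observations and 10% are kinds the curation filter must remove.
* **Floras**: per basin and per decadal area class (10¹<A≤10² … 10⁶<A≤10⁷
  ha), rectangles with log-uniform area, random aspect ratio (½–2) and
  uniform position; classes exceeding the basin area are truncated (or
  skipped) with a warning.  The reported list is the exact set of species
  whose occupied range overlaps the rectangle — a flora smaller than one
  cell still overlaps the cell it sits in — optionally thinned by a
  non-detection probability (default 0).

All randomness flows from one master seed through named substreams
(environment, species, ranges, occurrences, floras, bias, split,
background), so a world is bit-reproducible and any stage can be re-run in
isolation.

### What the generator does and does not emulate

It reproduces the *structure* the analysis relies on: correlated predictors,
contrasting guild biology, survey bias (which the target-group background
exists to absorb), record-kind noise, stratified evaluation areas, and the
dispersal-limitation mechanism that makes stacked models overpredict.  It
does not mimic real geography, real bioclim values, irregular flora
polygons, taxonomic noise, or spatially autocorrelated detection failure.
Two consequences matter when reading results:

* Because synthetic floras are axis-aligned rectangles, their bounding boxes
  exceed them by at most one cell ring.  The z denominator
  log(A_bbox) − log(A_flora) is therefore often tiny, and per-flora z values
  are heavy-tailed (means far above 1 for the overpredicted guild).  Real
  floras have irregular shapes and materially larger boxes, giving tamer z
  distributions; the *direction* of the diagnostic (z ≫ 0.35 ⇒ overprediction
  is not an area artefact) is what transfers.
* Passing recovery tests show the pipeline recovers known mechanisms under
  these conditions; they do not certify accuracy on real occurrence data,
  where georeferencing error, taxonomic drift and non-equilibrium ranges add
  failure modes the generator does not model.

## 5. Study sizes

The multi-seed parameter-recovery study runs ten master seeds on a scaled
world — 200×200 cells, 15 species per guild, 5 floras per stratum (90 per
seed) — which preserves every mechanism of the full-size world while keeping
a study to a few minutes on one CPU.  The full-size default world (126
species, 180 floras) is used for structural bookkeeping (e.g. the
180 × 126 = 22,680 cropped-model count) and is the default for `enmstack run`.
In the scaled world the largest size class is truncated to the basin area
(a 200×200 grid of 100-ha cells holds 1.33×10⁶ ha per basin), which the
generator reports with a warning; class-10⁷ floras then span (10⁶, 1.33×10⁶] ha.

## 6. Known limitations

* The maximum-entropy fit is a re-implementation, not a port: agreement with
  the historical Maxent binary is structural (same objective family), not
  numerical.
* Planar geometry only; real-data use requires pre-projected equal-area
  rasters.
* No spatial blocking in the 70/30 split, matching the emulated protocol;
  spatially autocorrelated presences therefore make test omission an
  optimistic estimate, which is one reason observed test omission can sit
  below the training bound.
* OLS regressions ignore spatial autocorrelation between floras (plain OLS
  is the emulated protocol).
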