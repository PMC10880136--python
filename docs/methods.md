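# Methods

## Model and assumptions

The cumulative niche approach treats a species' realised niche as the
axis-aligned box spanned by its occurrence records in standardised
environmental space, and asks how the volume of that box (the *niche
breadth* `B = ∏ A_j`, where `A_j` is the per-variable amplitude max − min)
grows as data accumulate. The reasoning parallels species-accumulation
curves in community ecology: if adding data stops enlarging the estimate,
the estimate is probably complete. The approach assumes

* occurrence records are an (approximately) unbiased sample of the occupied
  environments — the `bias_screen` diagnostic exists precisely because this
  often fails;
* the environmental layers are co-registered and ecologically relevant;
* the range product is an acceptable niche-size surrogate. It deliberately
  ignores correlation structure and holes inside the box; it is the
  simplest volume measure that makes the accumulation logic exact and
  monotone. Alternative metrics (kernel hypervolumes, convex hulls) are an
  extension point, not implemented.

Standardisation uses the sample standard deviation (n − 1 denominator) over
each layer's non-masked cells; the convention is recorded in
`StandardizationParams` (`ddof`) so the population convention can be
replayed. Whether the moments should be taken over land cells only or the
full grid is undocumented in common practice; we use non-masked cells.

## Curve construction

*Native*: records are shuffled into folds — folds of 100 above 1000
records, folds of 10 for 31–1000, folds of 1 at ≤ 30. A trailing smaller
fold keeps the remainder, because the reference breadth must use every
record; n = 1000 falls in the folds-of-10 regime (strict reading of "more
than 1000"). Fold membership is reshuffled in each of the 10 repetitions:
the repetitions exist to average out ordering, and frozen folds would
defeat that.

*Alien*: a fresh uniform permutation of the invaded regions per repetition;
step k is breadth(native ∪ regions 1..k) / breadth(native). Regions whose
records were all discarded remain as (flagged) no-op steps so the x-axis
stays the full region count.

*Background*: one uniform random point per 0.25° cell whose center lies in
the region (an any-overlap rule is available); points landing on nodata are
redrawn up to 10 times, then the cell is skipped. Points are drawn once per
run and reused across repetitions — only the region order varies — so the
alien and background curves differ only in *what* each region contributes,
not in sampling noise between repetitions. The ratio basis includes the
native records, mirroring the alien curve, and the run manifest records
this choice. Setting `include_alien_occurrences` additionally pools the
regions' records into the background basis, which guarantees the background
curve dominates the alien curve pointwise; it is off by default because the
coarse background grid need not hit the records' exact conditions.

Because the per-variable extrema are carried exactly (never re-derived from
products), incremental updates are bitwise identical to batch computation
and every repetition row is non-decreasing by construction.

## Asymptote rule and outcome classification

"Approaches an asymptote" is judged on the mean curve with a dual
criterion, both thresholds configurable and recorded in the manifest:

* `fraction_at_95` ≤ `max_fraction` (default 0.5): the curve must cover
  95% (`rise_threshold`) of its total rise within the first half of its
  steps. The rise is measured from the curve's conceptual origin — 0 for
  the native curve, 1 for alien/background.
* `tail_slope` ≤ `tail_slope_max` (default 0.01): the mean per-step
  increase over the final 20% of steps, relative to the total rise, must be
  near zero.

A flat curve counts as reached (`fraction_at_95 = 1/n`); curves with fewer
than 3 steps return an *undetermined* verdict treated as not-reached.
The defaults are calibrated to the qualitative benchmark that "less than
half the data suffices for over 90% of the breadth" describes a
well-sampled niche.

The scenario letter is the native/alien verdict 2×2 (a: both reached,
b: alien only, c: native only, d: neither). Background headroom — the
background curve ending more than 5% (relative, `headroom_margin`) above
the alien curve — does not change the letter; instead, a reached alien
curve without headroom is demoted to *uninformative-nested*: the nested
flag is raised and projection confidence drops to low. This resolves the
ambiguous no-headroom cases explicitly rather than inventing a fifth
letter, and the report carries the demotion note.

`bias_screen` compares a focal species' asymptotic breadth against a
reference point set (stratified-random locations or a wider species
group); a focal breadth below half (default) of the reference breadth flags
that the asymptote may only describe the well-sampled niche portion.

## Variable selection

Step 1 is the iterative pairwise-exclusion variant of the |r| < 0.7 rule:
while any pair of variables has |Pearson r| ≥ 0.7, the worst pair is found
and its higher-VIF member dropped (numerical ties, e.g. a symmetric pair,
drop the lexicographically later name). A single pass can leave violating
pairs; iteration cannot. Correlations and VIFs are computed on the pooled
presence + background values of the standardised layers (correlation is
affine-invariant, so standardisation only affects VIF reporting).

Step 2 ranks variables by a presence–background model. The exact ENM the
rule was designed around is not reproducible from published settings alone,
so the estimator is a named, pluggable strategy
(`register_estimator`); the default is an L2-regularised logistic
classifier with linear + quadratic features. Contributions are jackknife
gains — the drop in training gain when a variable is left out, floored at
zero, falling back to variable-alone gains when the full model is
degenerate — normalised to sum to 100%. Variables below 5% are dropped; if
all fall below, the single best is kept with a warning, since an empty
variable set would make every breadth undefined. The background sample for
this step is drawn uniformly from valid cells inside the native range
(10,000 by default; the synthetic-scenario runs use 1,000, which is ample
for a 10⁴-cell landscape).

## The synthetic generator

`synthetic` generates the full input quadruple with known ground truth:
layers are linear gradients in evenly spaced directions plus smoothed
Gaussian noise (amplitude `smoothness`), standardised; an optional mixing
matrix creates deliberately collinear layers; an optional folded (tent-map)
x-coordinate makes distant places environmentally identical. Species are
axis-aligned tolerance boxes in standardised space, so the true breadth and
the expected accumulation behaviour are analytic (the amplitude of n
uniform draws on width w has expectation w·(n − 1)/(n + 1)).

The scenario presets realise the four outcomes on a 100×100-cell landscape
(0.05° cells) with two orthogonal gradients plus one collinear blend layer,
200 native records and 10 invaded regions:

* complete native sampling (uniform over suitable cells) yields a native
  curve that covers 95% of its rise within ~30% of its folds;
* clustered native sampling (95% of records from a central stripe along
  the dominant gradient, 5% diffuse) makes the envelope depend on the few
  diffuse records, holding the curve below saturation past half the folds;
* regions spanning the full novel gradient band, with 30 records each,
  saturate the alien curve at its first steps, while the regions extend
  beyond the species' tolerance (background headroom);
* a "two-sided" layout slices regions *along* two gradient directions so
  each region contributes its own increment; the curve cannot approach its
  ceiling until the far slices of both directions have been drawn, which
  happens late in almost every ordering;
* the nested preset places regions on the mirrored arm of a folded
  landscape, strictly inside the native envelope, so the alien curve equals
  exactly 1 and the background curve is flat — the nestedness signature.

What the generator does *not* emulate: dispersal limitation, biotic
interactions, spatially autocorrelated observation effort, coordinate
error, non-box (e.g. unimodal continuous) suitability. Passing the scenario
tests therefore shows the machinery responds correctly to data
completeness and environmental nestedness, not that real occurrence data
meet the approach's assumptions.

## Numerical choices and degenerate inputs

* Grid cells are half-open, lower-left closed; points on a raster's
  top/right edge belong to the last cell; the thinning/background grids are
  anchored at (−180°, −90°). Longitudes must lie in [−180, 180]
  (no antimeridian wrap).
* Thinning keeps one record per 2.5 arc-minute cell, chosen uniformly under
  the run seed (not first-come), so upstream sort order cannot leak in.
* A record inside both the native range and a checklist region is native
  (conservative against inflating apparent expansion); a record on the
  shared boundary of two alien regions goes to the lexicographically
  smaller region id.
* Breadth of an empty variable set is an error, not 1 — a silent 1 would
  corrupt every ratio. A zero reference breadth (fewer than two
  environmentally distinct native records) errors, naming the flat
  variables.
* One run seed fans out to per-stage seeds via CRC-32 of the stage tag, so
  stages can be re-run in isolation; all derived seeds are below 2³¹.

## Problem sizes

The test suite and the acceptance script run on 100×100-cell landscapes,
200 native records, 10 regions and 20 seeds per scenario preset — sizes at
which every designed effect is comfortably resolved while a full 100-run
scenario sweep completes in seconds. Curve-law checks use 200 random point
clouds; the range-law check uses 1,000 simulations at n = 99.

## Known limitations

* The range product is sensitive to single outlying records (any one point
  can stretch an amplitude); the thinning step and the bias screen mitigate
  but do not remove this.
* Administrative regions are treated as given; their political boundaries
  make the background curve scale-dependent (over-represented in large
  regions, under-represented in small ones).
* The asymptote rule is a heuristic on the mean curve; no saturating model
  is fitted and no confidence band is produced.
* Shapefile/GeoPackage input is not supported — vector data must be
  GeoJSON; rasters must be ESRI ASCII grids, already co-registered
  (no reprojection or resampling).
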