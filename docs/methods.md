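# Methods

This note documents the models, conventions and numerical choices behind
`seedscape`, and what the synthetic studies do and do not establish.

## Study design being modelled

A set of old-growth forest patches (default 16) embedded in a
human-modified tropical mosaic, each sampled at its centre with N = 10
plots of 1 m², every tree seedling counted and identified, and each
species labelled by dispersal syndrome. Analyses use animal-dispersed
species only, since they dominate seed rain in these systems (~94% of
individuals in the emulated design). The landscape is a classified raster
with 10 m cells and seven cover classes: old-growth forest (1), secondary
forest (2), floodplain (3), arboreal crop (4), cattle pasture (5),
anthropogenic (6) and water (7).

## Diversity decomposition

Hill numbers at orders q = 0, 1, 2 per patch. Within each plot j, relative
abundances `p_ij` are that plot's counts over its own total; plots get
equal weight regardless of how many individuals they hold, and the
patch-level mean `p̄_i` is the arithmetic mean of `p_ij` over plots. Gamma
uses `p̄_i`; alpha averages the plot-level sums inside the exponent
(`(1/N) Σ_j Σ_i p_ij^q`); beta is the exact quotient γ/α and lies in
[1, N]. The q = 1 cases use the Shannon limits with the `0·ln 0 ≡ 0`
convention.

Choices worth stating:

- **Equal plot weights, not pooled individuals.** Pooling would weight
  plots by their abundance; the per-plot-normalized reading matches the α
  formula's (1/N) prefactor. The pooled variant would be a small extension
  but is deliberately not a switch: silently mixing the two produces
  incomparable β values.
- **Empty plots are an error, not silently dropped.** Dropping a plot
  changes N and with it β's upper bound; the caller must decide what an
  empty plot means. The synthetic generator guarantees at least one
  animal-dispersed individual per plot for the same reason.
- **q restricted to {0, 1, 2}** at the block level. A general-q
  `effective_number` is exposed for the continuity check at q → 1 and for
  exploratory use.
- **Sample coverage** uses the improved singleton/doubleton estimator
  `Ĉ = 1 − (f1/n)·[(n−1)f1/((n−1)f1 + 2f2)]`, with Ĉ = 1 when f1 = 0 (no
  singletons: the sample is treated as complete).

## Landscape metrics

All metrics are class-level (focal class: old-growth forest) inside
circular buffers of radius 300–1500 m in 100 m steps, membership decided
by the cell-centre-in-circle test. Conventions follow the common defaults
of class-level landscape-metric software:

- **Patches** are 8-connected components; **adjacency/edge counts** are
  rook (4-neighbour). Components clipped by the buffer rim count fully.
- **AI** = 100·g/g_max with g the single-count like-adjacencies and g_max
  the most-compact-arrangement maximum for the class's cell area
  (n = ⌊√A⌋, m = A − n²: 2n(n−1), +2m−1 if m ≤ n, +2m−2 if m > n). Absent
  class → missing; single cell → 0.
- **PI** is the mean over components of the nearest-neighbour distance to
  any other component, measured between cell centres. Fewer than two
  components → missing value (a zero would fake maximal connectivity);
  missing values drop that patch×radius from downstream fits.
- **EC** weights each boundary edge by the habitat-quality rank gap
  between old-growth forest (rank 7) and the neighbouring cover, linearly
  rescaled to [0, 1] by d = (7 − rank)/6 on the seven-point scale (water
  lowest, old-growth highest); per-patch contrasts are averaged
  area-weighted. Edges at the buffer rim are excluded from denominators so
  the "outside" never contributes contrast; fully interior components
  contribute 0.

The connectivity rule, contrast-weight construction and PI distance
convention are documented substitutes where the field's software offers
several; each is isolated behind one function so a variant is a local
change.

## Scale of effect

For each response–metric pair and radius, a simple OLS model is scored by
leave-two-out cross-validation: all C(n, 2) pairs of patches are held out
in turn, the model is refitted on the remaining n − 2, and
`SS̄_cv` is the **per-held-out-observation** mean squared prediction error
(divide by 2·C(n, 2)). This normalization makes the numerator
commensurate with the `(1/n) Σ (y_i − ȳ)²` denominator, so an exactly
linear dataset scores exactly 1; a per-split-sum variant
(`normalization="split"`) is provided because the prose description
"average sum of squares" admits both readings. R²_CV is ≤ 1 and unbounded
below; negative values mean worse than the mean-only model.

The selected radius is the argmax over the 13 radii, ties broken toward
the smallest radius (parsimony toward local scales, and deterministic).
Radii with fewer than 4 complete pairs are excluded. The bootstrap
resamples patches with replacement, re-selects per replicate, and redraws
replicates on which no radius is valid (e.g. a constant resampled
response), so counts always sum to B; the reported mean ± SD is over the B
selected radii. The C(n, 2) refits use closed-form downdates of the
simple-regression sufficient statistics, vectorized over pairs; the test
suite pins them to an explicit enumerate-and-refit oracle.

## Multimodel inference

Global additive models only (small n forbids interactions). Candidates are
all 2^T subsets plus the null; each is fitted by Gaussian OLS.
`k` counts intercept + slopes + residual variance (null model k = 2), and
`AICc = −2 logL + 2k + 2k(k+1)/(n − k − 1)`; candidates with n ≤ k + 1 are
skipped with a recorded reason. Akaike weights are computed over the full
candidate set; the 95% confidence set is the shortest ranking prefix whose
cumulative weight reaches 0.95 (the crossing model included), and weights
are renormalized inside the set before averaging so the averages are
convex combinations. Averaging is **full** (zero-substitution): a term
absent from a model contributes a zero coefficient. Unconditional SEs
follow Burnham–Anderson, `USE_j = Σ w_i √(var(β_ij) + (β_ij − β̄_j)²)`
with `var` the squared OLS standard error; importance is the summed weight
of models containing the term; a term is *influential* when β̄ ± USE
excludes zero. Conditional averaging and the renormalization choice are
the two points where reasonable implementations differ; full averaging
with renormalization is the default here because it keeps estimates
shrunk toward zero for weakly supported terms.

VIF ≥ 4 on the global model aborts that response with a diagnostic rather
than silently dropping a term. The pipeline's automatic global-model
builder (used when none is supplied) takes each response's top-3
predictors by best R²_CV at their selected scales and then iteratively
drops the highest-VIF term until the screen passes.

## Synthetic studies

The generator exists to make the planted truth recoverable, with the
statistical texture of real seedling data:

- **Landscape:** modified random clusters — i.i.d. occupancy at
  probability `clustering` (default 0.5, below the 4-neighbour site
  percolation threshold ≈ 0.593 so clusters stay distinct), 4-connected
  cluster labelling, clusters assigned largest-first to the cover class
  with the greatest remaining area deficit, unoccupied cells inheriting
  the nearest assigned class. Defaults: 12 × 12 km, 10 m cells, ~19%
  old-growth forest in a pasture-dominated matrix. `clustering = 0`
  degenerates to i.i.d. cells.
- **Patch centres** fall on forest cells ≥ 1500 m from the raster edge
  (so the largest buffer always fits), pairwise ≥ 1000 m apart.
- **Communities:** each patch's target log effective-number of typical
  species is `ln 6 + effect·z + N(0, noise_sd)` with z the standardized
  focal metric at the true radius (defaults: FC at 800 m, effect 1.0,
  noise SD 0.25). The target is mapped through
  `1 + (S−1)(1 − exp(−e^η/(S−1)))`, a strictly increasing squash that
  approximates `1 + e^η` far below the S-species ceiling and saturates
  smoothly, so diversity remains strictly monotone in the signal even when
  noise is switched off. A lognormal species-abundance distribution
  (fixed standard-normal species effects scaled by σ) is then tuned by
  bisection on σ to hit the target exponential Shannon entropy — σ = 0
  gives a uniform community, large σ extreme dominance. Individuals
  (≈ 79 per patch, the emulated seedling density) are spread over plots by
  a Dirichlet-multinomial with concentration θ (default 10); θ → ∞ makes
  plots identical (β → 1), small θ raises within-patch turnover. Draws
  leaving any plot without an animal-dispersed individual are regenerated,
  with a deterministic one-per-plot fallback after 100 attempts. 94% of
  each patch's species are labelled animal-dispersed.

What the generator does *not* emulate: spatial autocorrelation of
communities beyond what the shared landscape induces, temporal turnover,
dispersal kernels, species-specific habitat affinities, and observation
error in the land-cover classification. Passing tests therefore show the
*estimators* behave correctly under the design's assumptions, not that any
particular field system satisfies them.

## Problem sizes and numerical choices

Validation uses 100 replicate synthetic studies for scale recovery
(bootstrap B = 1000 each) and driver identification, 200 random small
blocks against an arbitrary-precision symbolic oracle (tolerance 1e-10),
exhaustive brute-force enumeration for grid metrics (≤ 8×8) and
leave-two-out splits (n ≤ 8), and 200 pure-noise replicates for the
null-model check. Argmax ties break to the smallest radius; degenerate
predictors (constant on any calibration split) and zero-variance responses
raise typed errors rather than returning NaN silently; perfect
collinearity in the VIF screen reports `inf` instead of raising. All
randomness flows from explicit seeds; every generator is a pure function
of its seed.

## Known limitations

- PI uses cell-centre (not polygon-edge) distances; at 10 m cells the
  difference is below one cell width.
- The lognormal SAD is a stand-in: its parameters are not calibrated to a
  particular species list, only to the dominance-with-many-rares pattern.
- The automatic global-model builder is one defensible rule among several;
  supply `global_models` explicitly to reproduce a specific specification.
- Incidence-based diversity, rarefaction/extrapolation and asymptotic
  estimators are out of scope, as are mixed models and spatially explicit
  error structures.
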