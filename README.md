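# seedscape

Multi-scale landscape analysis of tree-seedling diversity in fragmented
tropical forest, as a tested, reusable Python library.

The scientific question the package addresses: **which components of
landscape composition and configuration influence seedling α- and
β-diversity within forest patches, and at which spatial scale?** Around
each sampled forest patch, landscape structure can be measured in buffers
of many radii; the radius at which a landscape metric best predicts a
biological response is that metric's *scale of effect*. The package
implements the full analysis chain for this question and, because suitable
field data are rarely shareable, ships a synthetic-study generator with a
*planted* scale of effect so every stage can be validated against known
ground truth.

## What it computes

**Diversity** (per patch of N small plots): Hill numbers in effective
numbers of species,

- γ of order q: `(Σ_i p̄_i^q)^{1/(1−q)}`, with `p̄_i` the mean over plots of
  within-plot relative abundances, and `exp(−Σ p̄_i ln p̄_i)` at q = 1;
- α of order q: `[(1/N) Σ_j Σ_i p_ij^q]^{1/(1−q)}` (and the analogous
  Shannon limit at q = 1);
- β = γ/α ∈ [1, N], the effective number of completely distinct plot
  assemblages;
- Chao–Shen sample coverage `Ĉ = 1 − (f1/n)·[(n−1)f1/((n−1)f1 + 2f2)]`.

q = 0, 1, 2 weight species occurrence vs abundance: *all*, *typical* and
*dominant* species. Analyses restrict communities to animal-dispersed
species.

**Landscape metrics** (class level, in 13 circular buffers of 300–1500 m):
old-growth and secondary forest cover (FC, SF), patch density (PD),
aggregation index (AI), patch isolation (PI) and a quality-ranked,
area-weighted edge-contrast index (EC).

**Scale of effect**: per (response, metric) pair, 13 single-predictor
linear models scored by the leave-two-out cross-validated coefficient of
determination

```
R²_CV = 1 − SS̄_cv / [(1/n) Σ (y_i − ȳ)²]
```

with SS̄_cv the mean squared prediction error over all C(n, 2) held-out
patch pairs; the radius maximizing R²_CV is selected, and its uncertainty
is estimated by bootstrap resampling of patches (B = 1000).

**Multimodel inference**: predictors fixed at their selected scales form a
global additive model; all subsets plus the null are ranked by AICc,
Akaike weights give a 95% confidence set, and coefficients are
model-averaged with Burnham–Anderson unconditional standard errors and
summed-weight variable importances. A VIF ≥ 4 screen guards against
collinearity; Shapiro–Wilk, Clark–Evans and Mantel-style screens are
reported as diagnostics.

## Worked example

`examples/03_scale_of_effect.py` simulates a 16-patch study in which
forest cover at an 800 m radius drives the log effective number of typical
species (effect 1 SD, residual SD 0.25), then scans all 13 radii:

```
radius_m  R2_CV
    300  -0.210
    ...
    700   0.765
    800   0.897  <- scale of effect
    900   0.848
    ...
   1500   0.265

bootstrap (B=500): mode 800 m, mean 845.8 +/- 142.7 m
```

The cross-validated R² peaks at the planted radius: a model fitted on 14
patches predicts the two held-out patches almost perfectly there, and the
bootstrap mode agrees with the point selection. The other examples cover
the diversity decomposition, the buffer metrics, the AICc averaging step
and the one-call pipeline (`run_pipeline` / `seedscape run-all`), which
writes every intermediate table (communities, diversity, metrics,
profiles, bootstrap counts, rankings, averaged estimates, diagnostics) to
an output directory.

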