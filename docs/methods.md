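# Methods

This note documents the models and procedures implemented in `ilta`, the
assumptions behind them, the defaults and why they were chosen, and what
the synthetic-data tests do and do not establish.

## The dataset cascade

Fossil leaf analysis works on nested subsets of a collection, because the
different measurements have different preservation demands:

| level | contents | criterion |
|---|---|---|
| Dataset 1 | all scored leaves | ≥ 50 % of lamina preserved, characters readable |
| Dataset 2 | outline-reconstructable leaves | preserved fraction ≥ 0.70 (inclusive) |
| Dataset 3 | measurement subsample | simple random draw of 400 leaves per site |
| Dataset 4 | multivariate complete cases | see filters below |
| Dataset 5 | imputation-enlarged modelling set | Dataset-4 filters after LM_A imputation |

Dataset 4 removes, in this order: (1) incomplete cases for the
multivariate variable set; (2) leaf-size or LM_A values outside Tukey's
fences `[Q1 − 1.5·IQR, Q3 + 1.5·IQR]` with linear-interpolation quartiles,
computed per site (per-site because trait distributions differ between
sites; a pooled variant is available); (3) fossil-species with fewer than
five remaining leaves; (4) TCTs with fewer than five remaining leaves
(deleted by default; merging into an `"other"` class is available by
flag).  The order — completeness before outliers before rarity — was a
genuinely open choice; it is fixed this way so that rarity is judged on
the cleaned set, and the returned removal ledger lets any alternative
order be audited.  Boundary thresholds read "at least" literally, so 0.70
and five are inclusive.

## Trait combination types

Sixteen classes arise from four binary characters: lobation (lobed /
unlobed), margin (entire / toothed), primary venation (pinnate /
palmate), secondary venation (looped / non-looped).  The default letter
table enumerates the quartets in nested order (lobation → margin →
primary → secondary, second state last), giving A = unlobed / entire /
pinnate / looped through P = lobed / toothed / palmate / non-looped.
The table is data, loadable from CSV; the default satisfies the anchor
letters fixed by usage for these floras (A, B, E, F, P, and the
Cercidiphyllum-G / Tilia-H placements).  The letters not pinned by any
anchor follow the same enumeration but are a convention, not a claim.

Assignment is specimen-based when all four characters are readable; when
only the secondary venation is unreadable and the species diagnosis
implies exactly one letter, the taxonomy-based letter is used (combined
approach); in every other case the leaf is unclassifiable and excluded —
no character is ever guessed.  Spectra report percentages against two
denominators (all leaves, and assigned leaves only); the all-leaves
denominator is the default display because it makes letter shares read as
assemblage fractions.

The 8-class coarsening merges letters differing only in secondary
venation (`E/F` etc.), for analyses where that character's frequent
unreadability would otherwise bias sample composition.

## Quantitative traits

Lamina area is the shoelace area of the reconstructed outline polygon.
Length is the extent of the outline along the principal axis of its
vertex cloud, width the orthogonal extent.  The principal axis
approximates the midrib axis, which the program cannot know; for typical
leaf outlines the difference is negligible, but strongly asymmetric
laminae could diverge.  The area index IA = preserved / reconstructed
area is the preservation criterion of the cascade.

LM_A comes from the dicot petiole allometry
`log10(LM_A) = 3.070 + 0.382 log10(pw²/area)` (pw in mm, area in mm²,
LM_A in g/m²).  Logs are base 10: the source allometry is a log10
regression, and the natural-log reading produces values far outside any
observed leaf range (a sanity check in the test suite).  The analytic
inverse (petiole width given LM_A and area) is provided and round-trips
to 1e-9; the synthetic generator uses it to plant petiole widths.

Species-mean LM_A maps to phenology as deciduous (< 87 g/m²),
intermediate (87–129, boundaries inclusive — "between" read literally),
evergreen (> 129).  Means require at least five measured leaves per
species, enforced separately per metric.

## Herbivory metrics

DAM% = 100 × damaged leaves / all leaves; the denominator includes
undamaged leaves, so the statistic is a leaf-level prevalence.  DTO
counts (leaf, damage-type) records without standardisation — a leaf with
k types contributes k.  DTR counts distinct damage types.

Rarefaction is sample-based with leaves as sampling units.  With N
leaves and type *i* on N_i of them, a uniformly random n-leaf subset
misses type *i* with probability `q_i = C(N−N_i, n)/C(N, n)`, so
`E[S_n] = Σ (1 − q_i)`.  The variance uses the exact joint-absence
probabilities `q_ij = C(N−u_ij, n)/C(N, n)` with u_ij the number of
leaves carrying *i* or *j*:
`Var = Σ q_i(1−q_i) + 2 Σ_{i<j} (q_ij − q_i q_j)`.
Binomial coefficients are evaluated in log space (gammaln), and the
curve satisfies E[S_1] = mean per-leaf richness, E[S_N] = observed
richness, SD(N) = 0.  Because published descriptions of "the SD of the
resamples" are ambiguous between this analytic form and a Monte-Carlo
spread, both are implemented; the analytic form is the default and the
Monte-Carlo resampler is retained as an independent cross-check (they
agree to 3 SE in the test suite, and the analytic form matches exhaustive
enumeration in exact rational arithmetic on all small matrices tested).
Rarefaction refuses samples below 20 leaves (a conventional floor for
these assemblages), overridable by flag.

Damage types map to functional feeding groups (hole feeding, margin
feeding, surface feeding, skeletonization, mining, galling,
piercing-and-sucking); hole + margin + surface + skeletonization form the
"external foliage feeding" scope.  The shipped catalog covers the types
recorded on the two floras this package was developed against; DT 78 and
DT 81 are placed with hole feeding provisionally and the catalog is
user-overridable.  Unmapped numbers fall back to `"other"` and are
recorded.

HI = damaged area / lamina area, a dimensionless fraction per leaf.

## LM_A imputation

Missing LM_A is imputed by the Bayesian-linear-regression ("norm") step
of chained-equation imputation.  Only one variable is incomplete, so the
chained system reduces to a single model: LM_A on a locality indicator
plus leaf size, fitted over the pooled complete cases.  Species is
deliberately not a predictor — per-species regressions are underpowered
at the typical handful of measured leaves and show no usably strong
correlation — but species governs *eligibility*: a missing value is
imputed only when the specimen's species has ≥ 5 measured LM_A values in
the same site, which keeps imputations within species whose LM_A range
the data actually constrains.

Each cycle draws σ²* from RSS/χ²(n−rank), β* from N(β̂, σ²* (XᵀX)⁻¹)
(rank-aware pseudo-inverse, so collinear designs degrade gracefully), and
the imputed value from the predictive normal.  The reported value is the
mean of 10 cycles.  Averaging cycles shrinks the predictive variance —
a deliberate trade: the pipeline wants one working value per leaf rather
than a full multiple-imputation analysis, and the diagnostics retain the
per-cycle draws so the un-averaged spread remains inspectable.  A range
filter (on by default) discards imputed values below the minimum measured
LM_A of the site — the direction in which regression extrapolation
produces physically implausible leaves; symmetric above-maximum removal
is available by flag.  Measured values are never altered, and the whole
run is deterministic under its seed.

## Statistical battery

*Mann-Whitney*: the reported W is the first-sample U with ½-weighting of
ties (computed from rank sums); this is the convention under which the
statistic is comparable across software that reports "W".  P-values
follow the usual exact / tie-corrected-normal switch.  W, not p, is the
stable quantity for cross-checks.

*Kruskal-Wallis post hoc*: joint midranks, the tie-corrected H statistic,
and Fisher-LSD comparisons on mean ranks with pooled rank variance scaled
by (N−1−H)/(N−k), df = N−k.  The compact letter display assigns one
letter per maximal run of mutually non-different groups in mean-rank
order; groups share a letter iff not significantly different at α = 0.05.

*PCA*: variables standardised to unit variance (correlation-matrix PCA),
eigendecomposition via SVD; eigenvalues sum to the number of variables;
contribution of variable v to axis k = 100·loading²(v,k)/Σ_v loading².
Requires complete cases and ≥ 6 rows; constant columns are rejected by
name.  The five canonical traits are LM_A, area, width, length, and the
length/width ratio.

*GLMs*: Gamma error with identity link for positive responses whose
effects are read additively on the original scale (LM_A, leaf size,
damaged area, HI); binomial with logit for damage presence/absence.
Fitting is IRLS via statsmodels; non-convergence raises with the last
deviance.  Stepwise selection is greedy and bidirectional on AIC from the
full model, with a 1e-10 tie guard (ties keep the current model); the
selected AIC never exceeds the full model's, and the trace is returned.
Type-II ANOVA refits the model without each term (no interactions exist
in this suite, so marginality is trivial) and reports LR χ², df, and p.
R² is Nagelkerke's `[1 − (L0/L1)^(2/n)]/[1 − L0^(2/n)]`; binomial models
additionally report Tjur's R² (mean fitted probability among successes
minus failures).

*Shapiro-Wilk* is exposed for normality screening (3 ≤ n ≤ 5000).

## Synthetic assemblages

The generator draws, per leaf: a species from site-specific relative
abundances; lamina area and "true" LM_A from species log-normal laws
(evergreen species centred above 129 g/m², deciduous below 87, so the
LM_A-phenology link is planted); length/width from an elliptical model
with a species aspect ratio; the true petiole width from the allometry
inverse; damage types as independent Bernoulli draws per (leaf, type)
with species rates; and a total damaged-area fraction from a per-species
Beta law, split across the leaf's types by a Dirichlet draw (deciduous
Beta(1.5, 30), mean ≈ 4.8 %, evergreen Beta(1, 40), mean ≈ 2.4 % — a
planted phenology effect on HI).  A taphonomy layer then masks the truth:
preservation fraction from Beta(6, 4) (≈ 27 % of leaves pass the 0.70
measurement cut), petiole present with probability 0.4, multiplicative
log-normal noise (σ = 0.05) on the observed petiole width, and secondary
venation unreadable with probability 0.15 (exercising the taxonomy
fallback).  Per-leaf gamma frailty on damage rates is available as an
overdispersion hook, off by default.  The full unmasked truth is returned
beside the observable table, and a perfect-preservation spec disables
masking entirely, under which every observed value equals its true value
exactly (the end-to-end identity test).

Two presets encode the qualitative contrast between a deciduous-dominated
flora (modal TCT F ≈ 65 %, DAM% ≈ 4, larger low-LM_A leaves) and an
evergreen-dominated one (modal TCTs A/E, DAM% ≈ 12, smaller high-LM_A
leaves); a two-site preset combines them.  What the generator does *not*
emulate: phylogenetic correlation of traits, mechanistic taphonomy
(transport, fragmentation geometry), within-species spatial structure,
and non-independent damage-type co-occurrence.  Tests passing on these
presets therefore show the pipeline's correctness and statistical
behaviour under its own assumptions, not that real assemblages satisfy
those assumptions.

## Numerical choices and degenerate inputs

Binomial coefficients in log space; rarefaction variance clipped at zero
against rounding; quartiles by linear interpolation; the imputation
sampler uses the pseudo-inverse and matrix square root by
eigendecomposition, so constant or collinear predictors yield the
minimum-norm fit instead of failing; empty damage sets produce
zero-column incidence matrices; an empty sample makes DAM% an error
rather than 0 (the quantity is undefined, and silently returning 0 would
bias comparisons); AIC ties in stepwise selection keep the current model;
when the full model handed to stepwise selection does not itself
converge, selection starts from the best-AIC fittable submodel rather
than failing, and only an unfittable intercept-only model raises.

## Known limitations

Length is a principal-axis extent, not a midrib measurement.  The
rarefaction variance is the within-sample hypergeometric form; it does
not include between-assemblage sampling variance.  The imputation
averages cycles rather than propagating between-imputation variance into
the GLMs.  The letter table beyond the anchored letters is a convention.
GLM suites on small damaged-leaf subsets (tens of leaves) have limited
power to separate collinear predictors such as phenology, LM_A and
locality; selection among them is then seed-sensitive even when the
planted signal is real.
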