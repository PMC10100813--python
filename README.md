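# ilta — integrated leaf trait analysis of fossil dicot leaf assemblages

`ilta` is a Python library for paleobotanists and paleoecologists who work
with assemblages of fossil dicot leaves and want, from one specimen table,
a combined picture of

* **leaf architecture** — each leaf's four binary characters (lobation,
  margin, primary venation, secondary venation) classified into one of 16
  trait combination types (TCTs), lettered A–P, with assemblage spectra;
* **quantitative traits** — lamina area, length, width, and leaf mass per
  area (LM_A, g/m²) estimated from the petiole-width allometry

  `log10(LM_A) = 3.070 + 0.382 · log10(petiole_width² / leaf_area)`

  with phenology inferred from species-mean LM_A (< 87 g/m² deciduous,
  87–129 intermediate, > 129 evergreen);
* **insect herbivory** — damage frequency (DAM%), damage-type occurrence
  (DTO), observed and rarefied damage-type richness (DTR), per functional
  feeding group, and the herbivory index HI = damaged area / lamina area.
  Rarefaction is analytic and sample-based (leaves as units):

  `E[S_n] = Σ_i [1 − C(N−N_i, n) / C(N, n)]`

  with the exact hypergeometric variance including pairwise co-occurrence
  terms, cross-checked by a Monte-Carlo resampler;
* **missing-data handling** — Bayesian-regression imputation of missing
  LM_A (locality + leaf size as predictors, 10 averaged posterior-draw
  cycles, below-range filter), since petioles are rarely preserved;
* **multivariate structure** — correlation-matrix PCA of five traits with
  per-axis variable contributions, and a five-model GLM suite
  (Gamma/identity for traits and damage extent, binomial/logit for damage
  presence) with stepwise-AIC selection, type-II likelihood-ratio ANOVA,
  and Nagelkerke/Tjur R².

The analysis runs over a nested dataset cascade (all scored leaves →
≥ 70 % preserved → fixed per-site random subsample → cleaned complete
cases → imputation-enlarged modelling set), and every stage is exercised
without any field data by a synthetic-assemblage generator whose two
presets mimic a deciduous-dominated and an evergreen-dominated early
Oligocene lake flora.

## Worked example

`examples/` contains one short script per capability.  For instance
herbivory metrics with standardised richness
(`python examples/03_herbivory_rarefaction.py`):

```
sf-like (4935 leaves):
  DAM% =  3.51   (leaves with >= 1 damage type)
  DTO  =   175   (total leaf x damage-type records)
  DTR  =    13   (distinct damage types)
  DTR rarefied to 400 leaves = 6.30 (SD 1.45; Monte-Carlo check 6.30)
sube-like (1349 leaves):
  DAM% = 13.05   (leaves with >= 1 damage type)
  DTO  =   187   (total leaf x damage-type records)
  DTR  =    13   (distinct damage types)
  DTR rarefied to 400 leaves = 10.20 (SD 1.07; Monte-Carlo check 10.20)
```

Reading: in the evergreen-dominated flora 13.05 % of leaves carry at least
one damage type against 3.51 % in the deciduous-dominated one, and after
standardising both samples to 400 leaves the former still supports the
higher damage-type richness (10.20 vs 6.30 expected types) — raw richness
comparisons would be confounded by the unequal sample sizes.  The
Monte-Carlo column is an independent resampling check of the analytic
expectation.

The imputation + multivariate stage
(`python examples/05_impute_and_multivariate.py`) prints, among others:

```
PCA on 708 leaves: PC1+PC2 explain 84.5% of trait variance
  l/w-ratio contribution to PC2: 89.9%
M4 selected: damaged_area_mm2 ~ leaf_area_mm2 + phenology_modern
```

PC1 is the size/leaf-economics axis and PC2 leaf circularity; the
damaged-area model keeps leaf size and phenology as explanatory variables.

A thin CLI wraps the same calls: `ilta run --preset two-site --seed 1
--out run_dir`, `ilta simulate`, `ilta filter`, `ilta sample`.

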