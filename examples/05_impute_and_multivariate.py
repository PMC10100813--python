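"""Impute missing LM_A, then run the trait PCA and the GLM suite.

Petioles are rarely preserved, so most leaves lack LM_A.  Missing values
for species with enough measured leaves are filled by Bayesian-regression
imputation (locality + leaf size as predictors, 10 averaged cycles),
enlarging the multivariate dataset.  The PCA spans the trait morphospace;
stepwise-AIC GLMs ask which variables explain damaged area and the
herbivory index.
"""

from ilta import (
    ImputationSpec,
    build_dataset4,
    filter_dataset2,
    generate_assemblage,
    impute_lma,
    pca_traits,
    sample_dataset3,
    scenario_presets,
    stepwise_aic,
)
from ilta.lma_impute import imputation_report
from ilta.pipeline import default_model_suite, prepare_model_frame

species, taphonomy = scenario_presets()["two-site"]
d1, _ = generate_assemblage(species, taphonomy,
                            n_leaves={"Sf": 2000, "SuBe": 1700}, seed=1)
d3 = sample_dataset3(filter_dataset2(d1), 400, seed=2)

imputed, diagnostics = impute_lma(d3, ImputationSpec(seed=3))
print("\n".join(imputation_report(diagnostics).splitlines()[2:7]))

d5, _ = build_dataset4(imputed)
frame = prepare_model_frame(d5).dropna(
    subset=["lma_gm2", "leaf_area_mm2", "leaf_width_mm", "leaf_length_mm",
            "length_width_ratio"]
)
pca = pca_traits(frame)
print(
    f"\nPCA on {len(frame)} leaves: PC1+PC2 explain "
    f"{pca.variance_explained[:2].sum():.1f}% of trait variance"
)
print(
    "  l/w-ratio contribution to PC2: "
    f"{pca.contributions.loc['length_width_ratio', 'PC2']:.1f}%"
)

suite = default_model_suite()
damaged = frame[(frame["damaged01"] == 1) & (frame["herbivory_index"] > 0)]
for key in ("M4", "M5"):
    selected = stepwise_aic(suite[key], damaged)
    print(f"{key} selected: {selected.formula.formula}")
# PC1 is the size/economics axis, PC2 leaf circularity; the damage-extent
# models keep leaf size (M4) and the leaf-economics signal (M5).
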