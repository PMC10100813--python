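"""Generate a two-site fossil leaf assemblage and walk the dataset cascade.

The cascade mirrors how a fossil collection is narrowed down for
quantitative work: all scored leaves (Dataset 1), leaves at least 70 %
preserved (Dataset 2), a 400-per-site random measurement subsample
(Dataset 3), and the cleaned complete-case set (Dataset 4).
"""

from ilta import (
    build_dataset4,
    filter_dataset2,
    generate_assemblage,
    sample_dataset3,
    scenario_presets,
)

species, taphonomy = scenario_presets()["two-site"]
d1, _truth = generate_assemblage(
    species, taphonomy, n_leaves={"Sf": 2000, "SuBe": 1700}, seed=42,
)
d2 = filter_dataset2(d1)
d3 = sample_dataset3(d2, n_per_site=400, seed=43)
d4, ledger = build_dataset4(d3)

print(f"Dataset 1 (all scored leaves):        {len(d1)}")
print(f"Dataset 2 (>= 70% preserved):         {len(d2)}")
print(f"Dataset 3 (400-per-site subsample):   {len(d3)}")
print(f"Dataset 4 (clean complete cases):     {len(d4)}")
print(f"  removed: {ledger}")
# Each level is a subset of the previous one; the removal ledger accounts
# for every specimen dropped between Datasets 3 and 4.
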