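"""Classify leaves into trait combination types and compare two floras.

Each leaf's four binary characters (lobation, margin, primary venation,
secondary venation) map to one of 16 letters A-P.  The spectrum of
letters summarises the architectural make-up of an assemblage: a
deciduous-dominated flora is rich in toothed, non-loop-veined TCT F,
an evergreen-dominated one in entire-margined / loop-veined A and E.
"""

from ilta import generate_assemblage, scenario_presets, tct_spectrum
from ilta.tct import TraitQuartet, classify

# classify a single leaf
quartet = TraitQuartet("unlobed", "toothed", "pinnate", "non-looped")
print(f"unlobed/toothed/pinnate/non-looped -> TCT {classify(quartet)}")

for preset in ("sf-like", "sube-like"):
    species, taphonomy = scenario_presets()[preset]
    flora, _ = generate_assemblage(species, taphonomy, n_leaves=2000,
                                   seed=7, name=preset)
    spectrum = tct_spectrum(s.tct_combined for s in flora)
    top = spectrum["percent_total"].sort_values(ascending=False).head(3)
    print(f"\n{preset}: top TCTs (% of all {spectrum.attrs['n_total']} leaves)")
    for letter, pct in top.items():
        print(f"  TCT {letter}: {pct:5.2f}%")
# Percentages are over all leaves including the unclassifiable remainder,
# so a letter's share reads directly as a fraction of the assemblage.
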