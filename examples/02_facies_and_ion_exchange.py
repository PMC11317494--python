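"""Hydrochemical facies, controlling mechanism and ion-exchange direction."""

from hydrochem import fixture_site_means, to_meq
from hydrochem.facies import cai_indices, classify

for s in fixture_site_means():
    bal = to_meq(s)
    f = classify(s, bal)
    c = cai_indices(bal)
    print(f"{s.site_id}: {f.facies_label:11s} Chadha=({f.chadha_x:+.1f}, {f.chadha_y:+.1f}) "
          f"Gibbs={f.gibbs_zone}  CAI-I={c.cai1:+.3f} CAI-II={c.cai2:+.3f} ({c.direction})")

# Every site is Ca-Mg-HCO3 water in the rock-weathering field of the Gibbs
# diagram: chemistry set by carbonate dissolution, not evaporation or rain.
# Negative chloro-alkaline indices mean the water trades its Na/K for Ca/Mg
# held on clays and carbonates (direct ion exchange).
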