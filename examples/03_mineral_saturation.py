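"""Mineral saturation state: which phases this water precipitates or dissolves."""

from hydrochem import fixture_site_means
from hydrochem.saturation import speciate

for s in fixture_site_means():
    r = speciate(s)
    si = r.si
    print(f"{s.site_id}: I={r.ionic_strength:.2e} mol/L  log pCO2={r.log_pco2:+.2f}  "
          f"SI calcite {si['calcite']:+.2f}, dolomite {si['dolomite']:+.2f}, "
          f"gypsum {si['gypsum']:+.2f}, halite {si['halite']:+.2f}")

# SI > 0: the water is supersaturated and tends to precipitate the mineral
# (calcite, aragonite, dolomite here); SI < 0: it can still dissolve it
# (gypsum, anhydrite, halite).  log pCO2 < 0 (around -2.9, i.e. ~3x the
# atmospheric partial pressure but below carbonate saturation) is typical of
# a river degassing CO2 gained from soil respiration.
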