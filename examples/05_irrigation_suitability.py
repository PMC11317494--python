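"""Irrigation suitability: classical sodicity/salinity indices and the IWQI."""

from hydrochem import fixture_site_means, to_meq
from hydrochem.irrigation import irrigation_indices, iwqi_score

for s in fixture_site_means():
    bal = to_meq(s)
    i = irrigation_indices(bal)
    w = iwqi_score(s, bal)
    print(f"{s.site_id}: SAR={i.sar:.3f} Na%={i.na_pct:.1f} SSP={i.ssp:.1f} "
          f"PS={i.ps:.2f} RSC={i.rsc:+.2f}  IWQI={w.score:.1f} ({w.restriction_class} restriction)")

# Low SAR (<10) and Na% (<20) mean no sodicity hazard to soil structure;
# PS < 3 and RSC < 1.25 put every site in the safest salinity and residual-
# carbonate classes.  The class-interpolated IWQI is harsher: dilute water
# (Na and Cl below the scale's best class) scores in the 40-55 band, a
# high-restriction rating driven by the scale's design rather than toxicity.
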