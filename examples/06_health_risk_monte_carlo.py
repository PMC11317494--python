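"""USEPA non-carcinogenic risk: deterministic HQ/HI plus Monte Carlo spread."""

import numpy as np

from hydrochem import fixture_site_means
from hydrochem.risk import McConfig, RISK_ELEMENTS, mc_campaign, risk_assessment

sites = fixture_site_means()
means = {el: float(np.mean([s.conc[el] for s in sites])) for el in RISK_ELEMENTS}

for cohort in ("child", "adult"):
    r = risk_assessment(means, cohort)
    hqs = ", ".join(f"{el} {v:.3f}" for el, v in r.hq.items())
    print(f"{cohort}: HQ = {hqs}; HI = {r.hi:.3f} ({'AT RISK' if r.at_risk else 'below 1'})")

conc = {el: [s.conc[el] for s in sites] for el in RISK_ELEMENTS}
for s in mc_campaign(conc, McConfig(n_iter=10_000, seed=1)):
    print(f"MC {s.element:3s} {s.cohort:5s}: mean HQ {s.mean:.3f} "
          f"[p5 {s.p5:.3f}, p95 {s.p95:.3f}]  P(HQ>1) = {s.prob_hq_gt_1:.4f}")

# A hazard quotient is the ingested dose over the reference dose; values
# below 1 are considered safe.  Children carry ~3.8x the adult dose per
# mg/L (higher intake per kg body weight), so their HI approaches 1 at the
# campaign means while every simulated mean HQ stays below the threshold.
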