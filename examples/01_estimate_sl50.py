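"""Estimate per-element SL50 from a simulated growth series.

Generates a cleared-and-stained-style survey (80 specimens, 8-50 mm SL)
of a 15-element fin whose ray-apparition timing follows a V-shaped
gradient from a central initiation site, then recovers each element's
SL50 — the standard length at which half the specimens have the element —
by logistic regression with a Bonferroni-gated likelihood-ratio test.
"""
from finseq import SimConfig, estimate_sl50_profile, make_sl50_profile, \
    simulate_coding

cfg = SimConfig(seed=1)  # defaults mirror the trout study design
table = simulate_coding(cfg, events=[4])
profile = estimate_sl50_profile(table, "dorsal", 4)
truth = make_sl50_profile(cfg, 4)

print(f"{'element':>8} {'true SL50':>10} {'estimate':>9} {'status':>15}")
for entry, true_val in zip(profile.entries, truth):
    est = f"{entry.sl50:9.3f}" if entry.sl50 is not None else "        -"
    print(f"{entry.element.label:>8} {true_val:10.3f} {est} "
          f"{entry.status:>15}")
print(f"\n{profile.n_elements_tested} elements tested; nominal level "
      f"0.05/{profile.n_elements_tested} per element.")
print("Estimates track the V-shaped truth to within about a millimetre "
      "per element; the smallest SL50 marks the initiation site.")
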