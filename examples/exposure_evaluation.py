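"""Exposure-band arithmetic and mortality odds ratios from count tables.

Works directly from a per-patient band count table (<16 / 16-32 / 32-64 /
64-96 / >96 mg/L) and 2x2 death/survival counts: attainment fractions at
each band edge and unadjusted odds ratios with Woolf confidence intervals
versus therapeutic exposure.
"""

from pipertdm import BAND_LABELS, BAND_ORDER, BandDistribution, odds_ratio_woolf

counts = dict(zip(BAND_ORDER, [1, 18, 72, 66, 22]))
dist = BandDistribution.from_counts(counts)

print(f"n = {dist.n} patients")
for band in BAND_ORDER:
    print(f"  {BAND_LABELS[band]:>6} mg/L: {dist.counts[band]:3d} "
          f"({100 * dist.fractions[band]:.1f}%)")
for edge, label in [(16.0, "100% fT>MIC"), (32.0, "minimum therapeutic"),
                    (64.0, "100% fT>4xMIC"), (96.0, "potentially harmful")]:
    print(f"above {edge:>4.0f} mg/L ({label}): {100 * dist.fraction_above(edge):.1f}%")

# deaths/survivors above 96 mg/L vs inside the therapeutic window
r = odds_ratio_woolf(13, 8, 17, 55)
print(f"\nmortality >96 vs 32-64 mg/L: OR {r.or_value:.3f} "
      f"(95% CI {r.ci_low:.3f}-{r.ci_high:.3f}, p = {r.p_value:.3f})")
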