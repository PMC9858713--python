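"""Construct six-level alert thresholds and classify a predicted OR.

Reproduces the worked classification from a published alert table: a
summer stratum with median OR 1.9162 and tabulated dispersion 3.7221 gives
critical values c_g = exp{median(lnOR) + 0.5 (g-2) SE(lnOR)}; a forecast
OR of 2.4511 falls between c2 and c3, i.e. alert level 3 — under both
readings of the dispersion column (SD of lnOR, or its exponential).
"""

from crossrisk import AlertThresholds, classify, threshold_table_report

for scale in ("log", "or"):
    thr = AlertThresholds.from_or_stats(
        "Northern", "Summer", median_or=1.9162, dispersion=3.7221,
        dispersion_scale=scale,
    )
    c = thr.critical_values
    level = classify(2.4511, thr)
    print(f"dispersion read as {scale!r}: c1..c6 = "
          + ", ".join(f"{v:.3g}" for v in c))
    print(f"  OR 2.4511 -> level {level}")

print("\nBoth readings agree on level 3: the OR lies above c2 = 1.9162 "
      "(the median) but below c3 in either scale.")

table = threshold_table_report(
    [AlertThresholds.from_or_stats("Northern", "Summer", 1.9162, 3.7221, "or")]
)
print("\nThreshold report row (OR-scale columns):")
print(table.round(3).to_string(index=False))
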