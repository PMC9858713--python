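"""Build the matched case-minus-control design matrix for one region.

Each onset contributes one row of exposure differences: case days 0/-1/-3
versus control days exactly one week earlier (-7/-8/-10), with the
control-window temperatures seasonally adjusted by the fitted annual sine
so that slow seasonal drift does not look like a short-term contrast.
"""

from crossrisk import (
    EnvSimConfig,
    EventSimConfig,
    build_design_matrix,
    fit_seasonal_sine,
    northern_covariates,
    simulate_environment,
    simulate_events_study_mode,
)

series = simulate_environment(EnvSimConfig(n_days=730, seed=1))
cov = northern_covariates()
onsets = simulate_events_study_mode(series, cov, EventSimConfig(n_events=50, seed=2))
print(f"{len(onsets)} onset records, e.g.\n{onsets.head(3)}\n")

sine_fits = {v: fit_seasonal_sine(series, v) for v in ("min_temp", "max_temp")}
design = build_design_matrix(onsets, series, cov, sine_fits=sine_fits)
print(f"design: {design.n_events} rows x {len(design.terms)} terms "
      f"({len(design.exclusions)} events excluded for missing history)")
print("terms:", ", ".join(design.terms[:4]), "...")
row = design.frame.iloc[0]
active = [t for t in design.terms if row[t] != 0]
print(f"\nfirst event is in {row['season']}; its nonzero columns are the "
      f"{len(active)} {row['season']} terms:")
print(row[active].astype(float).round(2))
print("A season-crossed term is zero outside the event's own season, so a "
      "Northern-style spec always has at most 6 of 24 entries active per row.")
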