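# crossrisk

Bayesian case-crossover modelling of short-term environmental disease risk,
with six-level odds-ratio alert intervals.

Weather swings and air pollution can trigger acute events (the motivating
application is first attacks of ischemic heart disease) in susceptible
people. Because such events depend heavily on personal confounders that
administrative databases do not record, the case-crossover design compares
each subject with **themself**: exposure near onset (case window, days 0,
−1, −3) against the same subject's exposure exactly one week earlier
(control window, days −7, −8, −10). `crossrisk` implements that design end
to end for daily series of minimum/maximum temperature, average/maximum
relative humidity and ozone, and is aimed at environmental epidemiologists
and health-warning services who want probabilistic, region- and
season-specific risk statements rather than a single point estimate.

## The model

For event *i* with case-minus-control difference vector
*d*<sub>*i*</sub> = (X<sub>*ip*1</sub> − X<sub>*ip*2</sub>)<sub>*p*=1..P</sub>,
the 1:1 matched conditional likelihood is an intercept-free logistic model

P(case on index day) = σ(*d*<sub>*i*</sub>ᵀβ),  σ(u) = 1/(1+e^(−u)),

with independent Normal(0, 100) priors on each β<sub>*p*</sub>. The
posterior is sampled by adaptive component-wise random-walk Metropolis
(default 60,000 iterations, 10,000 burn-in, thinning 10 → exactly 5,000
retained draws); summaries report posterior means, equal-tailed 95%
credible intervals and DIC = 2·mean D(β) − D(mean β). Covariate terms are
season-crossed (one coefficient per season, active only in the event's
season); control-window temperatures are first adjusted by a fitted
365.25-day sinusoid so that slow seasonal drift does not masquerade as a
one-week contrast.

A day's predicted log odds ratio is lnOR = βᵀ*d*. Per region × season, the
six alert levels use critical values

c<sub>*g*</sub> = exp{median(lnOR) + 0.5·(*g*−2)·SD(lnOR)},  *g* = 1..6,

computed over all retained case days in the stratum; a predicted OR gets
the smallest level *g* with OR < c<sub>*g*</sub> (capped at 6), and the
posterior draws turn that into per-level probabilities.

The restricted source data (insurance onset records, weather-bureau and
air-quality series) are replaced by a synthetic module that generates
bounded sinusoid+AR(1) exposure series and events with **known**
coefficients — either exact conditional-likelihood day-pairs (for
parameter-recovery validation) or onset dates from an exp(xᵀβ) hazard (for
end-to-end runs).

## Worked example

```python
from crossrisk import *

series = simulate_environment(EnvSimConfig(n_days=800, seed=3))
spec = CovariateSpec("Northern", (CovariateTerm("min_temp", 0, season_crossed=False),
                                  CovariateTerm("ave_rh", 0, season_crossed=False)))
truth = {"min_temp_lag0": -0.3, "ave_rh_lag0": 0.1}
pairs = simulate_events_pair_mode(series, spec,
                                  EventSimConfig(n_events=500, beta_true=truth, seed=11))
draws = run_mcmc(pairs, PriorSpec(),
                 MCMCSettings(iterations=20_000, burn_in=5_000, thinning=5, seed=42))
print(summarize(draws, pairs).table.round(3))
```

prints

```
                mean  ci_2.5  ci_97.5      ess
term
min_temp_lag0 -0.264  -0.302   -0.227  2115.931
ave_rh_lag0    0.094   0.079    0.110  2505.717
```

i.e. from 2,000 matched pairs the posterior recovers the generating
coefficients (−0.3, +0.1) within its credible intervals: each 1 °C higher
minimum temperature on the index day lowers the odds of an event by about
23% (e^−0.264 ≈ 0.77) in this synthetic world. Alert construction from a
published-style summary row:

```python
thr = AlertThresholds.from_or_stats("Northern", "Summer",
                                    median_or=1.9162, dispersion=3.7221,
                                    dispersion_scale="or")
print(thr.critical_values.round(3))   # [ 0.993  1.916  3.697  7.132 13.76  26.547]
print(classify(2.4511, thr))          # 3
```

A forecast OR of 2.4511 lies between c2 and c3 → a level-3 alert, and the
same level results if the dispersion column is read on the log-OR scale.

`examples/` contains one short narrative script per capability
(simulation, design matrix, Bayesian fit, alert construction, full
pipeline); each prints what it computes and what the numbers mean.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the tracked headline quantity from scratch by running the
package: it rebuilds the six-level alert thresholds from the published
Northern-Taiwan summer statistics under both admissible readings of the
dispersion column, classifies the predicted OR of 2.4511 against them,
checks the readings agree, and writes the resulting level to the JSON file.
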