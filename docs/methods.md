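# Methods

## Design and estimand

The package analyses a 1:1 self-matched case-crossover design. For each
event, exposures are read on the case days 0, −1 and −3 relative to onset
and on the control days −7, −8 and −10 — each control day exactly one week
before its case day, so day-of-week effects cancel and the subject's
time-invariant confounders are controlled by construction. The estimand is
the vector β of log odds ratios per unit of exposure difference in the
matched conditional likelihood

P(y_i = 1 | d_i, β) = σ(d_iᵀβ),

where d_i is the case-minus-control difference vector and y_i = 1 when the
event fell on the index day. Although the generative story can be written
as an unconditional Bernoulli regression on raw exposures, only the
conditional (differenced, intercept-free) form identifies the within-pair
contrast of a case-crossover study, and that is what the package fits
throughout.

### Covariate expansion

Base terms are (variable, lag) pairs; a season-crossed term expands into
four columns (Spring, Summer, Autumn, Winter in that fixed order), nonzero
only in the event's season, where the season of an event is the season of
its onset day and applies to all its lagged terms. Column order is the
declared base-term order with seasons nested inside, so coefficient
indexing is reproducible. The three bundled regional presets expand to 24
(Northern-style: six crossed terms), 25 (Central-Southern-style: the same
six plus ozone at day 0, not season-crossed) and 20 columns
(Eastern-style: five crossed terms).

Season month boundaries are a configuration choice (no single convention
is universal); the default Mar–May / Jun–Aug / Sep–Nov / Dec–Feb is the
standard meteorological convention for a subtropical setting and is
overridable via `SeasonMap`.

### Seasonal sine adjustment

Temperature has a strong annual cycle, so a one-week case/control offset
carries a predictable seasonal drift that would bias the differences. The
package fits value(d) = a0 + a1·sin(ωd) + a2·cos(ωd) with ω fixed at
2π/365.25 per day by ordinary least squares (the sin+cos basis is the
linear form of amplitude+phase, hence closed-form and exact on pure
sinusoids) and shifts each control-window temperature by
fitted(case day) − fitted(control day). On a purely sinusoidal series the
adjusted differences vanish identically; this is asserted to 1e−9 in the
tests. The adjustment is applied to `min_temp` and `max_temp` by default —
humidity and ozone enter raw — and the variable list is configurable. The
fit is to the daily series; for the one-week difference this is equivalent
to fitting smoothed weekly temperature under pure seasonality, so the
choice is immaterial exactly where the adjustment matters. Events missing
any required exposure day are excluded and logged, never imputed.

## Prior, sampler and summaries

Each coefficient gets an independent Normal prior with mean 0 and variance
100 (SD 10) — effectively flat over any plausible log odds ratio per unit
of a meteorological variable, while remaining proper.

The sampler is component-wise random-walk Metropolis: one iteration sweeps
all coordinates, proposing Gaussian steps with per-coordinate scales. The
schedule (60,000 iterations, 10,000 burn-in, thinning 10) retains exactly
(60000 − 10000)/10 = 5000 draws by default. Scales adapt multiplicatively
every 50 sweeps during burn-in toward a 0.44 acceptance rate (the
classical one-dimensional random-walk optimum) and are frozen afterwards,
so the post-burn-in chain satisfies detailed balance for the exact
posterior. The likelihood is evaluated incrementally (only the proposed
coordinate's contribution to the linear predictor changes), with
`logaddexp` guards keeping it finite for |d·β| up to and beyond 700.
Initialisation is at β = 0 by default for determinism; all randomness
flows from a single seeded generator per run, so fixed seed + inputs give
bit-identical artifacts.

Correctness of the sampler is tested against an independent dense
grid-quadrature posterior in a one-coefficient model (200 pairs, 50,000
iterations): the retained-draw histogram must be within total variation
0.02 of the quadrature posterior. The binning for that comparison — 12
equal-width bins over the quadrature grid's ±4.5 posterior-SD support —
was fixed before measurement; typical observed TV is 0.007–0.015.

Summaries are per-term posterior means and equal-tailed 2.5%/97.5%
quantiles (the convention when only "95% credible interval" is specified),
an effective sample size from Geyer's initial-positive-sequence
autocorrelation estimator, and DIC computed from the conditional
deviance D(β) = −2 log L as DIC = 2·mean D − D(mean β) (Spiegelhalter's
pD = mean D − D(mean β) form). A frequentist cross-check `fit_mle`
maximises the same likelihood by damped Newton-Raphson with the analytic
Hessian; complete separation is flagged rather than fatal. In tests the
MLE is compared against an intercept-free statsmodels logistic fit, and
the posterior mean under a variance-10⁶ prior against the MLE.

## Alert intervals

For each region × season stratum the lnOR values of all retained case
days (predicted with the posterior-mean β) give m = median(lnOR) and
s = SD(lnOR, sample), and the critical values c_g = exp{m + 0.5(g−2)s},
g = 1..6 — a geometric progression with ratio exp(0.5 s) anchored at
c2 = exp(m). Classification assigns the smallest g with OR < c_g, capping
at 6, i.e. level g occupies [c_{g−1}, c_g) with c0 = 0; this is the only
interval convention consistent with the published worked example (an OR of
2.4511 between c2 = 1.9162 and c3 must yield level 3). Published alert
tables are ambiguous about whether the tabulated dispersion is s itself or
exp(s); both readings are supported (`dispersion_scale="log"|"or"`), both
yield level 3 in the worked example, and the report writer emits OR-scale
columns by default (`raw_log_stats` switches to log-scale). The role of c6
as an open top is resolved by the cap-at-6 convention. Posterior level
probabilities classify every retained draw's OR and report per-level
relative frequencies.

## Synthetic data: what it emulates and what it does not

Each exposure variable is mean + amplitude·sin(2πd/365.25 + phase) + AR(1)
noise (stationary start). Defaults describe a subtropical coastal climate:
minimum temperature 19 °C ± 5.5 °C annual swing peaking in mid July with
AR coefficient 0.7 and innovation SD 1.5 °C; a diurnal spread of
6.5 ± 1.5 °C (floored at 1 °C) added to give the maximum; average RH 77%
(amplitude 3, AR 0.5, SD 4), maximum RH a floored positive 15 ± 4-point
spread above it capped at 100%; ozone 30 ± 8 units (AR 0.6, SD 6), clipped
at 0. Humidity is generated unbounded then clipped to [0, 100]; clipping
events are rare under defaults and logged. The spread construction is used
for both temperature and humidity so the ordering invariants hold by
construction rather than by rejection.

Pair mode inverts the conditional likelihood exactly — draw an index day,
form d as the design builder would, label the event "index day" with
probability σ(dᵀβ_true) — so it is the statistically exact surface for
parameter recovery: with n = 2000 pairs and β_true = (−0.3, 0.1) the
posterior means land within ±0.1 of truth and 95% credible intervals cover
each coefficient in ≥ 42 of 50 replicates (observed 44 and 47). Study mode
samples onset dates with probability ∝ exp(x_dayᵀβ_true) over the timeline
and exercises the whole pipeline; because the hazard fixes the seasonal
distribution of onsets, per-season event counts are honoured in pair mode
only, and study mode draws 4×n_events over the full timeline. Onsets are
otherwise uniform (the null model), a configurable default.

What a green test does **not** establish: the generator has no spatial
correlation between regions, no day-of-week or holiday structure in
onsets, no measurement error or station heterogeneity in exposures, no
long-term pollution trends, and no subject-level covariates — so passing
recovery tests validate the estimator and pipeline, not any epidemiologic
claim about real data.

## Numerical and degenerate-input choices

* Retained-draw count is floor((iterations − burn-in)/thinning), exact by
  construction of the retention rule.
* An all-zero design column triggers a warning and its posterior equals
  the prior; an empty design or nonpositive OR raises.
* Alert thresholds need ≥ 2 lnOR values (sample SD undefined below that);
  zero spread collapses all six critical values to the median OR.
* Floating-point artifacts are written with 6 significant digits so
  reruns are byte-stable; determinism tests compare file hashes.
* Date arithmetic is in whole calendar days; day 0 is the onset day.

## Limitations

Single-referent (1:1) matching only — time-stratified or bidirectional
referent schemes and 1:M matching are out of scope, as are real forecast
ingestion, record-linkage of onset data, and economic evaluation of
alerts. DIC is reported but no model-selection machinery is built on it.
Regions are always fitted independently; there is no hierarchical pooling
across regions or seasons.
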