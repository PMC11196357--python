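# Methods

This note documents the statistical procedures implemented in
`emafeedback`, the assumptions behind them, the defaults that matter, and
what the synthetic-data tests do and do not demonstrate.

## Study design model

The pipeline assumes a prompt-based EMA protocol: four daily survey blocks
(morning, noon, afternoon, evening) at semi-random times within fixed clock
windows, plus one weekly survey attached to the evening window of a fixed
weekday (default Sunday). For a window of `D` days containing `W` weekly
days the schedule holds exactly `4D + W` prompts; an 85-day window with 12
Sundays gives 352. Semi-random send times are drawn uniformly within each
slot window from a seeded generator; they affect display only, never
counts. The default slot windows (08:00–11:00, 11:30–14:30, 15:00–18:00,
18:30–21:30) are a plausible waking-hours layout and are configurable —
every verifiable quantity (prompt counts, compliance) is independent of
them.

A prompt counts as *completed* when at least one response record exists for
its (date, slot), regardless of how many items were answered; this matches
a prompt-level completion heatmap and makes compliance invariant to the
number of items per block. Percentages round half-up (204/352 → 58,
236/352 → 67). The cohort completion histogram uses fixed width-5 bins with
left-closed edges; 100% falls in the terminal bin, so counts always sum to
the number of participants.

## Data model and validation

Responses travel in one long CSV dialect (comma-separated, UTF-8, ISO 8601
timestamps with zone) with columns
`participant_key, date, slot, timestamp, variable, value`. Validation is
report-based, never raising on content: unknown variables, out-of-scale
Likert values, unknown categories, and duplicate
(participant, date, slot, variable) records are listed individually. The
duplicate rule keeps the earliest timestamp (the in-the-moment submission),
ties broken by file order. Timestamps are stored zone-aware; dates are
taken as written since prompt slots are local-time concepts.

## Descriptives

Item means are arithmetic means over observed values only — no imputation
enters any descriptive quantity, so summaries always show raw data.
Scatter displays jitter points uniformly within ±0.25 scale units; jitter
exists only in display copies. Relative frequencies include zero-count
categories. Peak-affect search maximizes the mean of the positive-affect
items over (date, slot) prompts; best-week/worst-week recap uses fixed
calendar weeks (default Monday–Sunday, the weekly survey closing the week)
and requires at least 4 observations for a week to qualify, preventing a
single stray answer from becoming the "best week". All ties break toward
earlier dates (then earlier slots), making reports deterministic.

## LOESS trend

The smoother is the classical locally estimated scatterplot smoother: for
each evaluation point `x0`, take the `k = ⌈span·n⌉` nearest observations
in time (all points tied with the k-th distance included), weight them by
the tricube kernel `w_i = (1 − (d_i/d_max)³)³`, and fit a degree-1
weighted least-squares line whose value at `x0` is the fitted trend. The
span defaults to 0.5 — a middle setting that preserves multi-week trends
while removing prompt-to-prompt noise — and is exposed in configuration
because no single span suits every participant. Degree is fixed at 1:
local linear fits are robust on short idiographic series and reproduce
globally linear data exactly, which the tests exploit as a closed-form
check. No robustness (iterative reweighting) passes are performed, keeping
the estimator a deterministic single pass. Series with fewer than 20
observations (configurable) are gated out and displayed as raw
scatterplots.

Degenerate cases: if all `k` nearest neighbours sit exactly at `x0`, the
fit degrades to their mean; non-finite observations are dropped before
fitting.

## Kalman imputation

Missing prompts are filled per variable, prior to network estimation only,
with the posterior mean of a local-level Gaussian state-space model: a
random-walk latent level observed with noise,

    mu_t = mu_{t−1} + w_t,  w ~ N(0, q);   y_t = mu_t + v_t,  v ~ N(0, r).

The two variances are fitted by maximum likelihood (L-BFGS-B on
log-variances, bounded to (1e−8, 1e3) × sample variance) from the fixed
deterministic start r₀ = s²/2, q₀ = s²/10, making fits reproducible. The
initial level is the observed mean with a large variance (10⁴ × s²,
effectively diffuse). Missing time points skip the filter's update step;
the Rauch–Tung–Striebel smoother then interpolates through gaps using both
past and future information. Imputed values are clipped to the item's scale
bounds; observed entries are returned bitwise unchanged. At least 5
observed values are required.

The local level is deliberately the minimal model — no trend or seasonal
state. It treats the series as a slowly drifting mean plus noise, which is
adequate for filling isolated prompt gaps in Likert series. It will
under-serve strongly periodic series (e.g., a pronounced morning/evening
cycle); this is a known limitation and the model choice is explicit in the
module so a richer state-space form can replace it.

## Lag-1 VAR networks

Per participant and mode, the design stacks (X_{t−1}, X_t) pairs. The
daily design pairs only consecutive slots within the same calendar day
(morning→noon, noon→afternoon, afternoon→evening): the overnight gap is
about 11 hours, not 4, and including it would mix two different lag
estimands. The evening design pairs evenings of calendar days exactly one
day apart. At least 30 pairs are required.

Estimation proceeds in two regularized stages on variables standardized to
mean 0, variance 1 over the used rows (partial correlations are
scale-free, ℓ1 penalties are not):

1. **Temporal stage.** Each outcome is lasso-regressed on all lag-1
   predictors over 50 log-spaced penalties from λ_max (the smallest
   penalty zeroing every coefficient) down to 0.01·λ_max. Each distinct
   active set is refit by OLS to de-bias it, and the extended BIC
   `n log(RSS/n) + k log n + 2γ k log p` selects the model (γ = 0.5, the
   standard conservative choice). Rows of B come from the refits.
2. **Contemporaneous stage.** The graphical lasso runs on the residual
   covariance over an analogous 50-point grid; EBIC for Gaussian graphical
   models (`−2ℓ + E log n + 4γ E log p`, E = number of edges) selects the
   precision matrix K.

The reported network is ω_ij = −κ_ij/√(κ_ii κ_jj) with a zero diagonal;
entries below 1e−8 count as absent edges. The temporal matrix B is
estimated and retained but not displayed — directed lag-1 networks are
deliberately out of the report's scope. Networks are computed only for
participants who completed *strictly more than* 50% of the mode's relevant
surveys (all daily prompts for the daily network, evening prompts for the
evening one), and on the k = 6 candidate items whose distributions are
most normal for that individual (lowest |skewness| + |excess kurtosis|,
ties alphabetical).

The cohort plausibility statistic pools all nonzero edges across a set of
networks, classifies each by its endpoints (NA–NA, PA–PA, PA–NA), and
reports the proportion whose sign deviates from expectation (positive
within classes, negative across). Only edges between classified affect
items are counted.

## Synthetic cohorts

The generator emulates the assumed protocol: six daily affect items driven
by a joint latent VAR(1) on the daily prompt grid; morning, evening, and
weekly Likert items on independent AR(1) latents (φ = 0.4); categorical
context items i.i.d. per prompt. Latents are standardized by their
stationary variances (discrete Lyapunov solution) and discretized at fixed
symmetric thresholds (−1.5, −0.9, −0.3, 0.3, 0.9, 1.5) into 1–7 responses,
keeping latent moments interpretable. The default innovation precision has
off-diagonal −0.3 within each affect block and +0.1 across blocks —
partial correlations of +0.3 within and −0.1 across — i.e., exactly the
sign structure the plausibility check expects; the default temporal matrix
is diagonal with φ = 0.3.

Missingness is participant-level MCAR by default: each participant draws a
completion fraction from N(0.58, 0.20²) clipped to [0.01, 0.99] — a cohort
averaging 58% compliance with a 1%–99% range — and prompts are kept
Bernoulli-wise. An `evening_bias` parameter subtracts from the evening
keep-probability to create slot-dependent (MAR) missingness for
stress-testing. Every participant is an integer-indexed substream of the
master seed, so cohorts are reproducible participant-by-participant across
platforms.

What the generator does *not* emulate: context-dependent (NMAR)
missingness tied to the latent state, response styles (scale-end pile-ups,
careless responding), time-of-day mean structure, weekday/weekend effects,
and drift in compliance over the study. Passing tests therefore
demonstrate that the pipeline recovers the structures it assumes under
idealized sampling — not that those structures hold in any real cohort.

## Verification strategy and problem sizes

Each numerical component is checked against an independent construction:
LOESS against a per-point normal-equations WLS oracle (100 random
instances, agreement to 1e−8); the Kalman smoother against naive
forward-backward recursions and against an external state-space
implementation with known initialization; imputation accuracy against
last-observation-carried-forward on AR(1) simulations (100 replicates,
20% gaps); network estimation against its own construction invariants
(symmetry, |ω| < 1, positive-definite K), a two-variable
innovation-correlation recovery design, and a 50-replicate true-null
calibration at n = 500 where ≥ 90% of fits must return an empty edge set.
The end-to-end surface is a 100-participant cohort with 200 daily prompts
each under the default completion model: pooled daily-network edge-sign
deviations must stay at or below 10% per class (measured: well under 1%).
These problem sizes keep the full suite and the acceptance script to a few
minutes on a single CPU while leaving each check statistically
comfortable. Daily-mode networks are pooled for that check because the
generator's VAR(1) truth holds exactly on the within-day lag; evening
designs reuse daily items at a 24-hour lag where the generator's implied
contemporaneous structure is only approximate.

## Reports

Bundles are deterministic functions of (data, configuration): section
texts come from a message catalog keyed by section id (English shipped,
locales pluggable at run time), figures are rebuilt from the data on each
run, and any stage failure downgrades only its own section to an
explanatory text. Rendering produces one self-contained HTML file plus PNG
figures per participant, with filenames derived solely from the
pseudonymous key. CSV artifacts and manifest texts are byte-stable under a
fixed seed; PNG bytes are not compared (figure determinism is checked
through the underlying data tables).
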