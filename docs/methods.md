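# Methods

This note records the statistical procedures `surrokit` implements, the
conventions and numerical choices behind them, what the synthetic trial
generator does and does not emulate, and the known limitations.

## 1. Pseudo-IPD reconstruction from digitized curves

Inputs are the digitized coordinates (t_k, S_k) of a published Kaplan–Meier
curve, the numbers-at-risk table {(T_j, N_j)} with T_0 = 0 and N_0 = n, and
optionally the published total event count. Digitized survival values carry
pixel noise, so readers clip them to [0, 1] and project onto non-increasing
sequences by decreasing isotonic least squares (pool-adjacent-violators)
rather than rejecting the file.

Within each risk interval [T_j, T_{j+1}) the reconstruction maintains the
running at-risk count n, the reconstructed KM value Ŝ, and a fractional
event carry. At each digitized step the event count is
d_k = round(n·(1 − S_k/Ŝ) + carry), clamped to [0, n], with the rounding
residual carried to the next step so that integer conservation holds.
Censorings are placed at the deterministic positions
T_j + (i − ½)/c · (T_{j+1} − T_j), i = 1..c — a fixed stand-in for "uniform
over the interval" that keeps reconstruction free of random state — and the
count c is scanned until the implied at-risk count at T_{j+1} equals N_{j+1}
exactly. Two rounding pathologies are handled explicitly:

- event roundings interact with censoring positions, so the implied at-risk
  count is not strictly monotone in c and can skip the target by one; the
  residual is then settled with censorings placed after every step of the
  interval, which cannot disturb event counts;
- digitization noise can make the implied events overshoot the published
  count even with c = 0; the integer rounding of d_k is free to go the other
  way, so trailing events in the interval are trimmed and the running KM
  value re-anchored to the digitized curve.

Beyond the last risk-table entry no censoring is assumed and events continue
to be derived from the curve steps; when a published total event count is
available the residual is reconciled against it (excess implied events
become censorings at the same times, missing events are added at the last
digitized time). Survivors are censored at the end of the digitized span.
Ties between an event and a censoring at the same time are resolved
events-first, the standard KM convention.

The procedure is deterministic: identical input gives identical output.
Fidelity is validated by re-estimating the KM curve from the reconstruction;
the package's acceptance threshold is a sup-norm of 0.02 over the digitized
point times on noiseless fixtures (the source analyses only describe visual
inspection, so the tolerance is this artifact's own). Exact recovery of
event times and counts is attainable only when censorings do not interleave
with events inside a risk interval (e.g. administrative cutoff without
staggered entry); with staggered accrual the deterministic placement can
shift individual event roundings, and fidelity is then bounded rather than
exact — the same behaviour the published algorithm exhibits.

## 2. Endpoint statistics

The product-limit estimator is computed in-package (pooling needs its
per-interval Greenwood increments and at-risk counts); lifelines serves as
an independent cross-check in the test suite. Conventions:

- Quantile at event fraction q: the first event time with Ŝ ≤ 1 − q (infimum
  crossing, weak inequality), `None` when the curve never crosses. CIs
  invert the pointwise complementary log-log band (Brookmeyer–Crowley
  style): the lower survival band crosses the threshold earlier and yields
  the lower limit.
- RMST(τ): exact step-function area on [0, τ]; variance
  Σ_{t_k<τ} A_k² d_k/(n_k(n_k − d_k)) with A_k the area beyond t_k; normal
  CI. τ must lie within observed follow-up unless `allow_extend=True`
  carries the last Ŝ forward — silent extrapolation would be misleading.
- Survival rate at t: step lookup with a cloglog CI.
- All CIs are 95% two-sided throughout.

## 3. Random-effects pooled survival curves

Arms are pooled on a common grid (monthly by default) from 0 to the shortest
arm's follow-up. Per interval, each arm contributes its conditional survival
p_i = Ŝ_i(g_{j+1})/Ŝ_i(g_j), transformed to θ_i = log(−log p_i); its
variance is the arm's Greenwood increment over the interval, delta-scaled by
1/(log p_i)². Intervals in which an arm has no events receive a half-event
continuity floor 0.5/(n_r(n_r − ½)) on the log-p scale so the arm keeps a
finite weight; conditional survivals are clipped to [10⁻⁶, 1 − 10⁻⁶] before
the transform, and an interval in which every arm is flat contributes a
pooled conditional survival of exactly 1. The θ_i are pooled per interval by
DerSimonian–Laird (method-of-moments τ², truncated at zero; inverse-variance
random-effects weights), the pooled curve is the cumulative product of the
back-transformed conditionals, and pointwise CIs accumulate the pooled
interval variances on the log-survival scale. Pooled quantiles interpolate
the grid curve linearly; their CIs are the crossing times of the band.

I² = max(0, (Q − df)/Q)·100 is computed per interval. A single summary I²
per endpoint is reported by convention at the interval containing the pooled
median (the source analyses attach one I² to each pooled median without
stating the mapping; this is the package's convention, falling back to the
last interval when the median is not reached). Arms, not trials, are the
pooling unit when a trial contributes several arms.

## 4. Proportional-hazards diagnostics between PFS and OS

The two endpoints of one arm are stacked with a binary endpoint indicator
and compared by a Cox model for that single covariate. The same patient
appears in both groups with no within-patient correlation adjustment — a
deliberate mirror of the pragmatic PFS-vs-OS comparison, listed under
limitations. The partial likelihood uses Breslow tie handling (reconstructed
IPD is heavily tied at digitized step times) and is maximized by Newton
iteration (|Δβ| < 10⁻⁸, ≤ 50 iterations); a brute-force likelihood grid and
lifelines are the oracles in tests.

Proportionality is tested with the Grambsch–Therneau scaled-Schoenfeld
statistic, implemented as the score test for the coefficient of the
covariate-by-g(t) interaction evaluated at the PH fit; for a single
covariate the two formulations coincide. The default time scaling is the
KM-based g(t) = 1 − Ŝ(t−) of the stacked sample, robust to the censoring
pattern. When p < 0.05, time-dependent models with effect β₀ + β₁ g(t) are
fit for g ∈ {t, log t, 1{t ≥ 6 mo}} — the log transform covers smoothly
monotone HR(t), the 6-month step the delayed-separation pattern typical of
immunotherapy — and the best model, the PH model included as the
one-parameter candidate, is chosen by AIC = 2k − 2ℓ. HR(t) is emitted
monthly for the chosen model. The candidate set and the KM time scaling are
this package's choices; the source analyses name neither.

## 5. Surrogacy meta-regression

R² is the squared sample-size-weighted Pearson correlation,
(Σw·dx·dy)²/(Σw·dx²·Σw·dy²) with deviations about weighted means — exactly
the R² of the weighted least-squares fit of the OS statistic on the PFS
statistic. Weights are arm sample sizes, not inverse variances. The default
CI is the Olkin–Finn large-sample Wald interval
R² ± z·sqrt(4R²(1 − R²)²(n − 2)²/((n² − 1)(n + 3))), deliberately not
truncated at 0 or 1 (weak associations then show negative lower bounds, as
the published intervals do; on the packaged tables this interval reproduces
the published CIs exactly). A percentile bootstrap over arms (weights
carried, 2000 replicates, seeded) is available as a sensitivity method.

Arms missing either statistic of a pair — unreported, or a quantile the
curve never reached — are excluded pairwise, never imputed; strata with
fewer than 3 usable arms are skipped with a logged reason, and inclusion
lists are logged for audit. Subgroup interaction p-values come from the WLS
fit of y on {x, group, x·group} (two-sided t-test on the interaction term);
a subgroup split needs at least 2 arms per group. Arms treating mixed
treatment lines are excluded from first-vs-second splits; the follow-up
split uses a configurable cutoff (default 24 months — the source analyses
do not state one). ORR surrogacy regresses the OS rate at end of follow-up
(taken from the arm record when reported, else the last observed time) on
the ORR.

## 6. Synthetic trial generator

Each patient follows a three-state illness–death process with transition
hazards h_prog (progression), h_death_pre (death before progression) and
h_death_post (death after progression, clock restarting at progression).
PFS is the first transition out of the initial state, so PFS ≤ OS for every
patient by construction. Transitions are exponential by default — giving
closed-form or one-dimensional-numeric truth for every endpoint statistic —
with per-transition Weibull shapes available solely to create
non-proportional hazards for diagnostic tests. Censoring is uniform accrual
over `accrual_mo` plus an administrative cutoff, no dropout, so independent
censoring holds exactly. Trial-level heterogeneity is a bivariate-normal
pair of log-hazard shifts per trial: the PFS shift scales h_prog and
h_death_pre, the OS shift scales h_death_post, and their correlation ρ is
the dial that induces trial-level surrogacy. A single global seed drives
per-trial substreams with fixed offsets, so output is reproducible and
order-independent.

Defaults (per month): h_prog = 0.30, h_death_pre = 0.01, h_death_post =
0.08; trial-effect SDs 0.25 (PFS) and 0.40 (OS) with ρ = 0.7; 24 trials of
235 patients accrued over 12 months with a 30-month cutoff. These emulate
second-line systemic-therapy trials in advanced hepatocellular carcinoma —
median PFS ≈ 2.2 months, median OS ≈ 12 months, between-trial spread of a
similar magnitude to the published trial sets — and deliberately make
post-progression survival dominate OS. The latter matters because the
illness–death structure couples the endpoints mechanically: the progression
clock is part of OS, so even at ρ = 0 the trial-level R² between PFS and OS
statistics does not vanish exactly. With these rates the residual
correlation is small (mean estimated R² ≈ 0.1 at ρ = 0, including the
~1/(k−1) small-sample bias of R² with k = 20 trials), and the mapping from
ρ² to the recovered trial-level R² is monotone and close to the identity
(≈ 0.58 at ρ² = 0.5, ≈ 0.85 at ρ² = 0.9, attenuation from within-trial
estimation noise).

What the generator does not emulate: treatment crossover, post-progression
therapy sequencing, dependent censoring or dropout, competing mortality from
hepatic decompensation, between-arm treatment effects within a trial, or
reporting artifacts other than grid-sampling-plus-rounding digitization
(the digitizer also never records exactly zero while the true curve is
positive, mirroring a curve still visibly above the axis). Passing tests on
synthetic data therefore demonstrate the correctness and calibration of the
machinery under an idealized trial process, not robustness to those
real-data confounders.

## 7. Problem sizes used in checks

The automated checks run at sizes chosen to keep Monte-Carlo error well
below the asserted tolerances: n = 10,000 for single-arm consistency
oracles (sup-norm 0.02, RMST 0.05), n = 5,000/arm for pooled-median
recovery (±0.3 months), 200 replicates of n = 500/group for the size and
power of the Schoenfeld test, and 100 replicates of 20 trials × 500
patients for trial-level R² recovery (±0.15). The reconstruction round trip
uses n = 200 with a quarterly risk table and 4-decimal digitization.

## 8. Known limitations

- Arm-level surrogacy only; individual-level surrogacy (Kendall's τ, copula
  models) is out of scope because reconstructed PFS and OS records cannot be
  linked within patients.
- The stacked PFS-vs-OS Cox comparison ignores within-patient correlation;
  its p-values are calibrated for the stacked-sample null, as verified by
  simulation, but are not a substitute for a paired analysis.
- The Wald R² interval is a large-sample approximation used with as few as
  7 arms; the bootstrap alternative is provided for sensitivity.
- Reconstruction fidelity is bounded, not exact, whenever censoring
  interleaves with events inside a risk interval (see §1).
- Weighted R² values recomputed from published rounded tables inherit the
  input rounding; two-decimal agreement is expected for the RMST pairs but
  the Q1 pair can differ by up to ±0.01.
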