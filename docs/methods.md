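# Methods notes

This note records the modelling conventions, default parameters, and the
design choices made where more than one reasonable construction existed.
Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Data model and screening

A session log is a table of trial events — user, session, 1-based trial
index, learn/test flag, UTC timestamp, optional integer UTC offset,
correctness (test trials only), and seconds elapsed since session start.
Within a session, trial indices are contiguous from 1 and elapsed time is
non-decreasing; the reader enforces both and rejects files with
line-numbered diagnostics. The CSV dialect is UTF-8, comma-separated,
ISO 8601 timestamps with trailing `Z`, `true`/`false`/empty correctness;
writing is canonical, so write∘read is byte-stable.

Local clock time is real-valued hours in [0, 24). `mode="none"` uses the
UTC clock unchanged (the convention for a cohort without timezone
metadata, and for a direct replication that must stay comparable to it);
`mode="per_user_offset"` adds each user's integer offset modulo 24.
Half-hour bins use the half-open convention [k·0.5, (k+1)·0.5).

Screening defaults — drop sessions with fewer than 5 test trials,
sessions longer than 6 hours, then users with fewer than 2 remaining
sessions — are deliberately conservative stand-ins, not canonical: the
screening rules used on the original cohorts were never published. All
thresholds are configurable, the order (trial → session → user) is
fixed, and user-level counts are taken after session removal, which
makes screening idempotent.

## Synthetic generator

The generator emulates the structure the analyses assume, at
user-configurable scale:

- **Session counts** per user are negative binomial (Poisson when the
  requested SD does not exceed the mean), clipped to ≥ 1. The cohort-2
  preset uses mean 16.81, SD 15.71.
- **Session lengths** are a gamma–Poisson mixture (negative binomial
  with gamma shape 2) whose mean is modulated multiplicatively by a
  diurnal harmonic; the preset's analytic expected length is calibrated
  to 58.63 trials, ≈ 16.8 minutes at 17.2 s/trial. No distributional
  family for counts or lengths is claimed by the source descriptives;
  over-dispersed families are this package's documented convention.
- **Accuracy** is additive on the probability scale — quadratic fatigue
  curve in trial order, an early-session difficulty handicap
  (`difficulty_gradient · exp(−(k−1)/3)` over roughly the first 10 test
  trials, mimicking harder items being scheduled first), a session-level
  diurnal term, and per-user intercept/slope effects — then clamped to
  [0.01, 0.99] before Bernoulli sampling. The probability (not logit)
  scale is used because every downstream model is linear in accuracy, so
  recovery targets live on the scale the fits report.
- **Start times** are drawn from the 48-bin normalization of a harmonic
  login intensity floored at zero; the preset peaks late in the evening
  (≈ 20:30–21:00) with a deep night trough.
- The preset fatigue curve is built from its scientific anchors: peak at
  trial 75 and a 5% latent drop by trial 150 (β2 = −0.05/75²,
  β1 = −2·β2·75, β0 = 0.80). The diurnal accuracy term has a 1%
  peak-to-trough range peaking at 14:00. UTC offsets span −9..−5.

A single seeded `numpy` generator drives all sampling in a fixed order
(users, then sessions, then trials), so logs are bit-reproducible. The
truth record stores the config, per-user effects and per-session latents.

What the generator does **not** emulate: item-level difficulty structure
beyond the early-session handicap, induced correlation between a user's
preferred study hour and their ability, scheduling-algorithm dynamics,
or day-to-day nonstationarity. Passing recovery tests therefore show
that the estimators recover the stated structure when it is present —
not that real logs contain no further confounds (the time-of-day
analyses in particular do not control for user-level behavior).

The dedicated recovery preset (`make_recovery_config`) keeps the same
latent quadratic but switches the difficulty handicap and diurnal term
off — so the latent curve *is* the estimand — and uses 6 sessions/user
at base length 90 so the smoothed bins cover the region around the
vertex. With the handicap on, early bins are depressed and the fitted
peak shifts slightly later; the estimate is then conservative by
construction, which the full preset's demo numbers illustrate.

## Within-session fatigue

Five consecutive test trials form one bin (trailing partial bins are
dropped to keep bin variance homogeneous; configurable). Bins span learn-
trial gaps — they count test trials only while the axis value keeps the
original trial indices — a convention, since the alternative (resetting
at gaps) is equally defensible. The elapsed-time axis uses minutes from
session start at the bin mean.

Mixed models use a random intercept and random **linear** slope per
group only; the quadratic term is fixed-effect-only, because richer
random structures routinely fail to converge on data of this shape.
Estimation is maximum likelihood (not REML) so AIC is comparable across
fixed-effect forms; `k` counts fixed effects + 3 covariance parameters +
the residual variance. The optimizer chain is lbfgs → cg → Powell:
variance components near zero put the MLE on the boundary, where
gradient methods stall but Powell converges. Non-convergence is reported
honestly in the returned fit object; nothing falls back silently.

Noise-free inputs (the exact-recovery tests) make the mixed-model
likelihood degenerate (residual variance → 0), so when the fixed
polynomial interpolates the data to machine precision the fitter returns
the exact least-squares solution with a flagged message, infinite
log-likelihood and −∞ AIC.

## Diurnal regression and WAIC

The harmonic basis is sin/cos pairs (linear in parameters; the
amplitude–phase form is derivable). Bins with zero weight are omitted
from all likelihoods, never imputed. The weighted likelihood treats a
bin mean with weight w as having variance σ²/w, which matches weighted
least squares at the mode.

WAIC needs a posterior. The Bayesian fit is a conjugate Gibbs sampler
for the weighted normal regression: β ~ N(0, (10·sd(y))² I) and
σ² ~ Scaled-Inv-χ²(ν₀ = 1, s₀² = sd(y)²), 200 burn-in + 2000 kept draws,
seeded. The inverse-chi-squared prior (rather than, say, a half-normal
on σ) was chosen for exact conditional conjugacy: both full conditionals
are closed-form, so the sampler is fast, deterministic given the seed,
and tuning-free; it is equally weakly informative at these data scales.
From the draws: lppd = Σᵢ log meanₛ p(yᵢ|θₛ), p_waic = Σᵢ Varₛ log
p(yᵢ|θₛ) (sample variance, ddof = 1), WAIC = −2(lppd − p_waic). Model
selection names a winner only at a WAIC margin ≥ 2 (mirroring the AIC
rule); out-of-sample transfer uses weighted RMSE of a frozen model with
no refitting. Absolute WAIC values depend on this prior/posterior
machinery and are not comparable across implementations; only the
selection logic is.

## Theory curves and deviance

The three theory curves are smoothed piecewise-linear families on a
min-max-standardized [0, 1] metric scale, with anchors exposed in
`TheoryParams`: wake 07:00, sleep onset 01:00, evening rise from 18:00,
night level 0.05, plateau 0.60, peak 1.00, SD ribbon = 15% of the
plateau, 1-h transitions, Gaussian smoothing (SD 0.35 h) on a 0.01-h
circular grid. A Gaussian observation model is the minimal location-
scale likelihood consistent with a mean ± SD specification. Scoring
weights each session once (per-session mode) or each bin by its session
count (binned mode); both are supported because deviance magnitudes
depend directly on the observation unit. The exact curves used in the
original pre-registration are not recoverable; the module's claims are
about the scoring machinery (additivity, affine equivariance,
self-consistency), not one fixed parameterization.

## Moderation

Per-session coefficients come from a quadratic model grouped by session
with random intercept, linear and quadratic deviations per session
(Powell optimizer); each session's coefficients are the fixed effects
plus its empirical-Bayes deviations. Sessions by the same user are not
given a separate user level: the session-level deviation absorbs the
user's shift, which is the quantity the moderation regression needs.
Empirical-Bayes shrinkage biases the between-session spread of the
extracted coefficients toward zero, so recovered spreads are read as
lower bounds. The time-of-day regressions are unweighted OLS on sin/cos
terms (cluster-robust-by-user covariance optional), with per-term
two-sided t-tests and a joint F-test; the six-test battery uses
α = .008 ≈ .05/6.

## Depletion simulator

Discrete time (default 5-minute steps, must divide the hour) rather than
event-driven, for simplicity and exact reproducibility. Per step: asleep
agents recover toward a full reservoir at `recovery_per_hour`; awake
agents receive a task with probability rate·Δt, losing a truncated-
normal demand (reservoir floored at 0); idle awake agents rest with a
configurable probability, recovering at the same rate. Wake times are
normal (truncated to 04:00–12:00); sleep onset is shared. The lenient
preset — 0.5 tasks/h of mean demand 0.05, rest probability 0.5,
recovery 0.02/h — is the package's minimal realization of a "forgiving
day"; its acceptance is property-based (flat at rate 0, monotone decline
without recovery, decline within an hour of mean wake), not a
reproduction of any published figure.

## Pipeline scale and determinism

The demo runs two generated cohorts of 120 users (≈ 2000 sessions,
≈ 120k trials each) — one to two orders of magnitude below the motivating
cohorts, chosen so a full run completes in about a minute on one core
while every selection margin of interest (ΔAIC ≫ 2, theory NLL margins
≫ 0) remains decisive. The moderation stage subsamples at most 800
sessions (seeded) before the session-grouped fit. All stages are
deterministic given the study seed; rerunning a demo reproduces every
output file byte-for-byte.

## Known limitations

- The fatigue estimate inherits the non-random item-difficulty
  conservatism discussed above; no item-response correction is applied.
- Diurnal analyses pool sessions across users (no per-user curves); a
  user-composition confound is possible on real data.
- WAIC values are machinery-specific (prior scale, draw count); only
  differences within one run are meaningful.
- The depletion model is a caricature for establishing a qualitative
  prediction, not a fitted model of any population.
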