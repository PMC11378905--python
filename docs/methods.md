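# Methods

This note documents the models implemented in `infocond`, the choices made
where the methods literature leaves the design open, and what the synthetic
data can and cannot establish.

## Protocol model

A protocol is the tuple (paradigm, contingency, tone duration *T* and kind,
mean ITI, mean IRI, tones/session, collection window). Expected per-session
exposures are linear in these parameters: tone time = n·T̄ (the mean
duration for variable tones), ITI time = n·ITI. Expected rewards depend on
how the schedule runs:

- **Negative contingency** (both paradigms): the scheduling process runs
  only during ITIs, so expected rewards = ITI time / IRI.
- **Zero contingency, operant**: the random-interval schedule runs
  session-wide, so expected rewards = context time / IRI.
- **Zero contingency, Pavlovian**: the pellet *budget* equals the ITI-only
  schedule's (ITI time / IRI) — the truly-random control delivers the same
  number of pellets as its negative-contingency twin — but pellets fall at
  random times across the whole session, so expected counts split across
  states in proportion to exposure. This is the only reading consistent
  with the published per-session reward counts for the mixed-duration
  zero-contingency control.

Rates are reported per minute (the convention of the published protocol
table); all internal computation is in seconds. Informativeness uses the
tone-offset convention ι = λ_R|ITI / λ_R|C throughout: every bundled
protocol is negative- or zero-contingency, and for zero contingency the
convention gives ι = 1 by construction. `informativeness(..., signal="onset")`
covers positive contingencies.

Credit assignment solves the 2×2 system with `numpy.linalg.solve`; the
matrix is declared singular when |p(~T|C) − 1| < 1e-9 (tone never on), in
which case both attributed rates are the contextual rate.

`fit_k` defaults to log-space least squares (closed form
ln k = mean(ln n_R + ln(ι−1))) because acquisition scores disperse
multiplicatively and are conventionally displayed log-log; a linear-space
option is provided. The method that produced the published k = 255 is not
recorded, so both are exposed and the default is a package choice.

## Synthetic sessions

A session is an alternating ITI→tone cycle (n cycles; the session ends at
the last tone offset). ITIs are exponential; tones are fixed, exponential,
or drawn uniformly from an explicit duration list. The timeline is kept in
integer deciseconds (0.1-s recording resolution, matching behavioral
hardware); durations are rounded to the grid with a one-tick minimum, and
event times are generated in continuous time within their segment and
floored to the grid, which keeps negative-contingency rewards strictly
outside tones.

Pavlovian pellets are a Poisson process on the *eligible clock*: under a
negative contingency the process pauses (is not reset) at tone onset, which
preserves the exponential IRI over concatenated ITI time. Operant rewards
use single arming: an exponential arming interval elapses on the eligible
clock, the timer freezes while a reward is pending, and the next response
in an eligible state collects it (a reward armed before a tone is held
until the first ITI response).

The agent is a piecewise-constant Poisson responder simulated by thinning:
one baseline rate in both states before the change point (a cumulative
pellet count, carried across a subject's sessions), separate ITI and tone
rates after it. The change point is hard because the acquisition statistic
estimates an onset; per-subject lognormal jitter of the change point is
available for cohort heterogeneity. Rat baseline response rates are not
published for these protocols; the default (5/min) is a configuration
value, not a claim. Seeding: one integer seed per session is split via
`SeedSequence.spawn` into scheduler and agent sub-streams; cohorts give
subject *i* the seed `base_seed + i`, from which jitter and per-session
31-bit seeds are drawn deterministically.

The generator emulates the statistical structure of real sessions — not
satiety drifts, magazine training, movement artifacts, or photometry.
Passing tests therefore certify the analysis pipeline and its calibration
under the generative assumptions, not robustness to un-modeled behavior.

## Acquisition statistics

Responses within the collection window (default 2 s) after each reward are
excluded, and each state's exposure is reduced by the union of those
windows (clipped at session ends and split at state transitions). The
window is half-open, (reward, reward + w]: a lever press that shares its
timestamp with the reward it earned is anticipatory responding and is
kept. Checkpoints are reward deliveries; exposures and counts are
truncated at the reward's own timestamp and accumulate across sessions
concatenated in chronological order with inter-session time excluded.

Rate estimates use the Jeffreys posterior mean (n + ½)/t — the mean rather
than the mode so that zero counts still give a positive rate. The evidence
is n·D_KL(Exp(λ̂_tone) ‖ Exp(λ̂_ITI)) with n the cumulative adjusted tone
response count, compared to the Γ(½, 1) null (= χ²₁/2). Two properties are
deliberate and documented rather than "fixed": thresholds are applied per
checkpoint with no multiplicity correction, and the Γ(½, 1) reference is
exact only when the ITI rate is estimated from much larger exposure than
the tone rate — with comparable exposures the statistic scales like
½(1 + n_T/n_ITI)·χ²₁. The null-calibration Monte Carlo therefore uses a
50-fold reference exposure, and the p-criteria are gated on the sign of
the rate difference the contingency predicts (the statistic itself is
two-sided). The max-cum-difference criterion is the global argmax (argmin
for the opposite direction) of the running Σ(λ̂_tone − λ̂_ITI) record.

Calibration figures computed by the suite and the acceptance script: the
ML gamma shape of 10,000 null statistics is 0.5 within ±0.05 and the
empirical type-I error at the 1% criterion is 0.010 within ±0.004.
Change-point recovery uses a 200-subject cohort of the 128-tone protocol
(two sessions per subject, change point at 100 pellets, tone rate 0 vs ITI
20/min): the median p01 pellets-to-acquisition falls a few pellets after
the true change point, within [100, 140].

## Within-tone profile model

Subjective time is t/(w_d·μ_R|C) with Weber fraction w_d = 0.16 and μ_R|C
the mean inter-reward interval in the context (1/λ_R|C). Drop and resume
latencies are exponential with time constant τ = 0.8 subjective units; the
low-rate occupancy is the self-convolution p_low(t) = (t/τ)e^(−t/τ),
peaking at 1/e at t = τ. The model rate over a tone of duration T is
λ(t) = λ_ITI − A·p_low(t)/max_[0,T] p_low, floored at zero. Peak
normalization over the window makes the amplitude A equal the observed
ITI-minus-minimum-tone rate difference, which is how the amplitude is
meant to be set (`amplitude = λ_ITI − min tone rate`); the raw
un-normalized occupancy is available via `normalized=False`. Empirical
decile profiles use half-open elapsed-fraction bins (boundary responses go
to the later bin) with exact bin-exposure accounting including
collection-window exclusions.

Model profiles require fixed-duration tones; variable-tone protocols have
no defined elapsed fraction and raise.

## Numerical choices

- Singularity tolerance for credit assignment: 1e-9 on p(~T|C) − 1.
- Γ(½, 1) tail probabilities via `scipy.stats.gamma.sf`.
- Checkpoint exposures evaluated exactly with piecewise-linear cumulative
  interval measures (`numpy.interp` over segment breakpoints), so the
  per-pellet analysis of a multi-session cohort is vectorised.
- Profile peak normalization uses a 2001-point grid over [0, T]; grids and
  subjective times scale exactly under power-of-two timescale changes, so
  scaled protocols yield bit-identical profiles.
- Monte-Carlo problem sizes in the test suite (300-session reward-count
  checks, 150-trace null means, 200-session profile recovery, 60-subject
  KS comparisons) were chosen so each check's sampling error is several
  times smaller than the tolerance it asserts.

## Known limitations

- The sequential detector's per-checkpoint thresholds are anticonservative
  under optional stopping; this mirrors the method as described and is
  calibrated only at a single fixed checkpoint.
- Operant "informativeness" uses obtained (not scheduled) rewards when
  computed from event logs; a slow responder therefore sees lower rates in
  both states.
- The profile model's subjective-moment count T/(w_d·μ_R|C) is exposed as
  a raw computation only; no claim is made that it reproduces any
  particular published annotation.
- No within-session nonstationarity (satiety, warm-up) and no gradual
  (non-step) learning in the default agent; a profile-shaped tone rate is
  the only within-state structure available.
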