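# Methods

`socialgaze` simulates extended, gaze-contingent encounters between a
virtual agent and a (synthetic) human participant in a shared 2D screen
environment — an agent face at the centre, four object areas of interest
(AOIs) around it — and estimates the temporal and probabilistic parameters
that govern joint-attention behaviour from the resulting event streams.
This note records the model, its assumptions, the defaults, and the
numerical and design choices.

## The agent model

The agent's behaviour is organised as a two-level stochastic state machine.

**Macro states** are persistent behavioural modes spanning the social-gaze
space: initiating joint attention (IJA), responding to joint attention
(RJA), and three non-interactive modes — partner-oriented (PO),
object-oriented (OO) and introspective (INT). **Micro states** are the
atomic units a macro state is composed of: one gaze direction (an object
AOI, straight at the partner, downward, or eyes closed), a duration law, a
row of transition probabilities over successor micro states and, for the
interactive states, gaze-contingent triggers. Timing and choice are both
probabilistic: successors are drawn from the transition row, durations from
the micro state's duration law.

* Non-interactive macro states advance by a first-order Markov chain
  (`markov_controller`). For OO and PO the per-AOI transition rows are the
  empirical gaze-shift matrices measured in adult participants; for INT,
  which has no published matrix, the default is 0.8 self-dwell on a
  lowered, off-AOI gaze target with the remainder split between partner
  and objects.
* The RJA controller arms on straight gaze; a human dwell onset on an
  object is a *bid*, followed with probability `follow_probability` (1.0
  in the high variant, 0.33 in the low one) after a reaction-time draw.
  The agent then dwells on the object and only re-arms afterwards; bids
  arriving mid-follow are ignored, not queued.
* The IJA controller waits for eye contact (up to `max_contact_wait`,
  default 5,000 ms), keeps contact for a straight-dwell draw, then shifts
  to an object chosen by configurable weights (uniform by default). The
  bid is a success iff the human's dwell on that object begins within the
  response window `w` (default 2,000 ms; the empirical source does not
  pin this value down). After success the agent dwells on the object; after failure it
  returns to straight gaze at the no-JA timeout.
* Eye blinks are superimposed as 100 ms closed-eye segments whose onsets
  form a renewal process. The default inter-blink interval is log-normal
  with mean 3,529 ms — about 17 blinks per minute, the rate displayed in
  the source estimates — and log-sd 0.3 (a documented default; the
  exact blink parameters are not public). Blinks overlay the display only; the
  micro-state clock underneath is untouched.

Time is integer milliseconds and the scheduler is event-driven (no frame
tick), so identical seeds and inputs produce byte-identical event logs.

## Duration laws

All timing draws and all fitted parameters use one of three families
standard for human response latencies: normal (`mu`, `rho` in ms),
log-normal (`mu`, `rho` on the log scale) and ex-Gaussian (Gaussian `mu`,
`rho` plus exponential mean `eta`, all ms). Closed-form moments:

| family  | mean                    | SD                                          |
|---------|-------------------------|---------------------------------------------|
| norm    | mu                      | rho                                         |
| lnorm   | exp(mu + rho²/2)        | mean · sqrt(exp(rho²) − 1)                  |
| exgauss | mu + eta                | sqrt(rho² + eta²)                           |

Draws are kept positive by redrawing non-positive values. This matters for
laws with substantial negative mass — the partner-dwell normal
(2480, 1670) has ~7% of its mass below zero — where the realised law is a
right-skewed truncated normal whose mean exceeds the nominal one, and
which an information-criterion comparison will (correctly) classify as
ex-Gaussian rather than normal. The log-normal and the tabulated
ex-Gaussian configurations are unaffected.

Fitting is per participant by maximum likelihood: closed-form estimators
for normal and log-normal; for the ex-Gaussian a skewness-based
method-of-moments start refined by bounded L-BFGS-B on the exact
log-likelihood, with a fixed initialisation so fits are deterministic.
The family shared across participants is selected by the Bayesian
information criterion `k·ln(n) − 2·loglik` *summed over participants*
(pooled selection; one family per parameter, matching how the empirical
table reports a single family per row). Participants with fewer than 10
observations for a parameter are dropped from the comparison symmetrically
for all candidate families.

Cross-participant summaries average the fitted parameter vectors
element-wise, and separately average the per-participant closed-form
means/SDs. For the ex-Gaussian the two conventions coincide for the mean
(mu + eta is linear); for the log-normal they differ (Jensen gap), and the
average-of-per-participant-moments convention is the one consistent with
the published summary table. One published inconsistency is deliberately
not forced: the partner-dwell normal row prints an estimated mean of
1,860 ms alongside mu = 2,480 ms, which no convention reproduces; the
package keeps the (mu, rho) parameters and flags the discrepancy here.

## The synthetic participant

The participant generator replaces the live eye tracker, producing
event-level behaviour with the statistical structure of the empirical
estimates, per instructed state:

* **RJA instruction** (agent initiates): the participant holds eye
  contact and answers each agent bid with probability 0.85 after a
  follow latency drawn from exGauss(350, 34.2, 124), dwelling on the
  object per lnorm(6.84, 0.27) before returning to the face. Bids
  arriving while still dwelling from the previous answer are declined.
* **IJA instruction** (agent responds): face dwell per lnorm(6.72, 0.46),
  then a shift to an object. If the agent follows, the object dwell runs
  from the agent's gaze arrival per lnorm(6.50, 0.58), after which the
  participant either re-fixates the face or, with probability 0.2, moves
  directly to the next object (this branch probability is not measured
  anywhere; it is a free profile knob). If the agent does not follow
  within the window, the object dwell runs per lnorm(7.26, 0.44).
* **PO / OO / INT**: a Markov walk over AOIs with the state's matrix and
  the state's object/face dwell laws. Published OO rows sum to 0.97–1.03
  because entries are printed to two decimals; they are renormalized at
  load, so e.g. the generating p(O1→O2) is 0.65/0.97 ≈ 0.670.

Saccades between AOIs take a constant 30 ms (excluded from dwells); there
is no oculomotor physiology (velocity profiles, pupil), no head movement,
and no drift. `render_samples` emulates the tracker: 60 Hz samples at the
active AOI's anchor plus a piecewise-constant micro-saccadic jitter offset
(sd 3 px, re-drawn every 100 ms), white measurement noise (sd 2 px),
linear interpolation during saccade gaps, and uniform dropout. Passing
tests on this generator therefore demonstrate internal consistency of the
pipeline — that the estimator recovers what the generator put in — not
fidelity to any individual human; real data add smooth pursuit, blinks on
the human side, calibration drift and non-stationarity that the generator
deliberately omits.

## Parsing

Fixation detection is dispersion-based (I-DT): maximal runs of valid
samples whose per-axis positional range stays within 40 px and that span
at least 60 ms; invalid gaps up to 75 ms are bridged. The original recordings
used tracker-side fixation events whose algorithm is not public, so these
thresholds are declared substitutes, exposed in `ParseConfig`. Fixation on/offsets are
refined to the midpoint between the boundary sample and its neighbour,
which removes the half-sample-period quantisation bias — without this the
recovered follow latency would sit ~8 ms high at 60 Hz. Consecutive
fixations whose centroids fall in the same AOI merge into one dwell (dwell
time = first onset to last offset, micro-saccades ignored); AOI overlap is
resolved by declaration order. A block is analysable when at least 2/3 of
its samples are valid (the boundary counts as included); the exclusion
ledger tallies mutually exclusive exclusion reasons in priority order.

## Estimation

`extract_timing` reads the eleven timing parameters off the paired event
streams by the bid/response grammar described above. Two conventions are
fixed here: only the first human dwell on the cued object counts as the
response to a bid, and the followed-bid object dwell is timed from the
agent's gaze arrival (which makes it structurally shorter than the
unfollowed-bid dwell, matching the empirical ordering). Dwells reaching
into the last 50 ms of a block are right-censored and emit no duration
observation; without this guard, block-end truncation biases dwell means
noticeably low. A smaller inspection-paradox bias remains — a behavioural
cycle must fit inside a 30 s block, so very long dwells are slightly
under-represented, on the order of −20 ms for ~1 s dwells — and shrinks
with block length; consistency tests therefore run at event level or with
sizes where it is below the test tolerance.

Transition matrices are estimated per participant from consecutive dwell
pairs with different AOIs (a merged dwell cannot follow itself, so the
diagonal is structurally zero), row-normalized, averaged entry-wise across
participants with undefined rows excluded, and renormalized. Attention
ratios are the on-AOI ratio (total dwell time over state duration) and the
face-object ratio (face dwell time over face-plus-object dwell time),
undefined ratios excluded rather than zero-filled. Heatmaps deposit a
duration-weighted quadratic kernel max(0, 1 − (r/R)²) per fixation with R
the pooled positional SD, sqrt((var_x + var_y)/2) — the published wording
does not fix pooled vs per-axis, so pooled is chosen — with a 5 px floor
for degenerate clouds, and a log1p display transform.

## Default experiment

60 blocks of 30 s; the five instructed states appear exactly 12 times
each, shuffled within successive rounds of five. Instructed RJA pairs with
the initiating agent; instructed IJA alternates the responding agent
between its always-follow and 0.33-follow variants (6/6; both variants
were used empirically but the split is not reported). The agent's own timing laws default to
the measured human laws, since the original a-priori agent values are
not public; everything is overridable via the YAML
config, and every artifact embeds the config digest and master seed.

## Problem sizes and known limitations

The recovery studies run at desk scale: transition-matrix recovery uses
50,000 simulated shifts; follow-latency recovery uses 33 synthetic
participants with 100 trials each rendered at 60 Hz. Known limitations:
the positivity-truncation interaction with wide normal laws (above); the
block-boundary length bias (above); I-DT cannot detect dwells shorter than
roughly the minimum fixation duration plus two sample periods, so sub-100
ms dwells truncated by a block end vanish from parsed streams; and the
synthetic participant is stationary across blocks, so the package cannot
exhibit (or test for) fatigue or learning effects.
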