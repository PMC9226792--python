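# Methods

`stopsig` implements, end to end, the analysis of a two-group selective
stop-signal EEG study: task design, a generative model of behavior and
EEG used in place of unavailable raw data, behavioral scoring with
integration-method SSRT, ERP component measurement, and the group-level
statistics. This note records the models, the defaults and why they were
chosen, the numerical decisions, and the known limitations — in
particular a structural bias of the SSRT estimator under this task's
random stop-signal delays, which the package measures rather than hides.

## Task design

A session is a single pseudorandom sequence of 700 trials: 350 *reactive*
(non-informative cue) and 350 *proactive* (informative left/right arrow
cue). 60% of trials are go trials requiring a bimanual button press; 40%
are stop trials in which a red circle appears on one side after a
stop-signal delay (SSD) and only that hand must be withheld. Within each
condition the 140 stop trials split 70 left / 70 right, and on proactive
stop trials the cue always points at the to-be-stopped side. Trial
timings default to cue 200 ms, fixation gap 1300 ms, go stimulus 100 ms,
stop circle 200 ms, all configurable.

Two points the design source leaves open were fixed as follows:

* **SSD scheme.** SSDs are drawn independently and uniformly from a
  50 ms grid spanning 50–500 ms. No adaptive (staircase) tracking is
  implemented; tracking is an explicit non-goal. The consequences of
  this choice for SSRT estimation are discussed below.
* **Sequence constraint.** "Pseudorandom order" is operationalized as a
  seeded uniform permutation repaired so that no more than 3 stop trials
  occur in a row (configurable), the standard practice to prevent
  strategic slowing after runs of stop signals. Conditions are
  interleaved in one sequence, not blocked.

`validate_schedule` checks every invariant (counts, cue congruence, SSD
bounds, run lengths) and reports violations instead of raising, so it can
be used on externally supplied schedules.

## Generative model of behavior

Behavior follows the independent horse-race model. Each hand's go finish
time is ex-Gaussian, `N(mu, sigma) + Exp(tau)` (defaults 560/50/170 ms,
giving a mean go RT of 730 ms to match the control group's reported
RT-Go). The stop process has a Gaussian latency truncated at zero, with
separate means for reactive and proactive stopping (defaults 345/340 ms,
SD 30 ms). On a stop trial the cued hand is withheld iff
`ssd + stop_latency < go_finish` and the stop process triggered at all
(trigger failures, default 2%). Proactive preparation is an additive
shift of go finish times on proactive trials (default 10 ms — the
reference behavioral tables show near-identical reactive and proactive
go RTs, so the default slowing is small). Uninhibited stop trials
produce a failed stop (both hands respond) or, with probability
`choice_error_p` (default 8%), a *choice error*: the to-be-stopped hand
responds alone while the required response of the other hand is missing.
Trial-level attention lapses (default 5%) yield go omissions, and on
stop trials a response-less trial; this is deliberate — it is exactly
the failure mode the SSRT estimator's omission-replacement rule
corrects.

Group defaults (`default_group_params`) mirror the direction and rough
magnitude of the reference study's group contrasts: the gamer group gets
faster go finishes (mean 650 ms), slowed proactive stopping (+40 ms),
more choice errors, a smaller cue-locked P3, a shallower stop-locked N2
and a larger stop-locked P3. Per-subject parameters are drawn around the
group means (between-subject SD 25 ms on timing parameters, 0.6 μV on
amplitudes).

## Generative model of EEG

Channels are Fz, F3, F4, Cz, C3, C4 plus one EOG, at 500 Hz. Each event
class adds a Gaussian-in-time component at a fixed latency with scalar
per-channel scalp weights:

| component | locked to | latency | amplitude | width (SD) | channels |
|---|---|---|---|---|---|
| P3 cue  | cue onset  | 400 ms | +3.5 μV | 45 ms | frontal |
| P3 go   | go onset   | 380 ms | +2.2 μV | 45 ms | central |
| N2 stop | stop onset | 270 ms | −1.5 μV | 30 ms | frontal |
| P3 stop | stop onset | 380 ms | +3.2 μV | 45 ms | central |

Amplitudes sit in the range of the reference study's component tables;
latencies sit inside the respective measurement windows by construction
(validated at parameter-build time). Background noise is 1/f Gaussian
noise at 8 μV RMS; blinks are a stereotyped 400 ms biphasic waveform
(positive lobe then a 30% negative rebound) at ~4/min, 90 μV at the EOG
with a frontally weighted scalp projection; gross artifacts are 200 ms
±150 μV pulses on a random scalp channel of a random 3% of trials
(probabilities are raised in specific tests to measure rejection
calibration).

Deliberate simplifications, and what they imply about test coverage:
frontal and central components live on **disjoint channel sets**, so a
noise-free simulation reproduces each template exactly at its own
electrodes — this gives the pipeline-linearity tests machine-precision
oracles, but means the generator does not model volume-conducted overlap
between components. There is no forward head model, no
stimulus-locked overlap between the go response and the stop response on
stop trials, and component latencies do not vary trial to trial within a
subject. Passing tests therefore certify the *measurement machinery*
(filtering, epoching, rejection, averaging, windowed peaks), not
robustness to component overlap or latency jitter in real EEG.

For statistical calibration and power studies the package also provides
`simulate_measures`, a subject-level measurement model that draws the
tidy per-subject component-measure table (the quantity the ANOVA
consumes) directly from the group model — amplitude = group template +
subject offset + cell noise. Hundreds of replicate studies are needed
for a type-I-error estimate, and re-synthesizing raw EEG would exercise
nothing the ERP tests have not already certified.

## Behavioral scoring and SSRT

Trials are classified exhaustively as go_correct / go_omission /
stop_success / stop_failed / stop_choice_error; on a stop trial the
cued hand withheld means success, both hands responding a failed stop,
and the cued hand responding alone a choice error. Go RT is the mean of
the responding hands' RTs; omissions are counted separately.

SSRT uses the integration method, per condition × stop direction: go
omissions are appended as copies of the maximum observed go RT, the go
RT list is sorted, the stop process is placed at the
`ceil(p(respond|signal) × N)`-th ranked RT, and the stratum's mean SSD is
subtracted. Choice errors count as responses (they are unsuccessful
stops); a configuration switch excludes them. Two scoring decisions
deserve note:

* Non-integer ranks round **up** (ceiling) — the conservative reading of
  "the nth RT", exact whenever `p × N` is integral.
* The go distribution entering the quantile is the **stopped hand's own
  go RTs**, not the two-hand average. The race on a stop-left trial is
  against the left hand's go process; averaging the two hands' RTs
  halves the RT variance and was measured (Monte-Carlo) to add about
  +28 ms of estimator bias. The RT-Go summary metric still reports the
  conventional two-hand mean.

### Known limitation: integration SSRT under random SSD

With SSDs drawn uniformly from the full 50–500 ms range,
p(respond|signal) is an average of the inhibition function over a very
wide window, and lands far from the go-RT median. The quantile map is
strongly nonlinear there, so `Q(p̄) − mean(SSD)` is *not* the mean stop
latency: the package measures a bias of roughly +70 ms when the true
stop latency is 250 ms, +20 ms at 340 ms, ≈0 at 380 ms (20 sessions of
420 go / 280 stop trials each). The same nonlinearity attenuates an
injected +40 ms group difference in stop latency to a recovered ≈+20 ms,
and when groups also differ in go speed the contrast can be swamped
entirely. The estimator itself is correct: under a fixed SSD placing
p(respond) near .5 — the classic tracking setting the method was
designed for — recovery bias is below 3 ms, which is unit-tested. The
acceptance script reports both numbers (`ssrt_recovery_bias_random_ssd_ms`,
`ssrt_recovery_bias_fixed_ssd_ms`) so the design-induced bias is visible
rather than calibrated away. Users analyzing real data from a
random-SSD variant of this task should treat between-group SSRT
contrasts with corresponding caution.

## ERP measurement

The continuous record is band-passed 0.1–45 Hz with a 4th-order
Butterworth filter applied forward–backward (zero phase; the double pass
squares the magnitude response, putting 60 Hz line noise >20 dB down).
Epochs span −200…+800 ms around cue, go and stop markers with a
−200…0 ms baseline; the window covers every component search window with
a standard pre-stimulus baseline. Input is assumed already linked-ear
referenced; a re-reference utility exists but is not applied by default.

Artifact handling, in order: epochs exceeding ±100 μV on any non-EOG
channel are flagged `amplitude` and excluded from averages (events too
close to the record edge are flagged `edge`, never raised); blink
activity is removed by FastICA decomposition of the channels × time
matrix, zeroing every component whose time course correlates with the
EOG channel at |r| > 0.8 before reconstruction, with a report of zeroed
components and correlations.

Component measures come from subject averages (then group grand
averages): P3 variants are the maximum value in their search window
(300–550 ms for P3 cue, 280–500 ms for go/stop P3); peaks are single
samples (a ±10 ms local-mean option exists but is off by default). The
stop-locked N2 is the **second negative local minimum by latency**,
ordinal counted over the whole post-stimulus waveform, required to lie
in 200–350 ms; if the second-ordinal minimum is not in the window but
in-window minima exist, the second (or, if only one, the most negative)
in-window minimum is returned flagged `fallback`; no negative in-window
minimum raises a missing-component signal. P3 cue and N2 stop are
measured at Fz/F3/F4 and go/stop P3 at Cz/C3/C4 — the assignment of the
results tables, which disagree with a looser textual description of the
cue P3 as central; the tables are what was actually measured, and the
electrode sets are configurable.

## Group statistics

Behavioral metrics and demographics are compared with two-sided
independent-samples t-tests, pooled-variance by default (Welch via a
flag); zero pooled variance with equal means returns t=0, p=1. Each ERP
measure feeds a balanced mixed (split-plot) repeated-measures ANOVA with
group as the between-subject factor and trial factor × electrode as
within-subject factors, computed by the univariate sums-of-squares
decomposition with subject as the blocking unit. Each effect is tested
against its own stratum's error term (subjects-within-groups for the
group effect; factor × subject within groups for within effects).
Unequal group sizes are handled exactly via count-weighted cell means;
unbalanced *within* cells raise a missing-cell error listing the
offending subject × cell pairs — no imputation. Effect size is partial
eta squared, `SS_effect / (SS_effect + SS_error)`. Sphericity
corrections are not applied by default (a Greenhouse–Geisser switch is a
non-goal at this stage and dfs are reported uncorrected); follow-up
pairwise group comparisons within the cells of an effect are Bonferroni
adjusted with the family equal to the number of cells compared.

The implementation is cross-checked three ways: an explicit
marginal-means enumeration oracle on 2×2×2 integral data (agreement to
1e-9 relative), `pingouin.mixed_anova` on the one-within-factor
reduction (exact F agreement), and a 200-study null simulation whose
group-effect rejection rate at α=.05 must stay in [0.03, 0.08].

Participant screening follows the mean-item VAT rule: gamer-eligible at
≥2.5, control-eligible at ≤1.5, neither in between; scores outside the
instrument's 0–5 range are rejected.

## Problem sizes, determinism, formats

Default study scale is 30 subjects per group × 700 trials; the test
suite and the acceptance script run reduced sizes chosen to exercise
every code path at comfortable runtimes — 60-trial sessions for EEG
round-trips, full 700-trial sessions where counts themselves are under
test (schedule bookkeeping, artifact rejection), 20 replicate sessions
for recovery studies, 200 replicate studies at n=8/group for
calibration. All randomness descends from one master seed split per
stage and subject (`numpy.random.default_rng`); no global RNG state is
used, and equal seeds give byte-identical pipeline outputs.

EEG interchange is European Data Format (EDF, 16-bit; round trips are
exact to one quantization step of the per-channel physical range);
events, schedules, behavior and measures are TSV/CSV; configurations are
YAML and round-trip to identical structures; every output table carries
the config hash and seed.
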