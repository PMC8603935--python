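# Methods

This note documents the models, conventions and design decisions behind the
package: what is computed, under which assumptions, and what the synthetic
data do and do not establish.

## Trigger rule

All times are seconds from session start. A **burst** is a maximal run of
licks in which every inter-lick interval (ILI) is ≤ the eligibility pause
(1 s default); every burst is therefore preceded by a pause > 1 s or by
session start, which is exactly the rig's eligibility condition. Within a
burst, the trigger fires at the first lick *j* (1-based, *j* ≥ 3) whose span
over the previous three licks, L_j − L_{j−2}, fits within the 1 s trigger
window. After a trigger no further trigger can fire until an ILI > 1 s
elapses, i.e. at most one distractor per burst.

This single rule reconciles the two phrasings of the task ("three
consecutive licks within 1 s" and "3–5 consecutive licks within 1 s"): when
early triples are too slow the trigger naturally lands on the 4th or 5th
lick. We record `burst_position` on every trial so the 3–5 distribution can
be audited, and we deliberately do **not** cap evaluation at the 5th lick —
positions > 5 are possible for pathological trains and are visible in the
audit rather than silently clipped.

Strictness conventions: the eligibility reset uses ILI **> 1 s** (strict),
matching the strict "> 1 s" distraction criterion. Bins are half-open
[t, t+1), 0-based. Duplicate lick timestamps (lickometer chatter) are
collapsed with a warning.

## Distraction classification and pauses

`post_pause` is the time from the distractor to the next lick;
`distracted = post_pause > 1 s`. If no lick follows, the pause is censored
at session end and the trial counts as distracted (the animal never
resumed). `pre_pause` runs from the last lick before the triggering burst to
the burst's first lick; a session-initial burst is censored at session
start. Censored pauses are **included** in probability computations but
**excluded** from pause-duration statistics by default (configurable):
including a 40-minute censored "pause" in a median would measure session
length, not behaviour.

## Photometry

The calcium channel is corrected with the isosbestic channel as reference:
OLS of iso onto ca over the **whole session** (the signals are already 3 Hz
low-passed at acquisition; no piecewise fitting), then
ΔF/F = (ca − fit)/fit. The fit uses the covariance form (slope =
cov(iso,ca)/var(iso)), which annihilates any exact affine combination
a·iso + b to double precision (~1e-16 observed) and removes shared
bleaching/motion structure while leaving calcium-only transients intact.
A constant isosbestic channel or a fitted reference crossing zero raises an
error rather than producing nonsense ΔF/F.

Snips span −5 to +15 s around each event and are decimated by **block
averaging** to a configurable rate (default 10 Hz): the acquisition rate
(~1 kHz) is redundant under the 3 Hz low-pass, block means commute with the
later 1 s binning (verified by test), and desk-scale arrays stay small.
Events whose window leaves the recording are dropped and logged, never
padded. Z-scoring is per-trial against the −5..0 s baseline; a zero-variance
baseline drops the trial with a warning. "Non-z-scored" control analyses
operate on the same ΔF/F snips without baseline normalisation.

Epoch defaults follow the main analysis text: pre −5..−1 s, early post
+1..+4 s, late post +5..+15 s. Some figure panels use +1..+3 / +4..+15;
both variants ship (`epoch_set: text|caption` in the study config) and the
discrepancy is surfaced rather than resolved. Clock alignment between
behaviour and photometry is explicit via `t0_offset`; there are no
resynchronisation heuristics.

## Statistics

The bin-wise comparison uses AUC = P(B > A) + ½P(B = A), computed from
ranks (identical to the normalised Mann–Whitney U), with per-bin p-values
from the Mann–Whitney test — exact for small untied samples, normal
approximation with tie correction otherwise — Bonferroni-corrected with
m = number of bins (20), one figure panel = one family. The per-bin
procedure is configurable (Mann–Whitney / Welch t / permutation with
10,000 shuffles) because different labs use different conventions for this
step; Mann–Whitney is the default as the test exactly dual to the AUC.
Trial-level ROC pools trials across rats (no mixed-model nesting; that is an
explicit non-goal).

Repeated-measures ANOVAs are standard within-subject decompositions
(one-way: df (k−1,(k−1)(n−1)); two-way interaction:
df ((a−1)(b−1),(a−1)(b−1)(n−1))), computed via statsmodels' AnovaRM on
per-subject means and cross-checked in the tests against an independent
sums-of-squares implementation to 1e-8. Sphericity corrections are not
applied. Degenerate inputs (zero effect **and** zero error, e.g. identical
columns or exactly additive data) make F a 0/0; we detect a vanishing
effect sum-of-squares (≤ 1e-12 of total SS) and report F = 0, p = 1, which
is the correct limit. Post-hoc paired contrasts use Bonferroni (one-way)
or Sidak, p' = 1 − (1−p)^m (two-way, within each epoch). Pause-duration
contrasts run on natural-log pauses (per-trial log, per-rat mean); the
pause–activity correlation is Pearson's r between log post-pause and mean
z-scored activity 0–3 s after the distractor, on distracted trials only.
Stimulus labels collapse into three classes for the effectiveness contrast:
contains white noise; contains tone without white noise; neither.

## Synthetic generator

Licking is an alternating renewal process: burst lengths 1 + Geometric(p =
0.05) (mean ≈ 21 licks, ~3 s), intra-burst ILIs lognormal(median 0.14 s,
σ = 0.25) ≈ 7 Hz licking, inter-burst pauses lognormal(median 5 s, σ = 0.6).
These values are ordinary rodent lick microstructure and yield a few
thousand licks and on the order of 100–400 delivered distractors per hour,
with a spontaneous post-trigger long-pause rate of ≈ 0.05 — the same order
as the low modelled-day distraction probabilities this task produces in
vivo (the trigger usually lands on a burst's 3rd lick, so a spontaneous
"distraction" requires the burst to end exactly there).

The generator runs the trigger rule **online** in streaming form while
emitting licks; this is the same rule as the offline detector, so the
delivered-distractor log and offline detection agree exactly on every seed
(tested, and re-verified by the acceptance script). On each delivered
distractor a Bernoulli(p_distract) gate decides the response: if it fires,
the burst is interrupted and the next pause is drawn from a long-pause
lognormal (median 5 s) truncated above the 1 s criterion; otherwise licking
continues per the baseline model. The measured distraction probability is
therefore p + (1−p)·p₀ with p₀ the spontaneous rate, so p is recovered
without bias by the adjustment (p_obs − p₀)/(1 − p₀), with p₀ estimated by
rerunning the generator with the gate disabled. The three-day fixture
protocol is: training day with no stimuli (modelled distractors only),
first distraction day p = 0.5, habituation day p = 0.25 with **unchanged**
transient amplitudes — behavioural habituation without neural habituation,
the dissociation this task design probes.

Photometry: both channels share a double-exponential bleaching envelope
(0.4 V·e^(−t/300 s) + 0.2 V·e^(−t/2500 s)) and sparse exponential motion
artifacts (rate 0.01 Hz, ±0.15 V, τ = 0.5 s); the calcium channel is the
shared structure scaled by 1.5 plus an offset, event-locked transients
(difference-of-exponentials kernel, rise 0.2 s, decay 1.5 s — GCaMP6s-like)
with peak amplitude 0.30 V on gated (distracted) trials and 0.15 V
otherwise, and independent Gaussian noise (SD 5 mV/sample per channel).
Default simulation rate is 100 Hz rather than the rig's ~1 kHz: under the
3 Hz acquisition low-pass the extra samples carry no information and
desk-scale arrays keep the suite fast; it is configurable up.

**What the synthetic data do not emulate:** satiety drift and slow
behavioural nonstationarity within a session; indicator kinetics beyond the
two-exponential kernel (no saturation, no bleaching of the transient
amplitude itself); hemodynamic or spectral crosstalk between channels;
correlated (non-Poisson) artifact trains; and any coupling between lick
motor events and the neural signal. Passing tests therefore demonstrate
that the pipeline recovers what its own model family generates — detector
correctness, correction exactness, calibrated error rates, unbiased
parameter recovery — not that the biological effects themselves are
reproduced from raw in-vivo recordings.

## Problem sizes

The default test and reproduction runs use desk-scale versions of the study
conditions: 600–1800 s sessions, 4–6 synthetic rats, 50–100 Hz photometry,
2,000 null replicates for the family-wise-error calibration and 20 seeds ×
100 trials per condition for parameter recovery. All sizes are arguments,
chosen so the whole battery runs in about a minute; conclusions were stable
when spot-checked at larger sizes.

## Known limitations

- Mann–Whitney p-values at very small trial counts (< ~8 per group) are
  conservative after Bonferroni; the permutation option is preferable there.
- The modelled-distractor comparison assumes training-day and
  distraction-day lick microstructure are otherwise exchangeable; the
  pipeline does not test that assumption.
- Raw acquisition-system tank files are not parsed in the core; sessions
  enter via the CSV/HDF5 formats documented in `lickdistract.io`.
- `burst_position` can exceed 5 on unusual trains (no cap); downstream
  consumers that need the strict 3–5 behaviour should filter on it.
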