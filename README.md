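# lickdistract

Analysis pipeline for **distraction during ongoing licking** experiments in
rodents, with paired **fibre-photometry** recordings.

In this task a rat licks freely for a palatable solution while a closed-loop
controller delivers a 1 s audiovisual *distractor* whenever the animal emits
3–5 consecutive licks within 1 s (after a pause of more than 1 s). A trial is
scored *distracted* when the pause in licking after the distractor exceeds
1 s. Applying the same trigger rule offline to a session recorded *without*
stimuli yields *modelled distractors* — the behavioural null against which
real distractor days are compared. Bulk calcium signals (e.g. GCaMP6s
recorded from midbrain populations) are acquired on two channels: a
calcium-sensitive channel and a calcium-insensitive isosbestic reference.

The package provides:

- **Trigger detection and trial classification** (`lickdistract.events`):
  the burst-trigger rule, post-/pre-distractor pauses, distraction
  probability, peri-event lick rates, tercile splits, pause ECDFs.
- **Photometry processing** (`lickdistract.photometry`): isosbestic
  regression correction ΔF/F = (F_ca − F_fit)/F_fit with
  F_fit = β̂₁·F_iso + β̂₀ fitted by OLS over the session; event-aligned snips
  (−5 to +15 s), z-scoring to the 5 s pre-event baseline, 1 s binning and
  epoch means (−5..−1, +1..+4, +5..+15 s).
- **Statistics** (`lickdistract.stats`): bin-wise ROC where
  AUC = P(x_B > x_A) + ½·P(x_B = x_A) (the normalised Mann–Whitney U),
  with per-bin Mann–Whitney p-values Bonferroni-corrected across the 20
  bins of a panel (t-test and permutation variants available);
  within-subject one- and two-way repeated-measures ANOVAs with
  Bonferroni/Sidak follow-ups; paired t-tests; log-pause contrasts;
  pause–activity correlations.
- **A closed-loop synthetic generator** (`lickdistract.simulate`):
  burst/pause renewal licking with the trigger rule running online, a
  Bernoulli distraction response with recoverable probability, and
  two-channel photometry with shared bleaching/artifacts plus
  calcium-only event-locked transients — every session ships with a
  ground-truth manifest.
- **Study orchestration** (`lickdistract.pipeline`, `lickdistract.io`,
  CLI `lickdistract`): session CSV/HDF5 formats, three-day study assembly,
  and the full analysis battery producing tidy CSV tables and a JSON
  report.

## Worked example

Simulate one closed-loop session, classify distraction, correct the
photometry and ask in which 1 s bins neural activity separates distracted
from non-distracted trials:

```python
import numpy as np
from lickdistract import (SyntheticConfig, generate_session, generate_photometry,
                          build_trials, distraction_probability, correct_isosbestic,
                          extract_snips, zscore_snips, bin_snips, binwise_roc)

cfg = SyntheticConfig(seed=8, session_length=900.0, p_distract=0.5)
licks, events, truth = generate_session(cfg)
trials = build_trials(licks, events)
print(f"{len(licks)} licks, {len(events)} distractors, "
      f"P(distracted) = {distraction_probability(trials):.3f}")

phot = generate_photometry(events, truth, cfg)
dff = correct_isosbestic(phot)
print(f"isosbestic fit: slope = {dff.fit_slope:.3f}, intercept = {dff.fit_intercept:.3f}")

z = zscore_snips(extract_snips(dff, [ev.time for ev in events]))
bins = bin_snips(z)
distracted = np.array([trials[i].distracted for i in z.event_index])
roc = binwise_roc(bins[~distracted], bins[distracted])
sig = [int(s) - 5 for s in np.flatnonzero(roc.significant)]
print(f"significant ROC bins (s from distractor): {sig}")
print(f"peak AUC = {roc.auc.max():.3f} at t = {roc.bin_starts[roc.auc.argmax()] - 5:+.0f} s")
```

Output:

```
1114 licks, 119 distractors, P(distracted) = 0.605
isosbestic fit: slope = 1.496, intercept = 0.571
significant ROC bins (s from distractor): [0, 1, 2, 3, 4, 5]
peak AUC = 0.690 at t = +3 s
```

The rat was distracted on 60% of trials (the generator's response
probability of 0.5 plus the spontaneous chance of a long pause); the OLS fit
recovers the generator's channel gain (1.5); and the trial classes separate
only in the bins at and after the distractor — AUC 0.69 means a randomly
chosen distracted trial exceeds a non-distracted one 69% of the time in
that bin.

The same analysis on a whole multi-rat study, from the shell:

```bash
lickdistract simulate study/ --rats 6 --seed 2021
lickdistract report study/ study_report/ --plots
```

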