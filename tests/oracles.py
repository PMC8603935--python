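"""Independent brute-force reference implementations used only by tests.

Each function re-derives a quantity from first principles with the slowest,
most literal algorithm available, deliberately sharing no code with the
package implementations it checks.
"""

from __future__ import annotations

import numpy as np


def brute_force_triggers(onsets, min_licks=3, window=1.0, pause=1.0):
    """O(n^2) literal scan of the trigger rule.

    Walk every lick; maintain eligibility explicitly: a trigger may fire at
    lick j only if j is at least the min_licks-th lick of the current run
    (run = licks back to the last gap > pause), the last min_licks licks
    span <= window, and no trigger has fired since the last gap > pause.
    """
    onsets = list(onsets)
    out = []
    last_trigger_idx = None
    for j in range(len(onsets)):
        # find start of the maximal run containing j
        start = j
        while start > 0 and onsets[start] - onsets[start - 1] <= pause:
            start -= 1
        pos = j - start + 1  # 1-based position within the run
        if pos < min_licks:
            continue
        if onsets[j] - onsets[j - (min_licks - 1)] > window:
            continue
        # no previous trigger within this run
        if last_trigger_idx is not None and last_trigger_idx >= start:
            continue
        out.append((onsets[j], pos))
        last_trigger_idx = j
    return out


def brute_force_auc(a, b):
    """Pair-counting AUC: P(b > a) + 0.5 P(b == a) over all pairs."""
    wins = ties = 0
    for x in a:
        for y in b:
            if y > x:
                wins += 1
            elif y == x:
                ties += 1
    return (wins + 0.5 * ties) / (len(a) * len(b))


def rm_anova_oneway_F(values):
    """Within-subject one-way F from the raw sums-of-squares decomposition."""
    values = np.asarray(values, dtype=float)
    n, k = values.shape
    grand = values.mean()
    ss_cond = n * ((values.mean(axis=0) - grand) ** 2).sum()
    ss_subj = k * ((values.mean(axis=1) - grand) ** 2).sum()
    ss_tot = ((values - grand) ** 2).sum()
    ss_err = ss_tot - ss_cond - ss_subj
    df_cond = k - 1
    df_err = (k - 1) * (n - 1)
    return (ss_cond / df_cond) / (ss_err / df_err)


def rm_anova_interaction_F(values):
    """Interaction F for a fully-crossed subjects x A x B within design."""
    values = np.asarray(values, dtype=float)
    n, a, b = values.shape
    grand = values.mean()
    mean_a = values.mean(axis=(0, 2))
    mean_b = values.mean(axis=(0, 1))
    mean_ab = values.mean(axis=0)
    ss_ab = n * ((mean_ab - mean_a[:, None] - mean_b[None, :] + grand) ** 2).sum()
    # error term: subject x A x B residual
    mean_s = values.mean(axis=(1, 2))
    mean_sa = values.mean(axis=2)
    mean_sb = values.mean(axis=1)
    resid = (
        values
        - mean_ab[None, :, :]
        - mean_sa[:, :, None]
        - mean_sb[:, None, :]
        + mean_a[None, :, None]
        + mean_b[None, None, :]
        + mean_s[:, None, None]
        - grand
    )
    ss_err = (resid**2).sum()
    df_ab = (a - 1) * (b - 1)
    df_err = (a - 1) * (b - 1) * (n - 1)
    return (ss_ab / df_ab) / (ss_err / df_err)


def loop_bin_means(data, fs, bin_width=1.0):
    """Per-trial binned means via an explicit double loop."""
    data = np.atleast_2d(data)
    per = int(round(bin_width * fs))
    n_bins = data.shape[1] // per
    out = np.empty((data.shape[0], n_bins))
    for i in range(data.shape[0]):
        for j in range(n_bins):
            out[i, j] = data[i, j * per : (j + 1) * per].mean()
    return out


def random_lick_train(rng, max_licks=200, t_max=100.0):
    """Random small lick train mixing fast bursts and long gaps."""
    n = int(rng.integers(0, max_licks + 1))
    gaps = rng.choice(
        [0.05, 0.1, 0.15, 0.3, 0.6, 0.9, 1.0, 1.01, 1.1, 2.0, 5.0],
        size=n,
        p=[0.25, 0.2, 0.15, 0.1, 0.05, 0.05, 0.05, 0.05, 0.04, 0.04, 0.02],
    ) * rng.uniform(0.8, 1.2, size=n)
    onsets = np.cumsum(gaps)
    return onsets[onsets < t_max]
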