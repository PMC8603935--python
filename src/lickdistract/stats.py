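"""Bin-wise ROC comparisons and repeated-measures contrasts.

The central comparison in this pipeline is a bin-by-bin ROC: for each 1 s
time bin of a peri-event matrix, the area under the ROC curve (AUC) between
two trial classes is the probability that a random trial from one class
exceeds a random trial from the other, with ties counted half.  The AUC is
the Mann-Whitney U statistic normalised by the number of pairs, so the
per-bin p-value comes from the Mann-Whitney test (exact for small samples,
normal approximation with tie correction otherwise), Bonferroni-corrected
across the bins of one panel.  A permutation test and a Welch t-test are
available as alternative per-bin procedures.

Repeated-measures ANOVAs (one-way for day/tercile/stimulus-class contrasts,
two-way for epoch x condition interactions) run on per-subject means, with
Bonferroni- or Sidak-adjusted pairwise follow-ups.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.anova import AnovaRM

from .events import InvalidInputError, Trial

__all__ = [
    "RocBinResult",
    "StatResult",
    "pairwise_auc",
    "binwise_roc",
    "one_way_rm_anova",
    "two_way_rm_anova",
    "paired_t",
    "log_pause_contrast",
    "pause_activity_correlation",
    "stimulus_type_contrast",
    "classify_stimulus",
]


@dataclass
class StatResult:
    """One inferential test: name, statistic, df, p, and any follow-ups."""

    name: str
    statistic: float
    df: tuple
    pvalue: float
    correction: str = "none"
    posthoc: Optional[pd.DataFrame] = None

    def __str__(self) -> str:  # F(2,24) = 28.5, p = 0.000 style
        df = ",".join(f"{d:g}" for d in self.df)
        return f"{self.name}({df}) = {self.statistic:.3g}, p = {self.pvalue:.4g}"


@dataclass
class RocBinResult:
    """Per-bin AUC with raw and Bonferroni-corrected p-values."""

    bin_starts: np.ndarray
    auc: np.ndarray
    p_raw: np.ndarray
    p_adj: np.ndarray
    significant: np.ndarray
    n_a: int
    n_b: int
    alpha: float = 0.05

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_start": self.bin_starts,
                "auc": self.auc,
                "p_raw": self.p_raw,
                "p_adj": self.p_adj,
                "significant": self.significant,
            }
        )


def pairwise_auc(vals_a: Sequence[float], vals_b: Sequence[float]) -> float:
    """P(b > a) + 0.5 P(b == a) over all pairs, via the rank statistic.

    Equivalent to the Mann-Whitney U statistic of group B divided by
    ``n_a * n_b``; ties contribute one half.
    """
    a = np.asarray(vals_a, dtype=float)
    b = np.asarray(vals_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InvalidInputError("pairwise_auc requires two non-empty groups")
    ranks = sps.rankdata(np.concatenate([a, b]))
    u_b = ranks[a.size :].sum() - b.size * (b.size + 1) / 2.0
    return float(u_b / (a.size * b.size))


def _bin_pvalue(a: np.ndarray, b: np.ndarray, method: str, rng, n_perm: int) -> float:
    if method == "mannwhitney":
        return float(sps.mannwhitneyu(b, a, alternative="two-sided").pvalue)
    if method == "ttest":
        return float(sps.ttest_ind(b, a, equal_var=False).pvalue)
    if method == "permutation":
        obs = abs(pairwise_auc(a, b) - 0.5)
        pooled = np.concatenate([a, b])
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            if abs(pairwise_auc(perm[: a.size], perm[a.size :]) - 0.5) >= obs - 1e-12:
                count += 1
        return (count + 1) / (n_perm + 1)
    raise InvalidInputError(f"unknown per-bin test {method!r}")


def binwise_roc(
    mat_a: np.ndarray,
    mat_b: np.ndarray,
    alpha: float = 0.05,
    bin_starts: Optional[np.ndarray] = None,
    method: str = "mannwhitney",
    n_perm: int = 10_000,
    seed: Optional[int] = None,
) -> RocBinResult:
    """Bin-by-bin ROC comparison of two trials x bins matrices.

    AUC is oriented so that values > 0.5 mean group B exceeds group A.
    Bonferroni correction uses m = number of bins (one panel = one family).
    """
    mat_a = np.atleast_2d(np.asarray(mat_a, dtype=float))
    mat_b = np.atleast_2d(np.asarray(mat_b, dtype=float))
    if mat_a.shape[1] != mat_b.shape[1]:
        raise InvalidInputError("matrices must have the same number of bins")
    if mat_a.shape[0] < 2 or mat_b.shape[0] < 2:
        raise InvalidInputError("each group needs at least 2 trials")
    m = mat_a.shape[1]
    rng = np.random.default_rng(seed)
    auc = np.empty(m)
    p_raw = np.empty(m)
    for j in range(m):
        auc[j] = pairwise_auc(mat_a[:, j], mat_b[:, j])
        p_raw[j] = _bin_pvalue(mat_a[:, j], mat_b[:, j], method, rng, n_perm)
    p_adj = np.minimum(1.0, m * p_raw)
    if bin_starts is None:
        bin_starts = np.arange(m, dtype=float)
    return RocBinResult(
        bin_starts=np.asarray(bin_starts, dtype=float),
        auc=auc,
        p_raw=p_raw,
        p_adj=p_adj,
        significant=p_adj < alpha,
        n_a=mat_a.shape[0],
        n_b=mat_b.shape[0],
        alpha=alpha,
    )


def _sanitize_f(f: float, p: float) -> tuple[float, float]:
    """Guard the 0/0 case: a zero effect with zero error gives F=0, p=1."""
    if not np.isfinite(f) or f < 0:
        return 0.0, 1.0
    return float(f), (float(p) if np.isfinite(p) else 1.0)


def _paired_t_cells(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    t, p = sps.ttest_rel(x, y)
    if not np.isfinite(t):  # identical cells: zero difference everywhere
        return 0.0, 1.0
    return float(t), float(p)


def _as_subject_matrix(values: np.ndarray, min_conditions: int = 2) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[1] < min_conditions:
        raise InvalidInputError("expected a subjects x conditions matrix")
    if np.any(~np.isfinite(values)):
        raise InvalidInputError("missing cells: repeated-measures design must be complete")
    return values


def one_way_rm_anova(
    values: np.ndarray, condition_names: Optional[Sequence[str]] = None
) -> StatResult:
    """One-way within-subject ANOVA on a subjects x conditions matrix.

    F has df (k-1, (k-1)(n-1)).  Post-hoc paired t-tests over all condition
    pairs are Bonferroni-corrected and attached as ``posthoc``.
    """
    values = _as_subject_matrix(values)
    n, k = values.shape
    if n < 3:
        raise InvalidInputError("need at least 3 subjects")
    if condition_names is None:
        condition_names = [f"c{i}" for i in range(k)]
    long = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(n), k),
            "condition": np.tile(condition_names, n),
            "value": values.ravel(),
        }
    )
    grand = values.mean()
    ss_cond = n * ((values.mean(axis=0) - grand) ** 2).sum()
    ss_tot = ((values - grand) ** 2).sum()
    if ss_tot == 0 or ss_cond <= 1e-12 * ss_tot:
        f, p = 0.0, 1.0  # no condition effect at all; F is 0/0 numerically
    else:
        tbl = AnovaRM(long, depvar="value", subject="subject", within=["condition"]).fit()
        row = tbl.anova_table.iloc[0]
        f, p = _sanitize_f(row["F Value"], row["Pr > F"])
    pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]
    m = len(pairs)
    rows = []
    for i, j in pairs:
        t, p_ij = _paired_t_cells(values[:, i], values[:, j])
        rows.append(
            {
                "a": condition_names[i],
                "b": condition_names[j],
                "t": float(t),
                "df": n - 1,
                "p_raw": float(p_ij),
                "p_adj": min(1.0, m * float(p_ij)),
            }
        )
    return StatResult(
        name="F",
        statistic=f,
        df=(k - 1, (k - 1) * (n - 1)),
        pvalue=p,
        correction="bonferroni",
        posthoc=pd.DataFrame(rows),
    )


def two_way_rm_anova(
    values: np.ndarray,
    epoch_names: Optional[Sequence[str]] = None,
    condition_names: Optional[Sequence[str]] = None,
) -> StatResult:
    """Two-way within-subject ANOVA on a subjects x epochs x conditions array.

    Returns the epoch x condition interaction, F with df
    ((a-1)(b-1), (a-1)(b-1)(n-1)), plus Sidak-adjusted pairwise condition
    contrasts within each epoch.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 3:
        raise InvalidInputError("expected subjects x epochs x conditions array")
    if np.any(~np.isfinite(values)):
        raise InvalidInputError("unbalanced design: all cells must be filled")
    n, a, b = values.shape
    if n < 2:
        raise InvalidInputError("need at least 2 subjects")
    if epoch_names is None:
        epoch_names = [f"e{i}" for i in range(a)]
    if condition_names is None:
        condition_names = [f"c{i}" for i in range(b)]
    long = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(n), a * b),
            "epoch": np.tile(np.repeat(epoch_names, b), n),
            "condition": np.tile(condition_names, n * a),
            "value": values.ravel(),
        }
    )
    grand = values.mean()
    cell = values.mean(axis=0)
    ss_ab = (
        n
        * (
            (cell - cell.mean(axis=1, keepdims=True) - cell.mean(axis=0, keepdims=True) + grand)
            ** 2
        ).sum()
    )
    ss_tot = ((values - grand) ** 2).sum()
    if ss_tot == 0 or ss_ab <= 1e-12 * ss_tot:
        f, p = 0.0, 1.0  # additive data: interaction SS (and its error) vanish
    else:
        tbl = AnovaRM(
            long, depvar="value", subject="subject", within=["epoch", "condition"]
        ).fit()
        row = tbl.anova_table.loc["epoch:condition"]
        f, p = _sanitize_f(row["F Value"], row["Pr > F"])
    pairs = [(i, j) for i in range(b) for j in range(i + 1, b)]
    m = a * len(pairs)
    rows = []
    for e in range(a):
        for i, j in pairs:
            t, p_ij = _paired_t_cells(values[:, e, i], values[:, e, j])
            rows.append(
                {
                    "epoch": epoch_names[e],
                    "a": condition_names[i],
                    "b": condition_names[j],
                    "t": float(t),
                    "df": n - 1,
                    "p_raw": float(p_ij),
                    "p_adj": min(1.0, 1.0 - (1.0 - float(p_ij)) ** m),
                }
            )
    return StatResult(
        name="F",
        statistic=f,
        df=((a - 1) * (b - 1), (a - 1) * (b - 1) * (n - 1)),
        pvalue=p,
        correction="sidak",
        posthoc=pd.DataFrame(rows),
    )


def paired_t(x: Sequence[float], y: Sequence[float]) -> StatResult:
    """Two-tailed paired t-test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise InvalidInputError("paired_t requires two equal-length vectors, n >= 2")
    t, p = sps.ttest_rel(x, y)
    if not np.isfinite(t):  # identical vectors: zero difference everywhere
        t, p = 0.0, 1.0
    return StatResult(name="t", statistic=float(t), df=(x.size - 1,), pvalue=float(p))


def log_pause_contrast(pauses_by_day: Sequence[Sequence[Sequence[float]]]) -> StatResult:
    """Day contrast on log-transformed pause durations.

    ``pauses_by_day[day][rat]`` is the vector of (non-censored, positive)
    pause durations for one rat on one day.  Pauses are natural-log
    transformed per trial, averaged per rat per day, and entered into a
    one-way repeated-measures ANOVA.
    """
    n_days = len(pauses_by_day)
    n_rats = len(pauses_by_day[0])
    means = np.empty((n_rats, n_days))
    import warnings as _warnings

    for d in range(n_days):
        for r in range(n_rats):
            p = np.asarray(pauses_by_day[d][r], dtype=float)
            bad = p <= 0
            if bad.any():
                _warnings.warn(f"excluded {bad.sum()} non-positive pause(s)")
                p = p[~bad]
            if p.size == 0:
                raise InvalidInputError("a rat has no positive pauses on some day")
            means[r, d] = np.log(p).mean()
    return one_way_rm_anova(means, [f"day{d}" for d in range(n_days)])


def pause_activity_correlation(
    post_pauses: Sequence[float], evoked_means: Sequence[float]
) -> StatResult:
    """Pearson correlation of log post-distractor pause with evoked activity.

    ``evoked_means`` is the mean z-scored signal in the 3 s after the
    distractor on distracted trials.
    """
    pauses = np.asarray(post_pauses, dtype=float)
    evoked = np.asarray(evoked_means, dtype=float)
    if pauses.size != evoked.size or pauses.size < 3:
        raise InvalidInputError("need >= 3 matched (pause, activity) points")
    if np.any(pauses <= 0):
        raise InvalidInputError("pauses must be positive for the log transform")
    if np.ptp(evoked) == 0 or np.ptp(pauses) == 0:
        raise InvalidInputError("correlation undefined for a constant vector")
    r, p = sps.pearsonr(np.log(pauses), evoked)
    return StatResult(name="r", statistic=float(r), df=(pauses.size - 2,), pvalue=float(p))


def classify_stimulus(label: Optional[str]) -> str:
    """Collapse a stimulus label into white-noise / tone / other classes."""
    if label is None:
        return "other"
    if "white_noise" in label:
        return "white_noise"
    if "tone" in label:
        return "tone"
    return "other"


def stimulus_type_contrast(trials_by_rat: Sequence[Sequence[Trial]]) -> StatResult:
    """Distractor-effectiveness contrast across stimulus classes.

    Trials are partitioned by stimulus class (contains white noise; contains
    tone without white noise; neither), per-rat distraction probabilities are
    computed per class, and the classes compared with a one-way
    repeated-measures ANOVA.  Rats missing a class are excluded.
    """
    import warnings as _warnings

    classes = ["white_noise", "tone", "other"]
    rows = []
    for rat_trials in trials_by_rat:
        probs = {}
        for cls in classes:
            sub = [t for t in rat_trials if classify_stimulus(t.event.stimulus_label) == cls]
            if sub:
                probs[cls] = sum(t.distracted for t in sub) / len(sub)
        if len(probs) == len(classes):
            rows.append([probs[c] for c in classes])
        else:
            _warnings.warn("rat excluded: no trials in some stimulus class")
    if len(rows) < 3:
        raise InvalidInputError("fewer than 3 rats with all stimulus classes")
    return one_way_rm_anova(np.asarray(rows), classes)
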