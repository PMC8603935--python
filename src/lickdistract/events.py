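"""Lick-train event detection and distraction classification.

A rat licking for a palatable solution emits "bursts" of licks at ~7 Hz
separated by pauses.  In the distraction task a 1 s audiovisual distractor is
delivered whenever the animal makes a short burst of licks (3-5 consecutive
licks within 1 s) after having paused for more than 1 s; the trial is scored
as *distracted* when the pause in licking that follows the distractor exceeds
1 s.  This module implements that trigger rule offline, the distracted/not
classification, and the lick-microstructure summaries built on top of them
(pre-distractor pauses, peri-event lick rates, tercile splits, pause ECDFs).

All times are seconds from session start; histogram bins are half-open
``[t, t + width)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from statsmodels.distributions.empirical_distribution import ECDF

__all__ = [
    "LickTrain",
    "DistractorEvent",
    "Trial",
    "TriggerParams",
    "STIMULUS_LABELS",
    "detect_trigger_events",
    "classify_distraction",
    "pre_distractor_pause",
    "build_trials",
    "distraction_probability",
    "peri_event_lick_rate",
    "tercile_groups",
    "pause_ecdf",
]

#: Closed vocabulary of distractor stimulus labels.  Single components plus
#: the audio-visual combinations actually deliverable by the rig.
STIMULUS_LABELS = (
    "light",
    "flashing_light",
    "tone",
    "white_noise",
    "light_tone",
    "light_white_noise",
    "flashing_light_tone",
    "flashing_light_white_noise",
)


class InvalidInputError(ValueError):
    """Raised when an operation receives structurally invalid input."""


@dataclass(frozen=True)
class TriggerParams:
    """Parameters of the closed-loop distractor trigger rule.

    Attributes
    ----------
    burst_min_licks : int
        Number of consecutive licks that must fall inside ``burst_window``
        for the trigger to fire (the rig's "3 consecutive licks within 1 s").
    burst_window : float
        Window, in seconds, spanned by those licks.
    eligibility_pause : float
        Pause (s) that must precede a burst before a new distractor may be
        delivered; also the inter-lick interval that terminates a burst.
    distraction_threshold : float
        Post-distractor pause (s) above which the trial is scored distracted
        (strictly greater than).
    """

    burst_min_licks: int = 3
    burst_window: float = 1.0
    eligibility_pause: float = 1.0
    distraction_threshold: float = 1.0

    def __post_init__(self) -> None:
        if self.burst_min_licks < 2:
            raise InvalidInputError("burst_min_licks must be >= 2")
        for name in ("burst_window", "eligibility_pause", "distraction_threshold"):
            if getattr(self, name) <= 0:
                raise InvalidInputError(f"{name} must be strictly positive")


@dataclass
class LickTrain:
    """Sorted lick onsets (and optional offsets) for one session."""

    onsets: np.ndarray
    offsets: Optional[np.ndarray] = None
    session_end: float = 3600.0

    def __post_init__(self) -> None:
        onsets = np.asarray(self.onsets, dtype=float)
        if onsets.ndim != 1:
            raise InvalidInputError("onsets must be a 1-D array")
        if np.any(np.diff(onsets) < 0):
            raise InvalidInputError("lick onsets must be sorted increasing")
        # duplicate timestamps (lickometer chatter) are collapsed to one
        if onsets.size and np.any(np.diff(onsets) == 0):
            warnings.warn("duplicate lick timestamps collapsed", stacklevel=2)
            keep = np.concatenate([[True], np.diff(onsets) > 0])
            onsets = onsets[keep]
            if self.offsets is not None:
                self.offsets = np.asarray(self.offsets, dtype=float)[keep]
        if onsets.size and (onsets[0] < 0 or onsets[-1] > self.session_end):
            raise InvalidInputError("lick onsets must lie in [0, session_end]")
        if self.offsets is not None:
            offsets = np.asarray(self.offsets, dtype=float)
            if offsets.shape != onsets.shape:
                raise InvalidInputError("offsets must match onsets in length")
            if np.any(offsets < onsets):
                raise InvalidInputError("each offset must be >= its onset")
            self.offsets = offsets
        self.onsets = onsets

    def __len__(self) -> int:
        return self.onsets.size


@dataclass(frozen=True)
class DistractorEvent:
    """One distractor presentation, real or modelled (virtual)."""

    time: float
    stimulus_label: Optional[str] = None
    modelled: bool = False

    def __post_init__(self) -> None:
        if self.stimulus_label is not None and self.stimulus_label not in STIMULUS_LABELS:
            raise InvalidInputError(
                f"unknown stimulus label {self.stimulus_label!r}; "
                f"expected one of {STIMULUS_LABELS}"
            )


@dataclass
class Trial:
    """One distractor trial with its surrounding pause structure."""

    event: DistractorEvent
    post_pause: float
    distracted: bool
    pre_pause: Optional[float] = None
    burst_position: Optional[int] = None
    censored_post: bool = False
    censored_pre: bool = False
    prior_event_in_baseline: bool = False


def _burst_slices(onsets: np.ndarray, eligibility_pause: float) -> list[slice]:
    """Maximal runs of licks whose every inter-lick interval <= eligibility_pause."""
    if onsets.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(onsets) > eligibility_pause) + 1
    edges = np.concatenate([[0], breaks, [onsets.size]])
    return [slice(a, b) for a, b in zip(edges[:-1], edges[1:])]


def detect_trigger_events(
    licks: LickTrain, params: TriggerParams = TriggerParams()
) -> list[tuple[float, int]]:
    """Apply the closed-loop trigger rule offline to a lick train.

    A burst is a maximal run of licks with every inter-lick interval
    <= ``eligibility_pause``; every burst is preceded by a qualifying pause
    (or session start) by construction.  Within a burst the trigger fires at
    the first lick ``j`` (1-based within the burst, ``j >= burst_min_licks``)
    whose span over the previous ``burst_min_licks`` licks fits inside
    ``burst_window``.  After a trigger no further trigger can occur until an
    inter-lick interval > ``eligibility_pause`` has elapsed, so at most one
    trigger fires per burst.

    Returns
    -------
    list of (time, burst_position)
        Trigger times in increasing order; ``burst_position`` is the 1-based
        index of the triggering lick within its burst.
    """
    onsets = licks.onsets
    m = params.burst_min_licks
    out: list[tuple[float, int]] = []
    for sl in _burst_slices(onsets, params.eligibility_pause):
        run = onsets[sl]
        if run.size < m:
            continue
        spans = run[m - 1 :] - run[: run.size - m + 1]
        hit = np.flatnonzero(spans <= params.burst_window)
        if hit.size:
            j = hit[0] + m  # 1-based position of the triggering lick
            out.append((float(run[j - 1]), int(j)))
    return out


def classify_distraction(
    licks: LickTrain, event_time: float, threshold: float = 1.0
) -> tuple[float, bool, bool]:
    """Post-distractor pause and the distracted/not call for one event.

    Returns ``(post_pause, distracted, censored)``.  When no lick follows the
    event the pause is censored at ``session_end - event_time`` and the trial
    counts as distracted (the animal never resumed licking).
    """
    if event_time > licks.session_end:
        raise InvalidInputError("event_time lies after session_end")
    idx = np.searchsorted(licks.onsets, event_time, side="right")
    if idx >= len(licks):
        return float(licks.session_end - event_time), True, True
    post_pause = float(licks.onsets[idx] - event_time)
    return post_pause, post_pause > threshold, False


def pre_distractor_pause(
    licks: LickTrain,
    event_time: float,
    params: TriggerParams = TriggerParams(),
) -> tuple[float, bool]:
    """Pause preceding the burst that triggered the event at ``event_time``.

    The pause runs from the last lick before the triggering burst to the
    burst's first lick.  If the burst is the session's first licking the
    pause is measured from session start and flagged censored.
    """
    onsets = licks.onsets
    slices = _burst_slices(onsets, params.eligibility_pause)
    idx = np.searchsorted(onsets, event_time, side="right") - 1
    if idx < 0:
        raise InvalidInputError("no lick at or before event_time")
    for sl in slices:
        if sl.start <= idx < sl.stop:
            burst_start = onsets[sl.start]
            if sl.start == 0:
                return float(burst_start), True
            return float(burst_start - onsets[sl.start - 1]), False
    raise AssertionError("unreachable: every lick belongs to a burst")


def build_trials(
    licks: LickTrain,
    events: Sequence[DistractorEvent],
    params: TriggerParams = TriggerParams(),
) -> list[Trial]:
    """Assemble one :class:`Trial` per event, preserving event order.

    ``burst_position`` is filled from the offline trigger scan when the event
    time coincides with a detected trigger; externally supplied events that do
    not line up with any trigger keep ``burst_position=None``.
    ``prior_event_in_baseline`` flags trials with another event inside the
    5 s pre-event baseline.
    """
    times = [ev.time for ev in events]
    if any(b < a for a, b in zip(times, times[1:])):
        raise InvalidInputError("events must be sorted by time")
    trig = {round(t, 9): pos for t, pos in detect_trigger_events(licks, params)}
    trials: list[Trial] = []
    prev_time: Optional[float] = None
    for ev in events:
        post, distracted, cens_post = classify_distraction(
            licks, ev.time, params.distraction_threshold
        )
        try:
            pre, cens_pre = pre_distractor_pause(licks, ev.time, params)
        except InvalidInputError:
            pre, cens_pre = None, True
        trials.append(
            Trial(
                event=ev,
                post_pause=post,
                distracted=distracted,
                pre_pause=pre,
                burst_position=trig.get(round(ev.time, 9)),
                censored_post=cens_post,
                censored_pre=cens_pre,
                prior_event_in_baseline=(
                    prev_time is not None and ev.time - prev_time < 5.0
                ),
            )
        )
        prev_time = ev.time
    return trials


def distraction_probability(trials: Sequence[Trial]) -> float:
    """Proportion of trials scored distracted (censored trials included)."""
    if not trials:
        raise InvalidInputError("distraction_probability of an empty trial list")
    return sum(t.distracted for t in trials) / len(trials)


def peri_event_lick_rate(
    licks: LickTrain,
    event_times: Sequence[float],
    window: tuple[float, float] = (-5.0, 15.0),
    bin_width: float = 1.0,
) -> np.ndarray:
    """Trials x bins matrix of lick rates (licks/s) around each event.

    Events whose window extends beyond the session are dropped with a
    warning.  Bins are half-open ``[t, t + bin_width)`` relative to the event.
    """
    lo, hi = window
    n_bins = int(round((hi - lo) / bin_width))
    edges = lo + bin_width * np.arange(n_bins + 1)
    rows = []
    dropped = 0
    for t in event_times:
        if t + lo < 0 or t + hi > licks.session_end:
            dropped += 1
            continue
        counts, _ = np.histogram(licks.onsets - t, bins=edges)
        rows.append(counts / bin_width)
    if dropped:
        warnings.warn(f"dropped {dropped} event(s) whose window exceeds the session")
    return np.array(rows).reshape(-1, n_bins)


def tercile_groups(trials: Sequence[Trial]) -> tuple[list[Trial], list[Trial], list[Trial]]:
    """Split trials (chronological order) into three contiguous terciles.

    With remainder ``r`` after division by 3, the first ``r`` groups receive
    one extra trial.
    """
    n = len(trials)
    if n < 3:
        raise InvalidInputError("need at least 3 trials for terciles")
    base, r = divmod(n, 3)
    sizes = [base + (1 if i < r else 0) for i in range(3)]
    out, i = [], 0
    for s in sizes:
        out.append(list(trials[i : i + s]))
        i += s
    return tuple(out)


def pause_ecdf(pauses: Sequence[float]) -> ECDF:
    """Empirical CDF of pause durations (censored values enter at their bound)."""
    pauses = np.asarray(pauses, dtype=float)
    if pauses.size == 0:
        raise InvalidInputError("pause_ecdf of an empty vector")
    return ECDF(pauses)
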