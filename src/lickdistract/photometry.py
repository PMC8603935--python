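"""Two-channel fibre-photometry processing.

The recording carries two demodulated streams: a calcium-modulated channel
(470 nm excitation, sensitive to GCaMP fluorescence) and an isosbestic
channel (405 nm, insensitive to calcium).  Bleaching and motion artifacts are
shared between channels, so regressing the isosbestic onto the calcium
channel and taking the fractional residual,

    dFF = (ca - fitted) / fitted,      fitted = slope * iso + intercept,

removes them while preserving calcium transients.  Corrected traces are cut
into peri-event snips, optionally z-scored to a pre-event baseline, and
reduced to 1 s bins or epoch means for statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .events import InvalidInputError

__all__ = [
    "PhotometrySession",
    "CorrectedTrace",
    "SnipMatrix",
    "EPOCHS_TEXT",
    "EPOCHS_CAPTION",
    "correct_isosbestic",
    "extract_snips",
    "zscore_snips",
    "bin_snips",
    "epoch_means",
    "session_rms",
]

#: Default analysis epochs (s, relative to the event): baseline, the period
#: immediately after the distractor, and the sustained period.
EPOCHS_TEXT = {"pre": (-5.0, -1.0), "early_post": (1.0, 4.0), "late_post": (5.0, 15.0)}
#: Alternative epoch boundaries used by some panels (1-3 s / 4-15 s).
EPOCHS_CAPTION = {"pre": (-5.0, -1.0), "early_post": (1.0, 3.0), "late_post": (4.0, 15.0)}


@dataclass
class PhotometrySession:
    """Paired calcium/isosbestic streams for one session.

    ``t0_offset`` places sample 0 on the behavioural clock: sample ``i`` was
    acquired at ``t0_offset + i / fs`` seconds of session time.
    """

    fs: float
    ca: np.ndarray
    iso: np.ndarray
    t0_offset: float = 0.0

    def __post_init__(self) -> None:
        self.ca = np.asarray(self.ca, dtype=float)
        self.iso = np.asarray(self.iso, dtype=float)
        if self.ca.shape != self.iso.shape or self.ca.ndim != 1:
            raise InvalidInputError("ca and iso must be 1-D arrays of equal length")
        if self.fs <= 0:
            raise InvalidInputError("fs must be positive")
        if not (np.all(np.isfinite(self.ca)) and np.all(np.isfinite(self.iso))):
            raise InvalidInputError("photometry samples must be finite")

    @property
    def duration(self) -> float:
        return len(self.ca) / self.fs


@dataclass
class CorrectedTrace:
    """Isosbestic-corrected dF/F trace with the fit coefficients."""

    dff: np.ndarray
    fs: float
    fit_slope: float
    fit_intercept: float
    t0_offset: float = 0.0


@dataclass
class SnipMatrix:
    """Event-aligned trials x samples matrix.

    Row ``i`` spans ``[event_i + window[0], event_i + window[1])`` at ``fs``
    samples/s.  ``event_index`` maps each retained row back to its position
    in the original event list (rows are dropped when an event's window falls
    outside the recording, or when a baseline has zero variance during
    z-scoring).
    """

    data: np.ndarray
    fs: float
    window: tuple[float, float] = (-5.0, 15.0)
    normalized: bool = False
    baseline_window: tuple[float, float] = (-5.0, 0.0)
    event_index: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        expected = int(round((self.window[1] - self.window[0]) * self.fs))
        if self.data.size and self.data.shape[1] != expected:
            raise InvalidInputError(
                f"snip length {self.data.shape[1]} != (post-pre)*fs = {expected}"
            )
        if self.event_index.size == 0 and self.data.size:
            self.event_index = np.arange(self.data.shape[0])

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def time_axis(self) -> np.ndarray:
        """Sample-centre times relative to the event."""
        n = self.data.shape[1]
        return self.window[0] + (np.arange(n) + 0.5) / self.fs


def correct_isosbestic(session: PhotometrySession) -> CorrectedTrace:
    """Fit the isosbestic channel to the calcium channel and take dF/F.

    An ordinary least-squares fit of ``iso`` onto ``ca`` over the full
    session estimates how shared structure (bleaching, motion) appears in
    the calcium channel; the fractional residual is the corrected signal.
    """
    iso, ca = session.iso, session.ca
    var = np.var(iso)
    if var == 0:
        raise InvalidInputError("isosbestic channel is constant; fit is degenerate")
    slope = np.cov(iso, ca, bias=True)[0, 1] / var
    intercept = float(np.mean(ca) - slope * np.mean(iso))
    fitted = slope * iso + intercept
    if np.any(fitted <= 0):
        raise InvalidInputError(
            "fitted reference crosses zero; re-baseline the raw channels "
            "before correction"
        )
    return CorrectedTrace(
        dff=(ca - fitted) / fitted,
        fs=session.fs,
        fit_slope=float(slope),
        fit_intercept=intercept,
        t0_offset=session.t0_offset,
    )


def extract_snips(
    trace: CorrectedTrace,
    event_times: Sequence[float],
    window: tuple[float, float] = (-5.0, 15.0),
    target_fs: float = 10.0,
) -> SnipMatrix:
    """Cut peri-event snips, decimating to ``target_fs`` by block averaging.

    Events whose window extends beyond the recording are dropped (their
    original indices are simply absent from ``event_index``).
    """
    if target_fs > trace.fs:
        raise InvalidInputError("target_fs must not exceed the acquisition rate")
    factor = trace.fs / target_fs
    if abs(factor - round(factor)) > 1e-9:
        raise InvalidInputError("fs must be an integer multiple of target_fs")
    factor = int(round(factor))
    n_raw = int(round((window[1] - window[0]) * trace.fs))
    n_out = n_raw // factor
    rows, kept = [], []
    n_samples = trace.dff.size
    dropped = 0
    for i, t in enumerate(event_times):
        start = int(round((t + window[0] - trace.t0_offset) * trace.fs))
        if start < 0 or start + n_raw > n_samples:
            dropped += 1
            continue
        seg = trace.dff[start : start + n_raw]
        rows.append(seg.reshape(n_out, factor).mean(axis=1))
        kept.append(i)
    if dropped:
        warnings.warn(f"dropped {dropped} event(s) outside the recorded window")
    data = np.array(rows).reshape(-1, n_out)
    return SnipMatrix(
        data=data,
        fs=target_fs,
        window=window,
        event_index=np.asarray(kept, dtype=int),
    )


def zscore_snips(
    snips: SnipMatrix, baseline: tuple[float, float] = (-5.0, 0.0)
) -> SnipMatrix:
    """Z-score each snip to its own pre-event baseline.

    Rows whose baseline has zero variance cannot be normalised and are
    dropped with a warning.
    """
    lo, hi = baseline
    if lo < snips.window[0] or hi > snips.window[1]:
        raise InvalidInputError("baseline must lie within the snip window")
    t = snips.time_axis()
    mask = (t >= lo) & (t < hi)
    base = snips.data[:, mask]
    mu = base.mean(axis=1, keepdims=True)
    sd = base.std(axis=1, ddof=0, keepdims=True)
    ok = sd[:, 0] > 0
    if not np.all(ok):
        warnings.warn(f"dropped {int((~ok).sum())} snip(s) with zero baseline SD")
    data = (snips.data[ok] - mu[ok]) / sd[ok]
    return SnipMatrix(
        data=data,
        fs=snips.fs,
        window=snips.window,
        normalized=True,
        baseline_window=baseline,
        event_index=snips.event_index[ok],
    )


def bin_snips(snips: SnipMatrix, bin_width: float = 1.0) -> np.ndarray:
    """Per-trial mean within each half-open ``bin_width`` s bin."""
    per_bin = bin_width * snips.fs
    if abs(per_bin - round(per_bin)) > 1e-9:
        raise InvalidInputError("bin_width must be an integer number of samples")
    per_bin = int(round(per_bin))
    n_bins = snips.data.shape[1] // per_bin
    return snips.data[:, : n_bins * per_bin].reshape(-1, n_bins, per_bin).mean(axis=2)


def epoch_means(
    snips: SnipMatrix, epochs: Optional[dict[str, tuple[float, float]]] = None
) -> dict[str, np.ndarray]:
    """Per-trial mean signal in each named epoch.

    Epochs must be non-overlapping and lie inside the snip window.  Returns
    a dict mapping epoch name to a length-``n_trials`` vector; averaging
    those per rat/condition yields the values entered into the
    repeated-measures contrasts.
    """
    if epochs is None:
        epochs = EPOCHS_TEXT
    spans = sorted(epochs.values())
    for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
        if b0 < a1:
            raise InvalidInputError("epochs must not overlap")
    lo, hi = snips.window
    t = snips.time_axis()
    out = {}
    for name, (e0, e1) in epochs.items():
        if e0 < lo or e1 > hi:
            raise InvalidInputError(f"epoch {name!r} lies outside the snip window")
        mask = (t >= e0) & (t < e1)
        out[name] = snips.data[:, mask].mean(axis=1)
    return out


def session_rms(trace: CorrectedTrace) -> float:
    """Root-mean-square of the corrected (non-z-scored) signal."""
    if trace.dff.size == 0:
        raise InvalidInputError("empty trace")
    return float(np.sqrt(np.mean(trace.dff**2)))
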