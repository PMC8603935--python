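"""Reading and writing the package's on-disk session formats.

Behavioural events travel as long-format CSV with columns
``rat_id, session_id, event_type, time_s, stimulus_label, modelled`` where
``event_type`` is one of ``lick_on``, ``lick_off``, ``distractor``.
Photometry travels as HDF5 (datasets ``/ca`` and ``/iso``, file attributes
``fs`` and ``t0_offset``) with a CSV fallback (columns
``time_s, ca, iso``).
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence

import h5py
import numpy as np
import pandas as pd

from .events import DistractorEvent, InvalidInputError, LickTrain
from .photometry import PhotometrySession

__all__ = [
    "write_behavior_csv",
    "read_behavior_csv",
    "write_photometry_h5",
    "read_photometry_h5",
    "write_photometry_csv",
    "read_photometry_csv",
]

BEHAVIOR_COLUMNS = ["rat_id", "session_id", "event_type", "time_s", "stimulus_label", "modelled"]


def write_behavior_csv(
    path: str | Path,
    rat_id: str,
    session_id: str,
    licks: LickTrain,
    events: Sequence[DistractorEvent] = (),
) -> None:
    """Write one session's licks and distractors as long-format CSV."""
    rows = []
    for i, t in enumerate(licks.onsets):
        rows.append((rat_id, session_id, "lick_on", t, "", 0))
        if licks.offsets is not None:
            rows.append((rat_id, session_id, "lick_off", licks.offsets[i], "", 0))
    for ev in events:
        rows.append(
            (rat_id, session_id, "distractor", ev.time, ev.stimulus_label or "", int(ev.modelled))
        )
    df = pd.DataFrame(rows, columns=BEHAVIOR_COLUMNS)
    df = df.sort_values("time_s", kind="stable")
    df.to_csv(path, index=False, float_format="%.9f")


def read_behavior_csv(
    path: str | Path, session_end: float = 3600.0
) -> tuple[LickTrain, list[DistractorEvent], str, str]:
    """Read a behavioural session CSV back into domain objects.

    Returns ``(licks, events, rat_id, session_id)``.  Schema violations
    raise a descriptive error naming the file and offending row.
    """
    df = pd.read_csv(path, dtype={"stimulus_label": str}, keep_default_na=False)
    missing = set(BEHAVIOR_COLUMNS) - set(df.columns)
    if missing:
        raise InvalidInputError(f"{path}: missing columns {sorted(missing)}")
    bad = ~df["event_type"].isin(["lick_on", "lick_off", "distractor"])
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise InvalidInputError(
            f"{path}: row {row + 2}: unknown event_type {df['event_type'].iloc[row]!r}"
        )
    onsets = df.loc[df.event_type == "lick_on", "time_s"].to_numpy(dtype=float)
    if np.any(np.diff(onsets) < 0):
        row = int(np.flatnonzero(np.diff(onsets) < 0)[0])
        raise InvalidInputError(f"{path}: lick onsets not sorted at lick index {row + 1}")
    offs = df.loc[df.event_type == "lick_off", "time_s"].to_numpy(dtype=float)
    licks = LickTrain(
        onsets=onsets,
        offsets=offs if offs.size == onsets.size else None,
        session_end=max(session_end, float(df["time_s"].max())) if len(df) else session_end,
    )
    events = [
        DistractorEvent(
            time=float(r.time_s),
            stimulus_label=(r.stimulus_label or None),
            modelled=bool(int(r.modelled)),
        )
        for r in df[df.event_type == "distractor"].itertuples()
    ]
    rat_id = str(df["rat_id"].iloc[0]) if len(df) else ""
    session_id = str(df["session_id"].iloc[0]) if len(df) else ""
    return licks, events, rat_id, session_id


def write_photometry_h5(path: str | Path, session: PhotometrySession) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("ca", data=session.ca, dtype="float64")
        f.create_dataset("iso", data=session.iso, dtype="float64")
        f.attrs["fs"] = session.fs
        f.attrs["t0_offset"] = session.t0_offset


def read_photometry_h5(path: str | Path) -> PhotometrySession:
    with h5py.File(path, "r") as f:
        return PhotometrySession(
            fs=float(f.attrs["fs"]),
            ca=f["ca"][:],
            iso=f["iso"][:],
            t0_offset=float(f.attrs.get("t0_offset", 0.0)),
        )


def write_photometry_csv(path: str | Path, session: PhotometrySession) -> None:
    t = session.t0_offset + np.arange(len(session.ca)) / session.fs
    pd.DataFrame({"time_s": t, "ca": session.ca, "iso": session.iso}).to_csv(
        path, index=False, float_format="%.9f"
    )


def read_photometry_csv(path: str | Path) -> PhotometrySession:
    df = pd.read_csv(path)
    for col in ("time_s", "ca", "iso"):
        if col not in df.columns:
            raise InvalidInputError(f"{path}: missing column {col!r}")
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) < 2:
        raise InvalidInputError(f"{path}: need at least two samples")
    dt = np.diff(t)
    if np.ptp(dt) > 1e-6:
        raise InvalidInputError(f"{path}: time axis is not uniformly sampled")
    return PhotometrySession(
        fs=1.0 / float(np.mean(dt)),
        ca=df["ca"].to_numpy(dtype=float),
        iso=df["iso"].to_numpy(dtype=float),
        t0_offset=float(t[0]),
    )
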