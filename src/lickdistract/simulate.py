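"""Closed-loop synthetic sessions with ground truth.

Licking is modelled as an alternating burst/pause renewal process: burst
lengths are geometric (plus a minimum of one lick), intra-burst inter-lick
intervals are lognormal around 140 ms (~7 Hz licking), and inter-burst
pauses are lognormal with a median of a few seconds.  While licks are
emitted the generator runs the distractor trigger rule *online*, exactly as
the rig did: when a burst of ``burst_min_licks`` licks lands inside the
trigger window, a distractor is delivered at that lick.  With probability
``p_distract`` the animal responds: the burst is interrupted and the next
pause is drawn from a long-pause distribution truncated above the 1 s
distraction criterion; otherwise licking continues per the baseline model
(so a "not distracted by chance" long pause can still occur when the
trigger happens to land on a burst's last lick).

Photometry is simulated as a shared double-exponential bleaching envelope
plus shared motion artifacts on both channels, with calcium-channel-only
event-locked transients (difference-of-exponentials kernel, GCaMP6s-like
rise ~0.2 s / decay ~1.5 s) and independent per-channel noise.

Everything is driven by a single seed: identical config + seed gives
byte-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Optional

import numpy as np

from .events import (
    DistractorEvent,
    InvalidInputError,
    LickTrain,
    STIMULUS_LABELS,
    TriggerParams,
)
from .photometry import PhotometrySession

__all__ = [
    "SyntheticConfig",
    "GroundTruthManifest",
    "generate_session",
    "generate_photometry",
    "fixture_suite",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator parameters for one synthetic session.

    Lick microstructure defaults give ~7 Hz licking in bursts of ~20 licks
    separated by ~5 s pauses; under the default trigger rule roughly one
    distractor is delivered per burst cycle (~8 s), and the spontaneous
    chance of a long pause right after a trigger (the trigger landing on a
    burst's last lick) is a few percent, matching the low modelled-day
    distraction probabilities seen in this task.
    """

    seed: int = 0
    session_length: float = 3600.0
    deliver_distractors: bool = True

    # lick microstructure
    intra_burst_ili_median: float = 0.14   # s; lognormal median, ~7 Hz
    intra_burst_ili_sigma: float = 0.25    # lognormal shape
    burst_length_p: float = 0.05           # geometric; mean length 1 + (1-p)/p
    inter_burst_pause_median: float = 5.0  # s
    inter_burst_pause_sigma: float = 0.6

    # distraction response
    p_distract: float = 0.5
    distracted_pause_median: float = 5.0   # s; truncated below at >1 s
    distracted_pause_sigma: float = 0.8

    # photometry
    fs: float = 100.0
    iso_level: float = 2.0                 # V, pre-bleach isosbestic level
    ca_slope: float = 1.5                  # shared-structure gain in ca channel
    ca_offset: float = 0.5                 # V
    bleach_amp1: float = 0.4               # V, fast bleaching component
    bleach_tau1: float = 300.0             # s
    bleach_amp2: float = 0.2               # V, slow component
    bleach_tau2: float = 2500.0            # s
    artifact_rate: float = 0.01            # Hz, shared motion artifacts
    artifact_amp: float = 0.15             # V
    artifact_tau: float = 0.5              # s
    noise_sd_ca: float = 0.005             # V per sample
    noise_sd_iso: float = 0.005
    kernel_rise: float = 0.2               # s, GCaMP6s-like
    kernel_decay: float = 1.5              # s
    amplitude_distracted: float = 0.30     # V at transient peak
    amplitude_not_distracted: float = 0.15

    def validate(self) -> None:
        if not 0.0 <= self.p_distract <= 1.0:
            raise InvalidInputError("p_distract must be in [0, 1]")
        if self.intra_burst_ili_median > 1.0:
            raise InvalidInputError(
                "intra-burst ILI median > 1 s makes trigger bursts impossible"
            )
        for name in (
            "session_length", "intra_burst_ili_median", "intra_burst_ili_sigma",
            "inter_burst_pause_median", "inter_burst_pause_sigma",
            "distracted_pause_median", "distracted_pause_sigma", "fs",
            "bleach_tau1", "bleach_tau2", "kernel_rise", "kernel_decay",
            "noise_sd_ca", "noise_sd_iso",
        ):
            if getattr(self, name) <= 0:
                raise InvalidInputError(f"{name} must be strictly positive")
        if not 0.0 < self.burst_length_p <= 1.0:
            raise InvalidInputError("burst_length_p must be in (0, 1]")
        if self.fs < 5.0 / self.kernel_decay:
            raise InvalidInputError("fs too low to resolve the transient kernel")


@dataclass
class GroundTruthManifest:
    """What the generator actually did, for parameter-recovery tests."""

    event_times: list[float] = field(default_factory=list)
    stimulus_labels: list[str] = field(default_factory=list)
    true_distracted: list[bool] = field(default_factory=list)
    transient_amplitudes: list[float] = field(default_factory=list)
    params: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruthManifest":
        return cls(**json.loads(text))


def _lognormal(rng: np.random.Generator, median: float, sigma: float) -> float:
    return float(np.exp(np.log(median) + sigma * rng.standard_normal()))


def generate_session(
    config: SyntheticConfig,
    params: TriggerParams = TriggerParams(),
    rng: Optional[np.random.Generator] = None,
) -> tuple[LickTrain, list[DistractorEvent], GroundTruthManifest]:
    """Simulate one session of closed-loop licking and distractor delivery.

    The online trigger state is the same streaming form of the offline rule
    in :func:`~lickdistract.events.detect_trigger_events`, so running the
    offline detector on the emitted lick train reproduces the delivered
    distractor log exactly.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    T = config.session_length
    licks: list[float] = []
    manifest = GroundTruthManifest(params={**asdict(config)})
    events: list[DistractorEvent] = []

    # streaming trigger state: current run of licks with ILIs <= eligibility
    run: list[float] = []
    fired = False

    t = _lognormal(rng, config.inter_burst_pause_median, config.inter_burst_pause_sigma)
    while t < T:
        n_burst = 1 + int(rng.geometric(config.burst_length_p))
        interrupted = False
        for i in range(n_burst):
            if t >= T:
                break
            licks.append(t)
            if run and t - run[-1] > params.eligibility_pause:
                run = [t]
                fired = False
            else:
                run.append(t)
            m = params.burst_min_licks
            if (
                config.deliver_distractors
                and not fired
                and len(run) >= m
                and run[-1] - run[-m] <= params.burst_window
            ):
                fired = True
                label = str(rng.choice(STIMULUS_LABELS))
                gate = bool(rng.random() < config.p_distract)
                events.append(DistractorEvent(time=t, stimulus_label=label))
                manifest.event_times.append(t)
                manifest.stimulus_labels.append(label)
                manifest.true_distracted.append(gate)
                manifest.transient_amplitudes.append(
                    config.amplitude_distracted if gate else config.amplitude_not_distracted
                )
                if gate:
                    # interrupted burst: long pause, truncated above 1 s
                    while True:
                        pause = _lognormal(
                            rng, config.distracted_pause_median, config.distracted_pause_sigma
                        )
                        if pause > params.distraction_threshold:
                            break
                    t += pause
                    interrupted = True
                    break
            if i < n_burst - 1:
                t += _lognormal(
                    rng, config.intra_burst_ili_median, config.intra_burst_ili_sigma
                )
        if not interrupted:
            t += _lognormal(
                rng, config.inter_burst_pause_median, config.inter_burst_pause_sigma
            )
    train = LickTrain(onsets=np.asarray(licks), session_end=T)
    return train, events, manifest


def _transient_kernel(fs: float, rise: float, decay: float, length: float = 10.0) -> np.ndarray:
    """Difference-of-exponentials kernel normalised to unit peak."""
    t = np.arange(0.0, length, 1.0 / fs)
    k = (1.0 - np.exp(-t / rise)) * np.exp(-t / decay)
    return k / k.max()


def generate_photometry(
    events: list[DistractorEvent],
    manifest: GroundTruthManifest,
    config: SyntheticConfig,
    rng: Optional[np.random.Generator] = None,
) -> PhotometrySession:
    """Simulate the paired calcium/isosbestic streams for a session.

    Both channels share the bleaching envelope and motion artifacts (the
    calcium channel scaled by ``ca_slope``); only the calcium channel gets
    event-locked transients, scaled per trial by the manifest amplitude.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    n = int(round(config.session_length * config.fs))
    t = np.arange(n) / config.fs
    bleach = (
        config.bleach_amp1 * np.exp(-t / config.bleach_tau1)
        + config.bleach_amp2 * np.exp(-t / config.bleach_tau2)
    )
    shared = config.iso_level + bleach
    n_art = rng.poisson(config.artifact_rate * config.session_length)
    art_times = np.sort(rng.uniform(0.0, config.session_length, size=n_art))
    art = np.zeros(n)
    art_kernel_len = int(round(6 * config.artifact_tau * config.fs))
    art_kernel = config.artifact_amp * np.exp(
        -np.arange(art_kernel_len) / (config.artifact_tau * config.fs)
    )
    for at in art_times:
        sign = 1.0 if rng.random() < 0.5 else -1.0
        i0 = int(round(at * config.fs))
        seg = art_kernel[: max(0, min(art_kernel_len, n - i0))]
        art[i0 : i0 + seg.size] += sign * seg
    shared = shared + art

    transients = np.zeros(n)
    kernel = _transient_kernel(config.fs, config.kernel_rise, config.kernel_decay)
    amps = manifest.transient_amplitudes or [0.0] * len(events)
    for ev, amp in zip(events, amps):
        i0 = int(round(ev.time * config.fs))
        seg = kernel[: max(0, min(kernel.size, n - i0))]
        transients[i0 : i0 + seg.size] += amp * seg

    iso = shared + config.noise_sd_iso * rng.standard_normal(n)
    ca = (
        config.ca_slope * shared
        + config.ca_offset
        + transients
        + config.noise_sd_ca * rng.standard_normal(n)
    )
    if np.any(iso <= 0) or np.any(ca <= 0):
        raise InvalidInputError("generated channels must be strictly positive")
    return PhotometrySession(fs=config.fs, ca=ca, iso=iso, t0_offset=0.0)


#: (session_id, deliver, p_distract) for the standard three-day protocol:
#: lick training (modelled distractors only), first distraction day, and a
#: habituation day with a lower response probability, unchanged amplitudes.
DAY_PLAN = (
    ("lick", False, 0.0),
    ("distraction", True, 0.5),
    ("habituation", True, 0.25),
)


def fixture_suite(
    out_dir: str | Path,
    n_rats: int = 6,
    base_seed: int = 2021,
    session_length: float = 3600.0,
    fs: float = 100.0,
    write_photometry: bool = True,
) -> dict:
    """Write a deterministic multi-rat, three-day synthetic study to disk.

    Produces, per rat and day, a behavioural events CSV, a photometry HDF5
    file, and a ground-truth manifest JSON, in the package's standard
    formats.  Returns the study index dict that was written to
    ``study.json``.
    """
    from . import io as ld_io

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(base_seed)
    index: dict = {"rats": {}, "base_seed": base_seed}
    for r, rat_ss in enumerate(ss.spawn(n_rats)):
        rat_id = f"rat{r:02d}"
        index["rats"][rat_id] = {}
        for (day, deliver, p), day_ss in zip(DAY_PLAN, rat_ss.spawn(len(DAY_PLAN))):
            seed = int(day_ss.generate_state(1)[0] % (2**31))
            cfg = SyntheticConfig(
                seed=seed,
                session_length=session_length,
                deliver_distractors=deliver,
                p_distract=p,
                fs=fs,
            )
            train, events, manifest = generate_session(cfg)
            base = out_dir / f"{rat_id}_{day}"
            ld_io.write_behavior_csv(
                base.with_suffix(".csv"), rat_id, day, train, events
            )
            entry = {"behavior": base.name + ".csv", "manifest": base.name + ".json"}
            if write_photometry:
                phot = generate_photometry(events, manifest, cfg)
                ld_io.write_photometry_h5(base.with_suffix(".h5"), phot)
                entry["photometry"] = base.name + ".h5"
            base.with_suffix(".json").write_text(manifest.to_json())
            index["rats"][rat_id][day] = entry
    (out_dir / "study.json").write_text(json.dumps(index, indent=1))
    return index
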