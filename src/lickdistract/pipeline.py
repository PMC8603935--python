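"""Study assembly and the full analysis battery.

A *study* is a set of rats each recorded over a standard three-day
protocol: a lick-training day with no stimuli (on which *modelled*
distractors are computed offline by applying the trigger rule to the lick
train), a first distraction day, and a habituation day.  The full analysis
reproduces the task's panel set: distraction probability and
log-transformed pauses across days, pooled lick-rate ROC for distracted vs
not-distracted trials, photometry ROC panels (modelled vs real, distracted
vs not, day 1 vs day 2 overall and split by trial class), epoch
repeated-measures ANOVAs, and the supplementary battery (terciles,
stimulus-class contrast, non-z-scored epochs, session RMS, baseline
activity, pause-activity correlation).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import io as ld_io
from .events import (
    DistractorEvent,
    InvalidInputError,
    LickTrain,
    Trial,
    TriggerParams,
    build_trials,
    detect_trigger_events,
    distraction_probability,
    peri_event_lick_rate,
    tercile_groups,
)
from .photometry import (
    EPOCHS_CAPTION,
    EPOCHS_TEXT,
    PhotometrySession,
    SnipMatrix,
    bin_snips,
    correct_isosbestic,
    epoch_means,
    extract_snips,
    session_rms,
    zscore_snips,
)
from .stats import (
    RocBinResult,
    StatResult,
    binwise_roc,
    log_pause_contrast,
    one_way_rm_anova,
    paired_t,
    pause_activity_correlation,
    stimulus_type_contrast,
    two_way_rm_anova,
)

__all__ = ["StudyConfig", "SessionData", "Study", "AnalysisReport", "load_study", "run_full_analysis"]

DAY_LICK, DAY_DISTRACTION, DAY_HABITUATION = "lick", "distraction", "habituation"


@dataclass
class StudyConfig:
    """Analysis configuration; defaults reproduce the main-text choices."""

    trigger: TriggerParams = field(default_factory=TriggerParams)
    epoch_set: str = "text"            # "text" (-5..-1/1..4/5..15) or "caption" (1..3/4..15)
    roc_method: str = "mannwhitney"    # or "ttest", "permutation"
    alpha: float = 0.05
    window: tuple[float, float] = (-5.0, 15.0)
    bin_width: float = 1.0
    target_fs: float = 10.0
    exclude_censored_pauses: bool = True   # from pause-duration statistics
    exclude_baseline_overlap: bool = False # trials with a prior event in the 5 s baseline
    seed: int = 0

    @property
    def epochs(self) -> dict[str, tuple[float, float]]:
        return EPOCHS_TEXT if self.epoch_set == "text" else EPOCHS_CAPTION

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        trig = TriggerParams(**raw.pop("trigger", {}))
        if "window" in raw:
            raw["window"] = tuple(raw["window"])
        return cls(trigger=trig, **raw)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SessionData:
    """One rat-day: behaviour, optional photometry, optional ground truth."""

    rat_id: str
    session_id: str
    licks: LickTrain
    events: list[DistractorEvent]
    photometry: Optional[PhotometrySession] = None
    manifest: Optional[dict] = None


@dataclass
class Study:
    sessions: dict[str, dict[str, SessionData]]  # rat_id -> day -> data

    @property
    def rats(self) -> list[str]:
        return sorted(self.sessions)

    def day(self, rat: str, day: str) -> SessionData:
        return self.sessions[rat][day]


@dataclass
class AnalysisReport:
    """All panel tables plus the inferential results, keyed by analysis name."""

    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    stats: dict[str, StatResult] = field(default_factory=dict)
    roc: dict[str, RocBinResult] = field(default_factory=dict)
    config: Optional[dict] = None

    def to_dir(self, out_dir: str | Path) -> None:
        """Write tidy CSV tables and a JSON manifest of the test results."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in self.tables.items():
            df.to_csv(out / f"{name}.csv", index=False)
        for name, r in self.roc.items():
            r.to_frame().to_csv(out / f"roc_{name}.csv", index=False)
        manifest = {
            "config": self.config,
            "stats": {
                name: {
                    "test": s.name,
                    "statistic": s.statistic,
                    "df": list(s.df),
                    "p": s.pvalue,
                    "correction": s.correction,
                }
                for name, s in self.stats.items()
            },
        }
        (out / "report.json").write_text(json.dumps(manifest, indent=1, default=float))


def load_study(study_dir: str | Path, config: Optional[StudyConfig] = None) -> Study:
    """Load a study written by :func:`~lickdistract.simulate.fixture_suite`.

    Reads ``study.json`` for the session index, then each behavioural CSV,
    photometry HDF5 and manifest.  Basic integrity (lick ordering, channel
    lengths) is enforced by the domain constructors at load time.
    """
    study_dir = Path(study_dir)
    index = json.loads((study_dir / "study.json").read_text())
    sessions: dict[str, dict[str, SessionData]] = {}
    for rat_id, days in index["rats"].items():
        sessions[rat_id] = {}
        for day, entry in days.items():
            licks, events, rat, sess = ld_io.read_behavior_csv(study_dir / entry["behavior"])
            phot = None
            if "photometry" in entry and (study_dir / entry["photometry"]).exists():
                phot = ld_io.read_photometry_h5(study_dir / entry["photometry"])
            manifest = None
            if "manifest" in entry and (study_dir / entry["manifest"]).exists():
                manifest = json.loads((study_dir / entry["manifest"]).read_text())
            sessions[rat_id][day] = SessionData(
                rat_id=rat_id, session_id=day, licks=licks, events=events,
                photometry=phot, manifest=manifest,
            )
    return Study(sessions=sessions)


# ---------------------------------------------------------------------------
# helpers


def _day_trials(data: SessionData, config: StudyConfig) -> list[Trial]:
    """Trials for one session; on the no-stimulus day, modelled distractors."""
    if data.events:
        events = data.events
    else:
        events = [
            DistractorEvent(time=t, modelled=True)
            for t, _ in detect_trigger_events(data.licks, config.trigger)
        ]
    trials = build_trials(data.licks, events, config.trigger)
    if config.exclude_baseline_overlap:
        trials = [t for t in trials if not t.prior_event_in_baseline]
    return trials


def _pause_values(trials: list[Trial], config: StudyConfig) -> np.ndarray:
    pauses = [
        t.post_pause
        for t in trials
        if not (config.exclude_censored_pauses and t.censored_post)
    ]
    return np.asarray(pauses, dtype=float)


def _zsnips(data: SessionData, times: list[float], config: StudyConfig) -> Optional[SnipMatrix]:
    if data.photometry is None:
        return None
    trace = correct_isosbestic(data.photometry)
    snips = extract_snips(trace, times, window=config.window, target_fs=config.target_fs)
    return zscore_snips(snips)


def _raw_snips(data: SessionData, times: list[float], config: StudyConfig) -> Optional[SnipMatrix]:
    if data.photometry is None:
        return None
    trace = correct_isosbestic(data.photometry)
    return extract_snips(trace, times, window=config.window, target_fs=config.target_fs)


def _epoch_rat_means(
    snips: SnipMatrix, config: StudyConfig
) -> dict[str, float]:
    per_trial = epoch_means(snips, config.epochs)
    return {name: float(v.mean()) for name, v in per_trial.items()}


# ---------------------------------------------------------------------------
# the full battery


def run_full_analysis(study: Study, config: Optional[StudyConfig] = None) -> AnalysisReport:
    """Run the complete behavioural + photometry analysis on a study.

    Sessions without photometry yield a behavioural-only report with a
    warning.  Every table carries (rat, session) keys so each row is
    traceable to its source.
    """
    if config is None:
        config = StudyConfig()
    report = AnalysisReport(config=config.to_dict())
    days = [DAY_LICK, DAY_DISTRACTION, DAY_HABITUATION]
    rats = study.rats

    trials: dict[str, dict[str, list[Trial]]] = {
        rat: {d: _day_trials(study.day(rat, d), config) for d in days if d in study.sessions[rat]}
        for rat in rats
    }
    have_all_days = all(set(days) <= set(trials[rat]) for rat in rats)

    # --- behaviour: probability of distraction by day -----------------------
    rows = []
    for rat in rats:
        for d, tr in trials[rat].items():
            if tr:
                rows.append({"rat_id": rat, "session_id": d,
                             "n_trials": len(tr),
                             "p_distracted": distraction_probability(tr)})
    prob_tbl = pd.DataFrame(rows)
    report.tables["distraction_probability_by_day"] = prob_tbl
    if have_all_days:
        mat = (
            prob_tbl.pivot(index="rat_id", columns="session_id", values="p_distracted")
            .loc[rats, days]
            .to_numpy()
        )
        report.stats["probability_by_day"] = one_way_rm_anova(mat, days)

        # log-transformed post-event pauses across days
        pauses_by_day = [
            [_pause_values(trials[rat][d], config) for rat in rats] for d in days
        ]
        if all(p.size for day in pauses_by_day for p in day):
            report.stats["log_pause_by_day"] = log_pause_contrast(pauses_by_day)

    # pause ECDF points (pooled per day)
    ecdf_rows = []
    for d in days:
        pooled = np.concatenate(
            [_pause_values(trials[rat][d], config) for rat in rats if d in trials[rat]]
            or [np.array([])]
        )
        if pooled.size:
            xs = np.sort(pooled)
            ecdf_rows.append(pd.DataFrame({
                "session_id": d, "pause_s": xs,
                "cum_prob": np.arange(1, xs.size + 1) / xs.size,
            }))
    if ecdf_rows:
        report.tables["pause_ecdf"] = pd.concat(ecdf_rows, ignore_index=True)

    # --- pooled lick-rate ROC: distracted vs not (first distraction day) ----
    lick_mats = {True: [], False: []}
    pre_post_rows = []
    for rat in rats:
        if DAY_DISTRACTION not in trials[rat]:
            continue
        data = study.day(rat, DAY_DISTRACTION)
        for flag in (False, True):
            times = [t.event.time for t in trials[rat][DAY_DISTRACTION] if t.distracted == flag]
            if times:
                mat = peri_event_lick_rate(data.licks, times, config.window, config.bin_width)
                lick_mats[flag].append(mat)
                # per-rat mean rates in the pre (-5..0) and post (+1..+15) epochs
                n_pre = int(round(-config.window[0] / config.bin_width))
                pre_post_rows.append({
                    "rat_id": rat, "distracted": flag,
                    "pre_rate": float(mat[:, :n_pre].mean()),
                    "post_rate": float(mat[:, n_pre + 1:].mean()),
                })
    bin_starts = config.window[0] + config.bin_width * np.arange(
        int(round((config.window[1] - config.window[0]) / config.bin_width))
    )
    if lick_mats[False] and lick_mats[True]:
        report.roc["lickrate_distracted_vs_not"] = binwise_roc(
            np.vstack(lick_mats[False]), np.vstack(lick_mats[True]),
            alpha=config.alpha, bin_starts=bin_starts,
            method=config.roc_method, seed=config.seed,
        )
        pp = pd.DataFrame(pre_post_rows)
        report.tables["lickrate_pre_post"] = pp
        both = pp.pivot(index="rat_id", columns="distracted", values="pre_rate").dropna()
        if len(both) >= 2:
            report.stats["lickrate_pre"] = paired_t(both[True], both[False])
        both = pp.pivot(index="rat_id", columns="distracted", values="post_rate").dropna()
        if len(both) >= 2:
            report.stats["lickrate_post"] = paired_t(both[True], both[False])

    # pre-distractor pauses, distracted vs not (pooled, log-transformed)
    pre_d, pre_nd = [], []
    for rat in rats:
        for t in trials[rat].get(DAY_DISTRACTION, []):
            if t.pre_pause is not None and not t.censored_pre and t.pre_pause > 0:
                (pre_d if t.distracted else pre_nd).append(t.pre_pause)
    if len(pre_d) >= 2 and len(pre_nd) >= 2:
        from scipy import stats as sps

        tt = sps.ttest_ind(np.log(pre_d), np.log(pre_nd), equal_var=False)
        report.stats["pre_pause_distracted_vs_not"] = StatResult(
            name="t", statistic=float(tt.statistic), df=(float(tt.df),),
            pvalue=float(tt.pvalue),
        )
        report.tables["pre_pause_medians"] = pd.DataFrame([
            {"group": "distracted", "median_pre_pause_s": float(np.median(pre_d)), "n": len(pre_d)},
            {"group": "not_distracted", "median_pre_pause_s": float(np.median(pre_nd)), "n": len(pre_nd)},
        ])

    # within-session habituation: probability across terciles (day 1)
    terc_rows = []
    for rat in rats:
        tr = trials[rat].get(DAY_DISTRACTION, [])
        if len(tr) >= 3:
            for i, grp in enumerate(tercile_groups(tr)):
                terc_rows.append({"rat_id": rat, "tercile": i + 1,
                                  "p_distracted": distraction_probability(grp)})
    if terc_rows:
        terc = pd.DataFrame(terc_rows)
        report.tables["tercile_probability"] = terc
        mat = terc.pivot(index="rat_id", columns="tercile", values="p_distracted").dropna()
        if len(mat) >= 3:
            report.stats["tercile_probability"] = one_way_rm_anova(
                mat.to_numpy(), ["t1", "t2", "t3"]
            )

    # distractor-type effectiveness
    by_rat = [trials[rat].get(DAY_DISTRACTION, []) for rat in rats]
    try:
        report.stats["stimulus_type"] = stimulus_type_contrast(by_rat)
    except InvalidInputError:
        pass

    # --- photometry ---------------------------------------------------------
    has_phot = all(
        study.day(rat, d).photometry is not None
        for rat in rats for d in days if d in study.sessions[rat]
    )
    if not has_phot:
        warnings.warn("photometry missing for some sessions; behavioural-only report")
        return report

    zsnips: dict[str, dict[str, SnipMatrix]] = {}
    rawsnips: dict[str, dict[str, SnipMatrix]] = {}
    for rat in rats:
        zsnips[rat], rawsnips[rat] = {}, {}
        for d in trials[rat]:
            times = [t.event.time for t in trials[rat][d]]
            z = _zsnips(study.day(rat, d), times, config)
            r = _raw_snips(study.day(rat, d), times, config)
            if z is not None:
                zsnips[rat][d] = z
            if r is not None:
                rawsnips[rat][d] = r

    def pooled_bins(day: str, flag: Optional[bool] = None, raw: bool = False) -> np.ndarray:
        """Pooled trials x bins matrix for one day, optionally one trial class."""
        mats = []
        src = rawsnips if raw else zsnips
        for rat in rats:
            if day not in src[rat]:
                continue
            sn = src[rat][day]
            binned = bin_snips(sn, config.bin_width)
            if flag is not None:
                tr = trials[rat][day]
                keep = np.array([tr[i].distracted == flag for i in sn.event_index])
                binned = binned[keep]
            if binned.size:
                mats.append(binned)
        return np.vstack(mats) if mats else np.empty((0, len(bin_starts)))

    def roc_panel(name: str, mat_a: np.ndarray, mat_b: np.ndarray) -> None:
        if mat_a.shape[0] >= 2 and mat_b.shape[0] >= 2:
            report.roc[name] = binwise_roc(
                mat_a, mat_b, alpha=config.alpha, bin_starts=bin_starts,
                method=config.roc_method, seed=config.seed,
            )

    roc_panel("phot_modelled_vs_distraction",
              pooled_bins(DAY_LICK), pooled_bins(DAY_DISTRACTION))
    roc_panel("phot_distracted_vs_not",
              pooled_bins(DAY_DISTRACTION, flag=False), pooled_bins(DAY_DISTRACTION, flag=True))
    roc_panel("phot_day1_vs_day2",
              pooled_bins(DAY_DISTRACTION), pooled_bins(DAY_HABITUATION))
    roc_panel("phot_day1_vs_day2_distracted",
              pooled_bins(DAY_DISTRACTION, flag=True), pooled_bins(DAY_HABITUATION, flag=True))
    roc_panel("phot_day1_vs_day2_not_distracted",
              pooled_bins(DAY_DISTRACTION, flag=False), pooled_bins(DAY_HABITUATION, flag=False))

    # epoch summaries and two-way RM-ANOVAs
    epoch_names = list(config.epochs)
    ep_rows = []

    def epoch_matrix(cells: list[tuple[str, Optional[bool]]]) -> Optional[np.ndarray]:
        """subjects x epochs x conditions array of per-rat epoch means."""
        out = np.full((len(rats), len(epoch_names), len(cells)), np.nan)
        for ri, rat in enumerate(rats):
            for ci, (day, flag) in enumerate(cells):
                if day not in zsnips[rat]:
                    return None
                sn = zsnips[rat][day]
                if flag is not None:
                    tr = trials[rat][day]
                    keep = np.array([tr[i].distracted == flag for i in sn.event_index])
                    if not keep.any():
                        return None
                    sn = SnipMatrix(
                        data=sn.data[keep], fs=sn.fs, window=sn.window,
                        normalized=sn.normalized, baseline_window=sn.baseline_window,
                        event_index=sn.event_index[keep],
                    )
                means = _epoch_rat_means(sn, config)
                for ei, name in enumerate(epoch_names):
                    out[ri, ei, ci] = means[name]
                    ep_rows.append({
                        "rat_id": rat, "condition": f"{day}:{flag}",
                        "epoch": name, "mean_z": means[name],
                    })
        return out

    m = epoch_matrix([(DAY_LICK, None), (DAY_DISTRACTION, None)])
    if m is not None:
        report.stats["epoch_x_day"] = two_way_rm_anova(m, epoch_names, ["modelled", "real"])
    m = epoch_matrix([(DAY_DISTRACTION, False), (DAY_DISTRACTION, True)])
    if m is not None:
        report.stats["epoch_x_trialtype"] = two_way_rm_anova(
            m, epoch_names, ["not_distracted", "distracted"]
        )
    report.tables["epoch_summaries"] = pd.DataFrame(ep_rows).drop_duplicates()

    # non-z-scored control: same epoch x trial-type contrast on raw dF/F
    raw_means = np.full((len(rats), len(epoch_names), 2), np.nan)
    ok = True
    for ri, rat in enumerate(rats):
        if DAY_DISTRACTION not in rawsnips[rat]:
            ok = False
            break
        sn = rawsnips[rat][DAY_DISTRACTION]
        tr = trials[rat][DAY_DISTRACTION]
        for ci, flag in enumerate((False, True)):
            keep = np.array([tr[i].distracted == flag for i in sn.event_index])
            if not keep.any():
                ok = False
                break
            sub = SnipMatrix(data=sn.data[keep], fs=sn.fs, window=sn.window,
                             event_index=sn.event_index[keep])
            means = _epoch_rat_means(sub, config)
            for ei, name in enumerate(epoch_names):
                raw_means[ri, ei, ci] = means[name]
    if ok:
        report.stats["epoch_x_trialtype_raw"] = two_way_rm_anova(
            raw_means, epoch_names, ["not_distracted", "distracted"]
        )

    # neural habituation within session: tercile epoch means (early_post)
    terc_neural = np.full((len(rats), 3), np.nan)
    for ri, rat in enumerate(rats):
        if DAY_DISTRACTION not in zsnips[rat]:
            continue
        sn = zsnips[rat][DAY_DISTRACTION]
        if sn.n_trials < 3:
            continue
        groups = np.array_split(np.arange(sn.n_trials), 3)
        sizes = [len(g) for g in groups]  # matches the tercile remainder rule
        start = 0
        for gi, s in enumerate(sizes):
            sub = SnipMatrix(data=sn.data[start:start + s], fs=sn.fs, window=sn.window)
            terc_neural[ri, gi] = _epoch_rat_means(sub, config)["early_post"]
            start += s
    if np.all(np.isfinite(terc_neural)):
        report.stats["tercile_neural"] = one_way_rm_anova(terc_neural, ["t1", "t2", "t3"])

    # session RMS and baseline comparisons between the two distractor days
    rms_rows, base_rows, post_rows = [], [], []
    for rat in rats:
        vals = {}
        for d in (DAY_DISTRACTION, DAY_HABITUATION):
            if d in study.sessions[rat] and study.day(rat, d).photometry is not None:
                vals[d] = session_rms(correct_isosbestic(study.day(rat, d).photometry))
        if len(vals) == 2:
            rms_rows.append({"rat_id": rat, **vals})
        base = {}
        post = {}
        for d in (DAY_DISTRACTION, DAY_HABITUATION):
            if d in rawsnips[rat]:
                means = _epoch_rat_means(rawsnips[rat][d], config)
                base[d] = means["pre"]
                post[d] = means["early_post"]
        if len(base) == 2:
            base_rows.append({"rat_id": rat, **base})
            post_rows.append({"rat_id": rat, **post})
    if len(rms_rows) >= 2:
        df = pd.DataFrame(rms_rows)
        report.tables["session_rms"] = df
        report.stats["rms_day1_vs_day2"] = paired_t(df[DAY_DISTRACTION], df[DAY_HABITUATION])
    if len(base_rows) >= 2:
        df = pd.DataFrame(base_rows)
        report.stats["baseline_raw_day1_vs_day2"] = paired_t(df[DAY_DISTRACTION], df[DAY_HABITUATION])
        df = pd.DataFrame(post_rows)
        report.stats["post_raw_day1_vs_day2"] = paired_t(df[DAY_DISTRACTION], df[DAY_HABITUATION])

    # pause-activity correlation on distracted trials (0-3 s evoked mean)
    pauses, evoked = [], []
    for rat in rats:
        if DAY_DISTRACTION not in zsnips[rat]:
            continue
        sn = zsnips[rat][DAY_DISTRACTION]
        tr = trials[rat][DAY_DISTRACTION]
        t_ax = sn.time_axis()
        mask = (t_ax >= 0.0) & (t_ax < 3.0)
        for row, i in zip(sn.data, sn.event_index):
            if tr[i].distracted and not tr[i].censored_post and tr[i].post_pause > 0:
                pauses.append(tr[i].post_pause)
                evoked.append(float(row[mask].mean()))
    if len(pauses) >= 3:
        try:
            report.stats["pause_activity_correlation"] = pause_activity_correlation(pauses, evoked)
        except InvalidInputError:
            pass

    return report
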