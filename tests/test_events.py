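"""Trigger detection, distraction classification and lick microstructure."""

import numpy as np
import pytest

from lickdistract import (
    DistractorEvent,
    InvalidInputError,
    LickTrain,
    TriggerParams,
    build_trials,
    classify_distraction,
    detect_trigger_events,
    distraction_probability,
    pause_ecdf,
    peri_event_lick_rate,
    pre_distractor_pause,
    tercile_groups,
)
from oracles import brute_force_triggers, random_lick_train


def train(*onsets, session_end=3600.0):
    return LickTrain(onsets=np.array(onsets, dtype=float), session_end=session_end)


class TestDetectTriggerEvents:
    @pytest.mark.parametrize(
        "onsets, expected",
        [
            ([0.0, 0.2, 0.4, 0.6, 3.0], [(0.4, 3)]),       # fires at the 3rd lick
            ([], []),                                        # empty session
            ([0.0, 0.5, 1.2], []),                           # triple spans 1.2 s > 1 s
            ([0.0, 0.2], []),                                # too few licks
            ([0.0, 0.9, 1.7, 1.9], [(1.9, 4)]),              # slow start, fires at 4th
            ([0.0, 0.2, 0.4, 2.0, 2.2, 2.4], [(0.4, 3), (2.4, 3)]),  # one per burst
        ],
    )
    def test_examples(self, onsets, expected):
        got = detect_trigger_events(train(*onsets))
        assert [(pytest.approx(t), p) for t, p in got] == expected

    def test_agrees_with_brute_force_scan(self, rng):
        for _ in range(300):
            onsets = random_lick_train(rng)
            lt = LickTrain(onsets=onsets, session_end=200.0)
            assert detect_trigger_events(lt) == brute_force_triggers(onsets)

    def test_consecutive_triggers_separated_by_long_ili(self, rng):
        """Any two triggers have an inter-lick interval > 1 s between them."""
        for _ in range(100):
            onsets = random_lick_train(rng)
            lt = LickTrain(onsets=onsets, session_end=200.0)
            times = [t for t, _ in detect_trigger_events(lt)]
            for t1, t2 in zip(times, times[1:]):
                between = onsets[(onsets > t1) & (onsets <= t2)]
                ilis = np.diff(np.concatenate([[t1], between]))
                assert np.any(ilis > 1.0)

    def test_unsorted_input_rejected(self):
        with pytest.raises(InvalidInputError):
            LickTrain(onsets=np.array([1.0, 0.5]))

    def test_duplicate_licks_collapsed(self):
        with pytest.warns(UserWarning, match="duplicate"):
            lt = LickTrain(onsets=np.array([0.0, 0.2, 0.2, 0.4]))
        assert len(lt) == 3


class TestClassifyDistraction:
    def test_pause_above_threshold_is_distracted(self):
        lt = train(1.0, 1.2, 1.4, 2.9)  # trigger at 1.4, next lick 1.5 s later
        assert classify_distraction(lt, 1.4) == (pytest.approx(1.5), True, False)

    def test_short_pause_not_distracted(self):
        lt = train(1.0, 1.2, 1.4, 1.7)
        assert classify_distraction(lt, 1.4) == (pytest.approx(0.3), False, False)

    def test_no_subsequent_lick_censored_distracted(self):
        lt = train(1.0, 1.2, 1.4, session_end=41.4)
        pause, distracted, censored = classify_distraction(lt, 1.4)
        assert (pause, distracted, censored) == (pytest.approx(40.0), True, True)

    def test_event_after_session_end_rejected(self):
        with pytest.raises(InvalidInputError):
            classify_distraction(train(1.0), 4000.0)

    def test_monotone_in_threshold(self, rng):
        """Raising the threshold never converts not-distracted to distracted."""
        onsets = random_lick_train(rng)
        lt = LickTrain(onsets=onsets, session_end=200.0)
        for t, _ in detect_trigger_events(lt):
            flags = [classify_distraction(lt, t, thr)[1] for thr in (0.5, 1.0, 2.0, 5.0)]
            assert flags == sorted(flags, reverse=True)


class TestPreDistractorPause:
    def test_pause_before_triggering_burst(self):
        lt = train(5.0, 8.0, 8.2, 8.4)
        assert pre_distractor_pause(lt, 8.4) == (pytest.approx(3.0), False)

    def test_first_burst_censored_at_session_start(self):
        lt = train(12.0, 12.2, 12.4)
        assert pre_distractor_pause(lt, 12.4) == (pytest.approx(12.0), True)

    def test_gap_just_above_eligibility(self):
        lt = train(5.0, 6.001, 6.2, 6.4)
        pre, censored = pre_distractor_pause(lt, 6.4)
        assert pre == pytest.approx(1.001)
        assert not censored


class TestBuildTrials:
    def test_no_events_no_trials(self):
        assert build_trials(train(1.0, 1.2, 1.4), []) == []

    def test_detected_events_have_burst_position(self):
        lt = train(1.0, 1.2, 1.4, 5.0, 5.2, 5.4, 5.6)
        events = [DistractorEvent(time=t) for t, _ in detect_trigger_events(lt)]
        trials = build_trials(lt, events)
        assert len(trials) == 2
        assert all(t.burst_position is not None and t.burst_position >= 3 for t in trials)

    def test_generator_round_trip(self, short_session):
        """Trial fields agree with the generator's ground-truth manifest."""
        _, lt, events, manifest = short_session
        trials = build_trials(lt, events)
        assert [t.event.time for t in trials] == manifest.event_times
        for trial, gate in zip(trials, manifest.true_distracted):
            if gate:  # a gated response forces a pause > 1 s
                assert trial.distracted
        assert all(t.burst_position is not None for t in trials)

    def test_external_event_without_burst_flagged(self):
        lt = train(10.0, 10.2, 10.4)
        trials = build_trials(lt, [DistractorEvent(time=10.3)])
        assert trials[0].burst_position is None


class TestSummaries:
    def test_distraction_probability(self):
        lt = train(*np.arange(10.0))
        trials = [
            build_trials(lt, [DistractorEvent(time=1.0)])[0] for _ in range(10)
        ]
        for t in trials[:7]:
            t.distracted = False
        for t in trials[7:]:
            t.distracted = True
        assert distraction_probability(trials) == pytest.approx(0.3)
        assert distraction_probability(trials[7:]) == 1.0
        with pytest.raises(InvalidInputError):
            distraction_probability([])

    def test_peri_event_lick_rate_counts(self):
        lt = train(10.1, 10.2, 10.9, session_end=100.0)
        mat = peri_event_lick_rate(lt, [10.0])
        assert mat.shape == (1, 20)
        assert mat[0, 5] == pytest.approx(3.0)  # bin [0, 1) holds all three licks
        assert mat[0, [0, 1, 2, 3, 4]].sum() == 0

    def test_no_licks_in_window_gives_zeros(self):
        lt = train(500.0, session_end=1000.0)
        assert np.all(peri_event_lick_rate(lt, [100.0]) == 0)

    def test_translation_equivariance(self):
        lt1 = train(10.1, 10.4, 12.3, session_end=100.0)
        lt2 = train(11.1, 11.4, 13.3, session_end=100.0)
        m1 = peri_event_lick_rate(lt1, [10.0])
        m2 = peri_event_lick_rate(lt2, [10.0])
        assert np.allclose(m1[0, 5:18], m2[0, 6:19])

    def test_out_of_session_events_dropped_with_warning(self):
        lt = train(10.0, session_end=100.0)
        with pytest.warns(UserWarning, match="dropped"):
            mat = peri_event_lick_rate(lt, [2.0, 50.0, 99.0])
        assert mat.shape[0] == 1

    @pytest.mark.parametrize("n, sizes", [(9, (3, 3, 3)), (10, (4, 3, 3)), (11, (4, 4, 3))])
    def test_tercile_sizes(self, n, sizes):
        lt = train(*np.arange(float(n)) * 3, session_end=3600.0)
        trials = build_trials(lt, [DistractorEvent(time=float(i * 3)) for i in range(n)])
        groups = tercile_groups(trials)
        assert tuple(len(g) for g in groups) == sizes
        # chronological and contiguous
        flat = [t for g in groups for t in g]
        assert [t.event.time for t in flat] == sorted(t.event.time for t in flat)

    def test_tercile_too_few_trials(self):
        with pytest.raises(InvalidInputError):
            tercile_groups([None, None])

    def test_pause_ecdf_matches_rank_oracle(self, rng):
        ecdf = pause_ecdf([1.0, 2.0, 3.0])
        assert ecdf(2.0) == pytest.approx(2 / 3)
        x = rng.exponential(2.0, size=57)
        ecdf = pause_ecdf(x)
        grid = np.linspace(0, 10, 101)
        expected = np.array([(np.sort(x) <= g).mean() for g in grid])
        assert np.allclose(ecdf(grid), expected)
        vals = ecdf(np.sort(x))
        assert np.all(np.diff(vals) >= 0) and vals[-1] == 1.0

    def test_pause_ecdf_empty_rejected(self):
        with pytest.raises(InvalidInputError):
            pause_ecdf([])
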