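"""ROC/AUC, repeated-measures contrasts and ancillary tests."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lickdistract import (
    DistractorEvent,
    InvalidInputError,
    LickTrain,
    Trial,
    binwise_roc,
    build_trials,
    log_pause_contrast,
    one_way_rm_anova,
    paired_t,
    pairwise_auc,
    pause_activity_correlation,
    stimulus_type_contrast,
    two_way_rm_anova,
)
from lickdistract.stats import classify_stimulus
from oracles import brute_force_auc, rm_anova_interaction_F, rm_anova_oneway_F


class TestPairwiseAuc:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ([1, 2, 3], [4, 5, 6], 1.0),     # complete separation
            ([1, 2, 3], [1, 2, 3], 0.5),     # identical multisets
            ([1, 3], [2, 4], 0.75),          # 3 of 4 pairs win
            ([1, 1], [1, 1], 0.5),           # all ties count half
        ],
    )
    def test_examples(self, a, b, expected):
        assert pairwise_auc(a, b) == pytest.approx(expected, abs=1e-12)

    def test_matches_brute_force_with_ties(self, rng):
        for _ in range(300):
            na, nb = rng.integers(1, 12, size=2)
            a = rng.integers(0, 5, size=na).astype(float)  # many ties
            b = rng.integers(0, 5, size=nb).astype(float)
            assert pairwise_auc(a, b) == pytest.approx(brute_force_auc(a, b), abs=1e-12)

    @given(
        st.lists(st.integers(0, 6), min_size=1, max_size=10),
        st.lists(st.integers(0, 6), min_size=1, max_size=10),
    )
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_orientation_identity(self, a, b):
        assert pairwise_auc(a, b) + pairwise_auc(b, a) == pytest.approx(1.0, abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(InvalidInputError):
            pairwise_auc([], [1.0])


class TestBinwiseRoc:
    def test_identical_groups_nothing_significant(self, rng):
        mat = rng.standard_normal((10, 20))
        res = binwise_roc(mat, mat.copy())
        assert np.allclose(res.auc, 0.5)
        assert not res.significant.any()

    def test_constructed_separation_localised(self, rng):
        mat_a = rng.standard_normal((30, 20))
        mat_b = rng.standard_normal((30, 20))
        mat_b[:, 6:10] += 10.0
        res = binwise_roc(mat_a, mat_b)
        assert list(np.flatnonzero(res.significant)) == [6, 7, 8, 9]
        assert np.all(res.auc[6:10] == 1.0)

    def test_orientation_identity_per_bin(self, rng):
        a = rng.standard_normal((8, 20))
        b = rng.standard_normal((9, 20))
        r1 = binwise_roc(a, b)
        r2 = binwise_roc(b, a)
        assert np.allclose(r1.auc + r2.auc, 1.0, atol=1e-12)

    def test_bonferroni_and_mask_consistent(self, rng):
        res = binwise_roc(rng.standard_normal((6, 20)), rng.standard_normal((6, 20)) + 1)
        assert np.allclose(res.p_adj, np.minimum(1.0, 20 * res.p_raw))
        assert np.array_equal(res.significant, res.p_adj < res.alpha)
        assert np.all(res.p_adj >= res.p_raw)

    def test_mismatched_bins_rejected(self, rng):
        with pytest.raises(InvalidInputError):
            binwise_roc(rng.standard_normal((5, 20)), rng.standard_normal((5, 19)))

    def test_permutation_and_ttest_agree_on_strong_effect(self, rng):
        a = rng.standard_normal((12, 4))
        b = rng.standard_normal((12, 4)) + 5.0
        for method in ("ttest", "permutation"):
            res = binwise_roc(a, b, method=method, n_perm=400, seed=0)
            assert res.significant.all()


class TestRmAnova:
    def test_identical_columns_F_zero_p_one(self):
        vals = np.tile(np.arange(5.0)[:, None], (1, 3))
        res = one_way_rm_anova(vals)
        assert res.statistic == 0.0
        assert res.pvalue == 1.0

    def test_hand_table_matches_ss_oracle(self):
        vals = np.array([[1.0, 2.0, 4.0], [2.0, 3.0, 5.0], [0.0, 2.0, 3.0], [1.0, 1.0, 4.0]])
        res = one_way_rm_anova(vals)
        assert res.statistic == pytest.approx(rm_anova_oneway_F(vals), abs=1e-8)
        assert res.df == (2, 6)

    def test_random_designs_match_ss_oracle(self, rng):
        for _ in range(50):
            n, k = rng.integers(3, 9), rng.integers(2, 5)
            vals = rng.standard_normal((n, k))
            res = one_way_rm_anova(vals)
            assert res.statistic == pytest.approx(rm_anova_oneway_F(vals), abs=1e-8)

    def test_subject_offset_invariance(self, rng):
        vals = rng.standard_normal((6, 3))
        shifted = vals + rng.standard_normal((6, 1)) * 10
        assert one_way_rm_anova(vals).statistic == pytest.approx(
            one_way_rm_anova(shifted).statistic, abs=1e-8
        )

    def test_posthoc_bonferroni_not_below_raw(self, rng):
        res = one_way_rm_anova(rng.standard_normal((8, 3)))
        assert (res.posthoc["p_adj"] >= res.posthoc["p_raw"] - 1e-15).all()

    def test_missing_cells_rejected(self):
        vals = np.ones((4, 3))
        vals[0, 0] = np.nan
        with pytest.raises(InvalidInputError):
            one_way_rm_anova(vals)


class TestTwoWayRmAnova:
    def test_additive_data_no_interaction(self, rng):
        n, a, b = 6, 3, 2
        subj = rng.standard_normal((n, 1, 1))
        ea = rng.standard_normal((1, a, 1))
        eb = rng.standard_normal((1, 1, b))
        vals = subj + ea + eb  # purely additive
        res = two_way_rm_anova(vals)
        assert res.statistic == pytest.approx(0.0, abs=1e-8)

    def test_crossover_matches_ss_oracle(self, rng):
        vals = rng.standard_normal((3, 3, 2)) * 0.1
        vals[:, 1, 1] += 4.0  # condition effect confined to one epoch
        res = two_way_rm_anova(vals)
        assert res.statistic == pytest.approx(rm_anova_interaction_F(vals), abs=1e-8)
        assert res.statistic > 10
        assert res.df == (2, 4)

    def test_random_designs_match_ss_oracle(self, rng):
        for _ in range(30):
            n, a, b = rng.integers(3, 7), rng.integers(2, 4), rng.integers(2, 4)
            vals = rng.standard_normal((n, a, b))
            res = two_way_rm_anova(vals)
            assert res.statistic == pytest.approx(rm_anova_interaction_F(vals), abs=1e-8)

    def test_sidak_adjustment_closed_form(self, rng):
        res = two_way_rm_anova(rng.standard_normal((5, 3, 2)))
        m = 3  # 3 epochs x 1 condition pair
        expected = 1.0 - (1.0 - res.posthoc["p_raw"]) ** m
        assert np.allclose(res.posthoc["p_adj"], np.minimum(1.0, expected))

    def test_unbalanced_rejected(self):
        vals = np.ones((4, 3, 2))
        vals[2, 1, 0] = np.nan
        with pytest.raises(InvalidInputError):
            two_way_rm_anova(vals)


class TestPairedT:
    def test_identical_vectors(self):
        res = paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0 and res.pvalue == 1.0

    def test_hand_example(self):
        x = np.array([2.0, 4.0, 6.0, 8.0, 10.0])
        y = np.array([1.0, 5.0, 5.0, 7.0, 12.0])
        d = x - y
        t_manual = d.mean() / (d.std(ddof=1) / np.sqrt(5))
        res = paired_t(x, y)
        assert res.statistic == pytest.approx(t_manual, abs=1e-12)
        assert res.df == (4,)

    def test_sign_flip(self, rng):
        x, y = rng.standard_normal(8), rng.standard_normal(8)
        r1, r2 = paired_t(x, y), paired_t(y, x)
        assert r1.statistic == pytest.approx(-r2.statistic, abs=1e-12)
        assert r1.pvalue == pytest.approx(r2.pvalue, abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(InvalidInputError):
            paired_t([1.0, 2.0], [1.0])


class TestAncillary:
    def test_log_pause_equal_days_F_zero(self):
        per_rat = [[2.0, 2.0], [3.0, 3.0], [4.0, 4.0], [5.0, 5.0]]
        pauses = [per_rat, per_rat, per_rat]  # identical across 3 days
        res = log_pause_contrast(pauses)
        assert res.statistic == pytest.approx(0.0, abs=1e-10)

    def test_log_pause_day_effect_detected(self, rng):
        n_rats = 12
        base = [rng.lognormal(1.0, 0.3, size=30) for _ in range(n_rats)]
        scaled = [3.0 * b for b in base]  # large multiplicative day effect
        res = log_pause_contrast([base, scaled, base])
        assert res.pvalue < 0.05

    def test_non_positive_pause_excluded_with_warning(self):
        pauses = [[[1.0, -1.0, 2.0]] * 3] * 3
        with pytest.warns(UserWarning, match="non-positive"):
            log_pause_contrast(pauses)

    def test_correlation_exact_linear(self):
        pauses = np.array([1.0, 2.0, 4.0, 8.0])
        evoked = np.log(pauses) * 2.0 + 1.0
        res = pause_activity_correlation(pauses, evoked)
        assert res.statistic == pytest.approx(1.0)

    def test_correlation_null_within_band(self, rng):
        pauses = rng.lognormal(1.0, 0.5, size=100)
        evoked = rng.standard_normal(100)
        res = pause_activity_correlation(pauses, evoked)
        assert abs(res.statistic) < 1.96 / np.sqrt(97) * 1.5

    def test_correlation_degenerate_rejected(self):
        with pytest.raises(InvalidInputError):
            pause_activity_correlation([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])

    def test_stimulus_classes_partition(self):
        from lickdistract import STIMULUS_LABELS

        classes = [classify_stimulus(lab) for lab in STIMULUS_LABELS]
        assert set(classes) == {"white_noise", "tone", "other"}
        assert all(isinstance(c, str) for c in classes)

    def _trials(self, probs, rng, n=30):
        """Synthetic labelled trials with class-specific distraction rates."""
        lt = LickTrain(onsets=np.arange(0.0, 200.0, 0.5), session_end=3600.0)
        labels = {"white_noise": "light_white_noise", "tone": "light_tone", "other": "light"}
        trials = []
        for cls, p in probs.items():
            for i in range(n):
                tr = build_trials(lt, [DistractorEvent(time=10.0, stimulus_label=labels[cls])])[0]
                tr.distracted = bool(rng.random() < p)
                trials.append(tr)
        return trials

    def test_stimulus_contrast_flat_probabilities(self, rng):
        by_rat = [self._trials({"white_noise": 0.5, "tone": 0.5, "other": 0.5}, rng) for _ in range(6)]
        res = stimulus_type_contrast(by_rat)
        assert res.pvalue > 0.05

    def test_stimulus_contrast_boosted_class_detected(self, rng):
        by_rat = [self._trials({"white_noise": 0.9, "tone": 0.3, "other": 0.3}, rng, n=60) for _ in range(8)]
        res = stimulus_type_contrast(by_rat)
        assert res.pvalue < 0.05
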