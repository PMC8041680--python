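import numpy as np
import pytest

from visearch import (AOILayout, Fixation, Outcome, RejectionReason, Scanpath,
                      SegmentationRules, TrialMeta, detect_fixations,
                      label_fixations, segment_trial, split_fixations_by_trial,
                      tabulate_validity)


@pytest.fixture(scope="module")
def aois(layout):
    return AOILayout.from_task_layout(layout)


def _meta(target=1, resp_t=7000.0, outcome=Outcome.CORRECT, responses=None):
    if responses is None:
        responses = [(resp_t, target)] if outcome is Outcome.CORRECT else []
        if outcome is Outcome.INCORRECT:
            responses = [(resp_t, target + 1)]
        if outcome is Outcome.CORRECTED:
            responses = [(resp_t - 400.0, target + 1), (resp_t, target)]
    return TrialMeta(1, 0.0, 2000.0, target, responses, outcome)


def _path(entries):
    """entries: list of (start, end, label); positions are irrelevant to the
    rules, so labels are attached directly."""
    return Scanpath([Fixation(s, e, 0.0, 0.0) for s, e, _ in entries],
                    [lab for _, _, lab in entries])


def _standard_tail(target="cell_1"):
    """A grid fixation opening the search plus a target fixation (late
    enough that any in-window cue fixation ends before it starts)."""
    return [(3800.0, 4100.0, "cell_4"), (4400.0, 4700.0, target)]


class TestLabelFixations:
    def test_centers_and_background(self, layout, aois):
        cue_c = layout.cue_aoi.center
        cell7_c = layout.grid_aois[6].center
        sp = label_fixations(
            [Fixation(0, 100, *cue_c), Fixation(200, 300, *cell7_c),
             Fixation(400, 500, 10.0, 10.0)], aois)
        assert sp.labels == ["cue", "cell_7", "outside"]

    def test_simulator_labels_recovered(self, td_participant, layout, aois):
        stream, metas, truth = td_participant
        per = split_fixations_by_trial(detect_fixations(stream),
                                       layout.n_trials, layout.trial_duration)
        for fixs, tr in zip(per, truth.trials):
            sp = label_fixations(fixs, aois)
            assert sp.labels == tr.scanpath.labels


class TestCueWindowRule:
    @pytest.mark.parametrize("onset,ok", [
        (1699.0, False), (1700.0, True), (2500.0, True),
        (3300.0, True), (3301.0, False),
    ])
    def test_window_boundaries_closed(self, onset, ok):
        sp = _path([(onset, onset + 400.0, "cue")] + _standard_tail())
        seg = segment_trial(sp, _meta())
        if ok:
            assert seg.valid and seg.encoding_start == onset
        else:
            assert seg.rejection_reason is RejectionReason.NO_CUE_FIXATION_IN_WINDOW

    def test_no_cue_fixation_at_all(self):
        seg = segment_trial(_path(_standard_tail()), _meta())
        assert seg.rejection_reason is RejectionReason.NO_CUE_FIXATION_IN_WINDOW

    def test_qualifies_by_onset_even_if_straddling_window_end(self):
        sp = _path([(3290.0, 4100.0, "cue"), (4200.0, 4400.0, "cell_2"),
                    (4600.0, 4900.0, "cell_1")])
        assert segment_trial(sp, _meta()).valid


class TestPrescanRule:
    def test_one_short_grid_fixation_allowed(self):
        sp = _path([(500.0, 790.0, "cell_3"), (2000.0, 2400.0, "cue")]
                   + _standard_tail())
        assert segment_trial(sp, _meta()).valid

    def test_two_grid_fixations_rejected(self):
        sp = _path([(500.0, 700.0, "cell_3"), (800.0, 1000.0, "cell_5"),
                    (2000.0, 2400.0, "cue")] + _standard_tail())
        seg = segment_trial(sp, _meta())
        assert seg.rejection_reason is RejectionReason.PREMATURE_GRID_SCANNING

    @pytest.mark.parametrize("dur,ok", [(300.0, True), (301.0, False)])
    def test_duration_cap_boundary(self, dur, ok):
        sp = _path([(500.0, 500.0 + dur, "cell_3"), (2000.0, 2400.0, "cue")]
                   + _standard_tail())
        seg = segment_trial(sp, _meta())
        assert seg.valid is ok

    def test_outside_fixations_do_not_count(self):
        sp = _path([(300.0, 900.0, "outside"), (1000.0, 1600.0, "outside"),
                    (2000.0, 2400.0, "cue")] + _standard_tail())
        assert segment_trial(sp, _meta()).valid


class TestRuleOrder:
    def test_outcome_checked_before_window(self):
        """A trial failing several rules carries the first reason only."""
        sp = _path([(100.0, 400.0, "cell_2"), (600.0, 1000.0, "cell_3")])
        seg = segment_trial(sp, _meta(outcome=Outcome.MISSING))
        assert seg.rejection_reason is RejectionReason.MISSING_RESPONSE
        seg = segment_trial(sp, _meta(outcome=Outcome.INCORRECT))
        assert seg.rejection_reason is RejectionReason.INCORRECT_RESPONSE

    def test_window_checked_before_prescan(self):
        sp = _path([(200.0, 600.0, "cell_2"), (700.0, 1100.0, "cell_3"),
                    (3400.0, 3800.0, "cue")] + [(4000.0, 4300.0, "cell_1")])
        seg = segment_trial(sp, _meta())
        assert seg.rejection_reason is RejectionReason.NO_CUE_FIXATION_IN_WINDOW

    def test_corrected_trials_use_final_press(self):
        sp = _path([(2000.0, 2400.0, "cue"), (3000.0, 3300.0, "cell_4"),
                    (3500.0, 3800.0, "cell_1"), (4500.0, 4800.0, "cell_1")])
        meta = _meta(outcome=Outcome.CORRECTED, resp_t=5000.0)
        seg = segment_trial(sp, meta)
        assert seg.valid
        # last target fixation before the final (correct) press at 5000
        assert seg.search_end == 4500.0

    def test_no_target_fixation_before_press(self):
        sp = _path([(2000.0, 2400.0, "cue"), (3000.0, 3300.0, "cell_4")])
        seg = segment_trial(sp, _meta(resp_t=6000.0))
        assert seg.rejection_reason is RejectionReason.NO_SEARCH_END

    def test_press_before_search_onset_rejected(self):
        sp = _path([(2000.0, 2400.0, "cue")] + _standard_tail())
        meta = _meta(resp_t=3200.0)  # press precedes first grid fixation
        seg = segment_trial(sp, meta)
        assert seg.rejection_reason is RejectionReason.NO_SEARCH_END


class TestSegmentsGeometry:
    def test_segments_adjacent_half_open(self):
        sp = _path([(2000.0, 2400.0, "cue"), (2600.0, 2900.0, "cue"),
                    (3100.0, 3400.0, "cell_5"), (3600.0, 4000.0, "cell_1")])
        seg = segment_trial(sp, _meta())
        assert seg.encoding_start == 2000.0
        assert seg.encoding_end == 3100.0  # first grid fixation onset
        assert seg.search_end == 3600.0
        assert seg.encoding_start < seg.encoding_end <= seg.search_end

    def test_simulator_boundaries_match_ground_truth(self, td_participant,
                                                     layout, aois):
        stream, metas, truth = td_participant
        per = split_fixations_by_trial(detect_fixations(stream),
                                       layout.n_trials, layout.trial_duration)
        dt = 1000.0 / stream.sampling_rate
        for fixs, meta, tr in zip(per, metas, truth.trials):
            seg = segment_trial(label_fixations(fixs, aois), meta)
            assert seg.status == tr.expected_status
            if tr.expected_reason is not None:
                assert seg.rejection_reason.value == tr.expected_reason
            if seg.valid:
                assert abs(seg.encoding_start - tr.encoding_start) <= dt
                assert abs(seg.encoding_end - tr.encoding_end) <= dt
                assert abs(seg.search_end - tr.search_end) <= dt


class TestTabulateValidity:
    def test_counts_partition(self, td_participant, layout, aois):
        stream, metas, truth = td_participant
        per = split_fixations_by_trial(detect_fixations(stream),
                                       layout.n_trials, layout.trial_duration)
        segs = [segment_trial(label_fixations(f, aois), m)
                for f, m in zip(per, metas)]
        counts = tabulate_validity(segs)
        assert counts.total == layout.n_trials
        assert counts.missing == sum(1 for t in truth.trials
                                     if t.outcome is Outcome.MISSING)
        assert counts.incorrect == sum(1 for t in truth.trials
                                       if t.outcome is Outcome.INCORRECT)
        assert counts.valid == sum(1 for t in truth.trials
                                   if t.expected_status == "valid")

    def test_all_valid_and_all_missing(self):
        sp_valid = _path([(2000.0, 2400.0, "cue")] + _standard_tail())
        segs = [segment_trial(sp_valid, _meta()) for _ in range(30)]
        c = tabulate_validity(segs)
        assert (c.valid, c.incorrect, c.missing) == (30, 0, 0)
        segs = [segment_trial(sp_valid, _meta(outcome=Outcome.MISSING))
                for _ in range(30)]
        c = tabulate_validity(segs)
        assert (c.valid, c.incorrect, c.missing) == (0, 0, 30)


def test_unsorted_fixations_rejected():
    sp = Scanpath.__new__(Scanpath)  # bypass ordering validation
    sp.fixations = [Fixation(3000.0, 3300.0, 0, 0), Fixation(2000.0, 2400.0, 0, 0)]
    sp.labels = ["cell_1", "cue"]
    with pytest.raises(ValueError, match="sorted"):
        segment_trial(sp, _meta())


def test_unlabeled_scanpath_rejected():
    sp = Scanpath([Fixation(2000.0, 2400.0, 0, 0)])
    with pytest.raises(ValueError, match="label"):
        segment_trial(sp, _meta())


def test_custom_rules_respected():
    rules = SegmentationRules(cue_window_ms=(1000.0, 2000.0))
    sp = _path([(1200.0, 1500.0, "cue")] + _standard_tail())
    assert segment_trial(sp, _meta(), rules).valid
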