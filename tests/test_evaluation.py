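"""Worked examples and invariants for peak extraction, tolerance matching,
overlap metrics and heart-rate agreement."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mhdnet.evaluation import (
    agreement,
    detection_metrics,
    heart_rate_series,
    mask_to_peaks,
    match_peaks,
    paired_heart_rates,
    segmentation_metrics,
)
from mhdnet.exceptions import ContractError
from mhdnet.labeling import peaks_to_pulse_train
from mhdnet.evaluation import MatchResult


class TestMaskToPeaks:
    def test_recovers_pulse_train_centers(self):
        probs = peaks_to_pulse_train([100, 500], 1024).values.astype(float)
        assert mask_to_peaks(probs, fs=1024.0) == [100, 500]

    def test_all_zero_gives_empty(self):
        assert mask_to_peaks(np.zeros(512), fs=1024.0) == []

    def test_short_runs_discarded(self):
        probs = np.zeros(512)
        probs[10:12] = 1.0
        probs[100:102] = 1.0
        assert mask_to_peaks(probs, fs=1024.0, min_run=3) == []

    def test_nearby_runs_merge(self):
        probs = np.zeros(1024)
        probs[100:110] = 0.8
        probs[150:160] = 1.0  # 40 samples (~39 ms) later -> same event
        peaks = mask_to_peaks(probs, fs=1024.0)
        assert len(peaks) == 1
        assert 150 <= peaks[0] < 160  # argmax plateau of the merged run

    def test_peak_is_run_argmax(self):
        probs = np.zeros(512)
        probs[50:60] = 0.6
        probs[55] = 0.9
        assert mask_to_peaks(probs, fs=1024.0) == [55]


class TestMatchPeaks:
    def test_within_tolerance_is_tp(self):
        m = match_peaks([1050], [1000], fs=1024.0)  # 48.8 ms
        assert (m.tp, m.fp, m.fn) == (1, 0, 0)
        assert m.matched_pairs == [(1050, 1000)]

    def test_outside_tolerance_is_fp_and_fn(self):
        m = match_peaks([1100], [1000], fs=1024.0)  # 97.7 ms
        assert (m.tp, m.fp, m.fn) == (0, 1, 1)

    def test_boundary_at_71_samples(self):
        # floor(0.070 * 1024) = 71 samples is the last accepted offset
        assert match_peaks([1071], [1000], fs=1024.0).tp == 1
        assert match_peaks([1072], [1000], fs=1024.0).tp == 0

    def test_missing_prediction_is_fn(self):
        m = match_peaks([], [1000], fs=1024.0)
        assert (m.tp, m.fp, m.fn) == (0, 0, 1)

    def test_one_to_one_matching(self):
        # one prediction may not claim two nearby truths
        m = match_peaks([1000], [995, 1030], fs=1024.0)
        assert (m.tp, m.fp, m.fn) == (1, 0, 1)
        assert m.matched_pairs == [(1000, 995)]

    def test_unsorted_rejected(self):
        with pytest.raises(ValueError):
            match_peaks([5, 3], [1], fs=1024.0)

    @settings(max_examples=50, deadline=None)
    @given(
        pred=st.lists(st.integers(0, 5000), max_size=15),
        truth=st.lists(st.integers(0, 5000), max_size=15),
    )
    def test_count_identities(self, pred, truth):
        pred, truth = sorted(set(pred)), sorted(set(truth))
        m = match_peaks(pred, truth, fs=1024.0)
        assert m.tp == len(m.matched_pairs) <= min(len(pred), len(truth))
        assert m.tp + m.fn == len(truth)
        assert m.tp + m.fp == len(pred)
        for p, t in m.matched_pairs:
            assert abs(p - t) <= 71


class TestSegmentationMetrics:
    def test_identical_masks(self):
        mask = np.zeros(100)
        mask[10:23] = 1
        s = segmentation_metrics(mask, mask)
        assert (s.iou_pct, s.dsc_pct) == (100.0, 100.0)

    def test_half_overlap_worked_example(self):
        pred = np.zeros(100)
        truth = np.zeros(100)
        pred[0:10] = 1
        truth[5:15] = 1  # TP=5 FP=5 FN=5
        s = segmentation_metrics(pred, truth)
        assert s.iou_pct == pytest.approx(33.33, abs=0.005)
        assert s.dsc_pct == pytest.approx(50.00, abs=0.005)

    def test_empty_prediction_scores_zero(self):
        truth = np.zeros(64)
        truth[5:10] = 1
        s = segmentation_metrics(np.zeros(64), truth)
        assert (s.iou_pct, s.dsc_pct) == (0.0, 0.0)

    def test_both_empty_is_perfect(self):
        s = segmentation_metrics(np.zeros(64), np.zeros(64))
        assert (s.iou_pct, s.dsc_pct) == (100.0, 100.0)

    def test_length_mismatch(self):
        with pytest.raises(ContractError):
            segmentation_metrics(np.zeros(64), np.zeros(65))

    @settings(max_examples=100, deadline=None)
    @given(st.integers(0, 2**20 - 1), st.integers(0, 2**20 - 1))
    def test_iou_never_exceeds_dsc(self, a, b):
        pred = np.array([int(c) for c in format(a, "020b")])
        truth = np.array([int(c) for c in format(b, "020b")])
        s = segmentation_metrics(pred, truth)
        assert s.iou_pct <= s.dsc_pct + 1e-12


class TestDetectionMetrics:
    def test_symmetric_example(self):
        d = detection_metrics(MatchResult(tp=99, fp=1, fn=1))
        assert (d.recall_pct, d.precision_pct, d.f1_pct) == (99.0, 99.0, 99.0)

    def test_asymmetric_example(self):
        d = detection_metrics(MatchResult(tp=3, fp=1, fn=0))
        assert d.recall_pct == 100.0
        assert d.precision_pct == 75.0
        assert d.f1_pct == pytest.approx(85.714, abs=5e-4)

    def test_degenerate_counts_warn_and_zero(self):
        with pytest.warns(UserWarning):
            d = detection_metrics(MatchResult(tp=0, fp=0, fn=0))
        assert (d.recall_pct, d.precision_pct, d.f1_pct) == (0.0, 0.0, 0.0)


class TestHeartRate:
    def test_constant_rate(self):
        peaks = list(range(0, 768 * 10, 768))
        assert heart_rate_series(peaks, 1024.0) == pytest.approx([80.0] * 9)

    def test_two_peaks(self):
        assert heart_rate_series([0, 1024], 1024.0) == [60.0]

    def test_single_peak_empty(self):
        assert heart_rate_series([500], 1024.0) == []

    def test_paired_rates_skip_missed_beats(self):
        truth = [0, 1000, 2000, 3000]
        pred = [5, 1010, 2990]  # beat at 2000 missed
        est, act = paired_heart_rates(pred, truth, fs=1024.0)
        assert len(est) == len(act) == 1  # only the 0-1000 interval survives
        assert act[0] == pytest.approx(60.0 * 1024 / 1000)


class TestAgreement:
    def test_identical_series(self):
        a = agreement([60.0, 70.0, 80.0], [60.0, 70.0, 80.0])
        assert a.pcc == pytest.approx(1.0)
        assert (a.bias_bpm, a.loa_low_bpm, a.loa_high_bpm) == (0.0, 0.0, 0.0)

    def test_constant_offset(self):
        a = agreement([62.0, 72.0, 82.0], [60.0, 70.0, 80.0])
        assert a.bias_bpm == pytest.approx(2.0)
        assert a.loa_low_bpm == pytest.approx(2.0)
        assert a.loa_high_bpm == pytest.approx(2.0)
        assert a.pcc == pytest.approx(1.0)

    def test_hand_computed_reference(self):
        est, act = [60.0, 70.0, 80.0], [60.0, 72.0, 78.0]
        # independent hand computation
        d = [e - a for e, a in zip(est, act)]  # 0, -2, 2
        bias = sum(d) / 3
        sd = math.sqrt(sum((x - bias) ** 2 for x in d) / 2)
        me, ma = sum(est) / 3, sum(act) / 3
        num = sum((e - me) * (a - ma) for e, a in zip(est, act))
        den = math.sqrt(
            sum((e - me) ** 2 for e in est) * sum((a - ma) ** 2 for a in act)
        )
        a_stats = agreement(est, act)
        assert a_stats.bias_bpm == pytest.approx(bias)
        assert a_stats.loa_low_bpm == pytest.approx(bias - 1.96 * sd)
        assert a_stats.loa_high_bpm == pytest.approx(bias + 1.96 * sd)
        assert a_stats.pcc == pytest.approx(num / den)
        assert a_stats.loa_low_bpm <= a_stats.bias_bpm <= a_stats.loa_high_bpm

    def test_zero_variance_warns(self):
        with pytest.warns(UserWarning):
            a = agreement([60.0, 60.0], [60.0, 61.0])
        assert math.isnan(a.pcc)


def test_pipeline_round_trip_masks_to_metrics():
    """Pulse train used as its own prediction scores perfectly."""
    peaks = [500, 1500, 2500]
    probs = peaks_to_pulse_train(peaks, 4096).values.astype(float)
    found = mask_to_peaks(probs, fs=1024.0)
    m = match_peaks(found, peaks, fs=1024.0)
    d = detection_metrics(m)
    assert (d.recall_pct, d.precision_pct, d.f1_pct) == (100.0, 100.0, 100.0)
    with warnings.catch_warnings():
        warnings.simplefilter("error")
        s = segmentation_metrics(probs >= 0.5, probs >= 0.5)
    assert s.dsc_pct == 100.0
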