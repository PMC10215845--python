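"""Scoring: mask -> peaks, tolerance matching, segmentation/detection
metrics, heart-rate series and Bland-Altman agreement.

Two families of metrics are computed. Samplewise segmentation overlap (IoU
and Dice) scores the predicted pulse-train mask against the label mask.
Eventwise detection metrics (recall, precision, F1) score extracted peak
locations: a prediction within 70 ms of an unmatched annotated peak is a
true positive; matching is greedy one-to-one in order of increasing time
error. Heart rate follows from consecutive R-R intervals, and agreement
between estimated and reference heart rate is summarized by Pearson
correlation and Bland-Altman bias with 95% limits of agreement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .exceptions import ContractError

DEFAULT_TOLERANCE_MS = 70.0


@dataclass
class MatchResult:
    tp: int
    fp: int
    fn: int
    matched_pairs: list[tuple[int, int]] = field(default_factory=list)

    def __add__(self, other: "MatchResult") -> "MatchResult":
        return MatchResult(
            tp=self.tp + other.tp,
            fp=self.fp + other.fp,
            fn=self.fn + other.fn,
            matched_pairs=self.matched_pairs + other.matched_pairs,
        )


@dataclass
class SegmentationMetrics:
    iou_pct: float
    dsc_pct: float


@dataclass
class DetectionMetrics:
    recall_pct: float
    precision_pct: float
    f1_pct: float


@dataclass
class AgreementStats:
    pcc: float
    bias_bpm: float
    loa_low_bpm: float
    loa_high_bpm: float


def mask_to_peaks(
    probabilities: np.ndarray,
    fs: float = 1024.0,
    threshold: float = 0.5,
    min_run: int = 3,
    merge_gap_ms: float = 100.0,
) -> list[int]:
    """Extract peak sample indices from a per-sample probability mask.

    Binarize at ``threshold``, drop runs shorter than ``min_run``, merge
    runs separated by less than ``merge_gap_ms``, and report one index per
    remaining run: the center of the run's argmax plateau (the left of the
    two centers when the plateau has even width). For the rectangular
    training labels this recovers the annotated peak exactly.
    """
    p = np.asarray(probabilities, dtype=float)
    mask = p >= threshold
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(len(mask))
    runs = [(s, e) for s, e in zip(starts, ends) if e - s >= min_run]
    if not runs:
        return []
    gap = merge_gap_ms / 1000.0 * fs
    merged = [list(runs[0])]
    for s, e in runs[1:]:
        if s - merged[-1][1] < gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    peaks = []
    for s, e in merged:
        seg = p[s:e]
        top = np.flatnonzero(seg == seg.max())
        # center of the argmax plateau; plateau may be non-contiguous for
        # merged runs, in which case the median index plays the same role
        peaks.append(int(s + top[(len(top) - 1) // 2]))
    return peaks


def match_peaks(
    predicted,
    truth,
    fs: float,
    tolerance_ms: float = DEFAULT_TOLERANCE_MS,
) -> MatchResult:
    """Greedy one-to-one matching within a tolerance window.

    Candidate pairs are considered in order of increasing |Δt| (ties:
    earlier truth peak, then earlier prediction); each peak participates in
    at most one pair. The tolerance in samples is floor(tolerance_ms/1000
    * fs) — 71 samples at 1024 Hz.
    """
    predicted = [int(x) for x in predicted]
    truth = [int(x) for x in truth]
    for name, seq in (("predicted", predicted), ("truth", truth)):
        if any(b < a for a, b in zip(seq, seq[1:])):
            raise ValueError(f"{name} peaks must be sorted")
    tol = int(np.floor(tolerance_ms / 1000.0 * fs))
    candidates = []
    j0 = 0
    for i, t in enumerate(truth):
        for j in range(j0, len(predicted)):
            d = predicted[j] - t
            if d < -tol:
                j0 = j + 1
                continue
            if d > tol:
                break
            candidates.append((abs(d), i, j))
    candidates.sort()
    used_t: set[int] = set()
    used_p: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for _, i, j in candidates:
        if i in used_t or j in used_p:
            continue
        used_t.add(i)
        used_p.add(j)
        pairs.append((predicted[j], truth[i]))
    tp = len(pairs)
    return MatchResult(
        tp=tp,
        fp=len(predicted) - tp,
        fn=len(truth) - tp,
        matched_pairs=sorted(pairs, key=lambda pr: pr[1]),
    )


def segmentation_metrics(
    predicted_mask: np.ndarray, truth_mask: np.ndarray
) -> SegmentationMetrics:
    """Samplewise IoU and Dice, in percent."""
    pm = np.asarray(predicted_mask).astype(bool)
    tm = np.asarray(truth_mask).astype(bool)
    if pm.shape != tm.shape:
        raise ContractError(f"mask shapes differ: {pm.shape} vs {tm.shape}")
    tp = int(np.count_nonzero(pm & tm))
    fp = int(np.count_nonzero(pm & ~tm))
    fn = int(np.count_nonzero(~pm & tm))
    if tp + fp + fn == 0:
        return SegmentationMetrics(iou_pct=100.0, dsc_pct=100.0)
    iou = 100.0 * tp / (tp + fn + fp)
    dsc = 100.0 * 2 * tp / (2 * tp + fn + fp)
    return SegmentationMetrics(iou_pct=iou, dsc_pct=dsc)


def detection_metrics(match: MatchResult) -> DetectionMetrics:
    """Recall, precision and F1 (percent) from tolerance-matched counts."""
    tp, fp, fn = match.tp, match.fp, match.fn
    if min(tp, fp, fn) < 0:
        raise ValueError("negative counts")

    def ratio(num, den, name):
        if den == 0:
            warnings.warn(f"{name}: 0/0 reported as 0")
            return 0.0
        return 100.0 * num / den

    return DetectionMetrics(
        recall_pct=ratio(tp, tp + fn, "recall"),
        precision_pct=ratio(tp, tp + fp, "precision"),
        f1_pct=ratio(tp, tp + 0.5 * (fp + fn), "f1"),
    )


def heart_rate_series(peaks, fs: float) -> list[float]:
    """Instantaneous heart rate (bpm) from consecutive R-R intervals."""
    peaks = list(peaks)
    if len(peaks) < 2:
        return []
    rr = np.diff(np.asarray(peaks, dtype=float))
    return list(60.0 * fs / rr)


def agreement(estimated_bpm, actual_bpm) -> AgreementStats:
    """Pearson correlation and Bland-Altman bias / 95% limits of agreement."""
    est = np.asarray(list(estimated_bpm), dtype=float)
    act = np.asarray(list(actual_bpm), dtype=float)
    if est.shape != act.shape or est.size < 2:
        raise ValueError("need two equal-length series with >= 2 entries")
    if est.std() == 0 or act.std() == 0:
        warnings.warn("zero-variance series; PCC undefined")
        pcc = float("nan")
    else:
        pcc = float(stats.pearsonr(est, act).statistic)
    diff = est - act
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1)) if diff.size > 1 else 0.0
    return AgreementStats(
        pcc=pcc,
        bias_bpm=bias,
        loa_low_bpm=bias - 1.96 * sd,
        loa_high_bpm=bias + 1.96 * sd,
    )


def paired_heart_rates(
    predicted,
    truth,
    fs: float,
    tolerance_ms: float = DEFAULT_TOLERANCE_MS,
) -> tuple[list[float], list[float]]:
    """Paired (estimated, actual) instantaneous HR from matched beats.

    Only R-R intervals whose two bounding truth beats are adjacent in the
    annotation and both matched to predictions contribute, so a missed beat
    drops the two intervals it touches instead of corrupting them.
    """
    res = match_peaks(predicted, truth, fs, tolerance_ms)
    by_truth = dict((t, p) for p, t in res.matched_pairs)
    truth = list(truth)
    est, act = [], []
    for a, b in zip(truth, truth[1:]):
        if a in by_truth and b in by_truth and by_truth[b] > by_truth[a]:
            act.append(60.0 * fs / (b - a))
            est.append(60.0 * fs / (by_truth[b] - by_truth[a]))
    return est, act
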