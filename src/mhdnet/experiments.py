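"""End-to-end experiment drivers: single-split scaled runs and 5-fold
cross-validation.

The scaled run is the package's desk-scale counterpart of the full
protocol: a synthetic cohort (default: five subjects, two 60-s records
each, severe "7T-like" artifact), one subject-wise 3/1/1 train/val/test
split, a reduced model (2 levels, 8 base filters, kernel 11, q=3) trained
for 15 epochs at batch 32, and the full scoring stack on the held-out
subject's records. Within each fold/split, detection and segmentation
counts are micro-aggregated over all test records before ratios are taken;
cross-validation averages the per-fold metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import evaluation as ev
from .exceptions import ConfigurationError
from .labeling import (
    DEFAULT_TRAIN_OVERLAP,
    FoldSplit,
    peaks_to_pulse_train,
    segment_records,
    subject_folds,
)
from .network import ModelConfig, MhdNet, build_variant, scaled_config
from .preprocess import FilterSpec, preprocess_signals
from .signal_io import EcgRecord
from .synthetic import SyntheticConfig, make_synthetic_records, preset
from .training import TrainConfig, TrainHistory, predict_masks, train_model

SCALED_TRAIN = TrainConfig(epochs=15, batch_size=32, learning_rate=1e-3)


def scaled_model_config(variant: str = "self_attention_mhdnet") -> ModelConfig:
    """The reduced architecture used by desk-scale experiments."""
    return scaled_config(build_variant(variant), levels=2, base_filters=8)


@dataclass
class SplitMetrics:
    """Scores of one train/val/test split, micro-aggregated over test records."""

    detection: ev.DetectionMetrics
    segmentation: ev.SegmentationMetrics
    agreement: ev.AgreementStats
    match: ev.MatchResult
    n_test_records: int
    n_test_beats: int
    n_test_samples: int = 0
    n_hr_pairs: int = 0
    per_record_peaks: dict[str, list[int]] = field(default_factory=dict)


def preprocess_records(
    records: list[EcgRecord], spec: FilterSpec = FilterSpec()
) -> list[EcgRecord]:
    out = []
    for r in records:
        out.append(
            EcgRecord(
                record_id=r.record_id,
                subject_id=r.subject_id,
                field_strength=r.field_strength,
                fs=r.fs,
                signals=preprocess_signals(r.signals, r.fs, spec),
                channel_names=r.channel_names,
                r_peaks=r.r_peaks,
            )
        )
    return out


def evaluate_model(
    model: MhdNet,
    test_records: list[EcgRecord],
    window_s: float = 4.0,
    tolerance_ms: float = ev.DEFAULT_TOLERANCE_MS,
    peak_kwargs: dict | None = None,
) -> SplitMetrics:
    """Predict masks on whole test records and score them."""
    peak_kwargs = peak_kwargs or {}
    total_match = ev.MatchResult(0, 0, 0, [])
    pred_masks, true_masks = [], []
    est_hr: list[float] = []
    act_hr: list[float] = []
    per_record_peaks: dict[str, list[int]] = {}
    n_beats = 0
    for rec in test_records:
        probs = predict_masks(rec, model, window_s=window_s)
        peaks = ev.mask_to_peaks(probs, fs=rec.fs, **peak_kwargs)
        per_record_peaks[rec.record_id] = peaks
        total_match = total_match + ev.match_peaks(
            peaks, rec.r_peaks, rec.fs, tolerance_ms
        )
        n = rec.signals.shape[-1]
        pred_masks.append(probs >= 0.5)
        true_masks.append(peaks_to_pulse_train(rec.r_peaks, n).values.astype(bool))
        e, a = ev.paired_heart_rates(peaks, rec.r_peaks, rec.fs, tolerance_ms)
        est_hr += e
        act_hr += a
        n_beats += len(rec.r_peaks)
    seg = ev.segmentation_metrics(
        np.concatenate(pred_masks), np.concatenate(true_masks)
    )
    agr = ev.agreement(est_hr, act_hr) if len(est_hr) >= 2 else ev.AgreementStats(
        float("nan"), float("nan"), float("nan"), float("nan")
    )
    return SplitMetrics(
        detection=ev.detection_metrics(total_match),
        segmentation=seg,
        agreement=agr,
        match=total_match,
        n_test_records=len(test_records),
        n_test_beats=n_beats,
        n_test_samples=sum(len(m) for m in true_masks),
        n_hr_pairs=len(est_hr),
        per_record_peaks=per_record_peaks,
    )


def run_split(
    records: list[EcgRecord],
    train_subjects: set[str],
    val_subjects: set[str],
    test_subjects: set[str],
    model_config: ModelConfig,
    train_config: TrainConfig,
    window_s: float = 4.0,
    train_overlap: float = DEFAULT_TRAIN_OVERLAP,
    filter_spec: FilterSpec = FilterSpec(),
) -> tuple[MhdNet, SplitMetrics, "TrainHistory"]:
    """Preprocess, window, train and score one subject-wise split."""
    groups = {
        "train": [r for r in records if r.subject_id in train_subjects],
        "val": [r for r in records if r.subject_id in val_subjects],
        "test": [r for r in records if r.subject_id in test_subjects],
    }
    for name, grp in groups.items():
        if not grp:
            raise ConfigurationError(f"no records for the {name} subjects")
    clean = {k: preprocess_records(v, filter_spec) for k, v in groups.items()}
    train_seg = segment_records(clean["train"], window_s, train_overlap)
    val_seg = segment_records(clean["val"], window_s, 0.0)
    model, history = train_model(train_seg, val_seg, model_config, train_config)
    metrics = evaluate_model(model, clean["test"], window_s=window_s)
    return model, metrics, history


def default_split(
    records: list[EcgRecord], seed: int
) -> tuple[set[str], set[str], set[str]]:
    """One seeded 3/1/1-style subject split (train gets the remainder)."""
    subjects = sorted({r.subject_id for r in records})
    if len(subjects) < 3:
        raise ConfigurationError("need at least 3 subjects for a 3-way split")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 11]))
    order = [subjects[i] for i in rng.permutation(len(subjects))]
    return set(order[2:]), {order[1]}, {order[0]}


def run_scaled_experiment(
    seed: int = 1,
    preset_name: str = "7T-like",
    variant: str = "self_attention_mhdnet",
    synth_config: SyntheticConfig | None = None,
    train_config: TrainConfig | None = None,
) -> tuple[MhdNet, SplitMetrics, list[EcgRecord]]:
    """The desk-scale end-to-end experiment on synthetic data."""
    cfg = synth_config or preset(preset_name, seed=seed)
    records = make_synthetic_records(cfg)
    tr, va, te = default_split(records, seed)
    tcfg = train_config or SCALED_TRAIN
    tcfg = TrainConfig(
        epochs=tcfg.epochs,
        batch_size=tcfg.batch_size,
        learning_rate=tcfg.learning_rate,
        pos_weight=tcfg.pos_weight,
        seed=seed,
    )
    model, metrics, _history = run_split(
        records, tr, va, te, scaled_model_config(variant), tcfg
    )
    return model, metrics, [r for r in records if r.subject_id in te]


def crossval(
    records: list[EcgRecord],
    model_config: ModelConfig,
    train_config: TrainConfig,
    n_folds: int = 5,
    seed: int = 0,
    window_s: float = 4.0,
) -> tuple[list[SplitMetrics], dict[str, float], FoldSplit]:
    """Full rotation: per round, 3 folds train / 1 validation / 1 test."""
    split = subject_folds(records, n_folds=n_folds, seed=seed)
    fold_metrics: list[SplitMetrics] = []
    for r in range(n_folds):
        tr, va, te = split.round_roles(r)
        _, m, _h = run_split(records, tr, va, te, model_config, train_config, window_s)
        fold_metrics.append(m)
    mean = {
        "recall_pct": float(np.mean([m.detection.recall_pct for m in fold_metrics])),
        "precision_pct": float(
            np.mean([m.detection.precision_pct for m in fold_metrics])
        ),
        "f1_pct": float(np.mean([m.detection.f1_pct for m in fold_metrics])),
        "iou_pct": float(np.mean([m.segmentation.iou_pct for m in fold_metrics])),
        "dsc_pct": float(np.mean([m.segmentation.dsc_pct for m in fold_metrics])),
    }
    return fold_metrics, mean, split
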