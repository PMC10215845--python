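"""Segmentation targets, windowing, and leak-free subject folds.

Each annotated R-peak becomes a rectangular pulse of height 1.0 and width
13 samples (~12.7 ms at 1024 Hz), centered on the annotation; the network
learns to reproduce this pulse train from the 3-lead signal. Records are
cut into fixed 4-s windows — overlapped for training augmentation,
non-overlapping for evaluation — and cross-validation folds are assigned
per subject so no subject's data leaks across folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence
import warnings

import numpy as np

from .exceptions import ConfigurationError

DEFAULT_PULSE_WIDTH = 13
DEFAULT_WINDOW_S = 4.0
DEFAULT_TRAIN_OVERLAP = 0.75


@dataclass
class PulseTrain:
    values: np.ndarray  # binary {0,1}, length n_samples
    pulse_width: int = DEFAULT_PULSE_WIDTH


@dataclass
class SegmentSet:
    """Parallel lists of (3 x window_len) inputs and binary targets."""

    inputs: list[np.ndarray] = field(default_factory=list)
    targets: list[np.ndarray] = field(default_factory=list)
    subject_ids: list[str] = field(default_factory=list)
    window_len: int = 4096
    stride: int = 4096

    def __len__(self) -> int:
        return len(self.inputs)

    def extend(self, other: "SegmentSet") -> None:
        if other.window_len != self.window_len:
            raise ConfigurationError(
                f"window_len mismatch: {other.window_len} vs {self.window_len}"
            )
        self.inputs.extend(other.inputs)
        self.targets.extend(other.targets)
        self.subject_ids.extend(other.subject_ids)

    @property
    def subjects(self) -> set[str]:
        return set(self.subject_ids)


@dataclass
class FoldSplit:
    n_folds: int
    assignment: dict[str, int]

    def subjects_in_fold(self, fold: int) -> list[str]:
        return sorted(s for s, f in self.assignment.items() if f == fold)

    def round_roles(self, round_index: int) -> tuple[set[str], set[str], set[str]]:
        """(train, val, test) subject sets for one rotation round.

        Round r tests on fold r, validates on fold (r+1) mod n, trains on
        the rest.
        """
        test_fold = round_index % self.n_folds
        val_fold = (round_index + 1) % self.n_folds
        train, val, test = set(), set(), set()
        for s, f in self.assignment.items():
            if f == test_fold:
                test.add(s)
            elif f == val_fold:
                val.add(s)
            else:
                train.add(s)
        return train, val, test


def peaks_to_pulse_train(
    peaks: Sequence[int], n_samples: int, pulse_width: int = DEFAULT_PULSE_WIDTH
) -> PulseTrain:
    """Rectangular pulses of the given width centered on each peak.

    Pulses are clipped at record boundaries; pulses from peaks closer than
    the width merge into one run.
    """
    values = np.zeros(n_samples, dtype=np.int8)
    half = pulse_width // 2
    prev = -1
    for p in peaks:
        p = int(p)
        if not (0 <= p < n_samples):
            raise ValueError(f"peak {p} outside [0, {n_samples})")
        if p < prev:
            raise ValueError("peaks must be sorted")
        prev = p
        values[max(0, p - half) : min(n_samples, p + half + 1)] = 1
    return PulseTrain(values=values, pulse_width=pulse_width)


def segment_record(
    record,
    window_s: float = DEFAULT_WINDOW_S,
    overlap_frac: float = 0.0,
    pulse_width: int = DEFAULT_PULSE_WIDTH,
) -> SegmentSet:
    """Cut a record into fixed windows paired with pulse-train target slices."""
    if not (0 <= overlap_frac < 1):
        raise ValueError(f"overlap_frac must be in [0, 1), got {overlap_frac}")
    window_len = int(round(window_s * record.fs))
    stride = int(round(window_len * (1.0 - overlap_frac)))
    n = record.signals.shape[-1]
    out = SegmentSet(window_len=window_len, stride=stride)
    if n < window_len:
        warnings.warn(
            f"record {record.record_id}: length {n} shorter than one "
            f"{window_len}-sample window; empty segment set"
        )
        return out
    train = peaks_to_pulse_train(record.r_peaks, n, pulse_width).values
    n_windows = (n - window_len) // stride + 1
    for i in range(n_windows):
        lo = i * stride
        hi = lo + window_len
        out.inputs.append(record.signals[:, lo:hi])
        out.targets.append(train[lo:hi])
        out.subject_ids.append(record.subject_id)
    return out


def segment_records(
    records: Iterable,
    window_s: float = DEFAULT_WINDOW_S,
    overlap_frac: float = 0.0,
    pulse_width: int = DEFAULT_PULSE_WIDTH,
) -> SegmentSet:
    out: SegmentSet | None = None
    for rec in records:
        seg = segment_record(rec, window_s, overlap_frac, pulse_width)
        if out is None:
            out = seg
        else:
            out.extend(seg)
    if out is None:
        raise ConfigurationError("no records supplied")
    return out


def subject_folds(records: Sequence, n_folds: int = 5, seed: int = 0) -> FoldSplit:
    """Deterministic balanced subject partition: seeded shuffle, round-robin."""
    subjects = sorted({r.subject_id for r in records})
    if len(subjects) < n_folds:
        raise ConfigurationError(
            f"{len(subjects)} distinct subjects < {n_folds} folds"
        )
    rng = np.random.default_rng(seed)
    order = [subjects[i] for i in rng.permutation(len(subjects))]
    return FoldSplit(
        n_folds=n_folds,
        assignment={s: i % n_folds for i, s in enumerate(order)},
    )
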