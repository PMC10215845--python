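"""Cleaning of MHD-corrupted ECG: bandpass, powerline notch, normalization.

All filters are applied forward-backward (zero phase), so R-peak timing —
which the segmentation labels encode sample-exactly — is not shifted.
Defaults follow common in-bore ECG practice: a 4th-order Butterworth
bandpass at 0.05–100 Hz and a Q=30 IIR notch at 50 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps


@dataclass(frozen=True)
class FilterSpec:
    low_cut_hz: float = 0.05
    high_cut_hz: float = 100.0
    notch_hz: float = 50.0
    notch_q: float = 30.0
    order: int = 4

    def validate(self, fs: float) -> None:
        nyq = fs / 2.0
        if not (0 < self.low_cut_hz < self.high_cut_hz):
            raise ValueError(
                f"need 0 < low_cut ({self.low_cut_hz}) < high_cut ({self.high_cut_hz})"
            )
        if self.high_cut_hz >= nyq:
            raise ValueError(
                f"high_cut_hz {self.high_cut_hz} must be below Nyquist {nyq}"
            )
        if not (0 < self.notch_hz < nyq):
            raise ValueError(f"notch_hz {self.notch_hz} outside (0, {nyq})")


def bandpass_filter(
    x: np.ndarray, fs: float, spec: FilterSpec = FilterSpec()
) -> np.ndarray:
    """Zero-phase Butterworth bandpass; accepts (n,) or (channels, n)."""
    spec.validate(fs)
    sos = sps.butter(
        spec.order, [spec.low_cut_hz, spec.high_cut_hz], btype="bandpass", fs=fs,
        output="sos",
    )
    return sps.sosfiltfilt(sos, np.asarray(x, dtype=float), axis=-1)


def notch_filter(
    x: np.ndarray, fs: float, spec: FilterSpec = FilterSpec()
) -> np.ndarray:
    """Zero-phase narrowband stop filter at the powerline frequency."""
    spec.validate(fs)
    b, a = sps.iirnotch(spec.notch_hz, spec.notch_q, fs=fs)
    return sps.filtfilt(b, a, np.asarray(x, dtype=float), axis=-1)


def preprocess_signals(
    signals: np.ndarray, fs: float, spec: FilterSpec = FilterSpec()
) -> np.ndarray:
    """Bandpass then notch, the record-level cleaning step."""
    return notch_filter(bandpass_filter(signals, fs, spec), fs, spec)


def normalize_segment(segment: np.ndarray) -> np.ndarray:
    """Per-channel z-score; a constant channel maps to all zeros.

    Accepts (channels, n) or (n,). Amplitude varies strongly between field
    strengths, so each window is standardized independently before the
    network.
    """
    seg = np.asarray(segment, dtype=float)
    squeeze = seg.ndim == 1
    if squeeze:
        seg = seg[None]
    if seg.size == 0:
        raise ValueError("empty segment")
    mu = seg.mean(axis=-1, keepdims=True)
    sd = seg.std(axis=-1, keepdims=True)
    # constant channels: sd may be ~1e-16 instead of 0 from rounding
    live = sd > 1e-12 * np.maximum(1.0, np.abs(mu))
    out = np.where(live, (seg - mu) / np.where(live, sd, 1.0), 0.0)
    return out[0] if squeeze else out
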