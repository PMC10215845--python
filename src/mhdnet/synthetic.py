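"""Synthetic 3-lead ECG with a controllable MHD-like artifact.

The generator provides records with exactly known R-peak times so that the
whole pipeline — labeling, training, peak scoring — can run without any
external recording. A beat is a sum of Gaussian bumps (P, Q, R, S, T) with
fixed relative timings; the static-field artifact is modeled after its
dominant in-bore manifestation: a strongly inflated T wave plus a bowed
ST segment, scaled by ``mhd_severity``. Two presets mirror the qualitative
regimes: ``3T-like`` (T comparable to R) and ``7T-like`` (T exceeds R, so a
naive amplitude detector locks onto T waves). Baseline wander, broadband
noise and a 50 Hz powerline component are added on top, and the single
cardiac/artifact source pair is mixed into three pseudo-leads with distinct
polarities and weights.

Ground truth is exact by construction: the R index of each beat is the
center of the R bump of the clean cardiac source, independent of artifact
severity and noise.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .exceptions import ConfigurationError
from .signal_io import EcgRecord, LIMB_LEADS, write_manifest, write_record

# (amplitude, center offset as fraction of RR, width in seconds)
_BEAT_BUMPS = {
    "P": (0.15, -0.22, 0.025),
    "Q": (-0.12, -0.040, 0.010),
    "R": (1.00, 0.0, 0.012),
    "S": (-0.25, 0.040, 0.012),
    "T": (0.35, 0.32, 0.060),
}
_R_FRACTION = 0.35  # R bump position inside the beat window
_T_GAIN_PER_SEVERITY = 1.0  # T amplitude multiplier is 1 + this * severity
_ST_BOW_AMP_PER_SEVERITY = 0.18

# lead mixing: rows = leads I, II, III; cols = (cardiac source, MHD source)
DEFAULT_LEAD_MIXING = np.array(
    [
        [1.00, 1.00],
        [0.80, 1.25],
        [-0.90, 0.70],
    ]
)


@dataclass(frozen=True)
class SyntheticConfig:
    n_subjects: int = 5
    records_per_subject: int = 2
    duration_s: float = 60.0
    fs: float = 1024.0
    hr_mean_bpm: float = 70.0
    hr_sd_bpm: float = 6.0  # between-subject spread of resting HR
    rr_jitter_frac: float = 0.05  # lognormal sigma of beat-to-beat RR
    mhd_severity: float = 1.0
    baseline_wander_amp: float = 0.25
    noise_sd: float = 0.03
    powerline_amp_50hz: float = 0.05
    lead_mixing: np.ndarray = field(
        default_factory=lambda: DEFAULT_LEAD_MIXING.copy()
    )
    seed: int = 0

    def validate(self) -> None:
        if self.duration_s * self.fs < 4 * self.fs:
            raise ConfigurationError(
                f"duration_s={self.duration_s} shorter than one 4-s window"
            )
        if self.hr_mean_bpm <= 20 or self.hr_mean_bpm >= 200:
            raise ConfigurationError("hr_mean_bpm outside a plausible range")
        if self.mhd_severity < 0:
            raise ConfigurationError("mhd_severity must be >= 0")


def preset(name: str, **overrides) -> SyntheticConfig:
    """Named severity presets for the two static-field regimes."""
    if name == "3T-like":
        cfg = SyntheticConfig(mhd_severity=1.0)
    elif name == "7T-like":
        cfg = SyntheticConfig(mhd_severity=2.0)
    elif name == "clean":
        cfg = SyntheticConfig(
            mhd_severity=0.0,
            baseline_wander_amp=0.0,
            noise_sd=0.0,
            powerline_amp_50hz=0.0,
        )
    else:
        raise ValueError(f"unknown preset {name!r}")
    return replace(cfg, **overrides) if overrides else cfg


def synth_beat(
    fs: float, rr_s: float, mhd_severity: float
) -> tuple[np.ndarray, np.ndarray, int]:
    """One beat: (cardiac vector, artifact vector, true R sample index).

    The cardiac vector is the clean Gaussian-bump beat; the artifact vector
    holds the severity-scaled T-wave excess and ST bowing, kept separate so
    leads can mix the two sources with different weights. The R index is
    the center of the R bump — by construction the argmax of the clean R
    component — and never depends on severity.
    """
    if not (0.3 <= rr_s <= 2.0):
        raise ValueError(f"rr_s {rr_s} outside [0.3, 2.0]")
    n = int(round(rr_s * fs))
    t = np.arange(n) / fs
    r_time = _R_FRACTION * rr_s
    cardiac = np.zeros(n)
    for amp, frac, width in _BEAT_BUMPS.values():
        center = r_time + frac * rr_s
        cardiac += amp * np.exp(-0.5 * ((t - center) / width) ** 2)
    t_amp, t_frac, t_width = _BEAT_BUMPS["T"]
    t_center = r_time + t_frac * rr_s
    artifact = (
        t_amp
        * _T_GAIN_PER_SEVERITY
        * mhd_severity
        * np.exp(-0.5 * ((t - t_center) / t_width) ** 2)
    )
    # bowed ST segment between S and T, widening with severity
    st_center = r_time + 0.5 * t_frac * rr_s
    artifact += (
        _ST_BOW_AMP_PER_SEVERITY
        * mhd_severity
        * np.exp(-0.5 * ((t - st_center) / (2.5 * t_width)) ** 2)
    )
    r_index = int(round(r_time * fs))
    return cardiac, artifact, r_index


def make_synthetic_record(
    config: SyntheticConfig,
    subject_id: str,
    record_id: str,
    hr_mean_bpm: float | None = None,
    amplitude: float = 1.0,
) -> EcgRecord:
    """Deterministic record synthesis under ``config.seed`` + ids."""
    config.validate()
    hr = hr_mean_bpm if hr_mean_bpm is not None else config.hr_mean_bpm
    # per-record substream so different records never share noise
    ss = np.random.SeedSequence(
        [
            config.seed,
            zlib.crc32(subject_id.encode()) % 2**31,
            zlib.crc32(record_id.encode()) % 2**31,
        ]
    )
    rng = np.random.default_rng(ss)
    n_total = int(round(config.duration_s * config.fs))
    cardiac = np.zeros(n_total)
    artifact = np.zeros(n_total)
    r_peaks: list[int] = []
    pos = 0
    rr_base = 60.0 / hr
    while True:
        rr = rr_base * np.exp(config.rr_jitter_frac * rng.standard_normal())
        rr = float(np.clip(rr, 0.3, 2.0))
        beat_c, beat_a, r_idx = synth_beat(config.fs, rr, config.mhd_severity)
        if pos + len(beat_c) > n_total:
            break
        cardiac[pos : pos + len(beat_c)] += amplitude * beat_c
        artifact[pos : pos + len(beat_a)] += amplitude * beat_a
        r_peaks.append(pos + r_idx)
        pos += len(beat_c)

    t = np.arange(n_total) / config.fs
    mix = np.asarray(config.lead_mixing, dtype=float)
    signals = np.empty((3, n_total))
    for lead in range(3):
        x = mix[lead, 0] * cardiac + mix[lead, 1] * artifact
        # baseline wander: two sub-0.5 Hz sinusoids with random phase/freq
        for _ in range(2):
            f0 = rng.uniform(0.05, 0.4)
            phase = rng.uniform(0, 2 * np.pi)
            x = x + config.baseline_wander_amp * 0.5 * np.sin(
                2 * np.pi * f0 * t + phase
            )
        x = x + config.powerline_amp_50hz * np.sin(
            2 * np.pi * 50.0 * t + rng.uniform(0, 2 * np.pi)
        )
        x = x + config.noise_sd * rng.standard_normal(n_total)
        signals[lead] = x

    return EcgRecord(
        record_id=record_id,
        subject_id=subject_id,
        field_strength="synthetic",
        fs=config.fs,
        signals=signals,
        channel_names=LIMB_LEADS,
        r_peaks=r_peaks,
    )


def make_synthetic_records(config: SyntheticConfig) -> list[EcgRecord]:
    """All records of a synthetic cohort, per-subject HR/amplitude drawn
    from seeded ranges."""
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 915]))
    records = []
    for s in range(config.n_subjects):
        subject_id = f"synth{s:03d}"
        hr = float(
            np.clip(
                rng.normal(config.hr_mean_bpm, config.hr_sd_bpm), 45.0, 120.0
            )
        )
        amp = float(rng.uniform(0.8, 1.2))
        for r in range(config.records_per_subject):
            record_id = f"{subject_id}r{r}"
            records.append(
                make_synthetic_record(
                    config, subject_id, record_id, hr_mean_bpm=hr, amplitude=amp
                )
            )
    return records


def make_synthetic_dataset(config: SyntheticConfig, out_dir) -> Path:
    """Write a WFDB + manifest tree that `signal_io.load_dataset` consumes."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in make_synthetic_records(config):
        write_record(rec, out_dir)
        rows.append(
            {
                "record": rec.record_id,
                "subject": rec.subject_id,
                "field_strength": "synthetic",
            }
        )
    return write_manifest(rows, out_dir)
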