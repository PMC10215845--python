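"""Reading and writing ECG records in a WFDB-compatible layout.

Supports the subset of the WFDB family this pipeline needs: format-16
signal files (.dat, 16-bit little-endian two's complement, samples
interleaved across channels), plain-text headers (.hea) and MIT-format
annotation files. Datasets are described by a manifest CSV (one row per
record: ``record,subject,field_strength``) because signal headers do not
carry subject grouping reliably.

All peak locations are 0-based sample indices; time in seconds is
``index / fs``.
"""

from __future__ import annotations

import logging
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import AnnotationError, ConfigurationError, FormatError

logger = logging.getLogger(__name__)

FIELD_STRENGTHS = ("3T", "7T", "synthetic")
LIMB_LEADS = ("I", "II", "III")

# MIT annotation codes treated as beats (NORMAL, LBBB, RBBB, ..., unclassified)
DEFAULT_BEAT_CODES = frozenset(
    {1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 13, 25, 34, 35, 38, 41}
)
_NORMAL_BEAT = 1
_SKIP = 59
_NUM = 60
_SUB = 61
_CHN = 62
_AUX = 63


@dataclass
class AnnotationSet:
    record_id: str
    peak_samples: list[int]
    annotator: str = "unknown"

    def __post_init__(self):
        peaks = list(self.peak_samples)
        if any(p < 0 for p in peaks):
            raise AnnotationError("negative peak sample index")
        if any(b <= a for a, b in zip(peaks, peaks[1:])):
            raise AnnotationError("peak samples must be strictly increasing")
        self.peak_samples = peaks


@dataclass
class EcgRecord:
    record_id: str
    subject_id: str
    field_strength: str
    fs: float
    signals: np.ndarray  # (n_channels, n_samples)
    channel_names: tuple[str, ...]
    r_peaks: list[int] = field(default_factory=list)

    def __post_init__(self):
        self.signals = np.asarray(self.signals, dtype=float)
        if self.signals.ndim != 2:
            raise FormatError("signals must be a (channels, samples) matrix")
        if self.fs <= 0:
            raise FormatError(f"fs must be positive, got {self.fs}")
        if not np.isfinite(self.signals).all():
            raise FormatError("signals contain non-finite values")
        if self.field_strength not in FIELD_STRENGTHS:
            raise FormatError(
                f"field_strength must be one of {FIELD_STRENGTHS}, "
                f"got {self.field_strength!r}"
            )
        n = self.signals.shape[1]
        peaks = [int(p) for p in self.r_peaks]
        if any(p < 0 or p >= n for p in peaks):
            raise AnnotationError(f"r_peaks outside [0, {n})")
        if any(b <= a for a, b in zip(peaks, peaks[1:])):
            raise AnnotationError("r_peaks must be strictly increasing")
        self.r_peaks = peaks
        self.channel_names = tuple(self.channel_names)

    @property
    def n_channels(self) -> int:
        return self.signals.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


# --- annotation stream (MIT format) ------------------------------------


def write_annotations(path, peak_samples: Sequence[int]) -> None:
    """Write beat annotations (code NORMAL) in MIT format."""
    out = bytearray()
    prev = 0
    for p in sorted(int(x) for x in peak_samples):
        diff = p - prev
        prev = p
        if diff > 1023:
            out += struct.pack("<H", _SKIP << 10)
            out += struct.pack("<H", (diff >> 16) & 0xFFFF)
            out += struct.pack("<H", diff & 0xFFFF)
            diff = 0
        out += struct.pack("<H", (_NORMAL_BEAT << 10) | diff)
    out += struct.pack("<H", 0)  # EOF
    Path(path).write_bytes(bytes(out))


def read_annotations(path, beat_codes=DEFAULT_BEAT_CODES) -> list[int]:
    """Read beat sample indices from an MIT-format annotation stream."""
    path = Path(path)
    if not path.exists():
        raise AnnotationError(f"annotation file not found: {path}")
    data = path.read_bytes()
    peaks: list[int] = []
    t = 0
    i = 0
    while i + 1 < len(data):
        word = struct.unpack_from("<H", data, i)[0]
        i += 2
        code = word >> 10
        interval = word & 0x3FF
        if code == 0 and interval == 0:
            break
        if code == _SKIP:
            if i + 3 >= len(data):
                raise FormatError(f"truncated SKIP in {path}")
            hi = struct.unpack_from("<H", data, i)[0]
            lo = struct.unpack_from("<H", data, i + 2)[0]
            i += 4
            val = (hi << 16) | lo
            if val & 0x80000000:
                val -= 1 << 32
            t += val
            continue
        if code == _AUX:
            i += interval + (interval & 1)
            continue
        if code in (_NUM, _SUB, _CHN):
            continue
        t += interval
        if code in beat_codes:
            peaks.append(t)
    if not peaks:
        raise AnnotationError(f"no beat annotations in {path}")
    return sorted(peaks)


# --- header + signal files ----------------------------------------------


def _base_path(path) -> Path:
    p = Path(path)
    return p.with_suffix("") if p.suffix in (".hea", ".dat") else p


def write_record(record: EcgRecord, out_dir, annotation_ext: str = "atr") -> dict:
    """Write .hea/.dat/.atr files; returns the paths written.

    Per-channel gain is chosen so the signal spans most of the int16 range;
    the round-trip quantization error is bounded by 1/gain per sample.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out_dir}: {exc}") from exc
    rid = record.record_id
    n_sig, n_samp = record.signals.shape
    gains = []
    digital = np.empty((n_samp, n_sig), dtype=np.int16)
    for c in range(n_sig):
        amax = float(np.abs(record.signals[c]).max())
        gain = 30000.0 / amax if amax > 0 else 200.0
        gains.append(gain)
        digital[:, c] = np.clip(
            np.rint(record.signals[c] * gain), -32768, 32767
        ).astype(np.int16)

    dat_path = out_dir / f"{rid}.dat"
    digital.tofile(dat_path)

    lines = [f"{rid} {n_sig} {record.fs:g} {n_samp}"]
    for c in range(n_sig):
        first = int(digital[0, c]) if n_samp else 0
        csum = int(np.sum(digital[:, c], dtype=np.int64) % 65536)
        if csum >= 32768:
            csum -= 65536
        lines.append(
            f"{rid}.dat 16 {gains[c]:.12g}(0)/mV 16 0 {first} {csum} 0 "
            f"{record.channel_names[c]}"
        )
    hea_path = out_dir / f"{rid}.hea"
    hea_path.write_text("\n".join(lines) + "\n")

    ann_path = out_dir / f"{rid}.{annotation_ext}"
    write_annotations(ann_path, record.r_peaks)
    return {"header": hea_path, "signal": dat_path, "annotation": ann_path}


def _parse_header(hea_path: Path):
    lines = [
        ln.strip()
        for ln in hea_path.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    if not lines:
        raise FormatError(f"empty header: {hea_path}")
    head = lines[0].split()
    if len(head) < 4:
        raise FormatError(f"header line too short in {hea_path}: {lines[0]!r}")
    rid, n_sig, fs, n_samp = head[0], int(head[1]), float(head[2]), int(head[3])
    if n_sig < 1 or n_samp < 1:
        raise FormatError(f"{hea_path}: zero channels or zero samples")
    sigs = []
    for ln in lines[1 : 1 + n_sig]:
        tok = ln.split()
        if len(tok) < 3:
            raise FormatError(f"bad signal line in {hea_path}: {ln!r}")
        fname, fmt = tok[0], tok[1]
        if fmt != "16":
            raise FormatError(f"unsupported signal format {fmt!r} (only 16)")
        gspec = tok[2]
        units = gspec.split("/", 1)
        gb = units[0]
        baseline = 0
        if "(" in gb:
            g, b = gb.split("(")
            gain = float(g)
            baseline = int(b.rstrip(")"))
        else:
            gain = float(gb)
        if gain == 0:
            gain = 200.0
        desc = " ".join(tok[8:]) if len(tok) > 8 else f"ch{len(sigs)}"
        sigs.append({"file": fname, "gain": gain, "baseline": baseline, "name": desc})
    return rid, n_sig, fs, n_samp, sigs


def _select_leads(signals: np.ndarray, names: list[str]):
    """Prefer name-matched limb leads I, II, III; else first three channels."""
    norm = [n.strip().lower().removeprefix("lead ").strip() for n in names]
    want = [lead.lower() for lead in LIMB_LEADS]
    if all(w in norm for w in want) and signals.shape[0] >= 3:
        idx = [norm.index(w) for w in want]
        return signals[idx], LIMB_LEADS
    if signals.shape[0] < 3:
        raise FormatError(
            f"record has {signals.shape[0]} channels; 3 leads required"
        )
    if signals.shape[0] > 3:
        logger.warning(
            "lead names %s do not include I/II/III; taking first three channels",
            names,
        )
    return signals[:3], tuple(names[:3])


def read_record(
    signal_path,
    annotation_path,
    subject_id: str | None = None,
    field_strength: str = "synthetic",
    beat_codes=DEFAULT_BEAT_CODES,
) -> EcgRecord:
    """Read one WFDB record (header path or extension-less base) + beats."""
    base = _base_path(signal_path)
    hea_path = base.with_suffix(".hea")
    if not hea_path.exists():
        raise FileNotFoundError(f"header file not found: {hea_path}")
    rid, n_sig, fs, n_samp, sigs = _parse_header(hea_path)
    dat_path = hea_path.parent / sigs[0]["file"]
    if not dat_path.exists():
        raise FileNotFoundError(f"signal file not found: {dat_path}")
    raw = np.fromfile(dat_path, dtype="<i2")
    if raw.size < n_samp * n_sig:
        raise FormatError(
            f"{dat_path}: expected {n_samp * n_sig} samples, found {raw.size}"
        )
    digital = raw[: n_samp * n_sig].reshape(n_samp, n_sig).T.astype(float)
    gains = np.array([s["gain"] for s in sigs])[:, None]
    baselines = np.array([s["baseline"] for s in sigs])[:, None]
    signals = (digital - baselines) / gains
    names = [s["name"] for s in sigs]
    signals, channel_names = _select_leads(signals, names)
    peaks = read_annotations(annotation_path, beat_codes=beat_codes)
    if peaks and peaks[-1] >= n_samp:
        raise AnnotationError(
            f"annotation at sample {peaks[-1]} beyond record length {n_samp}"
        )
    return EcgRecord(
        record_id=rid,
        subject_id=subject_id if subject_id is not None else rid,
        field_strength=field_strength,
        fs=fs,
        signals=signals,
        channel_names=channel_names,
        r_peaks=peaks,
    )


# --- dataset manifest ----------------------------------------------------

MANIFEST_NAME = "manifest.csv"


def write_manifest(rows: list[dict], root) -> Path:
    """rows: dicts with keys record, subject, field_strength."""
    path = Path(root) / MANIFEST_NAME
    pd.DataFrame(rows, columns=["record", "subject", "field_strength"]).to_csv(
        path, index=False
    )
    return path


def load_dataset(
    root,
    field_strength: str,
    annotation_ext: str = "atr",
    beat_codes=DEFAULT_BEAT_CODES,
) -> list[EcgRecord]:
    """Load all records of one field strength listed in the manifest."""
    root = Path(root)
    manifest = root / MANIFEST_NAME
    if not manifest.exists():
        raise ConfigurationError(f"no manifest at {manifest}")
    df = pd.read_csv(manifest, dtype=str)
    missing = {"record", "subject", "field_strength"} - set(df.columns)
    if missing:
        raise ConfigurationError(f"manifest lacks columns {sorted(missing)}")
    sel = df[df["field_strength"] == field_strength]
    if sel.empty:
        found = sorted(df["field_strength"].unique())
        raise ConfigurationError(
            f"no records with field_strength={field_strength!r}; "
            f"manifest contains {found}"
        )
    records = []
    for _, row in sel.sort_values("record").iterrows():
        base = root / row["record"]
        rec = read_record(
            base,
            base.with_suffix(f".{annotation_ext}"),
            subject_id=row["subject"],
            field_strength=field_strength,
            beat_codes=beat_codes,
        )
        records.append(rec)
    return records
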