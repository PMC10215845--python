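"""WFDB-subset reader/writer round-trips and manifest-driven dataset loading."""

import numpy as np
import pytest

from mhdnet.exceptions import AnnotationError, ConfigurationError, FormatError
from mhdnet.signal_io import (
    AnnotationSet,
    EcgRecord,
    load_dataset,
    read_annotations,
    read_record,
    write_annotations,
    write_manifest,
    write_record,
)
from mhdnet.synthetic import make_synthetic_dataset, make_synthetic_records, preset


def make_record(n=4096, peaks=(1000, 2000), names=("I", "II", "III"), rng=None):
    rng = rng or np.random.default_rng(0)
    return EcgRecord(
        record_id="rec0",
        subject_id="sub0",
        field_strength="synthetic",
        fs=1024.0,
        signals=rng.normal(size=(len(names), n)),
        channel_names=names,
        r_peaks=list(peaks),
    )


class TestRoundTrip:
    def test_peaks_and_names_survive(self, tmp_path):
        rec = make_record()
        paths = write_record(rec, tmp_path)
        back = read_record(paths["header"], paths["annotation"])
        assert back.r_peaks == [1000, 2000]
        assert back.channel_names == ("I", "II", "III")
        assert back.n_samples == 4096
        assert back.fs == 1024.0

    def test_signal_error_bounded_by_quantization(self, tmp_path):
        rec = make_record()
        paths = write_record(rec, tmp_path)
        back = read_record(paths["header"], paths["annotation"])
        # per-channel gain is 30000 / max|x|; the error bound is half a step
        steps = np.abs(rec.signals).max(axis=1, keepdims=True) / 30000.0
        assert (np.abs(back.signals - rec.signals) <= 0.51 * steps).all()

    def test_empty_annotation_stream(self, tmp_path):
        rec = make_record(peaks=())
        paths = write_record(rec, tmp_path)
        assert paths["annotation"].exists()
        with pytest.raises(AnnotationError):
            read_record(paths["header"], paths["annotation"])

    def test_header_contract(self, tmp_path):
        paths = write_record(make_record(), tmp_path)
        head = paths["header"].read_text().splitlines()
        assert head[0].split() == ["rec0", "3", "1024", "4096"]

    def test_long_gap_annotations(self, tmp_path):
        # gaps beyond 1023 samples exercise the SKIP escape
        peaks = [10, 50000, 50040, 200000]
        write_annotations(tmp_path / "a.atr", peaks)
        assert read_annotations(tmp_path / "a.atr") == peaks


class TestLeadSelection:
    def test_twelve_lead_record_reduces_to_limb_leads(self, tmp_path):
        names = ("I", "II", "III", "aVR", "aVL", "aVF",
                 "V1", "V2", "V3", "V4", "V5", "V6")
        rec = make_record(names=names)
        paths = write_record(rec, tmp_path)
        back = read_record(paths["header"], paths["annotation"])
        assert back.channel_names == ("I", "II", "III")
        assert back.signals.shape[0] == 3

    def test_unnamed_channels_fall_back_to_first_three(self, tmp_path):
        names = ("ch1", "ch2", "ch3", "ch4")
        paths = write_record(make_record(names=names), tmp_path)
        back = read_record(paths["header"], paths["annotation"])
        assert back.channel_names == ("ch1", "ch2", "ch3")


class TestErrors:
    def test_missing_header_names_path(self, tmp_path):
        with pytest.raises(FileNotFoundError, match="nosuch"):
            read_record(tmp_path / "nosuch.hea", tmp_path / "nosuch.atr")

    def test_missing_annotation_file(self, tmp_path):
        paths = write_record(make_record(), tmp_path)
        with pytest.raises(AnnotationError):
            read_record(paths["header"], tmp_path / "absent.atr")

    def test_zero_channel_header_rejected(self, tmp_path):
        (tmp_path / "bad.hea").write_text("bad 0 1024 4096\n")
        with pytest.raises(FormatError):
            read_record(tmp_path / "bad.hea", tmp_path / "bad.atr")

    def test_record_invariants(self):
        with pytest.raises(AnnotationError):
            make_record(peaks=(2000, 1000))
        with pytest.raises(AnnotationError):
            make_record(peaks=(5000,))  # beyond n_samples
        with pytest.raises(FormatError):
            EcgRecord("r", "s", "synthetic", 1024.0,
                      np.array([[np.nan, 0.0]]), ("I",), [])

    def test_annotation_set_invariants(self):
        with pytest.raises(AnnotationError):
            AnnotationSet("r", [5, 5])


class TestDataset:
    def test_manifest_grouping(self, tmp_path):
        rows = []
        for s in range(2):
            for r in range(2):
                rec = make_record()
                rec.record_id = f"s{s}r{r}"
                rec.subject_id = f"s{s}"
                write_record(rec, tmp_path)
                rows.append(
                    {"record": rec.record_id, "subject": rec.subject_id,
                     "field_strength": "3T"}
                )
        write_manifest(rows, tmp_path)
        records = load_dataset(tmp_path, "3T")
        assert len(records) == 4
        assert {r.subject_id for r in records} == {"s0", "s1"}
        assert {r.field_strength for r in records} == {"3T"}
        assert [r.record_id for r in records] == sorted(r.record_id for r in records)

    def test_wrong_field_strength_lists_found(self, tmp_path):
        make_synthetic_dataset(
            preset("3T-like", duration_s=8.0, n_subjects=1,
                   records_per_subject=1, seed=0),
            tmp_path,
        )
        with pytest.raises(ConfigurationError, match="synthetic"):
            load_dataset(tmp_path, "7T")

    def test_generator_loader_round_trip(self, tmp_path):
        cfg = preset("7T-like", duration_s=8.0, n_subjects=2,
                     records_per_subject=1, seed=4)
        make_synthetic_dataset(cfg, tmp_path)
        loaded = {r.record_id: r for r in load_dataset(tmp_path, "synthetic")}
        for rec in make_synthetic_records(cfg):
            assert loaded[rec.record_id].r_peaks == rec.r_peaks
            assert loaded[rec.record_id].subject_id == rec.subject_id
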