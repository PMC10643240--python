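import numpy as np
import pytest

from cardioresp import (
    BeatSeries,
    FlowSignal,
    LoadError,
    SegmentMarkers,
    SubjectRecord,
    ValidationError,
    read_record,
    slice_epoch,
    write_record,
)
from cardioresp.records import records_equal


def make_minimal_record(n_beats=2, duration=1.0, fs=100.0):
    times = 0.5 + np.arange(n_beats) * 0.5
    beats = BeatSeries(
        time_s=times,
        rr_ms=np.full(n_beats, 500.0),
        sbp_mmhg=np.full(n_beats, 120.0),
        dbp_mmhg=np.full(n_beats, 80.0),
    )
    flow = FlowSignal(fs, 0.1 * np.sin(2 * np.pi * np.arange(int(duration * fs)) / fs))
    return SubjectRecord(
        subject_id="mini",
        beats=beats,
        flow=flow,
        segments=SegmentMarkers({"SR": (0.0, duration)}),
        weight_kg=73.0,
        height_cm=178.0,
    )


class TestRoundTrip:
    def test_minimal_fixture_round_trip(self, tmp_path):
        record = make_minimal_record()
        write_record(record, tmp_path / "mini")
        back = read_record(tmp_path / "mini")
        assert len(back.beats) == 2
        assert records_equal(record, back)

    def test_simulated_round_trip_field_by_field(self, tmp_path, sim_record):
        record, truth = sim_record
        write_record(record, tmp_path / "sim")
        back = read_record(tmp_path / "sim")
        assert records_equal(record, back)
        assert len(back.beats) == truth.beat_count

    def test_write_read_write_byte_identical(self, tmp_path, sim_record):
        record, _ = sim_record
        write_record(record, tmp_path / "a")
        back = read_record(tmp_path / "a")
        write_record(back, tmp_path / "b")
        for name in ("meta.json", "beats.csv", "flow.txt"):
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes()

    def test_absent_optional_column_stays_absent(self, tmp_path):
        record = make_minimal_record()
        assert record.beats.qt_s is None
        write_record(record, tmp_path / "r")
        text = (tmp_path / "r" / "beats.csv").read_text()
        assert "qt_s" not in text.splitlines()[0]
        back = read_record(tmp_path / "r")
        assert back.beats.qt_s is None

    def test_file_size_bounded(self, tmp_path, sim_record):
        record, _ = sim_record
        write_record(record, tmp_path / "r")
        total = sum(f.stat().st_size for f in (tmp_path / "r").iterdir())
        # 360 s at 100 Hz plus ~400 beats should stay well under 2 MiB of text
        assert total < 2 * 1024 * 1024


class TestLoadErrors:
    def test_missing_directory(self, tmp_path):
        with pytest.raises(LoadError):
            read_record(tmp_path / "nope")

    @pytest.mark.parametrize("victim", ["meta.json", "beats.csv", "flow.txt"])
    def test_missing_channel_named(self, tmp_path, victim):
        record = make_minimal_record()
        write_record(record, tmp_path / "r")
        (tmp_path / "r" / victim).unlink()
        with pytest.raises(LoadError, match=victim.split(".")[0]):
            read_record(tmp_path / "r")


class TestValidation:
    def test_non_monotone_beat_times_rejected(self):
        record = make_minimal_record()
        record.beats.time_s = np.array([0.5, 0.4])
        with pytest.raises(ValidationError, match="index 1"):
            record.validate()

    def test_rr_time_consistency_enforced(self):
        record = make_minimal_record()
        record.beats.rr_ms = np.array([500.0, 510.0])  # dt is 500 ms
        with pytest.raises(ValidationError, match="inconsistent"):
            record.validate()

    def test_pressure_ordering_enforced(self):
        record = make_minimal_record()
        record.beats.dbp_mmhg = np.full(2, 130.0)
        with pytest.raises(ValidationError, match="sbp > dbp"):
            record.validate()

    def test_flow_volume_conservation(self):
        record = make_minimal_record()
        record.flow.samples = record.flow.samples + 1.0  # constant inflow
        with pytest.raises(ValidationError, match="volume"):
            record.validate()

    def test_overlapping_segments_rejected(self):
        segments = SegmentMarkers({"SR": (0.0, 120.0), "CR6": (100.0, 220.0)})
        with pytest.raises(ValidationError, match="overlap"):
            segments.validate()


class TestSliceEpoch:
    @staticmethod
    def uniform_record():
        times = np.arange(1.0, 361.0)
        n = times.size
        beats = BeatSeries(
            time_s=times,
            rr_ms=np.full(n, 1000.0),
            sbp_mmhg=np.full(n, 120.0),
            dbp_mmhg=np.full(n, 80.0),
        )
        flow = FlowSignal(10.0, 0.01 * np.sin(np.arange(3600) / 10.0))
        return SubjectRecord(
            subject_id="u",
            beats=beats,
            flow=flow,
            segments=SegmentMarkers.default_protocol(),
            weight_kg=70.0,
            height_cm=175.0,
        )

    def test_uniform_sr_has_119_full_intervals(self):
        sliced = slice_epoch(self.uniform_record(), "SR")
        rr = sliced.beats.rr_ms
        # beat at t=1 s has its initiating beat at t=0 (record start, outside)
        assert np.isfinite(rr).sum() == 119 - 1 + 1  # 119 beats, first RR blanked
        assert np.isfinite(rr).sum() == 119

    def test_beat_exactly_at_window_end_excluded(self):
        record = self.uniform_record()
        sliced = slice_epoch(record, "SR")
        assert sliced.beats.time_s.max() < 120.0
        cr6 = slice_epoch(record, "CR6")
        assert 120.0 in cr6.beats.time_s  # the boundary beat lands in CR6

    def test_slices_partition_beats(self, sim_record):
        record, _ = sim_record
        seen = np.concatenate(
            [slice_epoch(record, lab).beats.time_s for lab in ("SR", "CR6", "CR15")]
        )
        assert seen.size == len(record.beats)
        assert np.array_equal(np.sort(seen), record.beats.time_s)

    def test_first_interval_blanked_when_crossing_boundary(self, sim_record):
        record, _ = sim_record
        cr6 = slice_epoch(record, "CR6")
        # the first CR6 beat's interval started in SR, so its RR is absent
        assert not np.isfinite(cr6.beats.rr_ms[0])
        assert np.isfinite(cr6.beats.rr_ms[1:]).all()

    def test_missing_label_raises_key_error(self):
        with pytest.raises(KeyError):
            slice_epoch(self.uniform_record(), "CR99")

    def test_rr_matches_time_differences(self, sim_record):
        record, _ = sim_record
        dt_ms = np.diff(record.beats.time_s) * 1000.0
        assert np.allclose(dt_ms, record.beats.rr_ms[1:], atol=1.0)
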