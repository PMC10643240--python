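"""Domain types and on-disk I/O for combined cardiorespiratory records.

A record couples a per-beat table (RR interval, finger blood pressure and
optional interval/volume annotations), a uniformly sampled airflow channel
(inhalation positive, L/s) and three labelled maneuver windows: SR
(spontaneous breathing), CR6 (paced 6/min) and CR15 (paced 15/min).

On disk a record is a directory of plain-text files::

    <subject>/
        meta.json   subject id, anthropometrics, sinus flag, segment windows,
                    flow header (sampling rate, start time)
        beats.csv   time_s,rr_ms,sbp_mmHg,dbp_mmHg[,qt_s,st_nu,sv_cm3,...]
        flow.txt    one sample per line, L/s

All times are seconds from record start; windows are half-open ``[start,
end)`` so every beat belongs to exactly one epoch.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Optional

import numpy as np
import pandas as pd

from .errors import LoadError, ValidationError

EPOCH_LABELS = ("SR", "CR6", "CR15")

#: beats.csv column order; columns beyond the first four are optional.
_BEAT_COLUMNS = (
    "time_s",
    "rr_ms",
    "sbp_mmHg",
    "dbp_mmHg",
    "qt_s",
    "st_nu",
    "sv_cm3",
    "edv_cm3",
    "esv_cm3",
)

#: tolerance (ms) between stored RR and successive beat-time differences
RR_TIME_TOL_MS = 1.0


def _as_float_array(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValidationError(f"{name} must be one-dimensional")
    return arr


@dataclass
class BeatSeries:
    """Per-beat annotations; ``rr_ms`` is the interval ending at each beat.

    Optional channels are ``None`` when absent; individual absent values
    within a present channel are NaN (e.g. the RR of a beat whose initiating
    beat fell outside an epoch window).
    """

    time_s: np.ndarray
    rr_ms: np.ndarray
    sbp_mmhg: np.ndarray
    dbp_mmhg: np.ndarray
    qt_s: Optional[np.ndarray] = None
    st_nu: Optional[np.ndarray] = None
    sv_cm3: Optional[np.ndarray] = None
    edv_cm3: Optional[np.ndarray] = None
    esv_cm3: Optional[np.ndarray] = None
    ectopic: Optional[np.ndarray] = None  # bool; filled by beat analysis

    def __post_init__(self):
        self.time_s = _as_float_array(self.time_s, "time_s")
        self.rr_ms = _as_float_array(self.rr_ms, "rr_ms")
        self.sbp_mmhg = _as_float_array(self.sbp_mmhg, "sbp_mmHg")
        self.dbp_mmhg = _as_float_array(self.dbp_mmhg, "dbp_mmHg")
        for name in ("qt_s", "st_nu", "sv_cm3", "edv_cm3", "esv_cm3"):
            val = getattr(self, name)
            if val is not None:
                setattr(self, name, _as_float_array(val, name))
        if self.ectopic is not None:
            self.ectopic = np.asarray(self.ectopic, dtype=bool)

    def __len__(self) -> int:
        return self.time_s.size

    def validate(self) -> None:
        n = len(self)
        for name in ("rr_ms", "sbp_mmhg", "dbp_mmhg"):
            if getattr(self, name).size != n:
                raise ValidationError(f"{name} length {getattr(self, name).size} != {n}")
        for name in ("qt_s", "st_nu", "sv_cm3", "edv_cm3", "esv_cm3", "ectopic"):
            val = getattr(self, name)
            if val is not None and val.size != n:
                raise ValidationError(f"{name} length {val.size} != {n}")
        if n == 0:
            return
        dt = np.diff(self.time_s)
        if np.any(dt <= 0):
            idx = int(np.argmax(dt <= 0))
            raise ValidationError(
                f"beat times not strictly increasing at index {idx + 1}"
            )
        finite_rr = self.rr_ms[np.isfinite(self.rr_ms)]
        if np.any(finite_rr <= 0):
            raise ValidationError("rr_ms must be positive")
        ok_bp = (self.sbp_mmhg > self.dbp_mmhg) & (self.dbp_mmhg > 0)
        if not np.all(ok_bp | ~np.isfinite(self.sbp_mmhg)):
            raise ValidationError("per-beat pressures must satisfy sbp > dbp > 0")
        # RR consistency with successive time differences (1 ms tolerance)
        rr_later = self.rr_ms[1:]
        check = np.isfinite(rr_later)
        if np.any(np.abs(dt[check] * 1000.0 - rr_later[check]) > RR_TIME_TOL_MS):
            idx = int(np.argmax(np.abs(dt * 1000.0 - np.where(check, rr_later, dt * 1000.0)) > RR_TIME_TOL_MS))
            raise ValidationError(
                f"rr_ms inconsistent with beat time difference at index {idx + 1}"
            )

    def to_frame(self) -> pd.DataFrame:
        data = {
            "time_s": self.time_s,
            "rr_ms": self.rr_ms,
            "sbp_mmHg": self.sbp_mmhg,
            "dbp_mmHg": self.dbp_mmhg,
        }
        optional = {
            "qt_s": self.qt_s,
            "st_nu": self.st_nu,
            "sv_cm3": self.sv_cm3,
            "edv_cm3": self.edv_cm3,
            "esv_cm3": self.esv_cm3,
        }
        for name, val in optional.items():
            if val is not None:
                data[name] = val
        return pd.DataFrame(data)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "BeatSeries":
        required = ("time_s", "rr_ms", "sbp_mmHg", "dbp_mmHg")
        for col in required:
            if col not in df.columns:
                raise LoadError(f"beat table is missing required column {col!r}")
        kwargs = dict(
            time_s=df["time_s"].to_numpy(float),
            rr_ms=df["rr_ms"].to_numpy(float),
            sbp_mmhg=df["sbp_mmHg"].to_numpy(float),
            dbp_mmhg=df["dbp_mmHg"].to_numpy(float),
        )
        for col, attr in (
            ("qt_s", "qt_s"),
            ("st_nu", "st_nu"),
            ("sv_cm3", "sv_cm3"),
            ("edv_cm3", "edv_cm3"),
            ("esv_cm3", "esv_cm3"),
        ):
            if col in df.columns:
                kwargs[attr] = df[col].to_numpy(float)
        return cls(**kwargs)


@dataclass
class FlowSignal:
    """Uniformly sampled airflow in L/s, inhalation positive."""

    fs_hz: float
    samples: np.ndarray
    start_s: float = 0.0

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        self.fs_hz = float(self.fs_hz)
        self.start_s = float(self.start_s)

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs_hz

    @property
    def time_s(self) -> np.ndarray:
        return self.start_s + np.arange(self.samples.size) / self.fs_hz

    def validate(self, mean_tol_l_s: float = 0.05) -> None:
        if self.fs_hz < 1.0:
            raise ValidationError("flow sampling rate must be at least 1 Hz")
        if not np.all(np.isfinite(self.samples)):
            raise ValidationError("flow samples must be finite")
        if self.samples.size and abs(float(np.mean(self.samples))) > mean_tol_l_s:
            raise ValidationError(
                "flow does not conserve volume: record mean "
                f"{np.mean(self.samples):.4f} L/s exceeds {mean_tol_l_s} L/s"
            )

    def crop(self, start: float, end: float) -> "FlowSignal":
        """Restrict to samples with time in ``[start, end)``."""
        t = self.time_s
        mask = (t >= start - 1e-9) & (t < end - 1e-9)
        idx = np.nonzero(mask)[0]
        if idx.size == 0:
            return FlowSignal(self.fs_hz, np.empty(0), start)
        return FlowSignal(self.fs_hz, self.samples[idx[0] : idx[-1] + 1], float(t[idx[0]]))


@dataclass
class SegmentMarkers:
    """Three labelled half-open windows ``[start, end)`` in record seconds."""

    windows: dict = field(default_factory=dict)  # label -> (start, end)

    def __getitem__(self, label: str) -> tuple:
        if label not in self.windows:
            raise KeyError(f"no segment labelled {label!r}")
        return self.windows[label]

    def __contains__(self, label: str) -> bool:
        return label in self.windows

    def items(self) -> Iterator:
        return iter(self.windows.items())

    def validate(self, record_duration: Optional[float] = None) -> None:
        labels = list(self.windows)
        if len(set(labels)) != len(labels):
            raise ValidationError("segment labels must be unique")
        for label, (start, end) in self.windows.items():
            if label not in EPOCH_LABELS:
                raise ValidationError(f"unknown segment label {label!r}")
            if not (end > start >= 0):
                raise ValidationError(f"segment {label} window [{start}, {end}) is empty")
            if record_duration is not None and start > record_duration:
                raise ValidationError(f"segment {label} starts beyond record end")
        present = [lab for lab in EPOCH_LABELS if lab in self.windows]
        bounds = [self.windows[lab] for lab in present]
        for (s0, e0), (s1, e1) in zip(bounds, bounds[1:]):
            if s1 < e0 - 1e-9:
                raise ValidationError("segments overlap or are out of SR, CR6, CR15 order")

    @classmethod
    def default_protocol(cls, epoch_s: float = 120.0) -> "SegmentMarkers":
        """Standard three-epoch protocol: consecutive equal windows."""
        return cls(
            {
                "SR": (0.0, epoch_s),
                "CR6": (epoch_s, 2 * epoch_s),
                "CR15": (2 * epoch_s, 3 * epoch_s),
            }
        )


@dataclass
class BpSummary:
    """Epoch means of finger pressures; pulse pressure averaged per beat."""

    sbpf: float
    dbpf: float
    pbpf: float


@dataclass
class SubjectRecord:
    subject_id: str
    beats: BeatSeries
    flow: FlowSignal
    segments: SegmentMarkers
    weight_kg: float
    height_cm: float
    sinus_rhythm: bool = True

    def validate(self) -> None:
        self.beats.validate()
        self.flow.validate()
        duration = self.flow.start_s + self.flow.duration_s
        self.segments.validate(record_duration=duration)
        if not (self.weight_kg > 0 and self.height_cm > 0):
            raise ValidationError("weight and height must be positive")


def slice_epoch(record: SubjectRecord, label: str) -> SubjectRecord:
    """Restrict a record to one labelled window.

    Beats with time in ``[start, end)`` are kept; the RR of the first kept
    beat is blanked to NaN unless its initiating beat also lies inside the
    window, so epoch RR series contain only fully contained intervals.
    """
    start, end = record.segments[label]
    beats = record.beats
    mask = (beats.time_s >= start) & (beats.time_s < end)
    idx = np.nonzero(mask)[0]

    def take(arr):
        return None if arr is None else arr[idx].copy()

    rr = beats.rr_ms[idx].copy()
    if idx.size:
        first = idx[0]
        initiating = beats.time_s[first] - beats.rr_ms[first] / 1000.0
        if not np.isfinite(beats.rr_ms[first]) or initiating < start - 1e-6:
            rr[0] = np.nan
    sliced = BeatSeries(
        time_s=beats.time_s[idx].copy(),
        rr_ms=rr,
        sbp_mmhg=beats.sbp_mmhg[idx].copy(),
        dbp_mmhg=beats.dbp_mmhg[idx].copy(),
        qt_s=take(beats.qt_s),
        st_nu=take(beats.st_nu),
        sv_cm3=take(beats.sv_cm3),
        edv_cm3=take(beats.edv_cm3),
        esv_cm3=take(beats.esv_cm3),
        ectopic=take(beats.ectopic),
    )
    return replace(
        record,
        beats=sliced,
        flow=record.flow.crop(start, end),
        segments=SegmentMarkers({label: (start, end)}),
    )


def _format_floats(values: np.ndarray) -> str:
    # repr gives the shortest round-tripping decimal form, so
    # write -> read -> write is byte-stable.
    return "\n".join(repr(float(v)) for v in values)


def write_record(record: SubjectRecord, path) -> None:
    """Serialize a validated record into a directory of text files."""
    record.validate()
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "subject_id": record.subject_id,
        "weight_kg": record.weight_kg,
        "height_cm": record.height_cm,
        "sinus_rhythm": bool(record.sinus_rhythm),
        "segments": {lab: [s, e] for lab, (s, e) in record.segments.items()},
        "flow": {"fs_hz": record.flow.fs_hz, "start_s": record.flow.start_s},
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    record.beats.to_frame().to_csv(path / "beats.csv", index=False)
    (path / "flow.txt").write_text(_format_floats(record.flow.samples) + "\n")


def read_record(path, default_segments: Optional[SegmentMarkers] = None) -> SubjectRecord:
    """Read and validate a record directory written by :func:`write_record`.

    ``default_segments`` supplies the protocol windows for records whose
    metadata carries none (e.g. imported from devices that only store the
    start time).
    """
    path = Path(path)
    if not path.is_dir():
        raise LoadError(f"record directory {path} does not exist")
    meta_path = path / "meta.json"
    if not meta_path.exists():
        raise LoadError("missing channel: meta.json")
    meta = json.loads(meta_path.read_text())
    beats_path = path / "beats.csv"
    if not beats_path.exists():
        raise LoadError("missing channel: beats.csv")
    flow_path = path / "flow.txt"
    if not flow_path.exists():
        raise LoadError("missing channel: flow.txt")

    # round_trip parsing: the default C float parser can be 1 ulp off,
    # which breaks byte-identical write -> read -> write
    beats = BeatSeries.from_frame(pd.read_csv(beats_path, float_precision="round_trip"))
    flow_meta = meta.get("flow")
    if not flow_meta or "fs_hz" not in flow_meta:
        raise LoadError("missing channel: flow sampling rate (meta.json flow.fs_hz)")
    samples = np.array(
        [float(line) for line in flow_path.read_text().split()], dtype=float
    )
    flow = FlowSignal(flow_meta["fs_hz"], samples, flow_meta.get("start_s", 0.0))

    segments_meta = meta.get("segments")
    if segments_meta:
        segments = SegmentMarkers({lab: tuple(w) for lab, w in segments_meta.items()})
    elif default_segments is not None:
        segments = default_segments
    else:
        raise LoadError("missing channel: segment markers (and no protocol default given)")

    record = SubjectRecord(
        subject_id=str(meta.get("subject_id", path.name)),
        beats=beats,
        flow=flow,
        segments=segments,
        weight_kg=float(meta["weight_kg"]),
        height_cm=float(meta["height_cm"]),
        sinus_rhythm=bool(meta.get("sinus_rhythm", True)),
    )
    record.validate()
    return record


def body_mass_index(weight_kg: float, height_cm: float) -> float:
    return weight_kg / (height_cm / 100.0) ** 2


def records_equal(a: SubjectRecord, b: SubjectRecord) -> bool:
    """Field-by-field equality (NaNs compare equal), used by round-trip tests."""

    def arr_eq(x, y):
        if x is None or y is None:
            return x is None and y is None
        return x.shape == y.shape and np.array_equal(x, y, equal_nan=True)

    if (a.subject_id, a.sinus_rhythm) != (b.subject_id, b.sinus_rhythm):
        return False
    if not (
        math.isclose(a.weight_kg, b.weight_kg)
        and math.isclose(a.height_cm, b.height_cm)
    ):
        return False
    if dict(a.segments.items()) != dict(b.segments.items()):
        return False
    if a.flow.fs_hz != b.flow.fs_hz or a.flow.start_s != b.flow.start_s:
        return False
    if not arr_eq(a.flow.samples, b.flow.samples):
        return False
    for name in (
        "time_s",
        "rr_ms",
        "sbp_mmhg",
        "dbp_mmhg",
        "qt_s",
        "st_nu",
        "sv_cm3",
        "edv_cm3",
        "esv_cm3",
    ):
        if not arr_eq(getattr(a.beats, name), getattr(b.beats, name)):
            return False
    return True
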