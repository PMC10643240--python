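"""Synthetic coupled cardiorespiratory cohort generator.

Beats come from an integral pulse frequency modulation (IPFM) scheme: a
beat fires whenever the running integral of the instantaneous rate

    m(t) = (1/RR0) * [1 + a_resp * flow_norm(t) + a_lf * sin(2*pi*0.1*t + phi) + eps(t)]

crosses the next integer, so derived RR series carry realistic harmonics
rather than phenomenological sinusoids. ``flow_norm`` is the airflow
normalized to unit peak per epoch, which makes the modulation amplitudes
directly interpretable in ms (RR) and mmHg (pressures).

Per-beat pressures get a respiratory oscillation plus an independent
0.1 Hz drive; the baroreflex is a beat-lagged linear coupling of the
previous systolic deviation back onto RR. Ectopic beats are injected as a
premature interval (0.6x) followed by a compensatory pause (1.4x), the
artifact class the downstream detector must flag.

Every subject/epoch is paired with a :class:`GroundTruth` twin holding the
injected parameter values, so recovery tests never reverse-engineer the
generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .errors import ConfigurationError, ValidationError
from .records import (
    BeatSeries,
    FlowSignal,
    SegmentMarkers,
    SubjectRecord,
)

LF_HZ = 0.1  # intrinsic low-frequency (Mayer) drive


@dataclass(frozen=True)
class BreathingProgram:
    """One epoch's breathing prescription.

    ``rate_min`` of ``None`` means spontaneous breathing: breath-to-breath
    period and tidal volume are jittered with log-normal dispersion.
    """

    rate_min: Optional[float]
    tidal_volume_l: float
    ti_s: Optional[float] = None
    te_s: Optional[float] = None
    rate_mean_min: float = 14.2
    rate_cv: float = 0.10
    vt_cv: float = 0.10
    ti_fraction: float = 0.42  # spontaneous inspiratory duty cycle

    def __post_init__(self):
        if self.tidal_volume_l <= 0:
            raise ValidationError("tidal volume must be positive")
        if self.rate_min is not None:
            if self.ti_s is None or self.te_s is None:
                raise ConfigurationError("paced programs need ti_s and te_s")
            period = 60.0 / self.rate_min
            if abs(self.ti_s + self.te_s - period) > 1e-6:
                raise ConfigurationError(
                    f"Ti + Te = {self.ti_s + self.te_s} s inconsistent with "
                    f"rate {self.rate_min}/min (period {period} s)"
                )


def paced_program(rate_min: float, tidal_volume_l: float) -> BreathingProgram:
    half = 30.0 / rate_min
    return BreathingProgram(
        rate_min=rate_min, tidal_volume_l=tidal_volume_l, ti_s=half, te_s=half
    )


def spontaneous_program(
    rate_mean_min: float = 14.2,
    tidal_volume_l: float = 0.57,
    rate_cv: float = 0.10,
    vt_cv: float = 0.10,
) -> BreathingProgram:
    return BreathingProgram(
        rate_min=None,
        tidal_volume_l=tidal_volume_l,
        rate_mean_min=rate_mean_min,
        rate_cv=rate_cv,
        vt_cv=vt_cv,
    )


@dataclass
class SimulationConfig:
    seed: int = 0
    epoch_s: float = 120.0
    flow_fs_hz: float = 100.0

    mean_rr_ms: float = 880.0
    rsa_gain_ms: float = 16.0  # RR modulation at unit normalized flow, at vt_ref
    rsa_vt_ref_l: float = 0.6  # RSA amplitude scales with tidal volume / vt_ref
    lf_amp_rr_ms: float = 20.0  # intrinsic 0.1 Hz RR modulation
    baroreflex_gain_ms_mmhg: float = 3.0
    rr_noise_ms: float = 3.0
    hr_shift_cr6_min: float = 3.0  # paced-breathing chronotropic response
    hr_shift_cr15_min: float = 9.0  # mild hyperventilation tachycardia

    sbp_mean_mmhg: float = 115.0
    dbp_mean_mmhg: float = 70.0
    resp_sbp_amp_mmhg: float = 4.0
    resp_dbp_amp_mmhg: float = 2.0
    lf_amp_sbp_mmhg: float = 2.5
    lf_amp_dbp_mmhg: float = 1.5
    bp_noise_mmhg: float = 0.6

    sv_mean_cm3: float = 66.0
    sv_resp_amp_cm3: float = 2.0
    esv_mean_cm3: float = 30.0
    sv_noise_cm3: float = 0.8

    qtc_true_s: float = 0.41
    qt_noise_s: float = 0.002

    vo2_fraction: float = 0.046
    flow_noise_l_s: float = 0.01
    ectopic_rate_per_beat: float = 0.0

    sr_program: BreathingProgram = field(default_factory=spontaneous_program)
    cr6_program: BreathingProgram = field(default_factory=lambda: paced_program(6.0, 1.7))
    cr15_program: BreathingProgram = field(default_factory=lambda: paced_program(15.0, 0.89))

    #: per-parameter coefficient of variation for between-subject dispersion
    cohort_cv: dict = field(
        default_factory=lambda: {
            "mean_rr_ms": 0.07,
            "rsa_gain_ms": 0.15,
            "lf_amp_rr_ms": 0.15,
            "baroreflex_gain_ms_mmhg": 0.20,
            "sbp_mean_mmhg": 0.05,
            "dbp_mean_mmhg": 0.05,
            "resp_sbp_amp_mmhg": 0.20,
            "lf_amp_sbp_mmhg": 0.20,
            "hr_shift_cr6_min": 0.30,
            "hr_shift_cr15_min": 0.30,
            "sv_mean_cm3": 0.08,
            "qtc_true_s": 0.02,
        }
    )

    def validate(self) -> None:
        if not (300.0 < self.mean_rr_ms < 2000.0):
            raise ValidationError("mean_rr_ms must lie in (300, 2000) ms")
        for name in (
            "rsa_gain_ms",
            "lf_amp_rr_ms",
            "baroreflex_gain_ms_mmhg",
            "resp_sbp_amp_mmhg",
            "resp_dbp_amp_mmhg",
            "lf_amp_sbp_mmhg",
            "sv_resp_amp_cm3",
            "ectopic_rate_per_beat",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")

    def programs(self) -> dict:
        return {"SR": self.sr_program, "CR6": self.cr6_program, "CR15": self.cr15_program}


@dataclass
class EpochTruth:
    rate_min: float
    tidal_volume_l: float
    lf_rr_power_ms2: float  # intrinsic 0.1 Hz RR power, a^2/2
    hf_rr_power_ms2: float  # RSA-driven power at paced breathing, a^2/2


@dataclass
class GroundTruth:
    qtc_s: float
    baroreflex_gain_ms_mmhg: float
    mean_rr_ms: float
    epochs: dict  # label -> EpochTruth
    ectopic_beat_indices: np.ndarray  # global indices of premature beats
    ectopic_flagged_indices: np.ndarray  # premature + compensatory-pause beats
    beat_count: int = 0


def _bandlimited_noise(n: int, fs: float, sd: float, rng: np.random.Generator) -> np.ndarray:
    """White noise low-passed to ~1 Hz, rescaled to the requested SD."""
    if sd <= 0 or n == 0:
        return np.zeros(n)
    from scipy import signal as sp_signal

    white = rng.standard_normal(n)
    if fs > 4.0:
        b, a = sp_signal.butter(2, min(1.0, fs / 4.0) / (fs / 2.0))
        white = sp_signal.filtfilt(b, a, white)
    std = white.std()
    return white * (sd / std) if std > 0 else np.zeros(n)


def _half_sine_breath(ti: float, te: float, vt: float, fs: float) -> np.ndarray:
    """One breath: half-sine inspiratory lobe (+vt), expiratory lobe (-vt)."""
    n_i = max(1, int(round(ti * fs)))
    n_e = max(1, int(round(te * fs)))
    ts_i = (np.arange(n_i) + 0.5) / fs
    ts_e = (np.arange(n_e) + 0.5) / fs
    insp = (np.pi * vt / (2.0 * ti)) * np.sin(np.pi * ts_i / ti)
    exp = -(np.pi * vt / (2.0 * te)) * np.sin(np.pi * ts_e / te)
    return np.concatenate([insp, exp])


def generate_flow(
    program: BreathingProgram,
    duration_s: float,
    fs: float,
    noise_sd_l_s: float = 0.0,
    rng: Optional[np.random.Generator] = None,
) -> FlowSignal:
    """Synthesize an airflow signal for one epoch."""
    rng = rng if rng is not None else np.random.default_rng()
    n_total = int(round(duration_s * fs))
    if program.rate_min is not None:
        for phase in (program.ti_s, program.te_s):
            if phase * fs < 10:
                raise ConfigurationError(
                    f"sampling rate {fs} Hz gives fewer than 10 samples per "
                    f"{phase}-s breath phase"
                )
        t = np.arange(n_total) / fs
        period = program.ti_s + program.te_s
        phase = np.mod(t, period)
        amp_i = np.pi * program.tidal_volume_l / (2.0 * program.ti_s)
        amp_e = np.pi * program.tidal_volume_l / (2.0 * program.te_s)
        samples = np.where(
            phase < program.ti_s,
            amp_i * np.sin(np.pi * phase / program.ti_s),
            -amp_e * np.sin(np.pi * (phase - program.ti_s) / program.te_s),
        )
    else:
        mean_period = 60.0 / program.rate_mean_min
        if mean_period * program.ti_fraction * fs < 10:
            raise ConfigurationError("sampling rate too low for the breathing program")
        sigma_p = np.sqrt(np.log(1.0 + program.rate_cv**2))
        sigma_v = np.sqrt(np.log(1.0 + program.vt_cv**2))
        chunks = []
        total = 0
        while total < n_total:
            period = mean_period * np.exp(rng.normal(-sigma_p**2 / 2, sigma_p))
            vt = program.tidal_volume_l * np.exp(rng.normal(-sigma_v**2 / 2, sigma_v))
            ti = program.ti_fraction * period
            te = period - ti
            breath = _half_sine_breath(ti, te, vt, fs)
            chunks.append(breath)
            total += breath.size
        samples = np.concatenate(chunks)[:n_total]
    samples = samples + _bandlimited_noise(n_total, fs, noise_sd_l_s, rng)
    return FlowSignal(fs_hz=fs, samples=samples)


def _flow_norm(flow_samples: np.ndarray, spans: list[tuple[int, int]]) -> np.ndarray:
    """Flow normalized to unit peak within each epoch span."""
    out = np.zeros_like(flow_samples)
    for a, b in spans:
        seg = flow_samples[a:b]
        peak = np.max(np.abs(seg)) if seg.size else 0.0
        out[a:b] = seg / peak if peak > 0 else 0.0
    return out


def _ipfm_beat_times(
    m: np.ndarray, t: np.ndarray, t_first: float = 0.0
) -> np.ndarray:
    """Beat times where the integral of the rate signal crosses integers."""
    integral = np.concatenate([[0.0], cumulative_trapezoid(m, t)])
    n_beats = int(np.floor(integral[-1]))
    if n_beats < 1:
        return np.empty(0)
    targets = np.arange(1, n_beats + 1, dtype=float)
    # integral is strictly increasing (m > 0), so inverse interpolation works
    return np.interp(targets, integral, t) + t_first


def _epoch_profiles(
    config: SimulationConfig, n_samples: int, spans: list[tuple[int, int]], labels: list[str]
) -> tuple[np.ndarray, np.ndarray]:
    """Piecewise-constant RSA amplitude (ms) and rate factor per sample.

    RSA amplitude scales with the epoch tidal volume (deeper breathing gives
    stronger sinus arrhythmia); the rate factor raises heart rate under
    paced breathing and mild hyperventilation.
    """
    rsa_amp = np.full(n_samples, config.rsa_gain_ms)
    rate_factor = np.ones(n_samples)
    hr0 = 60000.0 / config.mean_rr_ms
    programs = config.programs()
    shifts = {"SR": 0.0, "CR6": config.hr_shift_cr6_min, "CR15": config.hr_shift_cr15_min}
    for (a, b), label in zip(spans, labels):
        program = programs.get(label)
        if program is not None and config.rsa_vt_ref_l > 0:
            rsa_amp[a:b] = config.rsa_gain_ms * (
                program.tidal_volume_l / config.rsa_vt_ref_l
            )
        rate_factor[a:b] = (hr0 + shifts.get(label, 0.0)) / hr0
    return rsa_amp, rate_factor


def generate_beats(
    config: SimulationConfig,
    flow: FlowSignal,
    rng: np.random.Generator,
    spans: Optional[list[tuple[int, int]]] = None,
    span_labels: Optional[list[str]] = None,
) -> tuple[BeatSeries, GroundTruth]:
    """Run the coupled IPFM scheme over a (possibly multi-epoch) flow signal."""
    config.validate()
    t = flow.time_s
    if spans is None:
        spans = [(0, len(flow))]
    flow_norm = _flow_norm(flow.samples, spans)
    if span_labels is None:
        span_labels = [None] * len(spans)
    rsa_amp, rate_factor = _epoch_profiles(config, len(flow), spans, span_labels)

    rr0_s = config.mean_rr_ms / 1000.0
    a_resp = rsa_amp / config.mean_rr_ms
    a_lf = config.lf_amp_rr_ms / config.mean_rr_ms
    phi = rng.uniform(0, 2 * np.pi)
    eps = _bandlimited_noise(len(flow), flow.fs_hz, config.rr_noise_ms / config.mean_rr_ms, rng)
    modulation = 1.0 + a_resp * flow_norm + a_lf * np.sin(2 * np.pi * LF_HZ * t + phi) + eps
    modulation = np.clip(modulation, 0.1, None)
    m = rate_factor * modulation / rr0_s
    beat_times = _ipfm_beat_times(m, t)
    if beat_times.size < 3:
        raise ValidationError("simulation produced fewer than 3 beats")

    n = beat_times.size
    rr_ms = np.empty(n)
    rr_ms[0] = beat_times[0] * 1000.0 if beat_times[0] > 0 else config.mean_rr_ms
    rr_ms[1:] = np.diff(beat_times) * 1000.0

    flow_at = np.interp(beat_times, t, flow_norm)
    phi_sbp = rng.uniform(0, 2 * np.pi)
    sbp = (
        config.sbp_mean_mmhg
        + config.resp_sbp_amp_mmhg * flow_at
        + config.lf_amp_sbp_mmhg * np.sin(2 * np.pi * LF_HZ * beat_times + phi_sbp)
        + rng.normal(0, config.bp_noise_mmhg, n)
    )
    dbp = (
        config.dbp_mean_mmhg
        + config.resp_dbp_amp_mmhg * flow_at
        + config.lf_amp_dbp_mmhg * np.sin(2 * np.pi * LF_HZ * beat_times + phi_sbp)
        + rng.normal(0, config.bp_noise_mmhg, n)
    )

    # beat-lagged baroreflex: previous systolic deviation feeds back onto RR
    if config.baroreflex_gain_ms_mmhg > 0:
        dev = sbp - config.sbp_mean_mmhg
        rr_ms[1:] += config.baroreflex_gain_ms_mmhg * dev[:-1]

    # ectopics: premature interval then compensatory pause
    ectopic_idx: list[int] = []
    if config.ectopic_rate_per_beat > 0:
        candidates = np.arange(6, n - 6)
        draws = rng.random(candidates.size) < config.ectopic_rate_per_beat
        last = -10
        for idx, hit in zip(candidates, draws):
            if hit and idx - last > 6:
                ectopic_idx.append(int(idx))
                last = idx
        for idx in ectopic_idx:
            rr_ms[idx] *= 0.6
            rr_ms[idx + 1] *= 1.4

    # rebuild beat times from the final RR sequence so times and intervals agree
    beat_times = beat_times[0] + np.concatenate([[0.0], np.cumsum(rr_ms[1:]) / 1000.0])

    rr_s = rr_ms / 1000.0
    qt = config.qtc_true_s * np.sqrt(rr_s) + rng.normal(0, config.qt_noise_s, n)
    st = np.full(n, 0.09) + rng.normal(0, 0.01, n)
    sv = (
        config.sv_mean_cm3
        + config.sv_resp_amp_cm3 * flow_at
        + rng.normal(0, config.sv_noise_cm3, n)
    )
    esv = np.full(n, config.esv_mean_cm3) + rng.normal(0, config.sv_noise_cm3 / 2, n)
    edv = sv + esv

    beats = BeatSeries(
        time_s=beat_times,
        rr_ms=rr_ms,
        sbp_mmhg=sbp,
        dbp_mmhg=dbp,
        qt_s=qt,
        st_nu=st,
        sv_cm3=sv,
        edv_cm3=edv,
        esv_cm3=esv,
    )
    flagged = sorted(set(ectopic_idx) | {i + 1 for i in ectopic_idx})
    truth = GroundTruth(
        qtc_s=config.qtc_true_s,
        baroreflex_gain_ms_mmhg=config.baroreflex_gain_ms_mmhg,
        mean_rr_ms=config.mean_rr_ms,
        epochs={},
        ectopic_beat_indices=np.array(ectopic_idx, dtype=int),
        ectopic_flagged_indices=np.array(flagged, dtype=int),
        beat_count=n,
    )
    return beats, truth


def _epoch_truth(config: SimulationConfig, program: BreathingProgram) -> EpochTruth:
    rate = program.rate_min if program.rate_min is not None else program.rate_mean_min
    rsa_amp = config.rsa_gain_ms
    if config.rsa_vt_ref_l > 0:
        rsa_amp *= program.tidal_volume_l / config.rsa_vt_ref_l
    return EpochTruth(
        rate_min=rate,
        tidal_volume_l=program.tidal_volume_l,
        lf_rr_power_ms2=config.lf_amp_rr_ms**2 / 2.0,
        hf_rr_power_ms2=rsa_amp**2 / 2.0,
    )


def simulate_record(
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
    subject_id: str = "sim-000",
    weight_kg: float = 73.0,
    height_cm: float = 178.0,
) -> tuple[SubjectRecord, GroundTruth]:
    """Simulate a full three-epoch maneuver record for one subject."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    fs = config.flow_fs_hz
    per_epoch = int(round(config.epoch_s * fs))
    chunks = []
    spans = []
    for i, (label, program) in enumerate(config.programs().items()):
        seg = generate_flow(program, config.epoch_s, fs, config.flow_noise_l_s, rng)
        chunks.append(seg.samples)
        spans.append((i * per_epoch, (i + 1) * per_epoch))
    flow = FlowSignal(fs_hz=fs, samples=np.concatenate(chunks))
    beats, truth = generate_beats(
        config, flow, rng, spans=spans, span_labels=list(config.programs())
    )
    truth.epochs = {
        label: _epoch_truth(config, program)
        for label, program in config.programs().items()
    }
    record = SubjectRecord(
        subject_id=subject_id,
        beats=beats,
        flow=flow,
        segments=SegmentMarkers.default_protocol(config.epoch_s),
        weight_kg=weight_kg,
        height_cm=height_cm,
        sinus_rhythm=True,
    )
    record.validate()
    return record, truth


def _disperse(config: SimulationConfig, rng: np.random.Generator) -> SimulationConfig:
    """Draw one subject's parameters with log-normal between-subject dispersion.

    Draws are clipped at +-2 sigma so a finite cohort cannot contain
    physiologically absurd outliers (which would also defeat the clean
    generator / ectopic detector contract).
    """
    updates = {}
    for name, cv in config.cohort_cv.items():
        if cv <= 0:
            continue
        sigma = np.sqrt(np.log(1.0 + cv**2))
        base = getattr(config, name)
        z = float(np.clip(rng.normal(0.0, 1.0), -2.0, 2.0))
        updates[name] = float(base * np.exp(sigma * z - sigma**2 / 2))
    return replace(config, **updates)


def generate_cohort(
    n: int,
    config: Optional[SimulationConfig] = None,
    seed: Optional[int] = None,
) -> list[tuple[SubjectRecord, GroundTruth]]:
    """Simulate ``n`` independent subjects; deterministic given the seed."""
    if n < 1:
        raise ValidationError("cohort size must be at least 1")
    config = config if config is not None else SimulationConfig()
    seed = config.seed if seed is None else seed
    streams = np.random.SeedSequence(seed).spawn(n)
    out = []
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        subject_config = _disperse(config, rng)
        # anthropometrics drawn around the reference adult male
        weight = float(np.clip(rng.normal(73.0, 8.0), 50.0, 110.0))
        height = float(np.clip(rng.normal(178.0, 6.0), 155.0, 205.0))
        record, truth = simulate_record(
            subject_config,
            rng=rng,
            subject_id=f"sim-{i:03d}",
            weight_kg=weight,
            height_cm=height,
        )
        out.append((record, truth))
    return out
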