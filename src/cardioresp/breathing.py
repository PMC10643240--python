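"""Breath segmentation and breathing-pattern indices.

Breaths are delimited on a low-pass filtered copy of the airflow signal by
negative-to-positive zero crossings with a hysteresis band; candidate
breaths failing minimum-duration or minimum-volume rules are merged into
their neighbours. Volumes are integrated from the unfiltered flow
(inspiratory lobe for tidal volume, expiratory lobe for the ventilation
variability series).

Pattern indices follow the conventional definitions: Ti, Te and VT are
breath means, RR = 60/(Ti+Te) per minute, minute ventilation V = VT * RR,
and oxygen uptake is a configurable constant fraction of V (a flow-only
sensor cannot measure gas concentrations; the default fraction 0.046 keeps
VO2/V constant across epochs).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sp_signal

from .errors import AnalysisError
from .records import FlowSignal

DEFAULT_VO2_FRACTION = 0.046


@dataclass(frozen=True)
class BreathThresholds:
    lowpass_hz: float = 2.0
    hysteresis_l_s: float = 0.02
    min_phase_s: float = 0.5
    min_volume_l: float = 0.05


@dataclass
class Breath:
    t_start: float
    ti: float
    te: float
    vt_insp: float
    vt_exp: float

    @property
    def period(self) -> float:
        return self.ti + self.te


@dataclass
class BreathPattern:
    """Epoch means of the respiration pattern (one column of the breathing table)."""

    ti: float
    te: float
    vt: float
    vt_over_ti: float
    vt_over_te: float
    ti_frac: float
    rr_breath: float  # breaths per minute
    v_minute: float  # L/min
    vo2: float  # L/min


def _lowpass(flow: FlowSignal, cutoff_hz: float) -> np.ndarray:
    nyq = flow.fs_hz / 2.0
    if cutoff_hz >= nyq:
        return flow.samples.copy()
    b, a = sp_signal.butter(4, cutoff_hz / nyq)
    return sp_signal.filtfilt(b, a, flow.samples)


def _hysteresis_sign(x: np.ndarray, eps: float) -> np.ndarray:
    """Per-sample state +1/-1 with a +-eps dead band (chatter suppression)."""
    state = np.zeros(x.size, dtype=np.int8)
    cur = 1 if x.size and x[0] >= 0 else -1
    for i, v in enumerate(x):
        if v > eps:
            cur = 1
        elif v < -eps:
            cur = -1
        state[i] = cur
    return state


def segment_breaths(
    flow: FlowSignal, params: BreathThresholds = BreathThresholds()
) -> list[Breath]:
    """Split a flow signal into breaths; raises when fewer than 2 are found.

    The hysteresis state machine only *detects* cycle boundaries (so noise
    inside the dead band cannot split a breath); the boundary itself is then
    refined to the underlying zero crossing of the filtered flow, which
    keeps Ti/Te unbiased by the band width.
    """
    if len(flow) < 4:
        raise AnalysisError("insufficient breaths")
    filt = _lowpass(flow, params.lowpass_hz)
    state = _hysteresis_sign(filt, params.hysteresis_l_s)
    t = flow.time_s
    rising = list(np.nonzero((state[1:] == 1) & (state[:-1] == -1))[0] + 1)
    if state[0] == 1:
        rising.insert(0, 0)  # signal begins mid-inspiration

    def refine(idx: int) -> int:
        while idx > 0 and filt[idx - 1] >= 0:
            idx -= 1
        return idx

    min_period = 2 * params.min_phase_s
    starts: list[int] = []
    for idx in rising:
        idx = refine(int(idx))
        if starts and t[idx] - t[starts[-1]] < min_period:
            continue
        starts.append(idx)
    if not starts:
        raise AnalysisError("insufficient breaths")
    boundaries = starts + [len(flow)]

    dt = 1.0 / flow.fs_hz
    breaths: list[Breath] = []
    for a, b in zip(boundaries, boundaries[1:]):
        seg = flow.samples[a:b]
        # inspiration ends at the first negative excursion of the filtered flow
        neg = np.nonzero(filt[a:b] < 0)[0]
        insp_len = int(neg[0]) if neg.size else seg.size
        ti = insp_len * dt
        te = (seg.size - insp_len) * dt
        vt_insp = float(np.sum(np.clip(seg, 0.0, None)) * dt)
        vt_exp = float(-np.sum(np.clip(seg, None, 0.0)) * dt)
        breath = Breath(t_start=float(t[a]), ti=ti, te=te, vt_insp=vt_insp, vt_exp=vt_exp)
        if breaths and (
            ti < params.min_phase_s
            or te < params.min_phase_s
            or vt_insp < params.min_volume_l
        ):
            # merge an implausibly small candidate into the previous breath
            prev = breaths[-1]
            prev.te += breath.period
            prev.vt_insp += vt_insp
            prev.vt_exp += vt_exp
        else:
            breaths.append(breath)
    if len(breaths) < 2:
        raise AnalysisError("insufficient breaths")
    return breaths


def pattern_indices(
    breaths: list[Breath], vo2_fraction: float = DEFAULT_VO2_FRACTION
) -> BreathPattern:
    if len(breaths) < 2:
        raise AnalysisError("need at least 2 breaths for pattern indices")
    ti = float(np.mean([b.ti for b in breaths]))
    te = float(np.mean([b.te for b in breaths]))
    vt = float(np.mean([b.vt_insp for b in breaths]))
    rr = 60.0 / (ti + te)
    v_minute = vt * rr
    return BreathPattern(
        ti=ti,
        te=te,
        vt=vt,
        vt_over_ti=vt / ti,
        vt_over_te=vt / te,
        ti_frac=ti / (ti + te),
        rr_breath=rr,
        v_minute=v_minute,
        vo2=vo2_fraction * v_minute,
    )


def ventilation_series(breaths: list[Breath]) -> tuple[np.ndarray, np.ndarray]:
    """Breath-wise mean expiratory flow series (L/min) at breath start times."""
    if len(breaths) < 2:
        raise AnalysisError("need at least 2 breaths for a ventilation series")
    times = np.array([b.t_start for b in breaths])
    values = np.array([60.0 * b.vt_exp / b.te for b in breaths])
    return times, values


def ventilation_waveform(flow: FlowSignal) -> np.ndarray:
    """Airflow expressed in L/min, the input to the ventilation variability
    spectrum (its oscillation sits at the breathing frequency, so paced
    breathing lands the power in the matching band)."""
    return 60.0 * flow.samples
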