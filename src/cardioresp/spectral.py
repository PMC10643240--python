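"""Band-power spectral engine shared by RR, SBP, DBP and ventilation series.

Beat/breath event series are resampled to a uniform grid (4 Hz cubic
interpolation by default), detrended, and a Welch power spectral density is
integrated over the conventional short-record bands:

* VLF: (0, 0.04] Hz
* LF:  (0.04, 0.15] Hz
* HF:  (0.15, 0.4] Hz
* TP:  integral up to 0.4 Hz

Band powers are computed from the cumulative trapezoidal integral of the
density, so VLF + LF + HF = TP holds exactly. Normalized units follow
``LFn = LF/(TP - VLF) * 100`` and the centralization index is
``IC = (LF + VLF)/HF``. The baroreflex alpha-coefficient is
``sqrt(band_rr / band_sbp)`` in ms/mmHg.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy import interpolate, signal
from scipy.integrate import cumulative_trapezoid

from .errors import AnalysisError, ValidationError

DEFAULT_RESAMPLE_HZ = 4.0
DEFAULT_SEGMENT_S = 64.0
MIN_SERIES_SAMPLES = 64


@dataclass(frozen=True)
class BandScheme:
    """Contiguous half-open band edges in Hz; ``tp`` integrates to ``hf_hi``."""

    vlf_hi: float = 0.04
    lf_hi: float = 0.15
    hf_hi: float = 0.40

    def __post_init__(self):
        if not (0.0 < self.vlf_hi < self.lf_hi < self.hf_hi):
            raise ValidationError("band edges must satisfy 0 < vlf < lf < hf")


@dataclass
class SpectralIndices:
    """Band powers in the squared unit of the input series plus derivatives.

    Ratio fields are ``None`` ("absent") when their denominator power is
    zero; they are never coerced to 0.
    """

    tp: float
    vlf: float
    lf: float
    hf: float
    lfn: Optional[float] = None
    hfn: Optional[float] = None
    lfhf: Optional[float] = None
    ic: Optional[float] = None


@dataclass
class Baroreflex:
    """Spectral baroreflex sensitivity (alpha-coefficient), ms/mmHg."""

    br_lf: Optional[float]
    br_hf: Optional[float]


def resample_events(
    times: np.ndarray,
    values: np.ndarray,
    fs: float = DEFAULT_RESAMPLE_HZ,
) -> tuple[np.ndarray, np.ndarray]:
    """Interpolate an event series onto a uniform, detrended grid.

    Cubic interpolation over ``[first, last]`` event time; linear fallback
    below 4 points. The output has its mean and linear trend removed.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    keep = np.isfinite(times) & np.isfinite(values)
    times, values = times[keep], values[keep]
    if times.size < 4:
        raise AnalysisError("need at least 4 events to resample")
    span = times[-1] - times[0]
    if span < 30.0:
        raise AnalysisError(f"event span {span:.1f} s is too short (< 30 s)")
    kind = "cubic" if times.size >= 4 else "linear"
    f = interpolate.interp1d(times, values, kind=kind, assume_sorted=True)
    grid = times[0] + np.arange(int(np.floor(span * fs)) + 1) / fs
    grid = grid[grid <= times[-1] + 1e-12]
    out = signal.detrend(f(grid), type="linear")
    return grid, out


def band_powers(
    series: np.ndarray,
    fs: float,
    scheme: BandScheme = BandScheme(),
    segment_s: float = DEFAULT_SEGMENT_S,
    window: str = "hann",
    detrend: bool = True,
) -> SpectralIndices:
    """Welch band powers of a uniform series (density integrated per band)."""
    series = np.asarray(series, dtype=float)
    if series.size < MIN_SERIES_SAMPLES:
        raise AnalysisError(
            f"series of {series.size} samples is too short for spectral analysis"
        )
    nperseg = min(series.size, max(16, int(round(segment_s * fs))))
    freqs, psd = signal.welch(
        series,
        fs=fs,
        window=window,
        nperseg=nperseg,
        noverlap=nperseg // 2,
        detrend="linear" if detrend else False,
        scaling="density",
    )
    cum = np.concatenate([[0.0], cumulative_trapezoid(psd, freqs)])

    def cum_at(f: float) -> float:
        return float(np.interp(f, freqs, cum))

    vlf = cum_at(scheme.vlf_hi) - cum_at(freqs[0])
    lf = cum_at(scheme.lf_hi) - cum_at(scheme.vlf_hi)
    hf = cum_at(scheme.hf_hi) - cum_at(scheme.lf_hi)
    tp = vlf + lf + hf
    return normalize_and_ratios(SpectralIndices(tp=tp, vlf=vlf, lf=lf, hf=hf))


def normalize_and_ratios(powers: SpectralIndices) -> SpectralIndices:
    """Fill LFn/HFn, LF/HF and IC from raw band powers."""
    tp, vlf, lf, hf = powers.tp, powers.vlf, powers.lf, powers.hf
    if min(tp, vlf, lf, hf) < 0:
        raise ValidationError("band powers must be non-negative")
    if tp < vlf:
        raise ValidationError("total power smaller than VLF power")
    denom = tp - vlf
    lfn = 100.0 * lf / denom if denom > 0 else None
    hfn = 100.0 * hf / denom if denom > 0 else None
    lfhf = lf / hf if hf > 0 else None
    ic = (lf + vlf) / hf if hf > 0 else None
    return replace(powers, lfn=lfn, hfn=hfn, lfhf=lfhf, ic=ic)


def event_spectrum(
    times: np.ndarray,
    values: np.ndarray,
    fs: float = DEFAULT_RESAMPLE_HZ,
    scheme: BandScheme = BandScheme(),
    segment_s: float = DEFAULT_SEGMENT_S,
    window: str = "hann",
) -> SpectralIndices:
    """Convenience: resample an event series, then integrate band powers."""
    _, series = resample_events(times, values, fs=fs)
    return band_powers(series, fs=fs, scheme=scheme, segment_s=segment_s, window=window)


def baroreflex_alpha(rr_spectrum: SpectralIndices, sbp_spectrum: SpectralIndices) -> Baroreflex:
    """Alpha-coefficient per band: sqrt(RR power [ms^2] / SBP power [mmHg^2])."""

    def alpha(num: float, den: float, band: str) -> Optional[float]:
        if den <= 0:
            warnings.warn(
                f"SBP {band} power is zero; baroreflex alpha reported as absent",
                stacklevel=3,
            )
            return None
        return float(np.sqrt(num / den))

    return Baroreflex(
        br_lf=alpha(rr_spectrum.lf, sbp_spectrum.lf, "LF"),
        br_hf=alpha(rr_spectrum.hf, sbp_spectrum.hf, "HF"),
    )
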