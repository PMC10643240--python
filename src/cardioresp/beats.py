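"""Time-domain and geometric heart-rhythm indices plus the exclusion rule.

Ectopic (extrasystolic) beats are flagged with an 11-beat running-median
detector: beat *i* is ectopic when its RR deviates from the window median
by more than 20% of that median. Any flagged beat in any epoch — or a
non-sinus annotation — excludes the whole record from cohort analysis.

The geometric (histogram) indices use fixed 50-ms RR bins anchored at 0 ms,
with ties between equally tall bins broken toward the shorter-RR bin:

* Mo     mode of the RR distribution, s (centre of the tallest bin)
* AMo    share of intervals in the tallest bin, %
* MxDMn  RR variation range, s
* SI     AMo / (2 * Mo * MxDMn)       stress index, c.u.
* ABI    AMo / MxDMn                  autonomic balance index, c.u.
* SRAI   AMo / Mo                     subcortical regulation adequacy, c.u.
* ARI    1 / (Mo * MxDMn)             autonomic regulation index, c.u.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .errors import AnalysisError
from .records import BeatSeries, SubjectRecord, slice_epoch

DEFAULT_ECTOPIC_THRESHOLD = 0.20
ECTOPIC_WINDOW = 11
DEFAULT_BIN_MS = 50.0


@dataclass
class HrvTimeDomain:
    sdann: float  # SD of all NN intervals in the epoch, ms
    rmssd: float  # ms
    pnn50: float  # %

    @property
    def sdnn(self) -> float:
        """Alias: on 2-min epochs the SD of all NN intervals is the SDNN."""
        return self.sdann


@dataclass
class BaevskyIndices:
    mo: float  # s
    amo: float  # %
    mxdmn: float  # s
    abi: Optional[float]
    srai: float
    ari: Optional[float]
    si_stress: Optional[float]


@dataclass
class EcgIntervals:
    hr: float  # 1/min
    qtc: Optional[float]  # s, Bazett-corrected per beat then averaged
    p: Optional[float] = None
    pq: Optional[float] = None
    qrs: Optional[float] = None
    qt: Optional[float] = None
    st_level: Optional[float] = None


def clean_rr(beats: BeatSeries) -> np.ndarray:
    """RR intervals usable for index computation.

    Drops NaN RR (epoch-boundary intervals), flagged ectopic beats and the
    interval immediately following each flagged beat.
    """
    rr = beats.rr_ms
    valid = np.isfinite(rr)
    if beats.ectopic is not None:
        flagged = beats.ectopic
        following = np.zeros_like(flagged)
        following[1:] = flagged[:-1]
        valid &= ~flagged & ~following
    return rr[valid]


def clean_mask(beats: BeatSeries) -> np.ndarray:
    """Boolean mask of beats whose RR survives :func:`clean_rr`."""
    valid = np.isfinite(beats.rr_ms)
    if beats.ectopic is not None:
        flagged = beats.ectopic
        following = np.zeros_like(flagged)
        following[1:] = flagged[:-1]
        valid &= ~flagged & ~following
    return valid


def detect_ectopics(
    beats: BeatSeries,
    threshold: float = DEFAULT_ECTOPIC_THRESHOLD,
    window: int = ECTOPIC_WINDOW,
) -> tuple[BeatSeries, int]:
    """Flag beats whose RR deviates > ``threshold`` from a running median.

    The median window is centred on the beat and shrinks at the record
    edges. Returns a copy of the series with the ``ectopic`` flags set and
    the flag count.
    """
    rr = beats.rr_ms
    finite_idx = np.nonzero(np.isfinite(rr))[0]
    if finite_idx.size < window:
        raise AnalysisError(
            f"need at least {window} beats for ectopic detection, got {finite_idx.size}"
        )
    half = window // 2
    flags = np.zeros(len(beats), dtype=bool)
    vals = rr[finite_idx]
    for pos, idx in enumerate(finite_idx):
        lo = max(0, pos - half)
        hi = min(vals.size, pos + half + 1)
        med = float(np.median(vals[lo:hi]))
        if med > 0 and abs(vals[pos] - med) > threshold * med:
            flags[idx] = True
    flagged = replace(beats, ectopic=flags)
    return flagged, int(flags.sum())


def exclusion_gate(
    record: SubjectRecord, threshold: float = DEFAULT_ECTOPIC_THRESHOLD
) -> tuple[bool, Optional[str]]:
    """Decide keep/exclude for a record; reason names the epoch and rule.

    Mirrors the protocol's only exclusion condition: extrasystoles in any
    epoch, or non-sinus rhythm.
    """
    if not record.sinus_rhythm:
        return False, "non-sinus rhythm"
    beats = record.beats
    if beats.ectopic is None:
        beats, _ = detect_ectopics(beats, threshold=threshold)
        record = replace(record, beats=beats)
    for label in record.segments.windows:
        epoch = slice_epoch(record, label)
        if epoch.beats.ectopic is not None and epoch.beats.ectopic.any():
            return False, f"extrasystole at {label}"
    return True, None


def time_domain(rr_ms: np.ndarray) -> HrvTimeDomain:
    """Statistical HRV indices from clean NN intervals (ms)."""
    rr_ms = np.asarray(rr_ms, dtype=float)
    if rr_ms.size < 10:
        raise AnalysisError("need at least 10 clean intervals for time-domain indices")
    diffs = np.diff(rr_ms)
    return HrvTimeDomain(
        sdann=float(np.std(rr_ms, ddof=1)),
        rmssd=float(np.sqrt(np.mean(diffs**2))),
        pnn50=float(100.0 * np.mean(np.abs(diffs) > 50.0)),
    )


def baevsky(rr_ms: np.ndarray, bin_ms: float = DEFAULT_BIN_MS) -> BaevskyIndices:
    rr_ms = np.asarray(rr_ms, dtype=float)
    if rr_ms.size < 30:
        raise AnalysisError("need at least 30 clean intervals for geometric indices")
    bins = np.floor(rr_ms / bin_ms).astype(int)
    counts = np.bincount(bins)
    mode_bin = int(np.argmax(counts))  # argmax takes the first => shorter-RR tie break
    mo = (mode_bin + 0.5) * bin_ms / 1000.0
    amo = 100.0 * counts[mode_bin] / rr_ms.size
    mxdmn = float(rr_ms.max() - rr_ms.min()) / 1000.0
    if mxdmn > 0:
        si = amo / (2.0 * mo * mxdmn)
        abi = amo / mxdmn
        ari = 1.0 / (mo * mxdmn)
    else:
        si = abi = ari = None
    return BaevskyIndices(
        mo=mo, amo=amo, mxdmn=mxdmn, abi=abi, srai=amo / mo, ari=ari, si_stress=si
    )


def ecg_summary(beats: BeatSeries, mask: Optional[np.ndarray] = None) -> EcgIntervals:
    """HR and Bazett-corrected QT from clean beats; optional ST pass-through."""
    if mask is None:
        mask = clean_mask(beats)
    rr = beats.rr_ms[mask]
    if rr.size == 0:
        raise AnalysisError("no clean intervals for ECG summary")
    hr = 60000.0 / float(np.mean(rr))
    qtc = qt = None
    if beats.qt_s is not None:
        qt_vals = beats.qt_s[mask]
        ok = np.isfinite(qt_vals)
        if ok.any():
            qt = float(np.mean(qt_vals[ok]))
            qtc = float(np.mean(qt_vals[ok] / np.sqrt(rr[ok] / 1000.0)))
    st = None
    if beats.st_nu is not None:
        st_vals = beats.st_nu[mask]
        ok = np.isfinite(st_vals)
        if ok.any():
            st = float(np.mean(st_vals[ok]))
    return EcgIntervals(hr=hr, qtc=qtc, qt=qt, st_level=st)
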