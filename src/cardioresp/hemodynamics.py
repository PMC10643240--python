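"""Systemic hemodynamics derived from per-beat stroke-volume annotations,
blood-pressure summaries and the two cardiorespiratory synchronization
indices (Hildebrandt rate ratio and the volume synchronization index).

Stroke volume and chamber volumes enter as record annotations from the
simulator or an external estimator; this module only derives means and the
standard combinations (CO, CI, stroke index, MAP, peripheral resistance).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import ValidationError
from .records import BeatSeries, BpSummary

#: mmHg*min/dm^3 -> dyn*s/cm^5
GPVR_CONVERSION = 80.0


@dataclass
class Hemodynamics:
    edv: Optional[float]  # cm^3
    esv: Optional[float]  # cm^3
    sv: float  # cm^3
    co: float  # dm^3/min
    ci: float  # dm^3/min/m^2
    stroke_index: float  # cm^3/m^2
    gpvr: Optional[float]  # dyn*s/cm^5
    map: float  # mmHg
    bsa: float  # m^2


@dataclass
class SyncIndices:
    hi: float  # dimensionless rate ratio
    vsi: float  # dm^3/L


def body_surface_area(weight_kg: float, height_cm: float, formula: str = "dubois") -> float:
    """Body surface area in m^2 (DuBois default, Mosteller optional)."""
    if weight_kg <= 0 or height_cm <= 0:
        raise ValidationError("weight and height must be positive")
    if formula == "dubois":
        return 0.007184 * weight_kg**0.425 * height_cm**0.725
    if formula == "mosteller":
        return float(np.sqrt(weight_kg * height_cm / 3600.0))
    raise ValidationError(f"unknown body-surface formula {formula!r}")


def bp_summary(beats: BeatSeries, mask: Optional[np.ndarray] = None) -> BpSummary:
    """Epoch means of systolic, diastolic and per-beat pulse pressure.

    Pulse pressure is averaged beat-wise, which differs from the difference
    of the SBP/DBP means whenever the two channels oscillate out of phase.
    """
    sbp = beats.sbp_mmhg
    dbp = beats.dbp_mmhg
    if mask is not None:
        sbp, dbp = sbp[mask], dbp[mask]
    ok = np.isfinite(sbp) & np.isfinite(dbp)
    if not ok.any():
        raise ValidationError("no finite pressure annotations")
    return BpSummary(
        sbpf=float(np.mean(sbp[ok])),
        dbpf=float(np.mean(dbp[ok])),
        pbpf=float(np.mean(sbp[ok] - dbp[ok])),
    )


def hemodynamic_indices(
    beats: BeatSeries,
    bp: BpSummary,
    hr: float,
    bsa: float,
    mask: Optional[np.ndarray] = None,
) -> Hemodynamics:
    """Epoch hemodynamics: CO = mean SV * HR / 1000, MAP = DBP + PP/3,
    GPVR = 80 * MAP / CO."""
    if beats.sv_cm3 is None:
        raise ValidationError("stroke-volume annotations are absent")
    sv_vals = beats.sv_cm3 if mask is None else beats.sv_cm3[mask]
    ok = np.isfinite(sv_vals)
    if not ok.any():
        raise ValidationError("no finite stroke-volume annotations")
    sv = float(np.mean(sv_vals[ok]))

    def optional_mean(arr):
        if arr is None:
            return None
        vals = arr if mask is None else arr[mask]
        good = np.isfinite(vals)
        return float(np.mean(vals[good])) if good.any() else None

    edv = optional_mean(beats.edv_cm3)
    esv = optional_mean(beats.esv_cm3)
    co = sv * hr / 1000.0
    mean_ap = bp.dbpf + (bp.sbpf - bp.dbpf) / 3.0
    gpvr = GPVR_CONVERSION * mean_ap / co if co > 0 else None
    return Hemodynamics(
        edv=edv,
        esv=esv,
        sv=sv,
        co=co,
        ci=co / bsa,
        stroke_index=sv / bsa,
        gpvr=gpvr,
        map=mean_ap,
        bsa=bsa,
    )


def sync_indices(hr: float, rr_breath: float, co: float, v_minute: float) -> SyncIndices:
    """HI = HR / breathing rate; VSI = CO / minute ventilation."""
    if rr_breath <= 0 or v_minute <= 0:
        raise ValidationError("breathing rate and minute ventilation must be positive")
    return SyncIndices(hi=hr / rr_breath, vsi=co / v_minute)
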