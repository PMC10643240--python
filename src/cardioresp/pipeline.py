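"""Three-epoch maneuver orchestration: per-epoch index bundles, delta
increments against the spontaneous-breathing epoch, reactivity
classification against shipped quartile limits, and cohort statistics.

Index names follow the published table layout. Two indices share the
label "SI" in print; here the Baevsky stress index keeps ``SI`` and the
stroke index is ``SI_stroke``.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from . import beats as beats_mod
from . import breathing, hemodynamics, spectral
from .errors import AnalysisError, ExcludedRecordError, ValidationError
from .records import BpSummary, SubjectRecord, slice_epoch

EPOCH_ORDER = ("SR", "CR6", "CR15")
CONTRASTS = {"CR6": "SR-CR6", "CR15": "SR-CR15"}

CLASS_REDUCED = "reduced"
CLASS_EXPECTED = "expected"
CLASS_INCREASED = "increased"
CLASS_NOT_EVALUATED = "not_evaluated"


@dataclass
class AnalysisConfig:
    resample_hz: float = 4.0
    welch_segment_s: float = 64.0
    window: str = "hann"
    bands: spectral.BandScheme = field(default_factory=spectral.BandScheme)
    vo2_fraction: float = breathing.DEFAULT_VO2_FRACTION
    ectopic_threshold: float = beats_mod.DEFAULT_ECTOPIC_THRESHOLD
    breath_thresholds: breathing.BreathThresholds = field(
        default_factory=breathing.BreathThresholds
    )
    bsa_formula: str = "dubois"
    #: per-index multipliers for the geometric c.u. indices (abi, srai, ari,
    #: si_stress). Devices apply unpublished scaling constants; rather than
    #: guess them the factors default to 1 and are configurable.
    baevsky_scale: dict = field(default_factory=dict)


@dataclass
class EpochIndices:
    """Everything computed from one maneuver window."""

    label: str
    pattern: breathing.BreathPattern
    vrv: spectral.SpectralIndices
    hrv_spec: spectral.SpectralIndices
    hrv_time: beats_mod.HrvTimeDomain
    baevsky: beats_mod.BaevskyIndices
    ecg: beats_mod.EcgIntervals
    sbp_spec: spectral.SpectralIndices
    dbp_spec: spectral.SpectralIndices
    bp: BpSummary
    baroreflex: spectral.Baroreflex
    hemo: Optional[hemodynamics.Hemodynamics]
    sync: Optional[hemodynamics.SyncIndices]


@dataclass
class IncrementReport:
    """Per-index deltas (CR epoch minus SR) with reactivity classes."""

    delta_cr6: dict
    delta_cr15: dict
    class_cr6: dict = field(default_factory=dict)
    class_cr15: dict = field(default_factory=dict)


@dataclass
class SubjectReport:
    subject_id: str
    epochs: dict  # label -> EpochIndices
    flat: dict  # label -> {index name -> value}
    increments: IncrementReport


@dataclass
class CohortSummary:
    per_epoch: pd.DataFrame  # index, epoch, median, q1, q3, n
    wilcoxon: pd.DataFrame  # index, contrast, statistic, p_value, n
    increments: pd.DataFrame  # per-subject deltas (long form)
    excluded: list  # (subject_id, reason)
    n_included: int


def flatten_epoch(ep: EpochIndices) -> dict:
    """One epoch's scalar indices keyed by their published table names."""
    s = ep
    out = {
        "Ti": s.pattern.ti,
        "Te": s.pattern.te,
        "VT": s.pattern.vt,
        "VT/TI": s.pattern.vt_over_ti,
        "VT/TE": s.pattern.vt_over_te,
        "Ti/Ttot": s.pattern.ti_frac,
        "RR": s.pattern.rr_breath,
        "V": s.pattern.v_minute,
        "VO2": s.pattern.vo2,
        "TP_R": s.vrv.tp,
        "VLF_R": s.vrv.vlf,
        "LF_R": s.vrv.lf,
        "LF_Rn": s.vrv.lfn,
        "HF_R": s.vrv.hf,
        "HF_Rn": s.vrv.hfn,
        "LFHF_R": s.vrv.lfhf,
        "IC_R": s.vrv.ic,
        "HR": s.ecg.hr,
        "QTc": s.ecg.qtc,
        "ST": s.ecg.st_level,
        "TP": s.hrv_spec.tp,
        "VLF": s.hrv_spec.vlf,
        "LF": s.hrv_spec.lf,
        "LFn": s.hrv_spec.lfn,
        "HF": s.hrv_spec.hf,
        "HFn": s.hrv_spec.hfn,
        "LFHF": s.hrv_spec.lfhf,
        "IC_HR": s.hrv_spec.ic,
        "SDANN": s.hrv_time.sdann,
        "RMSSD": s.hrv_time.rmssd,
        "pNN50": s.hrv_time.pnn50,
        "Mo": s.baevsky.mo,
        "AMo": s.baevsky.amo,
        "MxDMn": s.baevsky.mxdmn,
        "ABI": s.baevsky.abi,
        "SRAI": s.baevsky.srai,
        "ARI": s.baevsky.ari,
        "SI": s.baevsky.si_stress,
        "SBPf": s.bp.sbpf,
        "DBPf": s.bp.dbpf,
        "PBPf": s.bp.pbpf,
        "TP_SBP": s.sbp_spec.tp,
        "VLF_SBP": s.sbp_spec.vlf,
        "LF_SBP": s.sbp_spec.lf,
        "LF_SBPn": s.sbp_spec.lfn,
        "HF_SBP": s.sbp_spec.hf,
        "HF_SBPn": s.sbp_spec.hfn,
        "LFHF_SBP": s.sbp_spec.lfhf,
        "IC_SBP": s.sbp_spec.ic,
        "TP_DBP": s.dbp_spec.tp,
        "VLF_DBP": s.dbp_spec.vlf,
        "LF_DBP": s.dbp_spec.lf,
        "LF_DBPn": s.dbp_spec.lfn,
        "HF_DBP": s.dbp_spec.hf,
        "HF_DBPn": s.dbp_spec.hfn,
        "LFHF_DBP": s.dbp_spec.lfhf,
        "IC_DBP": s.dbp_spec.ic,
        "BR_LF": s.baroreflex.br_lf,
        "BR_HF": s.baroreflex.br_hf,
    }
    if s.hemo is not None:
        out.update(
            {
                "EDV": s.hemo.edv,
                "ESV": s.hemo.esv,
                "SV": s.hemo.sv,
                "CO": s.hemo.co,
                "CI": s.hemo.ci,
                "GPVR": s.hemo.gpvr,
                "SI_stroke": s.hemo.stroke_index,
            }
        )
    if s.sync is not None:
        out.update({"VSI": s.sync.vsi, "HI": s.sync.hi})
    return out


def _beat_event_series(beats, values, mask):
    times = beats.time_s[mask]
    vals = values[mask]
    ok = np.isfinite(vals)
    return times[ok], vals[ok]


def analyze_epoch(
    record: SubjectRecord, label: str, config: AnalysisConfig
) -> EpochIndices:
    """Compute the full index bundle for one labelled window.

    The record's beats must already carry ectopic flags; flagged beats and
    the interval following each are excluded (bridged by interpolation in
    the spectral path).
    """
    epoch = slice_epoch(record, label)
    beats = epoch.beats
    mask = beats_mod.clean_mask(beats)
    rr = beats.rr_ms[mask]
    if rr.size < 30:
        raise AnalysisError(f"epoch {label}: too few clean beats ({rr.size})")

    breaths = breathing.segment_breaths(epoch.flow, config.breath_thresholds)
    pattern = breathing.pattern_indices(breaths, config.vo2_fraction)

    spec_kwargs = dict(
        fs=config.resample_hz,
        scheme=config.bands,
        segment_s=config.welch_segment_s,
        window=config.window,
    )
    vrv = spectral.band_powers(
        breathing.ventilation_waveform(epoch.flow),
        fs=epoch.flow.fs_hz,
        scheme=config.bands,
        segment_s=config.welch_segment_s,
        window=config.window,
    )
    t_rr, v_rr = _beat_event_series(beats, beats.rr_ms, mask)
    hrv_spec = spectral.event_spectrum(t_rr, v_rr, **spec_kwargs)
    t_s, v_s = _beat_event_series(beats, beats.sbp_mmhg, mask)
    sbp_spec = spectral.event_spectrum(t_s, v_s, **spec_kwargs)
    t_d, v_d = _beat_event_series(beats, beats.dbp_mmhg, mask)
    dbp_spec = spectral.event_spectrum(t_d, v_d, **spec_kwargs)

    hrv_time = beats_mod.time_domain(rr)
    baevsky = beats_mod.baevsky(rr)
    if config.baevsky_scale:
        from dataclasses import replace as _replace

        updates = {
            name: getattr(baevsky, name) * factor
            for name, factor in config.baevsky_scale.items()
            if getattr(baevsky, name, None) is not None
        }
        baevsky = _replace(baevsky, **updates)
    ecg = beats_mod.ecg_summary(beats, mask)
    bp = hemodynamics.bp_summary(beats, mask)
    baroreflex = spectral.baroreflex_alpha(hrv_spec, sbp_spec)

    hemo = sync = None
    if beats.sv_cm3 is not None:
        bsa = hemodynamics.body_surface_area(
            record.weight_kg, record.height_cm, config.bsa_formula
        )
        hemo = hemodynamics.hemodynamic_indices(beats, bp, ecg.hr, bsa, mask)
        sync = hemodynamics.sync_indices(
            ecg.hr, pattern.rr_breath, hemo.co, pattern.v_minute
        )
    return EpochIndices(
        label=label,
        pattern=pattern,
        vrv=vrv,
        hrv_spec=hrv_spec,
        hrv_time=hrv_time,
        baevsky=baevsky,
        ecg=ecg,
        sbp_spec=sbp_spec,
        dbp_spec=dbp_spec,
        bp=bp,
        baroreflex=baroreflex,
        hemo=hemo,
        sync=sync,
    )


def compute_increments(flat: dict) -> IncrementReport:
    """delta_X = X(CR epoch) - X(SR) for every scalar index present in both."""
    deltas = {}
    for cr in ("CR6", "CR15"):
        d = {}
        for name, value in flat[cr].items():
            base = flat["SR"].get(name)
            if value is None or base is None:
                d[name] = None
            else:
                d[name] = value - base
        deltas[cr] = d
    return IncrementReport(delta_cr6=deltas["CR6"], delta_cr15=deltas["CR15"])


def load_default_limits() -> pd.DataFrame:
    """Quartile reference limits shipped as package data.

    Derived from a published cohort of 183 male athletes; classifying other
    populations against them is a provenance caveat, not an error.
    """
    path = importlib.resources.files("cardioresp.data").joinpath("reference_limits.csv")
    with importlib.resources.as_file(path) as p:
        return pd.read_csv(p)


def classify_reactivity(
    report: IncrementReport, limits: Optional[pd.DataFrame] = None
) -> IncrementReport:
    """Assign reduced/expected/increased per index and contrast.

    The closed interval ``[q1, q3]`` classifies as expected; deltas below q1
    take the low-tail class, above q3 the high-tail class. Indices missing
    from the limits table are ``not_evaluated``.
    """
    if limits is None:
        limits = load_default_limits()
    lut = {
        (row["index"], row["contrast"]): row for _, row in limits.iterrows()
    }
    for contrast, deltas, classes in (
        ("SR-CR6", report.delta_cr6, report.class_cr6),
        ("SR-CR15", report.delta_cr15, report.class_cr15),
    ):
        for name, delta in deltas.items():
            row = lut.get((name, contrast))
            if row is None or delta is None:
                classes[name] = CLASS_NOT_EVALUATED
                continue
            q1, q3 = float(row["q1"]), float(row["q3"])
            if q1 > q3:
                raise ValidationError(f"limits for {name}/{contrast} have q1 > q3")
            if delta < q1:
                classes[name] = str(row.get("low_tail_class", CLASS_REDUCED))
            elif delta > q3:
                classes[name] = str(row.get("high_tail_class", CLASS_INCREASED))
            else:
                classes[name] = CLASS_EXPECTED
    return report


def analyze_subject(
    record: SubjectRecord,
    config: Optional[AnalysisConfig] = None,
    limits: Optional[pd.DataFrame] = None,
    apply_gate: bool = True,
) -> SubjectReport:
    """Full per-subject analysis; raises ExcludedRecordError when gated out."""
    config = config if config is not None else AnalysisConfig()
    flagged, _ = beats_mod.detect_ectopics(record.beats, config.ectopic_threshold)
    from dataclasses import replace as _replace

    record = _replace(record, beats=flagged)
    if apply_gate:
        keep, reason = beats_mod.exclusion_gate(record, config.ectopic_threshold)
        if not keep:
            raise ExcludedRecordError(reason)
    epochs = {label: analyze_epoch(record, label, config) for label in EPOCH_ORDER}
    flat = {label: flatten_epoch(ep) for label, ep in epochs.items()}
    increments = classify_reactivity(compute_increments(flat), limits)
    return SubjectReport(
        subject_id=record.subject_id, epochs=epochs, flat=flat, increments=increments
    )


def wilcoxon_paired(x: np.ndarray, y: np.ndarray) -> tuple:
    """Wilcoxon matched-pairs test.

    Exact null distribution when n (non-zero differences) <= 25 and there
    are no ties; normal approximation otherwise. Zero differences are
    dropped. Returns ``(statistic, p_value, n_used)``; an all-zero
    difference vector is not evaluable and returns ``(None, None, 0)``.
    """
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    d = d[np.isfinite(d)]
    d = d[d != 0]
    if d.size == 0:
        return None, None, 0
    ties = np.unique(np.abs(d)).size < d.size
    method = "exact" if (d.size <= 25 and not ties) else "approx"
    res = stats.wilcoxon(d, zero_method="wilcox", method=method)
    return float(res.statistic), float(res.pvalue), int(d.size)


def quartiles(values: np.ndarray) -> tuple:
    """Median and Q1/Q3 with linear order-statistic interpolation (type 7)."""
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size == 0:
        return np.nan, np.nan, np.nan
    q1, med, q3 = np.quantile(values, [0.25, 0.5, 0.75])
    return float(med), float(q1), float(q3)


def cohort_analysis(
    records: list,
    config: Optional[AnalysisConfig] = None,
    limits: Optional[pd.DataFrame] = None,
) -> tuple[CohortSummary, list]:
    """Gate, analyze and summarize a cohort.

    Returns the summary plus the per-subject reports of included records.
    """
    config = config if config is not None else AnalysisConfig()
    included: list[SubjectReport] = []
    excluded: list[tuple] = []
    for record in records:
        try:
            included.append(analyze_subject(record, config, limits))
        except ExcludedRecordError as err:
            excluded.append((record.subject_id, err.reason))
    if not included:
        raise AnalysisError("all subjects excluded; nothing to summarize")

    index_names = sorted(
        {name for rep in included for label in EPOCH_ORDER for name in rep.flat[label]}
    )
    per_epoch_rows = []
    wilcoxon_rows = []
    increment_rows = []
    for name in index_names:
        series = {}
        for label in EPOCH_ORDER:
            vals = np.array(
                [
                    rep.flat[label].get(name, np.nan)
                    if rep.flat[label].get(name) is not None
                    else np.nan
                    for rep in included
                ],
                dtype=float,
            )
            series[label] = vals
            med, q1, q3 = quartiles(vals)
            per_epoch_rows.append(
                {
                    "index": name,
                    "epoch": label,
                    "median": med,
                    "q1": q1,
                    "q3": q3,
                    "n": int(np.isfinite(vals).sum()),
                }
            )
        for a, b in (("SR", "CR6"), ("SR", "CR15"), ("CR6", "CR15")):
            pair = np.isfinite(series[a]) & np.isfinite(series[b])
            if pair.sum() >= 6:
                statistic, p, n_used = wilcoxon_paired(series[b][pair], series[a][pair])
            else:
                statistic, p, n_used = None, None, 0
            wilcoxon_rows.append(
                {
                    "index": name,
                    "contrast": f"{a}-{b}",
                    "statistic": statistic,
                    "p_value": p,
                    "n": n_used,
                }
            )
    for rep in included:
        for contrast, deltas in (
            ("SR-CR6", rep.increments.delta_cr6),
            ("SR-CR15", rep.increments.delta_cr15),
        ):
            classes = (
                rep.increments.class_cr6
                if contrast == "SR-CR6"
                else rep.increments.class_cr15
            )
            for name, delta in deltas.items():
                increment_rows.append(
                    {
                        "subject_id": rep.subject_id,
                        "index": name,
                        "contrast": contrast,
                        "delta": delta,
                        "class": classes.get(name, CLASS_NOT_EVALUATED),
                    }
                )
    summary = CohortSummary(
        per_epoch=pd.DataFrame(per_epoch_rows),
        wilcoxon=pd.DataFrame(wilcoxon_rows),
        increments=pd.DataFrame(increment_rows),
        excluded=excluded,
        n_included=len(included),
    )
    return summary, included


def export_empirical_limits(summary: CohortSummary) -> pd.DataFrame:
    """Quartiles of the cohort's own deltas in the reference-limits format,
    so a user cohort can define its own classification table."""
    rows = []
    inc = summary.increments
    for (name, contrast), grp in inc.groupby(["index", "contrast"]):
        vals = grp["delta"].to_numpy(dtype=float)
        med, q1, q3 = quartiles(vals)
        if not np.isfinite(q1):
            continue
        rows.append(
            {
                "index": name,
                "contrast": contrast,
                "q1": q1,
                "q3": q3,
                "low_tail_class": CLASS_REDUCED,
                "high_tail_class": CLASS_INCREASED,
            }
        )
    return pd.DataFrame(rows)
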