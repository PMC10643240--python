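# cardioresp

Analysis toolkit for a three-epoch **paced-breathing maneuver** applied to
combined cardiorespiratory recordings: two minutes of spontaneous breathing
(SR), two minutes of controlled breathing at 6/min (CR6, 0.1 Hz, 5 s in /
5 s out) and two minutes at 15/min (CR15, 0.25 Hz, 2 s in / 2 s out).

From a per-subject record — a beat table (RR interval, beat-to-beat finger
systolic/diastolic pressure, optional QT/ST/stroke-volume annotations), a
uniformly sampled airflow channel and the three epoch windows — the
pipeline computes, per epoch:

* **breathing pattern**: Ti, Te, VT, VT/Ti, VT/Te, Ti/Ttot, breathing rate,
  minute ventilation, VO2 (constant configurable fraction of ventilation);
* **ventilation variability (VRV)**: TP/VLF/LF/HF band powers of the
  airflow expressed in L/min, with normalized units, LF/HF and the
  centralization index;
* **heart-rate variability**: Welch band powers of the RR series
  (4 Hz cubic resampling), normalized units, LF/HF, IC; time-domain SDANN
  (SD of all NN in the epoch), RMSSD, pNN50; geometric (histogram) indices
  Mo, AMo, MxDMn, SI, ABI, SRAI, ARI;
* **blood-pressure variability** for SBP and DBP, plus finger-pressure
  means and per-beat pulse pressure;
* **baroreflex alpha-coefficient** BR_LF / BR_HF = sqrt(RR band power /
  SBP band power), ms/mmHg;
* **ECG summaries**: HR, Bazett-corrected QTc, ST pass-through;
* **hemodynamics** (from stroke-volume annotations): EDV, ESV, SV, CO, CI,
  stroke index, MAP, peripheral resistance, body surface area;
* **synchronization**: Hildebrandt index (HR / breathing rate) and the
  volume synchronization index (CO / minute ventilation).

Per-index increments δ = CR epoch − SR are classified as
**reduced / expected / increased** reactivity against shipped quartile
reference limits (derived from a published cohort of 183 male athletes;
`cardioresp limits export-default` writes them out). Cohort runs apply the
extrasystole/non-sinus exclusion gate first, report median (Q1; Q3) per
epoch and Wilcoxon matched-pairs tests between epochs, and can export a
cohort's own empirical limits.

A coupled **cardiorespiratory simulator** (integral pulse frequency
modulation with respiratory and 0.1 Hz drives, beat-lagged baroreflex
coupling, respiratory pressure/stroke-volume oscillations, optional
ectopic beats, between-subject dispersion) generates whole cohorts with
ground truth, so every stage is testable without recording hardware.

## CLI

```bash
cardioresp simulate --n 10 --seed 1 --out cohort/      # synthetic records
cardioresp analyze cohort/sim-000                      # one subject -> JSON
cardioresp cohort cohort/ --out summary/               # gate + stats + limits
cardioresp classify report.json --limits limits.csv    # reactivity classes
cardioresp limits export-default --out limits.csv      # shipped quartiles
cardioresp simulate --dump-defaults                    # simulator defaults
```

Records are plain-text directories (`meta.json`, `beats.csv`, `flow.txt`);
`analyze` on a record failing the exclusion gate exits 0 with an
`"excluded"` status and the reason.

## Package layout

| module | contents |
| --- | --- |
| `cardioresp.records` | domain types, validation, text I/O, epoch slicing |
| `cardioresp.simulate` | IPFM simulator, breathing programs, cohort generator |
| `cardioresp.breathing` | breath segmentation, pattern indices, ventilation series |
| `cardioresp.spectral` | resampling, Welch band powers, normalized units, baroreflex alpha |
| `cardioresp.beats` | ectopic detector, exclusion gate, time-domain and geometric HRV, ECG summary |
| `cardioresp.hemodynamics` | BSA, hemodynamic derivations, synchronization indices |
| `cardioresp.pipeline` | per-subject orchestration, increments, classification, cohort statistics |
| `cardioresp.cli` | `cardioresp` console entry point |
| `cardioresp/data/reference_limits.csv` | shipped δ quartile limits |
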