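import numpy as np
import pytest
from dataclasses import replace

from cardioresp import (
    ConfigurationError,
    SimulationConfig,
    generate_beats,
    generate_cohort,
    generate_flow,
    paced_program,
    simulate_record,
    spontaneous_program,
)
from cardioresp.records import records_equal
from cardioresp.spectral import event_spectrum


class TestGenerateFlow:
    def test_cr6_breath_count_and_volume(self, rng):
        program = paced_program(6.0, 1.7)
        flow = generate_flow(program, 120.0, 100.0, 0.0, rng)
        t = flow.time_s
        # count complete 10-s cycles via positive-lobe starts
        signs = np.sign(flow.samples)
        rises = np.nonzero((signs[1:] > 0) & (signs[:-1] <= 0))[0]
        assert rises.size == 12  # the first rise is the t = 0 sample itself
        # per-breath inspired volume = 1.7 L within 1%
        dt = 1.0 / flow.fs_hz
        one_breath = flow.samples[: int(5.0 * flow.fs_hz)]
        assert np.sum(one_breath) * dt == pytest.approx(1.7, rel=0.01)

    def test_cr15_periodicity(self, rng):
        flow = generate_flow(paced_program(15.0, 0.89), 120.0, 100.0, 0.0, rng)
        lag = int(4.0 * flow.fs_hz)
        x = flow.samples
        ac = np.corrcoef(x[:-lag], x[lag:])[0, 1]
        assert ac > 0.999

    def test_phase_volume_balance(self, rng):
        flow = generate_flow(paced_program(6.0, 1.7), 120.0, 100.0, 0.0, rng)
        dt = 1.0 / flow.fs_hz
        vol_in = np.sum(np.clip(flow.samples, 0, None)) * dt
        vol_out = -np.sum(np.clip(flow.samples, None, 0)) * dt
        assert vol_in == pytest.approx(12 * 1.7, rel=0.01)
        assert vol_out == pytest.approx(vol_in, rel=0.01)

    def test_spontaneous_rate_monte_carlo(self):
        # 100 epochs; empirical mean breath rate within 2 SE of the program mean
        rng = np.random.default_rng(1)
        program = spontaneous_program(rate_mean_min=14.2, rate_cv=0.10)
        rates = []
        for _ in range(100):
            flow = generate_flow(program, 60.0, 50.0, 0.0, rng)
            signs = np.sign(flow.samples)
            rises = np.nonzero((signs[1:] > 0) & (signs[:-1] <= 0))[0]
            if rises.size >= 2:
                periods = np.diff(flow.time_s[rises])
                rates.extend(60.0 / periods)
        rates = np.asarray(rates)
        se = rates.std(ddof=1) / np.sqrt(rates.size)
        assert abs(rates.mean() - 14.2) < 2 * se + 0.15

    def test_fs_too_low_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            generate_flow(paced_program(15.0, 0.9), 60.0, 4.0, 0.0, rng)


class TestGenerateBeats:
    def test_unmodulated_ipfm_is_regular(self, rng):
        config = SimulationConfig(
            mean_rr_ms=1000.0,
            rsa_gain_ms=0.0,
            lf_amp_rr_ms=0.0,
            baroreflex_gain_ms_mmhg=0.0,
            rr_noise_ms=0.0,
            bp_noise_mmhg=0.0,
            resp_sbp_amp_mmhg=0.0,
            resp_dbp_amp_mmhg=0.0,
            lf_amp_sbp_mmhg=0.0,
            lf_amp_dbp_mmhg=0.0,
        )
        flow = generate_flow(paced_program(6.0, 1.7), 120.0, 100.0, 0.0, rng)
        beats, _ = generate_beats(config, flow, rng)
        assert len(beats) in (119, 120)
        assert np.allclose(beats.rr_ms, 1000.0, atol=1e-6)

    def test_rsa_creates_peak_at_breathing_frequency(self, rng):
        config = SimulationConfig(
            rsa_gain_ms=40.0,
            rsa_vt_ref_l=0.0,  # no tidal-volume scaling for a single epoch
            lf_amp_rr_ms=0.0,
            baroreflex_gain_ms_mmhg=0.0,
            rr_noise_ms=0.0,
        )
        flow = generate_flow(paced_program(6.0, 1.7), 120.0, 100.0, 0.0, rng)
        beats, _ = generate_beats(config, flow, rng)
        spec = event_spectrum(beats.time_s, beats.rr_ms)
        # breathing at 0.10 Hz: RR power concentrates in the 0.04-0.15 band
        assert spec.lf > 0.8 * spec.tp

    def test_injected_ectopics_deviate_from_local_median(self):
        rng = np.random.default_rng(3)
        config = SimulationConfig(ectopic_rate_per_beat=0.04)
        flow = generate_flow(paced_program(6.0, 1.7), 120.0, 100.0, 0.0, rng)
        beats, truth = generate_beats(config, flow, rng)
        assert truth.ectopic_beat_indices.size >= 1
        rr = beats.rr_ms
        deviants = set()
        for i in range(len(beats)):
            lo, hi = max(0, i - 5), min(len(beats), i + 6)
            med = np.median(rr[lo:hi])
            if abs(rr[i] - med) > 0.2 * med:
                deviants.add(i)
        assert deviants == set(truth.ectopic_flagged_indices.tolist())

    def test_qt_tracks_bazett(self, rng):
        config = SimulationConfig(qt_noise_s=0.0)
        flow = generate_flow(paced_program(6.0, 1.7), 120.0, 100.0, 0.0, rng)
        beats, truth = generate_beats(config, flow, rng)
        qtc = beats.qt_s / np.sqrt(beats.rr_ms / 1000.0)
        assert np.allclose(qtc, truth.qtc_s, rtol=1e-9)


class TestGenerateCohort:
    def test_same_seed_byte_identical(self, tmp_path):
        from cardioresp import write_record

        a = generate_cohort(3, SimulationConfig(), seed=7)
        b = generate_cohort(3, SimulationConfig(), seed=7)
        for (ra, _), (rb, _) in zip(a, b):
            assert records_equal(ra, rb)
        write_record(a[0][0], tmp_path / "a")
        write_record(b[0][0], tmp_path / "b")
        assert (tmp_path / "a" / "beats.csv").read_bytes() == (
            tmp_path / "b" / "beats.csv"
        ).read_bytes()

    def test_different_seeds_differ(self):
        a = generate_cohort(1, SimulationConfig(), seed=1)[0][0]
        b = generate_cohort(1, SimulationConfig(), seed=2)[0][0]
        assert not records_equal(a, b)

    def test_zero_dispersion_gives_identical_parameters(self):
        config = SimulationConfig(cohort_cv={})
        cohort = generate_cohort(3, config, seed=5)
        truths = [t for _, t in cohort]
        assert len({t.qtc_s for t in truths}) == 1
        assert len({t.mean_rr_ms for t in truths}) == 1

    def test_paced_cr6_rate_exact_by_construction(self):
        from cardioresp import BreathThresholds, segment_breaths, slice_epoch
        from cardioresp.breathing import pattern_indices

        cohort = generate_cohort(5, SimulationConfig(flow_noise_l_s=0.0), seed=11)
        for record, _ in cohort:
            epoch = slice_epoch(record, "CR6")
            pattern = pattern_indices(segment_breaths(epoch.flow, BreathThresholds()))
            assert pattern.rr_breath == pytest.approx(6.0, abs=0.05)

    def test_record_validates(self, sim_record):
        record, _ = sim_record
        record.validate()

    def test_truth_carries_epoch_programs(self, sim_record):
        _, truth = sim_record
        assert truth.epochs["CR6"].rate_min == 6.0
        assert truth.epochs["CR15"].rate_min == 15.0
        assert truth.epochs["CR6"].tidal_volume_l == pytest.approx(1.7)
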