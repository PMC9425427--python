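import numpy as np
import pytest

from cracm.sweep_io import StimulusProtocol
from cracm.synthetic_data import (
    CohortSpec,
    IpscKinetics,
    SimCellSpec,
    geometric_depression,
    ipsc_waveform,
    simulate_cohort,
    simulate_loose_seal_recording,
    simulate_vc_recording,
    spike_template,
)


class TestIpscWaveform:
    def test_unit_peak(self):
        t = np.arange(0, 100, 0.01)
        w = ipsc_waveform(t, 0.8, 10.0)
        assert w.max() == pytest.approx(1.0, abs=1e-6)

    def test_zero_before_onset(self):
        assert np.all(ipsc_waveform(np.array([-5.0, -0.01]), 0.8, 10.0) == 0)

    def test_kinetics_validation(self):
        with pytest.raises(ValueError):
            IpscKinetics(rise_tau_ms=10.0, decay_tau_ms=0.8)
        with pytest.raises(ValueError):
            IpscKinetics(latency_mean_ms=0.0)


class TestVcSimulation:
    def test_unconnected_silent_cell_gives_flat_zero_sweeps(self, single_pulse_protocol):
        spec = SimCellSpec(connected=False, mini_rate_hz=0.0, noise_sd_pa=0.0)
        rec = simulate_vc_recording(spec, single_pulse_protocol, seed=0, n_sweeps=5)
        assert np.all(rec.sweeps == 0.0)

    def test_clean_event_peak_matches_ground_truth(self, clean_event_recording):
        # noise-free: peak magnitude equals the specified amplitude to 0.1 pA
        for sweep in clean_event_recording.sweeps:
            assert abs(sweep.min() + 500.0) <= 0.1
            peak_t = np.argmin(sweep) * 0.1
            assert peak_t > 100.0 + 2.0  # peak follows light onset + latency

    def test_sign_flips_at_minus40(self, single_pulse_protocol):
        spec = SimCellSpec(connected=True, ipsc_amplitude_pa=400.0,
                           mini_rate_hz=0.0, noise_sd_pa=0.0,
                           kinetics=IpscKinetics(latency_jitter_sd_ms=0.0))
        rec = simulate_vc_recording(spec, single_pulse_protocol, seed=1,
                                    n_sweeps=2, holding_potential_mv=-40.0)
        assert abs(rec.sweeps[0].max() - 400.0) <= 0.1
        assert rec.sweeps[0].min() >= -1.0

    def test_geometric_depression_closed_form(self):
        # per-pulse peaks follow A * 0.9**k exactly in the noise-free limit
        proto = StimulusProtocol.train(start_ms=500.0)
        spec = SimCellSpec(connected=True, ipsc_amplitude_pa=1000.0,
                           depression_profile=geometric_depression(0.9),
                           kinetics=IpscKinetics(latency_mean_ms=2.0,
                                                 latency_jitter_sd_ms=0.0),
                           mini_rate_hz=0.0, noise_sd_pa=0.0)
        rec = simulate_vc_recording(spec, proto, seed=2, n_sweeps=1,
                                    post_ms=500.0)
        sweep = rec.sweeps[0]
        for k, onset in enumerate(proto.pulse_onsets_ms[:10]):
            i0 = int(onset / 0.1)
            seg = sweep[i0:i0 + 450]
            residual_tail = sweep[i0 + int(2.0 / 0.1) - 1]  # superposed decay
            peak = -(seg.min() - residual_tail)
            assert peak == pytest.approx(1000.0 * 0.9 ** k, rel=0.01)

    def test_gbz_removes_evoked_and_minis(self, single_pulse_protocol):
        spec = SimCellSpec(connected=True, gbz_blocks=True, mini_rate_hz=5.0,
                           noise_sd_pa=0.0)
        rec = simulate_vc_recording(spec, single_pulse_protocol, seed=3,
                                    n_sweeps=3, gbz=True)
        assert np.all(rec.sweeps == 0.0)
        assert "GBZ" in rec.pharmacology

    def test_chr2_contamination_is_fast_and_gbz_insensitive(self, single_pulse_protocol):
        spec = SimCellSpec(connected=False, chr2_contaminated=True,
                           mini_rate_hz=0.0, noise_sd_pa=0.0)
        rec = simulate_vc_recording(spec, single_pulse_protocol, seed=4,
                                    n_sweeps=2, gbz=True)
        onset_idx = np.flatnonzero(rec.sweeps[0] < -1.0)[0]
        latency = onset_idx * 0.1 - 100.0
        assert 0.0 < latency < 1.0

    def test_seeded_determinism(self, single_pulse_protocol):
        spec = SimCellSpec(noise_sd_pa=15.0)
        a = simulate_vc_recording(spec, single_pulse_protocol, seed=42, n_sweeps=5)
        b = simulate_vc_recording(spec, single_pulse_protocol, seed=42, n_sweeps=5)
        assert np.array_equal(a.sweeps, b.sweeps)
        c = simulate_vc_recording(spec, single_pulse_protocol, seed=43, n_sweeps=5)
        assert not np.array_equal(a.sweeps, c.sweeps)


class TestLooseSealSimulation:
    def test_silent_cell(self):
        spec = SimCellSpec(baseline_rate_hz=0.0, noise_sd_pa=0.0)
        rec = simulate_loose_seal_recording(spec, StimulusProtocol.train(), seed=0,
                                            n_sweeps=3)
        assert np.all(rec.sweeps == 0.0)

    def test_full_suppression_empties_train_window(self):
        # 4 Hz, CV 0.1, factor 0: ~12 baseline spikes, none during the train
        spec = SimCellSpec(baseline_rate_hz=4.0, isi_cv=0.1,
                           suppression_factor=0.0, noise_sd_pa=0.0,
                           spike_amplitude_pa=100.0)
        proto = StimulusProtocol.train()
        base_counts, during_counts = [], []
        for seed in range(200):
            rec = simulate_loose_seal_recording(spec, proto, seed=seed, n_sweeps=1)
            trace = rec.sweeps[0]
            # spike positive lobes are unambiguous without noise
            spike_starts = np.flatnonzero(np.diff((trace > 50).astype(int)) == 1)
            t = spike_starts * 0.1
            base_counts.append(np.sum((t >= 0) & (t < 3000)))
            during_counts.append(np.sum((t >= 3000) & (t < 6000)))
        assert np.mean(base_counts) == pytest.approx(12.0, abs=3 * np.sqrt(12 / 200) + 0.5)
        assert sum(during_counts) == 0

    def test_no_suppression_preserves_rate(self):
        spec = SimCellSpec(baseline_rate_hz=4.0, isi_cv=0.2,
                           suppression_factor=1.0, noise_sd_pa=0.0)
        proto = StimulusProtocol.train()
        diffs = []
        for seed in range(100):
            rec = simulate_loose_seal_recording(spec, proto, seed=seed, n_sweeps=1)
            trace = rec.sweeps[0]
            t = np.flatnonzero(np.diff((trace > 50).astype(int)) == 1) * 0.1
            diffs.append(np.sum((t >= 3000) & (t < 6000)) - np.sum(t < 3000))
        # paired difference should be centred at zero
        assert abs(np.mean(diffs)) < 3 * np.std(diffs) / np.sqrt(len(diffs)) + 0.15

    def test_spike_waveform_duration_matches_spec(self):
        template = spike_template(2.5, 0.1)
        above = np.flatnonzero(np.abs(template) > 0.1 * np.max(np.abs(template)))
        measured = (above[-1] - above[0]) * 0.1
        assert measured == pytest.approx(2.5, abs=0.1)

    def test_invalid_cv_rejected(self):
        spec = SimCellSpec(baseline_rate_hz=4.0, isi_cv=-1.0)
        with pytest.raises(ValueError):
            simulate_loose_seal_recording(spec, StimulusProtocol.train(), seed=0,
                                          n_sweeps=1)


class TestCohortSimulation:
    def test_explicit_truth_vector_respected(self):
        truth = [True] * 18 + [False] * 8
        spec = CohortSpec("SNr_to_DLSproj", 26, connected_truth=truth,
                          conditions=(), seed=1)
        cells, table = simulate_cohort(spec)
        assert len(cells) == 26
        assert table["connected"].sum() == 18

    def test_p_connected_zero(self):
        spec = CohortSpec("DMS_loop", 10, p_connected=0.0, conditions=(), seed=2)
        _, table = simulate_cohort(spec)
        assert not table["connected"].any()

    def test_connected_fraction_binomial(self):
        fractions = []
        for seed in range(10):
            spec = CohortSpec("DLS_loop", 200, p_connected=0.5, conditions=(),
                              seed=seed)
            _, table = simulate_cohort(spec)
            fractions.append(table["connected"].mean())
        se = 0.5 / np.sqrt(200 * 10)
        assert abs(np.mean(fractions) - 0.5) <= 3 * se

    def test_connected_cells_carry_gbz_condition(self):
        truth = [True, False, True]
        spec = CohortSpec("DLS_loop", 3, connected_truth=truth,
                          conditions=("vc",), seed=3, n_sweeps=5)
        cells, _ = simulate_cohort(spec)
        assert "vc_gbz" in cells[0].recordings
        assert "vc_gbz" not in cells[1].recordings

    def test_cohort_determinism(self):
        spec = CohortSpec("DLS_loop", 2, conditions=("vc",), seed=9, n_sweeps=5)
        cells_a, _ = simulate_cohort(spec)
        cells_b, _ = simulate_cohort(spec)
        assert np.array_equal(cells_a[0].recordings["vc_baseline"].sweeps,
                              cells_b[0].recordings["vc_baseline"].sweeps)

    def test_truth_vector_length_validated(self):
        with pytest.raises(ValueError):
            CohortSpec("DLS_loop", 5, connected_truth=[True, False])
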