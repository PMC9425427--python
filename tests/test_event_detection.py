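import numpy as np
import pytest

from cracm.event_detection import (
    DetectedEvent,
    PRESET_MINUS40,
    PRESET_MINUS70,
    assess_gbz_block,
    classify_cell_connectivity,
    detect_events_per_sweep,
    detect_oipsc,
    exclude_chr2_contamination,
    qc_series_resistance,
)
from cracm.sweep_io import StimulusProtocol
from cracm.synthetic_data import (
    IpscKinetics,
    SimCellSpec,
    simulate_vc_recording,
)


def _event(sweep_index=0, amplitude=400.0, latency=1.8):
    return DetectedEvent(sweep_index=sweep_index, pulse_index=0,
                         onset_time_ms=100.0 + latency, latency_ms=latency,
                         peak_value_pa=-amplitude, amplitude_pa=amplitude)


class TestDetectOipsc:
    def test_flat_trace_has_no_event(self):
        assert detect_oipsc(np.zeros(3000), 100.0, PRESET_MINUS70) is None

    def test_clean_event_amplitude_and_latency(self, clean_event_recording):
        ev = detect_oipsc(clean_event_recording.sweeps[0], 100.0, PRESET_MINUS70)
        assert ev is not None
        assert ev.amplitude_pa == pytest.approx(500.0, abs=1.0)
        assert ev.latency_ms == pytest.approx(2.0, abs=0.1)
        assert ev.peak_value_pa < 0  # inward

    def test_event_outside_search_window_rejected(self, single_pulse_protocol):
        spec = SimCellSpec(connected=True, ipsc_amplitude_pa=500.0,
                           kinetics=IpscKinetics(latency_mean_ms=25.0,
                                                 latency_jitter_sd_ms=0.0),
                           mini_rate_hz=0.0, noise_sd_pa=0.0)
        rec = simulate_vc_recording(spec, single_pulse_protocol, seed=0, n_sweeps=1)
        assert detect_oipsc(rec.sweeps[0], 100.0, PRESET_MINUS70) is None

    def test_outward_preset_detects_positive_events(self, single_pulse_protocol):
        spec = SimCellSpec(connected=True, ipsc_amplitude_pa=300.0,
                           kinetics=IpscKinetics(latency_mean_ms=2.0,
                                                 latency_jitter_sd_ms=0.0),
                           mini_rate_hz=0.0, noise_sd_pa=0.0)
        rec = simulate_vc_recording(spec, single_pulse_protocol, seed=0,
                                    n_sweeps=1, holding_potential_mv=-40.0)
        ev = detect_oipsc(rec.sweeps[0], 100.0, PRESET_MINUS40)
        assert ev is not None and ev.peak_value_pa > 0
        assert ev.amplitude_pa == pytest.approx(300.0, abs=1.0)

    def test_trace_too_short_raises(self):
        with pytest.raises(ValueError):
            detect_oipsc(np.zeros(100), 5.0, PRESET_MINUS70)

    def test_false_positive_rate_on_noise(self, single_pulse_protocol):
        spec = SimCellSpec(connected=False, mini_rate_hz=0.0, noise_sd_pa=10.0)
        fp = 0
        n = 400
        for seed in range(n):
            rec = simulate_vc_recording(spec, single_pulse_protocol,
                                        seed=seed, n_sweeps=1)
            if detect_oipsc(rec.sweeps[0], 100.0, PRESET_MINUS70) is not None:
                fp += 1
        assert fp / n <= 0.01

    def test_sensitivity_and_bias_at_high_snr(self, single_pulse_protocol):
        rng = np.random.default_rng(1)
        detected, rel_err = 0, []
        n = 200
        for i in range(n):
            amp = max(float(np.exp(rng.normal(np.log(300.0), 0.8))), 50.0)
            spec = SimCellSpec(connected=True, ipsc_amplitude_pa=amp,
                               kinetics=IpscKinetics(latency_mean_ms=2.0),
                               mini_rate_hz=0.0, noise_sd_pa=10.0)
            rec = simulate_vc_recording(spec, single_pulse_protocol,
                                        seed=10_000 + i, n_sweeps=1)
            ev = detect_oipsc(rec.sweeps[0], 100.0, PRESET_MINUS70)
            if ev is not None:
                detected += 1
                rel_err.append((ev.amplitude_pa - amp) / amp)
        assert detected / n >= 0.95
        assert abs(float(np.mean(rel_err))) <= 0.05

    def test_latency_accuracy_noise_free(self, single_pulse_protocol):
        for true_latency in (1.5, 2.7, 4.0):
            spec = SimCellSpec(connected=True, ipsc_amplitude_pa=600.0,
                               kinetics=IpscKinetics(latency_mean_ms=true_latency,
                                                     latency_jitter_sd_ms=0.0),
                               mini_rate_hz=0.0, noise_sd_pa=0.0)
            rec = simulate_vc_recording(spec, single_pulse_protocol, seed=0,
                                        n_sweeps=1)
            ev = detect_oipsc(rec.sweeps[0], 100.0, PRESET_MINUS70)
            assert abs(ev.latency_ms - true_latency) <= 0.2


class TestClassifyConnectivity:
    def test_six_of_ten_sweeps_is_connected(self):
        detections = [_event(i) for i in range(6)] + [None] * 4
        connected, _, _ = classify_cell_connectivity(detections)
        assert connected

    def test_five_of_ten_sweeps_is_not_connected(self):
        detections = [_event(i) for i in range(5)] + [None] * 5
        connected, amp, lat = classify_cell_connectivity(detections)
        assert not connected and amp is None and lat is None

    def test_means_over_event_bearing_sweeps(self):
        detections = [_event(i, amplitude=400.0, latency=1.5) for i in range(10)]
        connected, amp, lat = classify_cell_connectivity(detections)
        assert connected and amp == 400.0 and lat == 1.5

    def test_order_invariance(self):
        rng = np.random.default_rng(0)
        detections = [_event(i, amplitude=100.0 + 10 * i) for i in range(7)] + [None] * 3
        reference = classify_cell_connectivity(detections)
        for _ in range(5):
            shuffled = list(detections)
            rng.shuffle(shuffled)
            assert classify_cell_connectivity(shuffled) == reference

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            classify_cell_connectivity([])


class TestGbzBlock:
    @pytest.fixture
    def protocol(self):
        return StimulusProtocol.single_pulse()

    def test_blocked_cell(self, protocol):
        spec = SimCellSpec(connected=True, gbz_blocks=True, noise_sd_pa=5.0)
        base = simulate_vc_recording(spec, protocol, seed=1, n_sweeps=6)
        gbz = simulate_vc_recording(spec, protocol, seed=2, n_sweeps=6, gbz=True)
        assert assess_gbz_block(base, gbz) == "blocked"

    def test_contaminated_cell_not_blocked(self, protocol):
        spec = SimCellSpec(connected=False, chr2_contaminated=True,
                           gbz_blocks=False, noise_sd_pa=5.0)
        base = simulate_vc_recording(spec, protocol, seed=3, n_sweeps=6)
        gbz = simulate_vc_recording(spec, protocol, seed=4, n_sweeps=6, gbz=True)
        assert assess_gbz_block(base, gbz) == "not_blocked"

    def test_unconnected_baseline_not_applicable(self, protocol):
        spec = SimCellSpec(connected=False, noise_sd_pa=5.0, mini_rate_hz=0.0)
        base = simulate_vc_recording(spec, protocol, seed=5, n_sweeps=6)
        gbz = simulate_vc_recording(spec, protocol, seed=6, n_sweeps=6, gbz=True)
        assert assess_gbz_block(base, gbz) == "not_applicable"

    def test_protocol_mismatch_rejected(self, protocol):
        spec = SimCellSpec(noise_sd_pa=5.0)
        base = simulate_vc_recording(spec, protocol, seed=1, n_sweeps=5)
        other = simulate_vc_recording(
            spec, StimulusProtocol.single_pulse(onset_ms=150.0), seed=2, n_sweeps=5)
        with pytest.raises(ValueError):
            assess_gbz_block(base, other)


class TestExclusions:
    @pytest.mark.parametrize(
        "assessment, latency, excluded",
        [
            ("not_blocked", 0.6, True),
            ("blocked", 0.6, False),
            ("not_blocked", 1.8, False),
        ],
        ids=["gbz-insensitive sub-ms", "blocked fast event", "gbz-insensitive slow"],
    )
    def test_chr2_rule_requires_both_conditions(self, assessment, latency, excluded):
        qc = exclude_chr2_contamination(assessment, latency)
        assert qc.passed == (not excluded)
        if excluded:
            assert qc.reason == "chr2_contaminated"

    @pytest.mark.parametrize(
        "rs_log, passed, reason",
        [
            ([15.0, 16.0, 15.0], True, "ok"),
            ([15.0, 26.0], False, "rs_too_high"),
            ([10.0, 13.5], False, "rs_drift"),
            ([20.0, 25.0], True, "ok"),  # 25 is not > 25; 25% drift within limit
        ],
    )
    def test_series_resistance_rules(self, rs_log, passed, reason):
        qc = qc_series_resistance(rs_log)
        assert qc.passed == passed and qc.reason == reason

    def test_empty_rs_log_rejected(self):
        with pytest.raises(ValueError):
            qc_series_resistance([])


def test_mini_ipscs_rarely_fool_the_cell_classifier(single_pulse_protocol):
    # unconnected cells with busy spontaneous activity must stay unconnected:
    # minis can hit the search window on occasional sweeps but not in >50%
    spec = SimCellSpec(connected=False, mini_rate_hz=5.0, noise_sd_pa=10.0)
    false_cells = 0
    for seed in range(30):
        rec = simulate_vc_recording(spec, single_pulse_protocol,
                                    seed=seed, n_sweeps=7)
        connected, _, _ = classify_cell_connectivity(
            detect_events_per_sweep(rec, PRESET_MINUS70))
        false_cells += connected
    assert false_cells == 0
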