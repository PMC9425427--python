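import numpy as np
import pytest

from cracm.sweep_io import Recording, StimulusProtocol
from cracm.synthetic_data import IpscKinetics, SimCellSpec, simulate_vc_recording


@pytest.fixture
def single_pulse_protocol():
    return StimulusProtocol.single_pulse()


@pytest.fixture
def clean_event_recording(single_pulse_protocol):
    """Noise-free 500 pA inward event at exactly 2.0 ms latency."""
    spec = SimCellSpec(
        connected=True,
        ipsc_amplitude_pa=500.0,
        kinetics=IpscKinetics(latency_mean_ms=2.0, latency_jitter_sd_ms=0.0),
        mini_rate_hz=0.0,
        noise_sd_pa=0.0,
    )
    return simulate_vc_recording(spec, single_pulse_protocol, seed=7, n_sweeps=3)


@pytest.fixture
def tiny_recording():
    """Short flat whole-cell recording for I/O round-trip tests."""
    proto = StimulusProtocol.single_pulse(onset_ms=50.0)
    sweeps = np.zeros((5, 2000))
    sweeps += np.linspace(0, 1, 2000) * 0.001  # non-trivial values
    return Recording(
        cell_id="c0",
        mode="whole_cell_vc",
        sweeps=sweeps,
        protocol=proto,
        holding_potential_mv=-70.0,
        rs_log=[15.0, 15.1, 14.9, 15.2, 15.0],
        pharmacology=frozenset({"TTX_4AP", "NBQX_AP5"}),
    )
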