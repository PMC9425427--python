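"""Short-term plasticity quantification for 60-pulse light trains at -40 mV.

At 20 Hz the 10-ms decay tail of each IPSC has not returned to baseline
when the next pulse arrives, so every pulse's amplitude is measured
against a *local* baseline taken in the 2 ms immediately preceding that
pulse's light onset. A pulse on which no event is detected contributes
amplitude 0 (a release failure), so normalized means average over
failures as well as successes. Amplitudes are averaged across sweeps
before normalizing to the first pulse.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from cracm.event_detection import (
    DetectorConfig,
    PRESET_MINUS40,
    detect_oipsc,
    robust_noise_sd,
)
from cracm.sweep_io import Recording

__all__ = [
    "TrainResponse",
    "segment_train_amplitudes",
    "compute_ppr",
    "detect_slow_current",
]

LOCAL_BASELINE_MS = 2.0
SLOW_CURRENT_WINDOW_MS = 500.0
SLOW_CURRENT_SKIP_MS = 50.0  # skip the last IPSC's decay tail
SLOW_CURRENT_THRESHOLD_SD = 5.0


@dataclass
class TrainResponse:
    """Per-pulse amplitudes of one cell's train response.

    ``amplitudes_pa`` are sweep-averaged per-pulse amplitudes;
    ``normalized`` divides by the first pulse (so ``normalized[0] == 1``).
    ``ppr`` is second/first, ``last_first`` is last/first.
    """

    amplitudes_pa: np.ndarray
    first_latency_ms: Optional[float] = None
    slow_current: Optional[bool] = None

    def __post_init__(self):
        amps = np.asarray(self.amplitudes_pa, dtype=float)
        if amps.ndim != 1 or amps.size < 2:
            raise ValueError("need per-pulse amplitudes for at least two pulses")
        if np.any(amps < 0):
            raise ValueError("amplitudes must be nonnegative")
        if amps[0] <= 0:
            raise ValueError("first-pulse amplitude must be positive (responding cell)")
        self.amplitudes_pa = amps

    @property
    def n_pulses(self) -> int:
        return self.amplitudes_pa.size

    @property
    def normalized(self) -> np.ndarray:
        return self.amplitudes_pa / self.amplitudes_pa[0]

    @property
    def ppr(self) -> float:
        return compute_ppr(self)

    @property
    def last_first(self) -> float:
        return float(self.amplitudes_pa[-1] / self.amplitudes_pa[0])


def segment_train_amplitudes(
    recording: Recording,
    config: DetectorConfig = PRESET_MINUS40,
) -> Optional[TrainResponse]:
    """Measure per-pulse amplitudes of a train recording.

    Returns ``None`` when the cell does not respond (no event detected on
    the first pulse in any sweep). The noise floor is estimated once from
    the pre-train baseline rather than per pulse, because 2-ms local
    baselines are too short for a stable noise estimate.
    """
    protocol = recording.protocol
    if protocol.kind != "train":
        raise ValueError("train plasticity analysis requires a train protocol")
    dt = recording.dt_ms
    onsets = protocol.pulse_onsets_ms
    period_ms = 1000.0 / protocol.train_frequency_hz
    n_pulses = protocol.n_pulses
    nb = int(round(LOCAL_BASELINE_MS / dt))

    # stable noise floor from the pre-train baseline of the averaged config
    i_first = int(round(onsets[0] / dt))
    pre = recording.sweeps[:, max(i_first - 500, 0):i_first]
    noise_sd = float(np.median([robust_noise_sd(s) for s in pre]))
    cfg = replace(
        config,
        min_amplitude_pa=(config.min_amplitude_pa
                          if config.min_amplitude_pa is not None
                          else max(5.0 * noise_sd, 1.0)),
        amplitude_window_ms=min(config.amplitude_window_ms, period_ms - 5.0),
    )

    amps = np.zeros((recording.n_sweeps, n_pulses))
    first_latencies = []
    for s in range(recording.n_sweeps):
        sweep = recording.sweeps[s]
        for k, onset in enumerate(onsets):
            i_on = int(round(onset / dt))
            local_baseline = sweep[i_on - nb:i_on]
            ev = detect_oipsc(
                sweep, onset, cfg, dt_ms=dt, sweep_index=s, pulse_index=k,
                baseline_override=local_baseline,
            )
            if ev is not None:
                amps[s, k] = ev.amplitude_pa
                if k == 0:
                    first_latencies.append(ev.latency_ms)

    mean_amps = amps.mean(axis=0)
    if mean_amps[0] <= 0:
        return None  # non-responding cell
    return TrainResponse(
        amplitudes_pa=mean_amps,
        first_latency_ms=float(np.mean(first_latencies)) if first_latencies else None,
        slow_current=detect_slow_current(recording),
    )


def compute_ppr(response: TrainResponse) -> float:
    """Paired-pulse ratio: second over first sweep-averaged amplitude."""
    if response.amplitudes_pa[0] <= 0:
        raise ValueError("PPR undefined with zero first-pulse amplitude")
    return float(response.amplitudes_pa[1] / response.amplitudes_pa[0])


def detect_slow_current(recording: Recording) -> bool:
    """Flag a sustained current outlasting the train.

    True iff the median of the sweep-averaged current in the 500 ms after
    the last pulse (skipping the last IPSC's decay tail) deviates from the
    pre-train baseline median by more than 5x the baseline noise SD.
    Fast evoked and miniature events are suppressed by the median.
    """
    protocol = recording.protocol
    dt = recording.dt_ms
    mean_trace = recording.sweeps.mean(axis=0)
    i_first = int(round(protocol.pulse_onsets_ms[0] / dt))
    i_base0 = max(i_first - int(round(SLOW_CURRENT_WINDOW_MS / dt)), 0)
    baseline = mean_trace[i_base0:i_first]
    base_med = float(np.median(baseline))
    base_sd = robust_noise_sd(baseline)
    i_last = int(round(protocol.pulse_onsets_ms[-1] / dt))
    j0 = i_last + int(round(SLOW_CURRENT_SKIP_MS / dt))
    j1 = min(i_last + int(round(SLOW_CURRENT_WINDOW_MS / dt)), mean_trace.size)
    if j0 >= j1:
        raise ValueError("sweep does not extend past the last pulse")
    post_med = float(np.median(mean_trace[j0:j1]))
    return abs(post_med - base_med) > SLOW_CURRENT_THRESHOLD_SD * max(base_sd, 1e-12)
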