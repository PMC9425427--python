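"""Loose-seal spike detection and tonic-firing suppression classification.

Dopamine neurons fire tonically (1-8 Hz, low-CV pacemaker) and have wide
extracellular action-potential waveforms (total duration > 2 ms), which is
used as an identity check. Effective inhibition is assessed with a 3-s
20-Hz light train: a cell counts as suppressed when its mean firing rate
during the train falls more than 2 SDs below the mean baseline rate, where
mean and SD are taken across sweeps of the rate in the 3 s preceding the
train.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import signal

from cracm.event_detection import QcResult, robust_noise_sd
from cracm.sweep_io import Recording, StimulusProtocol

__all__ = [
    "SpikeTrain",
    "FiringRates",
    "SpikeDetectParams",
    "detect_spikes",
    "detect_spikes_recording",
    "check_da_waveform",
    "compute_rates",
    "classify_suppression",
    "qc_tonic_firing",
    "exclude_light_evoked_excitation",
]

ANALYSIS_WINDOW_S = 3.0
DA_WAVEFORM_MIN_MS = 2.0
MIN_TONIC_RATE_HZ = 0.5
MAX_BASELINE_GAP_S = 2.0


@dataclass(frozen=True)
class SpikeDetectParams:
    """Band-pass + threshold spike detector settings.

    The trace is band-passed (default 100-2000 Hz), spikes are threshold
    crossings at ``threshold_sd`` times the MAD-based noise SD of the
    filtered trace, with a 2 ms refractory period between detections.
    """

    band_hz: tuple[float, float] = (100.0, 2000.0)
    threshold_sd: float = 6.0
    refractory_ms: float = 2.0
    waveform_halfwidth_ms: float = 4.0


@dataclass
class SpikeTrain:
    """Detected spike times (ms) plus the mean-waveform duration."""

    spike_times_ms: np.ndarray
    waveform_total_duration_ms: Optional[float] = None

    def __post_init__(self):
        t = np.asarray(self.spike_times_ms, dtype=float)
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("spike times must be strictly increasing")
        self.spike_times_ms = t

    @property
    def n_spikes(self) -> int:
        return self.spike_times_ms.size


@dataclass
class FiringRates:
    """Per-sweep firing rates in the baseline and during-train windows."""

    per_sweep_baseline_hz: np.ndarray
    per_sweep_during_hz: np.ndarray

    def __post_init__(self):
        self.per_sweep_baseline_hz = np.asarray(self.per_sweep_baseline_hz, float)
        self.per_sweep_during_hz = np.asarray(self.per_sweep_during_hz, float)
        if self.per_sweep_baseline_hz.shape != self.per_sweep_during_hz.shape:
            raise ValueError("baseline/during must cover the same sweeps")

    @property
    def n_sweeps(self) -> int:
        return self.per_sweep_baseline_hz.size

    @property
    def baseline_mean_hz(self) -> float:
        return float(np.mean(self.per_sweep_baseline_hz))

    @property
    def baseline_sd_hz(self) -> float:
        return float(np.std(self.per_sweep_baseline_hz, ddof=1))

    @property
    def during_mean_hz(self) -> float:
        return float(np.mean(self.per_sweep_during_hz))


def detect_spikes(
    sweep: np.ndarray,
    params: SpikeDetectParams = SpikeDetectParams(),
    *,
    dt_ms: float = 0.1,
) -> SpikeTrain:
    """Detect spikes in one loose-seal sweep.

    Spike times are placed at the extremum of each threshold-crossing
    excursion of the band-passed trace. The waveform duration is measured
    on the unfiltered mean spike waveform as the span where |signal|
    exceeds 10% of its peak.
    """
    x = np.asarray(sweep, dtype=float)
    if x.size == 0:
        raise ValueError("empty trace")
    fs = 1000.0 / dt_ms
    lo, hi = params.band_hz
    sos = signal.butter(3, [lo, min(hi, 0.45 * fs)], btype="bandpass",
                        fs=fs, output="sos")
    f = signal.sosfiltfilt(sos, x)
    noise_sd = robust_noise_sd(f)
    if noise_sd <= 0:
        noise_sd = 1e-12
    thr = params.threshold_sd * noise_sd

    above = np.abs(f) > thr
    if not above.any():
        return SpikeTrain(np.array([]), None)
    # group supra-threshold samples into excursions, take each extremum
    idx = np.flatnonzero(above)
    gaps = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[0], gaps + 1])
    ends = np.concatenate([gaps, [idx.size - 1]])
    peaks = []
    for a, b in zip(starts, ends):
        seg = idx[a:b + 1]
        peaks.append(seg[np.argmax(np.abs(f[seg]))])
    # refractory: merge detections closer than refractory_ms
    refr = params.refractory_ms / dt_ms
    kept = [peaks[0]]
    for p in peaks[1:]:
        if p - kept[-1] >= refr:
            kept.append(p)
        elif abs(f[p]) > abs(f[kept[-1]]):
            kept[-1] = p
    spike_idx = np.asarray(kept)
    times = spike_idx * dt_ms

    duration = _mean_waveform_duration(x, spike_idx, params, dt_ms)
    return SpikeTrain(times, duration)


def _mean_waveform_duration(x, spike_idx, params, dt_ms) -> Optional[float]:
    half = int(round(params.waveform_halfwidth_ms / dt_ms))
    # re-align every spike on its positive-lobe peak: the detector's |f|
    # extremum lands on either lobe of a biphasic spike, which would smear
    # the mean waveform
    search = int(round(1.5 / dt_ms))
    segs = []
    for i in spike_idx:
        lo, hi = max(i - search, 0), min(i + search + 1, x.size)
        j = lo + int(np.argmax(x[lo:hi]))
        if j - half >= 0 and j + half + 1 <= x.size:
            segs.append(x[j - half:j + half + 1])
    if not segs:
        return None
    wf = np.mean(segs, axis=0)
    wf = wf - np.median(wf)
    peak = np.max(np.abs(wf))
    if peak <= 0:
        return None
    above = np.flatnonzero(np.abs(wf) > 0.1 * peak)
    return float((above[-1] - above[0]) * dt_ms)


def detect_spikes_recording(
    recording: Recording,
    params: SpikeDetectParams = SpikeDetectParams(),
) -> list[SpikeTrain]:
    return [
        detect_spikes(recording.sweeps[s], params, dt_ms=recording.dt_ms)
        for s in range(recording.n_sweeps)
    ]


def check_da_waveform(train: SpikeTrain) -> bool:
    """Dopamine-neuron identity check: wide waveform, total duration > 2 ms."""
    if train.n_spikes < 5:
        raise ValueError("need at least 5 spikes to assess the waveform")
    if train.waveform_total_duration_ms is None:
        raise ValueError("spike train carries no waveform measurement")
    return train.waveform_total_duration_ms > DA_WAVEFORM_MIN_MS


def compute_rates(
    trains: Sequence[SpikeTrain],
    protocol: StimulusProtocol,
) -> FiringRates:
    """Per-sweep firing rates in the 3 s before and the 3 s of the train."""
    if protocol.kind != "train":
        raise ValueError("suppression analysis requires a train protocol")
    if len(trains) == 0:
        raise ValueError("need at least one sweep")
    t_start = protocol.pulse_onsets_ms[0]
    win = ANALYSIS_WINDOW_S * 1000.0
    if t_start < win:
        raise ValueError("sweep does not cover the 3 s baseline window")
    baseline, during = [], []
    for tr in trains:
        t = tr.spike_times_ms
        baseline.append(np.count_nonzero((t >= t_start - win) & (t < t_start)) / ANALYSIS_WINDOW_S)
        during.append(np.count_nonzero((t >= t_start) & (t < t_start + win)) / ANALYSIS_WINDOW_S)
    return FiringRates(np.asarray(baseline), np.asarray(during))


def classify_suppression(rates: FiringRates) -> bool:
    """The 2-SD suppression rule (strict inequality).

    Suppressed iff the mean during-train rate is more than 2 SDs below the
    mean baseline rate, with mean and SD computed across sweeps of the
    per-sweep baseline rates.
    """
    if rates.n_sweeps < 2:
        raise ValueError("suppression undefined with a single sweep (SD across sweeps)")
    return rates.during_mean_hz < rates.baseline_mean_hz - 2.0 * rates.baseline_sd_hz


def qc_tonic_firing(
    rates: FiringRates,
    trains: Optional[Sequence[SpikeTrain]] = None,
    stim_start_ms: Optional[float] = None,
) -> QcResult:
    """Exclude cells that do not fire tonically.

    Fails when the mean baseline rate is below 0.5 Hz, or (when spike
    trains are provided) when any sweep has a silent gap longer than 2 s
    within its baseline window -- bursty firing at a nominally adequate
    mean rate is not tonic pacemaking.
    """
    if rates.baseline_mean_hz < MIN_TONIC_RATE_HZ:
        return QcResult(False, "no_tonic_firing")
    if trains is not None and stim_start_ms is not None:
        win = ANALYSIS_WINDOW_S * 1000.0
        for tr in trains:
            t = tr.spike_times_ms
            t = t[(t >= stim_start_ms - win) & (t < stim_start_ms)]
            edges = np.concatenate([[stim_start_ms - win], t, [stim_start_ms]])
            if np.max(np.diff(edges)) > MAX_BASELINE_GAP_S * 1000.0:
                return QcResult(False, "no_tonic_firing")
    return QcResult(True)


def exclude_light_evoked_excitation(
    rates_baseline: FiringRates,
    rates_gbz: FiringRates,
) -> QcResult:
    """Exclusion rule for GBZ-insensitive light-evoked excitation.

    Fails (ChR2 contamination) iff the firing rate *increases* by more
    than 2 baseline SDs during the train in both the control and the GBZ
    condition; excitation abolished by GBZ is not contamination.
    """
    def excited(r: FiringRates) -> bool:
        return r.during_mean_hz > r.baseline_mean_hz + 2.0 * r.baseline_sd_hz

    if excited(rates_baseline) and excited(rates_gbz):
        return QcResult(False, "chr2_contaminated")
    return QcResult(True)
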