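"""Simulator for optogenetic circuit-mapping recordings with known ground truth.

Two recording modes are emulated:

* whole-cell voltage clamp: light-evoked IPSCs rendered as biexponential
  currents (inward at -70 mV with a high-chloride internal, outward at
  -40 mV with a low-chloride internal), on top of Poisson miniature IPSCs
  and white Gaussian noise;
* loose-seal cell-attached: tonic pacemaker spiking (low-CV ISI process)
  whose instantaneous rate is multiplicatively scaled during the light
  train, rendered with a biphasic extracellular spike template.

Cohort-level simulation draws per-cell parameters (connectivity flags,
amplitudes, latencies, firing rates, soma locations) from configurable
distributions and returns the dataset together with a ground-truth table,
so every stage of the analysis can be validated against known labels.

All simulated quantities use the package-wide units: pA, ms, mV, Hz.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from cracm.sweep_io import (
    CellRecord,
    CIRCUIT_PROJECTION,
    Recording,
    StimulusProtocol,
)

__all__ = [
    "IpscKinetics",
    "SimCellSpec",
    "CohortSpec",
    "ipsc_waveform",
    "spike_template",
    "simulate_vc_recording",
    "simulate_loose_seal_recording",
    "simulate_cell",
    "simulate_cohort",
]


@dataclass(frozen=True)
class IpscKinetics:
    """Biexponential IPSC kinetics and onset latency statistics.

    Defaults (0.8 ms rise, 10 ms decay, 1.8 ms mean latency with 0.2 ms
    jitter) produce the fast-rising, few-ms-latency events characteristic
    of monosynaptic GABAergic connections in slice recordings.
    """

    rise_tau_ms: float = 0.8
    decay_tau_ms: float = 10.0
    latency_mean_ms: float = 1.8
    latency_jitter_sd_ms: float = 0.2

    def __post_init__(self):
        if not 0 < self.rise_tau_ms < self.decay_tau_ms:
            raise ValueError("require 0 < rise_tau < decay_tau")
        if self.latency_mean_ms <= 0:
            raise ValueError("latency_mean_ms must be positive")


#: inner fraction of the biphasic spike template that stays above 10% of
#: the peak; used to invert the duration measurement when generating
_SPIKE_SPAN_FRACTION = 1.0 - math.asin(0.1) / math.pi


@dataclass
class SimCellSpec:
    """Ground-truth parameters for one simulated cell.

    ``connected`` controls whether light pulses evoke IPSCs at all;
    ``suppression_factor`` multiplies the tonic firing rate during the
    light train (1 = no effect, 0 = complete silencing);
    ``depression_profile`` holds per-pulse multiplicative scale factors
    for train stimulation (first entry must be 1).
    """

    connected: bool = True
    ipsc_amplitude_pa: float = 1200.0
    kinetics: IpscKinetics = field(default_factory=IpscKinetics)
    release_probability: float = 1.0
    depression_profile: Optional[np.ndarray] = None
    gbz_blocks: bool = True
    chr2_contaminated: bool = False
    baseline_rate_hz: float = 4.0
    isi_cv: float = 0.15
    #: slow drift of the pacemaker rate between sweeps (30 s apart);
    #: real tonic firing is never perfectly stationary across minutes
    rate_drift_cv: float = 0.05
    suppression_factor: float = 1.0
    spike_total_duration_ms: float = 2.5
    spike_amplitude_pa: float = 120.0
    mini_rate_hz: float = 2.0
    mini_amplitude_range_pa: tuple[float, float] = (20.0, 60.0)
    noise_sd_pa: float = 10.0
    location_mm: tuple[float, float, float] = (-3.2, 1.4, -4.3)

    def __post_init__(self):
        if not 0.0 <= self.release_probability <= 1.0:
            raise ValueError("release_probability must be in [0, 1]")
        if not 0.0 <= self.suppression_factor <= 1.0:
            raise ValueError("suppression_factor must be in [0, 1]")
        if self.depression_profile is not None:
            prof = np.asarray(self.depression_profile, dtype=float)
            if prof.ndim != 1 or prof.size == 0:
                raise ValueError("depression_profile must be a 1-D vector")
            if abs(prof[0] - 1.0) > 1e-12:
                raise ValueError("depression_profile[0] must be 1")
            if np.any(prof <= 0):
                raise ValueError("depression factors must be positive")
            self.depression_profile = prof

    def pulse_scale(self, pulse_index: int) -> float:
        if self.depression_profile is None:
            return 1.0
        if pulse_index >= len(self.depression_profile):
            return float(self.depression_profile[-1])
        return float(self.depression_profile[pulse_index])


def geometric_depression(ratio: float, n_pulses: int = 60) -> np.ndarray:
    """Per-pulse scale factors ratio**k for k = 0..n_pulses-1."""
    return ratio ** np.arange(n_pulses, dtype=float)


def ipsc_waveform(t_ms: np.ndarray, rise_tau_ms: float, decay_tau_ms: float) -> np.ndarray:
    """Unit-peak biexponential kernel exp(-t/tau_d) - exp(-t/tau_r), t >= 0."""
    t = np.asarray(t_ms, dtype=float)
    t_peak = (
        math.log(decay_tau_ms / rise_tau_ms)
        * rise_tau_ms * decay_tau_ms / (decay_tau_ms - rise_tau_ms)
    )
    norm = math.exp(-t_peak / decay_tau_ms) - math.exp(-t_peak / rise_tau_ms)
    out = np.where(
        t >= 0,
        np.exp(-np.clip(t, 0, None) / decay_tau_ms)
        - np.exp(-np.clip(t, 0, None) / rise_tau_ms),
        0.0,
    )
    return out / norm


def spike_template(total_duration_ms: float, dt_ms: float) -> np.ndarray:
    """Unit-peak biphasic extracellular spike (positive then negative lobe).

    The generated sine period is inflated so that the span where |w|
    exceeds 10% of the peak (the measurement convention used by the spike
    detector) equals ``total_duration_ms``.
    """
    period = total_duration_ms / _SPIKE_SPAN_FRACTION
    n = max(int(round(period / dt_ms)), 4)
    t = np.arange(n) * dt_ms
    return np.sin(2.0 * math.pi * t / period)


def _sweep_duration_ms(protocol: StimulusProtocol, post_ms: float) -> float:
    return protocol.pulse_onsets_ms[-1] + post_ms


# ---------------------------------------------------------------------------
# Whole-cell voltage clamp
# ---------------------------------------------------------------------------

def simulate_vc_recording(
    spec: SimCellSpec,
    protocol: StimulusProtocol,
    seed,
    *,
    n_sweeps: int = 7,
    holding_potential_mv: float = -70.0,
    gbz: bool = False,
    post_ms: float = 200.0,
    cell_id: str = "sim_cell",
) -> Recording:
    """Simulate a whole-cell voltage-clamp recording of light-evoked IPSCs.

    Evoked events occur per pulse with probability ``release_probability``
    and amplitude ``ipsc_amplitude_pa`` scaled by the per-pulse depression
    factor. At -70 mV (high-chloride internal) IPSCs are inward (negative);
    at -40 mV (low-chloride internal) they are outward (positive). With
    ``gbz=True`` and ``gbz_blocks=True`` all GABAergic currents (evoked and
    miniature) are removed; a ChR2-contaminated cell instead shows a
    GBZ-insensitive inward current with < 1 ms onset latency.
    """
    rng = np.random.default_rng(seed)
    dt = 0.1  # ms at 10 kHz
    duration_ms = _sweep_duration_ms(protocol, post_ms)
    n_samples = int(round(duration_ms / dt))
    sweeps = np.zeros((n_sweeps, n_samples))
    sign = -1.0 if holding_potential_mv < -55.0 else 1.0
    kin = spec.kinetics
    kernel_len = int(round((kin.decay_tau_ms * 8) / dt))
    kernel_t = np.arange(kernel_len) * dt

    gaba_active = not (gbz and spec.gbz_blocks)

    for s in range(n_sweeps):
        trace = sweeps[s]
        if spec.connected and gaba_active:
            for k, onset_ms in enumerate(protocol.pulse_onsets_ms):
                if rng.random() >= spec.release_probability:
                    continue
                latency = kin.latency_mean_ms + rng.normal(0.0, kin.latency_jitter_sd_ms)
                latency = max(latency, dt)
                amp = spec.ipsc_amplitude_pa * spec.pulse_scale(k)
                _add_event(trace, onset_ms + latency, sign * amp, kernel_t,
                           kin.rise_tau_ms, kin.decay_tau_ms, dt)
        if spec.chr2_contaminated:
            # direct opsin photocurrent: sub-ms onset, inward, GBZ-insensitive,
            # sustained for the light pulse then decaying
            for onset_ms in protocol.pulse_onsets_ms:
                latency = max(0.5 + rng.normal(0.0, 0.1), dt)
                amp = 0.6 * spec.ipsc_amplitude_pa
                _add_photocurrent(trace, onset_ms + latency, -amp,
                                  protocol.pulse_width_ms, dt)
        if gaba_active and spec.mini_rate_hz > 0:
            n_minis = rng.poisson(spec.mini_rate_hz * duration_ms / 1000.0)
            lo, hi = spec.mini_amplitude_range_pa
            for t_mini in rng.uniform(0, duration_ms, size=n_minis):
                amp = rng.uniform(lo, hi)
                _add_event(trace, t_mini, sign * amp, kernel_t,
                           kin.rise_tau_ms, kin.decay_tau_ms, dt)
        if spec.noise_sd_pa > 0:
            trace += rng.normal(0.0, spec.noise_sd_pa, size=n_samples)

    rs_log = list(np.round(15.0 + rng.normal(0.0, 0.3, size=n_sweeps), 2))
    pharmacology = {"TTX_4AP", "NBQX_AP5"} if holding_potential_mv < -55 else {"NBQX_AP5"}
    if gbz:
        pharmacology.add("GBZ")
    return Recording(
        cell_id=cell_id,
        mode="whole_cell_vc",
        sweeps=sweeps,
        protocol=protocol,
        holding_potential_mv=holding_potential_mv,
        pharmacology=frozenset(pharmacology),
        rs_log=rs_log,
    )


def _add_photocurrent(trace, onset_ms, signed_amp, pulse_width_ms, dt,
                      rise_tau=0.5, off_tau=2.0):
    i0 = int(round(onset_ms / dt))
    if i0 >= trace.size:
        return
    n_on = int(round(pulse_width_ms / dt))
    n_off = int(round(8 * off_tau / dt))
    t_on = np.arange(n_on) * dt
    shape_on = 1.0 - np.exp(-t_on / rise_tau)
    level = shape_on[-1] if n_on else 1.0
    t_off = np.arange(1, n_off + 1) * dt
    shape = np.concatenate([shape_on, level * np.exp(-t_off / off_tau)])
    n = min(shape.size, trace.size - i0)
    trace[i0:i0 + n] += signed_amp * shape[:n]


def _add_event(trace, onset_ms, signed_amp, kernel_t, rise, decay, dt):
    i0 = int(round(onset_ms / dt))
    if i0 >= trace.size:
        return
    n = min(kernel_t.size, trace.size - i0)
    trace[i0:i0 + n] += signed_amp * ipsc_waveform(kernel_t[:n], rise, decay)


# ---------------------------------------------------------------------------
# Loose-seal cell-attached
# ---------------------------------------------------------------------------

def _draw_spike_times(rng, duration_ms, baseline_rate_hz, isi_cv,
                      window, suppression_factor) -> np.ndarray:
    """Spike times (ms) from a truncated-Gaussian ISI process.

    The rate modulation during the light train is implemented by time
    rescaling: ISIs are drawn in operational time (unit baseline rate) and
    mapped back through the integrated rate, which compresses or removes
    spikes inside the train window without disturbing the process outside.
    """
    if baseline_rate_hz <= 0:
        return np.array([])
    if isi_cv <= 0:
        raise ValueError("isi_cv must be positive")
    t0, t1 = window
    # integrated operational time over the sweep, in units of baseline ISIs
    def op_time(t):
        base = min(t, t0) + max(t - t1, 0.0)
        inside = min(max(t - t0, 0.0), t1 - t0)
        return (base + suppression_factor * inside) * baseline_rate_hz / 1000.0

    total_op = op_time(duration_ms)
    mean_isi = 1.0  # operational units
    sd = isi_cv * mean_isi
    times_op = []
    t = rng.uniform(0.0, mean_isi)  # random phase so sweeps are not locked
    while t < total_op:
        times_op.append(t)
        isi = rng.normal(mean_isi, sd)
        while isi < 0.1 * mean_isi:
            isi = rng.normal(mean_isi, sd)
        t += isi
    times_op = np.asarray(times_op)
    # invert the piecewise-linear operational-time map
    rate = baseline_rate_hz / 1000.0  # spikes per ms
    op_t0 = t0 * rate
    op_t1 = op_t0 + suppression_factor * (t1 - t0) * rate
    out = np.empty_like(times_op)
    for i, u in enumerate(times_op):
        if u < op_t0:
            out[i] = u / rate
        elif u < op_t1 and suppression_factor > 0:
            out[i] = t0 + (u - op_t0) / (suppression_factor * rate)
        else:
            out[i] = t1 + (u - op_t1) / rate
    return out


def simulate_loose_seal_recording(
    spec: SimCellSpec,
    protocol: StimulusProtocol,
    seed,
    *,
    n_sweeps: int = 10,
    gbz: bool = False,
    post_ms: float = 1000.0,
    cell_id: str = "sim_cell",
) -> Recording:
    """Simulate a loose-seal recording of tonic firing with a light train.

    The cell fires as a pacemaker (truncated-Gaussian ISI process with CV
    ``isi_cv``); during the train window the instantaneous rate is scaled
    by ``suppression_factor``. GBZ removes the (GABA-mediated) suppression.
    A ChR2-contaminated cell shows GBZ-insensitive time-locked extra
    spikes on every light pulse.
    """
    if spec.baseline_rate_hz < 0:
        raise ValueError("baseline_rate_hz must be nonnegative")
    rng = np.random.default_rng(seed)
    dt = 0.1
    duration_ms = _sweep_duration_ms(protocol, post_ms)
    n_samples = int(round(duration_ms / dt))
    sweeps = np.zeros((n_sweeps, n_samples))

    if protocol.kind == "train":
        t_start = protocol.pulse_onsets_ms[0]
        t_end = t_start + protocol.train_duration_s * 1000.0
    else:
        t_start = t_end = protocol.pulse_onsets_ms[0]
    factor = 1.0 if gbz else spec.suppression_factor

    template = spike_template(spec.spike_total_duration_ms, dt)
    for s in range(n_sweeps):
        trace = sweeps[s]
        sweep_rate = spec.baseline_rate_hz * max(
            1.0 + rng.normal(0.0, spec.rate_drift_cv), 0.2)
        spike_times = _draw_spike_times(
            rng, duration_ms, sweep_rate, spec.isi_cv,
            (t_start, t_end), factor,
        )
        if spec.chr2_contaminated:
            locked = np.asarray(protocol.pulse_onsets_ms) + 1.0
            spike_times = np.sort(np.concatenate([spike_times, locked]))
        for t_spk in spike_times:
            i0 = int(round(t_spk / dt))
            n = min(template.size, n_samples - i0)
            if n > 0:
                trace[i0:i0 + n] += spec.spike_amplitude_pa * template[:n]
        if spec.noise_sd_pa > 0:
            trace += rng.normal(0.0, spec.noise_sd_pa, size=n_samples)

    pharmacology = {"NBQX_AP5"} | ({"GBZ"} if gbz else set())
    return Recording(
        cell_id=cell_id,
        mode="loose_seal",
        sweeps=sweeps,
        protocol=protocol,
        holding_potential_mv=None,
        pharmacology=frozenset(pharmacology),
        rs_log=None,
    )


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

#: per-circuit soma-location distributions (AP, ML, DV mean in mm; common SD).
#: Laterally projecting cells sit more laterally in the SNc.
_LOCATION_MEANS = {
    "SNr_to_DLSproj": (-3.2, 1.6, -4.3),
    "SNr_to_DMSproj": (-3.1, 1.0, -4.3),
    "DLS_loop": (-3.2, 1.6, -4.3),
    "DMS_loop": (-3.1, 1.0, -4.3),
    "ascending_spiral": (-3.2, 1.6, -4.3),
    "descending_spiral": (-3.1, 1.0, -4.3),
}
_LOCATION_SD = (0.25, 0.2, 0.15)


@dataclass
class CohortSpec:
    """Parameters for simulating one circuit cohort.

    Amplitudes are lognormal (median ``amplitude_median_pa``, log-SD
    ``amplitude_sigma``), spanning roughly 0.1-4.5 nA at the defaults.
    ``connected_truth`` / ``suppressed_truth`` pin per-cell ground truth
    explicitly (fixture mode) instead of Bernoulli draws.
    ``conditions`` selects which recordings each cell carries:
    any of "vc", "loose_seal", "train".
    """

    circuit: str
    n_cells: int
    p_connected: float = 0.6
    p_suppressed_given_connected: float = 0.8
    amplitude_median_pa: float = 1200.0
    amplitude_sigma: float = 0.8
    seed: int = 0
    connected_truth: Optional[Sequence[bool]] = None
    suppressed_truth: Optional[Sequence[bool]] = None
    suppression_factor_suppressed: float = 0.1
    conditions: tuple[str, ...] = ("vc", "loose_seal")
    n_sweeps: int = 7
    depression_ratio: float = 0.985
    noise_sd_pa: float = 10.0

    def __post_init__(self):
        if self.circuit not in _LOCATION_MEANS:
            raise ValueError(f"unknown circuit {self.circuit!r}")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        for p in (self.p_connected, self.p_suppressed_given_connected):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        for truth in (self.connected_truth, self.suppressed_truth):
            if truth is not None and len(truth) != self.n_cells:
                raise ValueError("truth vector length must equal n_cells")


def simulate_cell(
    spec: SimCellSpec,
    cell_id: str,
    circuit: str,
    seed,
    *,
    conditions: tuple[str, ...] = ("vc", "loose_seal"),
    n_sweeps: int = 7,
) -> CellRecord:
    """Build a CellRecord with the requested recording conditions."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    seeds = ss.spawn(6)
    recordings = {}
    if "vc" in conditions:
        proto = StimulusProtocol.single_pulse()
        recordings["vc_baseline"] = simulate_vc_recording(
            spec, proto, seeds[0], n_sweeps=n_sweeps, cell_id=cell_id)
        if spec.connected or spec.chr2_contaminated:
            recordings["vc_gbz"] = simulate_vc_recording(
                spec, proto, seeds[1], n_sweeps=n_sweeps, gbz=True, cell_id=cell_id)
    if "loose_seal" in conditions:
        proto = StimulusProtocol.train()
        recordings["loose_seal"] = simulate_loose_seal_recording(
            spec, proto, seeds[2], n_sweeps=max(n_sweeps, 5), cell_id=cell_id)
        if spec.chr2_contaminated:
            recordings["loose_seal_gbz"] = simulate_loose_seal_recording(
                spec, proto, seeds[3], n_sweeps=max(n_sweeps, 5), gbz=True,
                cell_id=cell_id)
    if "train" in conditions:
        proto = StimulusProtocol.train(start_ms=500.0)
        recordings["train_minus40"] = simulate_vc_recording(
            spec, proto, seeds[4], n_sweeps=n_sweeps,
            holding_potential_mv=-40.0, post_ms=700.0, cell_id=cell_id)
    return CellRecord(
        cell_id=cell_id,
        circuit=circuit,
        projection_target=CIRCUIT_PROJECTION[circuit],
        location_mm=spec.location_mm,
        recordings=recordings,
    )


def simulate_cohort(cohort: CohortSpec) -> tuple[list[CellRecord], pd.DataFrame]:
    """Simulate a full cohort; returns (cells, ground-truth table).

    Connectivity flags are Bernoulli(p_connected) and suppression flags
    Bernoulli(p_suppressed_given_connected) among connected cells, unless
    explicit truth vectors are supplied. The ground-truth table has one
    row per cell (cell_id, flags, amplitude, latency, rates, location).
    """
    rng = np.random.default_rng(np.random.SeedSequence(cohort.seed))
    cell_seeds = np.random.SeedSequence(cohort.seed).spawn(cohort.n_cells + 1)[1:]

    if cohort.connected_truth is not None:
        connected = np.asarray(cohort.connected_truth, dtype=bool)
    else:
        connected = rng.random(cohort.n_cells) < cohort.p_connected
    if cohort.suppressed_truth is not None:
        suppressed = np.asarray(cohort.suppressed_truth, dtype=bool)
    else:
        suppressed = connected & (
            rng.random(cohort.n_cells) < cohort.p_suppressed_given_connected
        )

    loc_mean = np.asarray(_LOCATION_MEANS[cohort.circuit])
    cells: list[CellRecord] = []
    truth_rows = []
    n_pulses = StimulusProtocol.train().n_pulses
    for i in range(cohort.n_cells):
        amp = float(np.clip(
            cohort.amplitude_median_pa * math.exp(rng.normal(0.0, cohort.amplitude_sigma)),
            80.0, 5000.0))
        latency = float(np.clip(rng.normal(1.8, 0.3), 1.0, 4.5))
        baseline_rate = float(rng.uniform(2.0, 6.0))
        location = tuple(loc_mean + rng.normal(0.0, 1.0, 3) * np.asarray(_LOCATION_SD))
        factor = cohort.suppression_factor_suppressed if suppressed[i] else 1.0
        spec = SimCellSpec(
            connected=bool(connected[i]),
            ipsc_amplitude_pa=amp,
            kinetics=IpscKinetics(latency_mean_ms=latency),
            depression_profile=geometric_depression(cohort.depression_ratio, n_pulses),
            baseline_rate_hz=baseline_rate,
            suppression_factor=factor,
            noise_sd_pa=cohort.noise_sd_pa,
            location_mm=location,
        )
        cell_id = f"{cohort.circuit}_{i:03d}"
        cells.append(simulate_cell(
            spec, cell_id, cohort.circuit, cell_seeds[i],
            conditions=cohort.conditions, n_sweeps=cohort.n_sweeps,
        ))
        truth_rows.append({
            "cell_id": cell_id,
            "circuit": cohort.circuit,
            "connected": bool(connected[i]),
            "suppressed": bool(suppressed[i]),
            "ipsc_amplitude_pa": amp,
            "latency_ms": latency,
            "baseline_rate_hz": baseline_rate,
            "suppression_factor": factor,
            "ap_mm": location[0],
            "ml_mm": location[1],
            "dv_mm": location[2],
        })
    return cells, pd.DataFrame(truth_rows)
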