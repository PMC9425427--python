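"""Data model and serialization for sweep-organized patch-clamp recordings.

A *dataset* on disk is a directory with a JSON manifest describing cells,
recording conditions and stimulus protocols, plus one CSV trace file per
recording (first column ``time_ms``, one column per sweep, currents in pA).
The layout is deliberately human-inspectable so that small fixtures can be
read in a text editor.

Unit conventions used throughout the package: currents in pA, times in ms,
voltages in mV, resistances in MOhm. Inward current is negative (standard
voltage-clamp convention). Each sweep starts at t = 0 ms and light onsets
are sweep-relative.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

CIRCUITS = (
    "SNr_to_DLSproj",
    "SNr_to_DMSproj",
    "DLS_loop",
    "DMS_loop",
    "ascending_spiral",
    "descending_spiral",
)

#: projection target implied by each circuit configuration (which striatal
#: subregion the recorded dopamine neuron projects to)
CIRCUIT_PROJECTION = {
    "SNr_to_DLSproj": "DLS",
    "SNr_to_DMSproj": "DMS",
    "DLS_loop": "DLS",
    "DMS_loop": "DMS",
    "ascending_spiral": "DLS",
    "descending_spiral": "DMS",
}

RECORDING_MODES = ("whole_cell_vc", "loose_seal")
PHARMACOLOGY_AGENTS = ("TTX_4AP", "NBQX_AP5", "GBZ")


class DatasetValidationError(ValueError):
    """Raised when a dataset or record violates a structural invariant."""


@dataclass(frozen=True)
class StimulusProtocol:
    """Light-stimulation protocol for one recording.

    Parameters
    ----------
    kind
        ``"single_pulse"`` or ``"train"``.
    pulse_width_ms
        Duration of each light pulse (default 5 ms).
    pulse_onsets_ms
        Sweep-relative onset time of each pulse, strictly increasing.
    train_frequency_hz, train_duration_s
        Train parameters (trains only). The standard train is 20 Hz for
        3 s, i.e. 60 pulses.
    nominal_irradiance_mw_mm2
        Light intensity at the slice; metadata only.
    """

    kind: str
    pulse_width_ms: float
    pulse_onsets_ms: tuple[float, ...]
    train_frequency_hz: Optional[float] = None
    train_duration_s: Optional[float] = None
    nominal_irradiance_mw_mm2: float = 10.0

    def __post_init__(self):
        if self.kind not in ("single_pulse", "train"):
            raise DatasetValidationError(f"unknown protocol kind {self.kind!r}")
        onsets = tuple(float(t) for t in self.pulse_onsets_ms)
        object.__setattr__(self, "pulse_onsets_ms", onsets)
        if len(onsets) == 0:
            raise DatasetValidationError("protocol needs at least one pulse onset")
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise DatasetValidationError("pulse onsets must be strictly increasing")
        if self.kind == "single_pulse":
            if len(onsets) != 1:
                raise DatasetValidationError("single_pulse protocol must have exactly one onset")
        else:
            if self.train_frequency_hz is None or self.train_duration_s is None:
                raise DatasetValidationError("train protocol requires frequency and duration")
            period = 1000.0 / self.train_frequency_hz
            gaps = np.diff(onsets)
            # one sample period of slack at the default 10 kHz rate
            if np.any(np.abs(gaps - period) > 0.1 + 1e-9):
                raise DatasetValidationError(
                    "train onsets are not evenly spaced at the stated frequency"
                )

    @property
    def n_pulses(self) -> int:
        return len(self.pulse_onsets_ms)

    @classmethod
    def single_pulse(cls, onset_ms: float = 100.0, pulse_width_ms: float = 5.0) -> "StimulusProtocol":
        return cls("single_pulse", pulse_width_ms, (onset_ms,))

    @classmethod
    def train(
        cls,
        start_ms: float = 3000.0,
        frequency_hz: float = 20.0,
        duration_s: float = 3.0,
        pulse_width_ms: float = 5.0,
    ) -> "StimulusProtocol":
        """Standard suppression / release-probability train: 20 Hz for 3 s."""
        n = int(round(frequency_hz * duration_s))
        onsets = tuple(start_ms + 1000.0 / frequency_hz * k for k in range(n))
        return cls("train", pulse_width_ms, onsets, frequency_hz, duration_s)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["pulse_onsets_ms"] = list(self.pulse_onsets_ms)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "StimulusProtocol":
        return cls(
            kind=d["kind"],
            pulse_width_ms=d["pulse_width_ms"],
            pulse_onsets_ms=tuple(d["pulse_onsets_ms"]),
            train_frequency_hz=d.get("train_frequency_hz"),
            train_duration_s=d.get("train_duration_s"),
            nominal_irradiance_mw_mm2=d.get("nominal_irradiance_mw_mm2", 10.0),
        )


@dataclass
class Recording:
    """One cell x one protocol: equal-length current sweeps plus metadata.

    ``sweeps`` is a float array of shape (n_sweeps, n_samples) in pA.
    Whole-cell recordings carry a per-sweep series-resistance log
    (``rs_log``, MOhm); loose-seal recordings do not.
    """

    cell_id: str
    mode: str
    sweeps: np.ndarray
    protocol: StimulusProtocol
    holding_potential_mv: Optional[float] = None
    sampling_rate_hz: float = 10_000.0
    sweep_interval_s: float = 30.0
    pharmacology: frozenset = frozenset()
    rs_log: Optional[list[float]] = None

    def __post_init__(self):
        if self.mode not in RECORDING_MODES:
            raise DatasetValidationError(f"{self.cell_id}: unknown recording mode {self.mode!r}")
        self.sweeps = np.asarray(self.sweeps, dtype=float)
        if self.sweeps.ndim != 2 or self.sweeps.shape[0] < 1:
            raise DatasetValidationError(
                f"{self.cell_id}: sweeps must be a (n_sweeps, n_samples) matrix"
            )
        self.pharmacology = frozenset(self.pharmacology)
        unknown = self.pharmacology - set(PHARMACOLOGY_AGENTS)
        if unknown:
            raise DatasetValidationError(f"{self.cell_id}: unknown pharmacology {sorted(unknown)}")
        if self.mode == "loose_seal":
            if self.rs_log is not None:
                raise DatasetValidationError(f"{self.cell_id}: loose-seal recordings carry no rs_log")
        elif self.rs_log is not None:
            self.rs_log = [float(r) for r in self.rs_log]
            if len(self.rs_log) != self.n_sweeps:
                raise DatasetValidationError(f"{self.cell_id}: rs_log length != number of sweeps")
        last_onset = self.protocol.pulse_onsets_ms[-1]
        if last_onset >= self.duration_ms:
            raise DatasetValidationError(f"{self.cell_id}: stimulus extends past end of sweep")

    @property
    def n_sweeps(self) -> int:
        return self.sweeps.shape[0]

    @property
    def n_samples(self) -> int:
        return self.sweeps.shape[1]

    @property
    def dt_ms(self) -> float:
        return 1000.0 / self.sampling_rate_hz

    @property
    def duration_ms(self) -> float:
        return self.n_samples * self.dt_ms

    @property
    def time_ms(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.dt_ms


@dataclass
class CellRecord:
    """Per-cell metadata plus its recordings keyed by condition name.

    Standard condition keys used by the pipeline:
    ``vc_baseline`` / ``vc_gbz`` (whole-cell, -70 mV single pulse),
    ``loose_seal`` / ``loose_seal_gbz`` (cell-attached train),
    ``train_minus40`` / ``train_minus40_gbz`` (whole-cell, -40 mV train).
    """

    cell_id: str
    circuit: str
    projection_target: str
    location_mm: tuple[float, float, float]  # (AP, ML, DV)
    recordings: dict[str, Recording] = field(default_factory=dict)

    def __post_init__(self):
        if self.circuit not in CIRCUITS:
            raise DatasetValidationError(f"{self.cell_id}: unknown circuit {self.circuit!r}")
        expected = CIRCUIT_PROJECTION[self.circuit]
        if self.projection_target != expected:
            raise DatasetValidationError(
                f"{self.cell_id}: circuit {self.circuit} implies projection target "
                f"{expected}, got {self.projection_target}"
            )
        loc = tuple(float(x) for x in self.location_mm)
        if len(loc) != 3 or not all(np.isfinite(loc)):
            raise DatasetValidationError(f"{self.cell_id}: location must be a finite (AP, ML, DV) triple")
        self.location_mm = loc
        for key, rec in self.recordings.items():
            if rec.cell_id != self.cell_id:
                raise DatasetValidationError(
                    f"{self.cell_id}: recording {key!r} belongs to cell {rec.cell_id!r}"
                )


@dataclass
class CellResult:
    """Per-cell classification output of the analysis pipeline."""

    cell_id: str
    circuit: str
    connected: Optional[bool] = None
    mean_amplitude_pa: Optional[float] = None
    mean_latency_ms: Optional[float] = None
    gbz_blocked: Optional[bool] = None
    suppressed: Optional[bool] = None
    baseline_rate_hz: Optional[float] = None
    baseline_sd_hz: Optional[float] = None
    during_rate_hz: Optional[float] = None
    ppr: Optional[float] = None
    last_first_ratio: Optional[float] = None
    first_latency_ms: Optional[float] = None
    slow_current: Optional[bool] = None
    qc_pass: bool = True
    qc_reason: str = "ok"

    #: stable column order for results tables
    COLUMNS = (
        "cell_id", "circuit", "connected", "mean_amplitude_pa", "mean_latency_ms",
        "gbz_blocked", "suppressed", "baseline_rate_hz", "baseline_sd_hz",
        "during_rate_hz", "ppr", "last_first_ratio", "first_latency_ms",
        "slow_current", "qc_pass", "qc_reason",
    )


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

_MANIFEST_NAME = "manifest.json"
_TRACE_DIR = "traces"


def _trace_filename(cell_id: str, condition: str) -> str:
    return f"{cell_id}__{condition}.csv"


def write_dataset(records: Iterable[CellRecord], path) -> Path:
    """Write a collection of cells to ``path`` (manifest + CSV traces).

    Returns the dataset directory. Traces are written with 1e-6 pA
    precision so that a read/write cycle is lossless to that tolerance.
    """
    path = Path(path)
    (path / _TRACE_DIR).mkdir(parents=True, exist_ok=True)
    manifest: dict = {"format_version": 1, "cells": []}
    for cell in records:
        entry = {
            "cell_id": cell.cell_id,
            "circuit": cell.circuit,
            "projection_target": cell.projection_target,
            "location_mm": list(cell.location_mm),
            "recordings": {},
        }
        for condition, rec in cell.recordings.items():
            fname = _trace_filename(cell.cell_id, condition)
            entry["recordings"][condition] = {
                "file": f"{_TRACE_DIR}/{fname}",
                "mode": rec.mode,
                "holding_potential_mv": rec.holding_potential_mv,
                "sampling_rate_hz": rec.sampling_rate_hz,
                "sweep_interval_s": rec.sweep_interval_s,
                "pharmacology": sorted(rec.pharmacology),
                "rs_log_mohm": rec.rs_log,
                "protocol": rec.protocol.to_dict(),
            }
            df = pd.DataFrame(
                rec.sweeps.T,
                columns=[f"sweep{i:02d}" for i in range(rec.n_sweeps)],
            )
            df.insert(0, "time_ms", rec.time_ms)
            df.to_csv(path / _TRACE_DIR / fname, index=False, float_format="%.6f")
        manifest["cells"].append(entry)
    with open(path / _MANIFEST_NAME, "w") as fh:
        json.dump(manifest, fh, indent=1)
    return path


def read_dataset(path) -> list[CellRecord]:
    """Load a dataset directory written by :func:`write_dataset`.

    All structural invariants are enforced on load; violations raise
    :class:`DatasetValidationError` naming the offending cell. Auxiliary
    files (e.g. a simulator ground-truth sidecar) are ignored.
    """
    path = Path(path)
    manifest_path = path / _MANIFEST_NAME
    if not manifest_path.exists():
        raise DatasetValidationError(f"no {_MANIFEST_NAME} in {path}")
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    cells: list[CellRecord] = []
    for entry in manifest["cells"]:
        cell_id = entry.get("cell_id", "<missing id>")
        recordings: dict[str, Recording] = {}
        for condition, meta in entry.get("recordings", {}).items():
            trace_path = path / meta["file"]
            if not trace_path.exists():
                raise DatasetValidationError(f"{cell_id}: missing trace file {meta['file']}")
            df = pd.read_csv(trace_path)
            if df.isna().any().any():
                raise DatasetValidationError(
                    f"{cell_id}: ragged sweeps (unequal lengths) in {meta['file']}"
                )
            sweep_cols = [c for c in df.columns if c != "time_ms"]
            sweeps = df[sweep_cols].to_numpy(dtype=float).T
            recordings[condition] = Recording(
                cell_id=cell_id,
                mode=meta["mode"],
                sweeps=sweeps,
                protocol=StimulusProtocol.from_dict(meta["protocol"]),
                holding_potential_mv=meta.get("holding_potential_mv"),
                sampling_rate_hz=meta.get("sampling_rate_hz", 10_000.0),
                sweep_interval_s=meta.get("sweep_interval_s", 30.0),
                pharmacology=frozenset(meta.get("pharmacology", [])),
                rs_log=meta.get("rs_log_mohm"),
            )
        cells.append(
            CellRecord(
                cell_id=cell_id,
                circuit=entry["circuit"],
                projection_target=entry["projection_target"],
                location_mm=tuple(entry["location_mm"]),
                recordings=recordings,
            )
        )
    return cells


def write_results_table(results: Sequence, path) -> Path:
    """Write per-cell results or cohort summaries to a CSV table.

    One row per item, columns in the stable order declared by the result
    type (``COLUMNS``); unknown dataclasses fall back to field order.
    """
    path = Path(path)
    rows = []
    columns = None
    for item in results:
        if hasattr(item, "to_row"):
            row = item.to_row()
        else:
            row = asdict(item)
        if columns is None:
            columns = list(getattr(type(item), "COLUMNS", row.keys()))
        rows.append(row)
    df = pd.DataFrame(rows, columns=columns)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path
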