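"""Spike-table and raw-voltage I/O for multi-electrode-array recordings.

The recording hardware modelled here is a 120-electrode planar array with
100 µm inter-electrode pitch sampled at 20 kHz.  Extracellular action
potentials (eAPs, "spikes") appear as brief negative voltage deflections;
each electrode's spike train is a pair of arrays (times in seconds,
negative-peak amplitudes in µV).

Raw-trace processing follows standard extracellular practice: a zero-phase
band-pass (Butterworth, 200–4000 Hz, 2nd order) followed by threshold
crossing at 6× a robust, median-based estimate of the noise scale.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import h5py
import numpy as np
import pandas as pd
from scipy import signal as sps

__all__ = [
    "ElectrodeMap",
    "VoltageRecording",
    "SpikeTrain",
    "Recording",
    "bandpass_filter",
    "detect_spikes",
    "read_spike_table",
    "write_spike_table",
    "read_voltage_h5",
    "write_voltage_h5",
]

# Row letters of the default 12x12 grid ('I' is skipped, as is conventional
# for MEA labelling to avoid confusion with '1').
_ROW_LETTERS = "ABCDEFGHJKLM"


@dataclass(frozen=True)
class ElectrodeMap:
    """Array geometry: electrode labels and planar coordinates in µm."""

    labels: tuple[str, ...]
    coordinates: np.ndarray  # shape (n, 2), µm
    pitch: float = 100.0

    def __post_init__(self) -> None:
        coords = np.asarray(self.coordinates, dtype=float)
        object.__setattr__(self, "coordinates", coords)
        if len(self.labels) != len(set(self.labels)):
            raise ValueError("electrode labels must be unique")
        if coords.shape != (len(self.labels), 2):
            raise ValueError("coordinates must be (n_electrodes, 2)")
        if len({tuple(c) for c in coords.tolist()}) != len(self.labels):
            raise ValueError("electrode coordinates must be unique")

    @property
    def n_electrodes(self) -> int:
        return len(self.labels)

    def __contains__(self, label: str) -> bool:
        return label in self.labels

    def position(self, label: str) -> tuple[float, float]:
        i = self.labels.index(label)
        return tuple(self.coordinates[i])

    @classmethod
    def default_120(cls, pitch: float = 100.0) -> "ElectrodeMap":
        """120-electrode map: a 12×12 grid with 6 electrodes cropped from
        each corner (triangular cut), 100 µm pitch."""
        labels: list[str] = []
        coords: list[tuple[float, float]] = []
        n = 12
        for r in range(n):
            for c in range(n):
                # triangular corner cut: rows 0..2 / 9..11 lose 3/2/1 cols
                top = min(r, n - 1 - r)
                left = min(c, n - 1 - c)
                if top + left < 3:
                    continue
                labels.append(f"{_ROW_LETTERS[r]}{c + 1}")
                coords.append((c * pitch, r * pitch))
        return cls(tuple(labels), np.array(coords), pitch)

    @classmethod
    def grid(cls, n_rows: int, n_cols: int, pitch: float = 100.0) -> "ElectrodeMap":
        """Small rectangular map, mainly for tests and simulations."""
        labels = [
            f"{_ROW_LETTERS[r]}{c + 1}" for r in range(n_rows) for c in range(n_cols)
        ]
        coords = np.array(
            [(c * pitch, r * pitch) for r in range(n_rows) for c in range(n_cols)]
        )
        return cls(tuple(labels), coords, pitch)


@dataclass
class VoltageRecording:
    """Per-electrode sampled extracellular voltage in µV."""

    sampling_rate: float  # Hz
    channels: dict[str, np.ndarray]  # label -> voltage (µV)
    electrode_map: ElectrodeMap

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        lengths = {len(v) for v in self.channels.values()}
        if len(lengths) > 1:
            raise ValueError("all channels must have identical length")
        for label in self.channels:
            if label not in self.electrode_map:
                raise ValueError(f"channel {label!r} not in electrode map")
        self.channels = {k: np.asarray(v, dtype=float) for k, v in self.channels.items()}

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values()))) if self.channels else 0

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate


@dataclass
class SpikeTrain:
    """One electrode's spikes: times (s, strictly increasing) and signed
    negative-peak amplitudes (µV, all < 0)."""

    electrode: str
    times: np.ndarray
    amplitudes: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        a = np.asarray(self.amplitudes, dtype=float)
        if t.shape != a.shape or t.ndim != 1:
            raise ValueError(
                f"electrode {self.electrode}: times and amplitudes must be "
                f"1-d arrays of equal length"
            )
        if t.size > 1 and not np.all(np.diff(t) > 0):
            bad = int(np.flatnonzero(np.diff(t) <= 0)[0]) + 1
            raise ValueError(
                f"electrode {self.electrode}: spike times not strictly "
                f"increasing at index {bad} (t={t[bad]:g})"
            )
        if np.any(a >= 0):
            bad = int(np.flatnonzero(a >= 0)[0])
            raise ValueError(
                f"electrode {self.electrode}: amplitude at index {bad} is "
                f"non-negative ({a[bad]:g} µV); spikes are negative deflections"
            )
        self.times = t
        self.amplitudes = a

    @property
    def n_spikes(self) -> int:
        return self.times.size

    def isis(self) -> np.ndarray:
        return np.diff(self.times)


@dataclass
class Recording:
    """A set of spike trains over an electrode map.

    ``trains`` may cover a subset of the map's electrodes; absent electrodes
    are treated as silent.
    """

    trains: dict[str, SpikeTrain]
    electrode_map: ElectrodeMap
    duration: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for label, tr in self.trains.items():
            if label not in self.electrode_map:
                raise ValueError(f"train electrode {label!r} not in electrode map")
            if tr.electrode != label:
                raise ValueError(f"train keyed {label!r} labels itself {tr.electrode!r}")
            if tr.n_spikes and tr.times[-1] > self.duration:
                raise ValueError(
                    f"electrode {label}: spike at {tr.times[-1]:g} s exceeds "
                    f"duration {self.duration:g} s"
                )

    @property
    def n_spikes(self) -> int:
        return sum(tr.n_spikes for tr in self.trains.values())

    def train(self, label: str) -> SpikeTrain:
        if label in self.trains:
            return self.trains[label]
        if label not in self.electrode_map:
            raise KeyError(label)
        return SpikeTrain(label, np.empty(0), np.empty(0))

    def active_electrodes(self) -> list[str]:
        return [e for e, tr in self.trains.items() if tr.n_spikes > 0]


# ---------------------------------------------------------------------------
# raw-trace processing


def bandpass_filter(
    rec: VoltageRecording,
    low: float = 200.0,
    high: float = 4000.0,
    order: int = 2,
) -> VoltageRecording:
    """Zero-phase Butterworth band-pass of every channel.

    The filter is applied forward-backward (``sosfiltfilt``) so that spike
    times are not shifted by the filter's phase response.
    """
    nyq = rec.sampling_rate / 2.0
    if not (0 < low < high):
        raise ValueError("require 0 < low < high")
    if high >= nyq:
        raise ValueError(f"high cutoff {high} Hz is at or above Nyquist ({nyq} Hz)")
    if order < 1:
        raise ValueError("order must be >= 1")
    sos = sps.butter(order, [low, high], btype="bandpass", fs=rec.sampling_rate, output="sos")
    filtered = {k: sps.sosfiltfilt(sos, v) for k, v in rec.channels.items()}
    return VoltageRecording(rec.sampling_rate, filtered, rec.electrode_map)


def robust_noise_sd(v: np.ndarray) -> float:
    """Median-based noise scale: median(|v|)/0.6745, robust to spikes."""
    v = np.asarray(v, dtype=float)
    if v.size == 0:
        return 0.0
    return float(np.median(np.abs(v)) / 0.6745)


def detect_spikes(
    rec: VoltageRecording,
    k_threshold: float = 6.0,
    dead_time: float = 1e-3,
) -> Recording:
    """Threshold detection of negative deflections on each channel.

    A spike is recorded at every local negative minimum whose value is below
    −k·σ, with σ the median-based noise scale of that channel.  Detections
    closer than ``dead_time`` (s) to a previous one on the same channel are
    suppressed (the more negative peak wins via ``find_peaks`` distance).
    """
    if k_threshold <= 0:
        raise ValueError("k_threshold must be positive")
    if dead_time < 0:
        raise ValueError("dead_time must be >= 0")
    fs = rec.sampling_rate
    distance = max(1, int(round(dead_time * fs)))
    trains: dict[str, SpikeTrain] = {}
    for label, v in rec.channels.items():
        sigma = robust_noise_sd(v)
        if v.size == 0 or sigma == 0.0:
            trains[label] = SpikeTrain(label, np.empty(0), np.empty(0))
            continue
        idx, _ = sps.find_peaks(-v, height=k_threshold * sigma, distance=distance)
        trains[label] = SpikeTrain(label, idx / fs, v[idx])
    return Recording(trains, rec.electrode_map, duration=rec.n_samples / fs)


# ---------------------------------------------------------------------------
# spike-table I/O

_CSV_COLUMNS = ["electrode", "time_s", "amplitude_uV"]


def write_spike_table(rec: Recording, path: str | Path, format: str | None = None) -> None:
    """Write a Recording as CSV (columns electrode,time_s,amplitude_uV) or
    HDF5 (one group per electrode with ``times``/``amplitudes`` datasets and
    root attributes ``duration`` and the electrode map)."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "csv":
        frames = [
            pd.DataFrame(
                {"electrode": label, "time_s": tr.times, "amplitude_uV": tr.amplitudes}
            )
            for label, tr in sorted(rec.trains.items())
        ]
        df = (
            pd.concat(frames, ignore_index=True)
            if frames
            else pd.DataFrame(columns=_CSV_COLUMNS)
        )
        df.to_csv(path, index=False)
    elif fmt == "hdf5":
        with h5py.File(path, "w") as f:
            f.attrs["duration"] = rec.duration
            f.attrs["pitch"] = rec.electrode_map.pitch
            f.attrs["electrode_labels"] = list(rec.electrode_map.labels)
            f.create_dataset("electrode_xy", data=rec.electrode_map.coordinates)
            g = f.create_group("electrodes")
            for label, tr in rec.trains.items():
                sub = g.create_group(label)
                sub.create_dataset("times", data=tr.times)
                sub.create_dataset("amplitudes", data=tr.amplitudes)
    else:
        raise ValueError(f"unknown format {fmt!r}; expected 'csv' or 'hdf5'")


def read_spike_table(
    path: str | Path,
    format: str | None = None,
    electrode_map: ElectrodeMap | None = None,
    duration: float | None = None,
) -> Recording:
    """Read a spike table written by :func:`write_spike_table`.

    For CSV, ``electrode_map`` defaults to the standard 120-electrode map and
    unknown labels or non-monotone times raise a validation error naming the
    offending row/electrode.
    """
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "csv":
        emap = electrode_map or ElectrodeMap.default_120()
        df = pd.read_csv(path)
        missing = [c for c in _CSV_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"CSV missing columns: {missing}")
        trains: dict[str, SpikeTrain] = {}
        for label, grp in df.groupby("electrode", sort=True):
            label = str(label)
            if label not in emap:
                row = int(grp.index[0]) + 2  # 1-based + header line
                raise ValueError(f"unknown electrode label {label!r} at CSV line {row}")
            t = grp["time_s"].to_numpy(dtype=float)
            if t.size > 1 and not np.all(np.diff(t) > 0):
                bad = int(grp.index[np.flatnonzero(np.diff(t) <= 0)[0] + 1]) + 2
                raise ValueError(
                    f"electrode {label}: non-monotone spike times at CSV line {bad}"
                )
            trains[label] = SpikeTrain(label, t, grp["amplitude_uV"].to_numpy(dtype=float))
        dur = duration
        if dur is None:
            dur = max((tr.times[-1] for tr in trains.values() if tr.n_spikes), default=0.0)
        return Recording(trains, emap, duration=float(dur))
    if fmt == "hdf5":
        with h5py.File(path, "r") as f:
            labels = tuple(str(x) for x in f.attrs["electrode_labels"])
            emap = electrode_map or ElectrodeMap(
                labels, np.asarray(f["electrode_xy"]), float(f.attrs.get("pitch", 100.0))
            )
            trains = {}
            for label in f["electrodes"]:
                g = f["electrodes"][label]
                trains[label] = SpikeTrain(
                    label, np.asarray(g["times"]), np.asarray(g["amplitudes"])
                )
            return Recording(trains, emap, duration=float(f.attrs["duration"]))
    raise ValueError(f"unknown format {fmt!r}; expected 'csv' or 'hdf5'")


def write_voltage_h5(rec: VoltageRecording, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["sampling_rate"] = rec.sampling_rate
        f.attrs["pitch"] = rec.electrode_map.pitch
        f.attrs["electrode_labels"] = list(rec.electrode_map.labels)
        f.create_dataset("electrode_xy", data=rec.electrode_map.coordinates)
        g = f.create_group("voltage")
        for label, v in rec.channels.items():
            g.create_dataset(label, data=v)


def read_voltage_h5(path: str | Path) -> VoltageRecording:
    with h5py.File(path, "r") as f:
        labels = tuple(str(x) for x in f.attrs["electrode_labels"])
        emap = ElectrodeMap(
            labels, np.asarray(f["electrode_xy"]), float(f.attrs.get("pitch", 100.0))
        )
        channels = {label: np.asarray(f["voltage"][label]) for label in f["voltage"]}
        return VoltageRecording(float(f.attrs["sampling_rate"]), channels, emap)


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".csv":
        return "csv"
    if suffix in {".h5", ".hdf5", ".hdf"}:
        return "hdf5"
    raise ValueError(f"cannot infer format from suffix {suffix!r}")
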