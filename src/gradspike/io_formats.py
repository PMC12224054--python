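"""Typed containers and on-disk formats for recordings and spike waveforms.

All times are seconds, sample indices are 0-based, and conversion happens
only at file boundaries.  Waveform matrices are laid out with spikes as rows
and samples as columns; downstream gradient and embedding code assumes that
orientation everywhere.
"""

from __future__ import annotations

import csv as _csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import h5py
import numpy as np
from scipy.io import loadmat, savemat


class FormatError(ValueError):
    """Raised when a file's layout does not match the declared format."""


class ConfigurationError(ValueError):
    """Raised when required metadata (e.g. a sampling rate) is missing."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class Recording:
    """Multichannel extracellular voltage trace.

    Parameters
    ----------
    samples
        ``(n_channels, n_timepoints)`` array in microvolts.
    sampling_rate
        Sampling frequency in Hz; must be positive.
    channel_positions
        Optional ``(n_channels, 2)`` array of (x, y) probe coordinates in µm.
    channel_ids
        Optional per-channel identifiers.
    """

    samples: np.ndarray
    sampling_rate: float
    channel_positions: Optional[np.ndarray] = None
    channel_ids: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D (channels x time) array")
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")
        bad = ~np.isfinite(self.samples)
        if bad.any():
            ch, idx = np.argwhere(bad)[0]
            raise ValueError(
                f"non-finite sample at channel {ch}, index {idx}"
            )
        if self.channel_positions is not None:
            self.channel_positions = np.asarray(self.channel_positions, dtype=float)
            if len(self.channel_positions) != self.n_channels:
                raise ValueError(
                    "channel_positions must have one entry per channel"
                )

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Recording):
            return NotImplemented
        return (
            np.array_equal(self.samples, other.samples)
            and self.sampling_rate == other.sampling_rate
            and _optional_equal(self.channel_positions, other.channel_positions)
        )


@dataclass
class WaveformSet:
    """A matrix of spike snippets with per-spike metadata.

    ``waveforms`` is ``(n_spikes, n_samples)``; ``spike_times`` are seconds
    and must be nondecreasing.  ``labels`` and ``overlap_flags`` are optional
    per-spike annotations (ground-truth unit ids, collision flags).
    """

    waveforms: np.ndarray
    spike_times: np.ndarray
    sampling_rate: float
    labels: Optional[np.ndarray] = None
    overlap_flags: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.waveforms = np.atleast_2d(np.asarray(self.waveforms, dtype=float))
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        if self.waveforms.size == 0:
            self.waveforms = self.waveforms.reshape(0, self.waveforms.shape[-1] if self.waveforms.ndim == 2 else 0)
        if self.waveforms.shape[0] != self.spike_times.shape[0]:
            raise ValueError("waveforms and spike_times must have equal length")
        if np.any(np.diff(self.spike_times) < 0):
            raise ValueError("spike_times must be sorted ascending")
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")
        for name in ("labels", "overlap_flags"):
            val = getattr(self, name)
            if val is not None:
                val = np.asarray(val)
                if val.shape[0] != self.n_spikes:
                    raise ValueError(f"{name} must have one entry per spike")
                setattr(self, name, val)

    @property
    def n_spikes(self) -> int:
        return self.waveforms.shape[0]

    @property
    def n_samples(self) -> int:
        return self.waveforms.shape[1]

    def peak_normalized(self) -> "WaveformSet":
        """Scale each waveform so max |amplitude| is 1 (no-op on zero rows)."""
        peaks = np.max(np.abs(self.waveforms), axis=1, keepdims=True)
        peaks[peaks == 0] = 1.0
        return replace(self, waveforms=self.waveforms / peaks)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WaveformSet):
            return NotImplemented
        return (
            np.array_equal(self.waveforms, other.waveforms)
            and np.array_equal(self.spike_times, other.spike_times)
            and self.sampling_rate == other.sampling_rate
            and _optional_equal(self.labels, other.labels)
            and _optional_equal(self.overlap_flags, other.overlap_flags)
        )


@dataclass
class GroundTruth:
    """True unit identities and spike times for scoring."""

    unit_ids: np.ndarray
    spike_times: np.ndarray
    overlap_flags: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.unit_ids = np.asarray(self.unit_ids)
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        if self.unit_ids.shape[0] != self.spike_times.shape[0]:
            raise ValueError("unit_ids and spike_times must have equal length")
        if self.overlap_flags is not None:
            self.overlap_flags = np.asarray(self.overlap_flags, dtype=bool)
            if self.overlap_flags.shape[0] != self.unit_ids.shape[0]:
                raise ValueError("overlap_flags must have one entry per spike")

    @property
    def n_spikes(self) -> int:
        return self.unit_ids.shape[0]

    @property
    def units(self) -> np.ndarray:
        return np.unique(self.unit_ids)


def _optional_equal(a, b) -> bool:
    if a is None and b is None:
        return True
    if a is None or b is None:
        return False
    return np.array_equal(a, b)


# ---------------------------------------------------------------------------
# waveform-set readers/writers
# ---------------------------------------------------------------------------

# Variable-name aliases used by the public simulated-dataset MAT files.
_MAT_ALIASES = {
    "waveforms": ("waveforms", "spikes"),
    "spike_times": ("spike_times", "index"),
    "labels": ("labels", "spike_class"),
    "overlap": ("overlap", "overlap_flags", "OVERLAP_DATA"),
}


def read_waveform_set(path, format: Optional[str] = None,
                      sampling_rate: Optional[float] = None) -> WaveformSet:
    """Read a :class:`WaveformSet` from CSV, MAT-v5 or HDF5.

    ``format`` defaults to the file suffix.  For CSV the sampling rate must
    be supplied (the format has no metadata slot); HDF5 and MAT carry it.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    fmt = format or _infer_format(path)
    if fmt == "csv":
        return _read_ws_csv(path, sampling_rate)
    if fmt == "hdf5":
        return _read_ws_hdf5(path)
    if fmt == "mat":
        return _read_ws_mat(path, sampling_rate)
    raise ValueError(f"unknown format {fmt!r}")


def write_waveform_set(ws: WaveformSet, path, format: Optional[str] = None) -> Path:
    """Write ``ws`` so that :func:`read_waveform_set` round-trips exactly."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "csv":
        _write_ws_csv(ws, path)
    elif fmt == "hdf5":
        _write_ws_hdf5(ws, path)
    elif fmt == "mat":
        _write_ws_mat(ws, path)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return path


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    return {
        ".csv": "csv", ".txt": "csv",
        ".h5": "hdf5", ".hdf5": "hdf5",
        ".mat": "mat",
    }.get(suffix, "hdf5")


def _read_ws_csv(path: Path, sampling_rate: Optional[float]) -> WaveformSet:
    if sampling_rate is None:
        raise ConfigurationError(
            f"CSV carries no sampling rate; pass sampling_rate= for {path}"
        )
    with open(path, newline="") as fh:
        reader = _csv.reader(fh)
        header = next(reader)
        rows = list(reader)
    cols = {name: i for i, name in enumerate(header)}
    n_wave = sum(1 for c in header if c.startswith("s"))
    widths = {len(r) for r in rows}
    if len(widths) > 1:
        raise FormatError(f"ragged waveform rows in {path}")
    times = np.array([float(r[cols["time"]]) for r in rows])
    wave = np.array(
        [[float(v) for v in r[cols["s0"]:cols["s0"] + n_wave]] for r in rows]
    ) if rows else np.empty((0, n_wave))
    labels = None
    if "label" in cols:
        labels = np.array([int(r[cols["label"]]) for r in rows])
    overlap = None
    if "overlap" in cols:
        overlap = np.array([r[cols["overlap"]] == "1" for r in rows])
    return WaveformSet(wave, times, sampling_rate, labels, overlap)


def _write_ws_csv(ws: WaveformSet, path: Path) -> None:
    header = ["time"] + [f"s{i}" for i in range(ws.n_samples)]
    if ws.labels is not None:
        header.append("label")
    if ws.overlap_flags is not None:
        header.append("overlap")
    with open(path, "w", newline="") as fh:
        writer = _csv.writer(fh)
        writer.writerow(header)
        for i in range(ws.n_spikes):
            row = [repr(float(ws.spike_times[i]))]
            row += [repr(float(v)) for v in ws.waveforms[i]]
            if ws.labels is not None:
                row.append(int(ws.labels[i]))
            if ws.overlap_flags is not None:
                row.append(int(ws.overlap_flags[i]))
            writer.writerow(row)


def _read_ws_hdf5(path: Path) -> WaveformSet:
    try:
        with h5py.File(path, "r") as f:
            wave = f["waveforms"][...]
            times = f["spike_times"][...]
            fs = float(f.attrs["sampling_rate"])
            labels = f["labels"][...] if "labels" in f else None
            overlap = f["overlap"][...].astype(bool) if "overlap" in f else None
    except OSError as exc:
        raise IOError(f"cannot read HDF5 file {path}: {exc}") from exc
    if wave.ndim == 1:
        wave = wave.reshape(0, 0) if wave.size == 0 else wave.reshape(1, -1)
    return WaveformSet(wave, times, fs, labels, overlap)


def _write_ws_hdf5(ws: WaveformSet, path: Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("waveforms", data=ws.waveforms)
        f.create_dataset("spike_times", data=ws.spike_times)
        f.attrs["sampling_rate"] = ws.sampling_rate
        if ws.labels is not None:
            f.create_dataset("labels", data=ws.labels)
        if ws.overlap_flags is not None:
            f.create_dataset("overlap", data=ws.overlap_flags.astype(np.uint8))


def _mat_lookup(data: dict, key: str):
    for alias in _MAT_ALIASES[key]:
        if alias in data:
            return data[alias]
    return None


def _read_ws_mat(path: Path, sampling_rate: Optional[float]) -> WaveformSet:
    try:
        data = loadmat(path, squeeze_me=False)
    except Exception as exc:  # scipy raises several types here
        raise IOError(f"cannot read MAT file {path}: {exc}") from exc
    wave = _mat_lookup(data, "waveforms")
    if wave is None:
        raise FormatError(f"no waveform variable found in {path}")
    wave = np.atleast_2d(np.asarray(wave, dtype=float))
    times_raw = _mat_lookup(data, "spike_times")
    if times_raw is None:
        raise FormatError(f"no spike-time variable found in {path}")
    times = np.asarray(times_raw, dtype=float).ravel()
    fs = sampling_rate
    if "sampling_rate" in data:
        fs = float(np.asarray(data["sampling_rate"]).ravel()[0])
    if fs is None:
        fs = 24000.0  # the public simulated dataset's rate
    # the public dataset stores times in ms; stored seconds pass through
    if "index" in data and "spike_times" not in data:
        times = times / 1000.0
    order = np.argsort(times, kind="stable")
    labels = _mat_lookup(data, "labels")
    if labels is not None:
        labels = np.asarray(labels).ravel()[order].astype(int)
    overlap = _mat_lookup(data, "overlap")
    if overlap is not None:
        overlap = np.asarray(overlap).ravel()[order].astype(bool)
    return WaveformSet(wave[order], times[order], fs, labels, overlap)


def _write_ws_mat(ws: WaveformSet, path: Path) -> None:
    out = {
        "waveforms": ws.waveforms,
        "spike_times": ws.spike_times,
        "sampling_rate": ws.sampling_rate,
    }
    if ws.labels is not None:
        out["labels"] = ws.labels
    if ws.overlap_flags is not None:
        out["overlap"] = ws.overlap_flags.astype(np.uint8)
    savemat(path, out)


# ---------------------------------------------------------------------------
# recording readers/writers
# ---------------------------------------------------------------------------

def read_recording(path, format: Optional[str] = None,
                   sampling_rate: Optional[float] = None) -> Recording:
    """Read a :class:`Recording` (HDF5 ``/samples`` layout, CSV, or MAT)."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    fmt = format or _infer_format(path)
    if fmt == "hdf5":
        with h5py.File(path, "r") as f:
            samples = f["samples"][...]
            fs = float(f.attrs.get("sampling_rate", 0)) or sampling_rate
            pos = f["channel_positions"][...] if "channel_positions" in f else None
    elif fmt == "csv":
        samples = np.loadtxt(path, delimiter=",", ndmin=2)
        fs, pos = sampling_rate, None
    elif fmt == "mat":
        data = loadmat(path)
        samples = np.atleast_2d(np.asarray(data["samples"], dtype=float))
        fs = sampling_rate
        if "sampling_rate" in data:
            fs = float(np.asarray(data["sampling_rate"]).ravel()[0])
        pos = data.get("channel_positions")
    else:
        raise ValueError(f"unknown format {fmt!r}")
    if fs is None or not fs > 0:
        raise ConfigurationError(
            f"{path} carries no sampling rate; pass sampling_rate="
        )
    return Recording(samples, fs, channel_positions=pos)


def write_recording(rec: Recording, path, format: Optional[str] = None) -> Path:
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "hdf5":
        with h5py.File(path, "w") as f:
            f.create_dataset("samples", data=rec.samples)
            f.attrs["sampling_rate"] = rec.sampling_rate
            if rec.channel_positions is not None:
                f.create_dataset("channel_positions", data=rec.channel_positions)
    elif fmt == "csv":
        np.savetxt(path, rec.samples, delimiter=",")
    elif fmt == "mat":
        out = {"samples": rec.samples, "sampling_rate": rec.sampling_rate}
        if rec.channel_positions is not None:
            out["channel_positions"] = rec.channel_positions
        savemat(path, out)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return path
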