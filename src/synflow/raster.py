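"""Spike-train containers, synaptic-timescale binning, and spike-file I/O.

The raw input to every analysis in this package is a set of per-neuron spike
trains: ascending spike times in milliseconds plus a recording duration.
Information-theoretic estimators operate on *binned* rasters: binary
neuron x time-bin matrices at bin widths matched to synaptic transmission
delays (roughly 1-14 ms).  A bin is 1 if it contains at least one spike; in
the sparse-firing regime the vast majority of bins are 0, which is the regime
the binary-alphabet estimators downstream assume.

Two on-disk formats are supported: a whitespace-separated two-column text
format (``neuron_id time_ms``, one spike per line, ``# key=value`` headers)
and an HDF5 layout (``/spikes/<id>`` arrays plus a ``duration_ms`` attribute).
Both round-trip exactly.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, Union

import h5py
import numpy as np

__all__ = [
    "SpikeTrain",
    "TimescaleSpec",
    "BinnedRaster",
    "TS1",
    "TS2",
    "TS3",
    "CANONICAL_TIMESCALES",
    "bin_spikes",
    "bin_trains",
    "read_spike_file",
    "write_spike_file",
    "SpikeFileFormatError",
]


class SpikeFileFormatError(ValueError):
    """Raised when a spike file cannot be parsed; names the offending line."""


@dataclass(frozen=True)
class SpikeTrain:
    """Spike times of one neuron.

    Parameters
    ----------
    neuron_id : int
        Integer label of the neuron.
    spike_times : ndarray of float
        Strictly ascending spike times in milliseconds, all in
        ``[0, duration_ms)``.
    duration_ms : float
        Recording duration in milliseconds; must be positive.
    """

    neuron_id: int
    spike_times: np.ndarray
    duration_ms: float

    def __post_init__(self) -> None:
        times = np.asarray(self.spike_times, dtype=np.float64)
        object.__setattr__(self, "spike_times", times)
        if not np.isfinite(self.duration_ms) or self.duration_ms <= 0:
            raise ValueError(f"duration_ms must be positive, got {self.duration_ms}")
        if times.ndim != 1:
            raise ValueError("spike_times must be one-dimensional")
        if times.size:
            if times[0] < 0:
                raise ValueError("negative spike time")
            if times[-1] >= self.duration_ms:
                raise ValueError("spike time at or beyond duration")
            if np.any(np.diff(times) <= 0):
                raise ValueError("spike_times must be strictly increasing")

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times.size)

    @property
    def rate_hz(self) -> float:
        return self.n_spikes / (self.duration_ms / 1000.0)


@dataclass(frozen=True)
class TimescaleSpec:
    """One (bin width, delay) pair at which information flow is estimated.

    ``bin_width_ms`` sets the raster granularity and ``delay_bins`` the number
    of bins separating the source past state from the target present state.
    ``span_ms`` records the approximate window of synaptic delays (ms) the
    pair covers; it is descriptive metadata, not used in computation.
    """

    label: str
    bin_width_ms: float
    delay_bins: int
    span_ms: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.bin_width_ms <= 0:
            raise ValueError("bin_width_ms must be positive")
        if self.delay_bins < 1:
            raise ValueError("delay_bins must be >= 1")
        if self.span_ms is None:
            lo = (self.delay_bins - 1) * self.bin_width_ms
            hi = (self.delay_bins + 1) * self.bin_width_ms
            object.__setattr__(self, "span_ms", (lo, hi))


#: Canonical synaptic timescales: 1 ms, 1.6 ms and 3.5 ms bins with delays
#: chosen so the (bin, delay) windows approximate 0.05-3, 1.6-6.4 and
#: 3.5-14 ms.  Override freely; nothing downstream hard-codes these.
TS1 = TimescaleSpec("TS1", 1.0, 1, (0.05, 3.0))
TS2 = TimescaleSpec("TS2", 1.6, 2, (1.6, 6.4))
TS3 = TimescaleSpec("TS3", 3.5, 2, (3.5, 14.0))
CANONICAL_TIMESCALES: tuple[TimescaleSpec, ...] = (TS1, TS2, TS3)


@dataclass(frozen=True)
class BinnedRaster:
    """Binary neurons x time-bins matrix at a single bin width."""

    matrix: np.ndarray
    bin_width_ms: float
    neuron_ids: tuple[int, ...]

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=np.uint8)
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "neuron_ids", tuple(self.neuron_ids))
        if m.ndim != 2 or m.shape[0] != len(self.neuron_ids):
            raise ValueError("matrix rows must match neuron_ids")
        if m.size and m.max() > 1:
            raise ValueError("raster entries must be binary")

    @property
    def n_bins(self) -> int:
        return int(self.matrix.shape[1])

    def row(self, neuron_id: int) -> np.ndarray:
        return self.matrix[self.neuron_ids.index(neuron_id)]


def _bin_width(spec: Union[TimescaleSpec, float]) -> float:
    return spec.bin_width_ms if isinstance(spec, TimescaleSpec) else float(spec)


def n_bins_for(duration_ms: float, spec: Union[TimescaleSpec, float]) -> int:
    """Number of complete bins in a recording; the trailing partial bin is dropped."""
    w = _bin_width(spec)
    # guard against float round-off on exact multiples (e.g. 3.0 / 1.0)
    return int(math.floor(duration_ms / w + 1e-9))


def bin_spikes(train: SpikeTrain, spec: Union[TimescaleSpec, float]) -> np.ndarray:
    """Binarize one spike train at the spec's bin width.

    Bin ``b`` covers ``[b*w, (b+1)*w)`` and is 1 iff at least one spike falls
    in it.  Multi-spike bins are clipped to 1; the trailing partial bin is
    discarded.

    Returns
    -------
    ndarray of uint8, length ``floor(duration_ms / bin_width)``.
    """
    w = _bin_width(spec)
    if w > train.duration_ms:
        raise ValueError(
            f"bin width {w} ms exceeds recording duration {train.duration_ms} ms"
        )
    n = n_bins_for(train.duration_ms, w)
    out = np.zeros(n, dtype=np.uint8)
    if train.n_spikes:
        idx = np.floor(train.spike_times / w).astype(np.intp)
        idx = idx[idx < n]
        out[idx] = 1
    return out


def spike_bins(train: SpikeTrain, spec: Union[TimescaleSpec, float]) -> np.ndarray:
    """Sorted unique bin indices occupied by spikes (sparse form of bin_spikes)."""
    w = _bin_width(spec)
    n = n_bins_for(train.duration_ms, w)
    idx = np.floor(train.spike_times / w).astype(np.int64)
    idx = np.unique(idx[idx < n])
    return idx


def bin_trains(
    trains: Sequence[SpikeTrain], spec: Union[TimescaleSpec, float]
) -> BinnedRaster:
    """Bin a set of trains (common duration required) into one raster."""
    if not trains:
        raise ValueError("no spike trains given")
    durations = {t.duration_ms for t in trains}
    if len(durations) > 1:
        raise ValueError(f"trains have differing durations: {sorted(durations)}")
    rows = [bin_spikes(t, spec) for t in trains]
    return BinnedRaster(
        np.vstack(rows), _bin_width(spec), tuple(t.neuron_id for t in trains)
    )


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

_TEXT_HEADER = "# synflow spikes"


def write_spike_text(trains: Sequence[SpikeTrain], path: Union[str, Path]) -> None:
    path = Path(path)
    duration = max(t.duration_ms for t in trains)
    with path.open("w") as fh:
        fh.write(f"{_TEXT_HEADER} v1\n")
        fh.write(f"# duration_ms={float(duration)!r}\n")
        for train in trains:
            for t in train.spike_times:
                fh.write(f"{train.neuron_id} {float(t)!r}\n")
            if train.n_spikes == 0:
                # keep empty trains alive across a round trip
                fh.write(f"# empty={train.neuron_id}\n")


def read_spike_text(
    path: Union[str, Path], duration_ms: float | None = None
) -> list[SpikeTrain]:
    path = Path(path)
    spikes: dict[int, list[float]] = {}
    empties: list[int] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body.startswith("duration_ms=") and duration_ms is None:
                    duration_ms = float(body.split("=", 1)[1])
                elif body.startswith("empty="):
                    empties.append(int(body.split("=", 1)[1]))
                continue
            parts = line.split()
            if len(parts) != 2:
                raise SpikeFileFormatError(
                    f"{path}:{lineno}: expected 'neuron_id time_ms', got {line!r}"
                )
            try:
                nid = int(parts[0])
                t = float(parts[1])
            except ValueError as exc:
                raise SpikeFileFormatError(f"{path}:{lineno}: {exc}") from None
            spikes.setdefault(nid, []).append(t)
    if duration_ms is None:
        if not spikes:
            raise SpikeFileFormatError(f"{path}: empty file and no duration header")
        duration_ms = max(max(v) for v in spikes.values()) + 1.0
        warnings.warn(
            f"{path}: no duration_ms header; using max spike time + 1 ms",
            stacklevel=2,
        )
    trains = []
    for nid in sorted(set(spikes) | set(empties)):
        times = np.asarray(spikes.get(nid, []), dtype=np.float64)
        if times.size and np.any(np.diff(times) < 0):
            warnings.warn(
                f"{path}: spike times for neuron {nid} not sorted; repairing",
                stacklevel=2,
            )
            times = np.sort(times)
        trains.append(SpikeTrain(nid, times, duration_ms))
    return trains


def write_spike_hdf5(trains: Sequence[SpikeTrain], path: Union[str, Path]) -> None:
    duration = max(t.duration_ms for t in trains)
    with h5py.File(path, "w") as fh:
        grp = fh.create_group("spikes")
        for train in trains:
            grp.create_dataset(str(train.neuron_id), data=train.spike_times)
        meta = fh.create_group("meta")
        meta.attrs["duration_ms"] = duration


def read_spike_hdf5(path: Union[str, Path]) -> list[SpikeTrain]:
    with h5py.File(path, "r") as fh:
        duration = float(fh["meta"].attrs["duration_ms"])
        trains = [
            SpikeTrain(int(nid), np.asarray(ds[()], dtype=np.float64), duration)
            for nid, ds in fh["spikes"].items()
        ]
    trains.sort(key=lambda t: t.neuron_id)
    return trains


def _infer_format(path: Path, fmt: str) -> str:
    if fmt != "auto":
        return fmt
    return "hdf5" if path.suffix.lower() in {".h5", ".hdf5"} else "text"


def read_spike_file(
    path: Union[str, Path], fmt: str = "auto", duration_ms: float | None = None
) -> list[SpikeTrain]:
    """Read spike trains from a text or HDF5 spike file."""
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "text":
        return read_spike_text(path, duration_ms=duration_ms)
    if fmt == "hdf5":
        return read_spike_hdf5(path)
    raise ValueError(f"unknown spike file format {fmt!r}")


def write_spike_file(
    trains: Sequence[SpikeTrain], path: Union[str, Path], fmt: str = "auto"
) -> None:
    """Write spike trains; format inferred from the suffix unless given."""
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "text":
        write_spike_text(trains, path)
    elif fmt == "hdf5":
        write_spike_hdf5(trains, path)
    else:
        raise ValueError(f"unknown spike file format {fmt!r}")
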