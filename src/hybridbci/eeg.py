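"""Core EEG containers and the on-disk recording bundle.

A :class:`Recording` is a continuous multichannel EEG signal (microvolts)
with a sampling rate, an ordered channel montage and a marker table; an
:class:`EpochSet` is the trials x channels x samples array cut around cue
markers.  The on-disk "recording bundle" is a directory with

* ``header.json`` -- fs, channel labels, dtype, sample count
* ``signal.bin``  -- float32 little-endian, samples-major
* ``markers.csv`` -- columns ``sample,label``

Sample indices are 0-based throughout; epoch windows are half-open
``[t0, t1)`` in milliseconds relative to the marker.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "MARKER_VOCABULARY",
    "CLASS_LABELS",
    "Marker",
    "BandDefinition",
    "Recording",
    "EpochSet",
    "read_recording",
    "write_recording",
    "read_csv_recording",
    "epoch",
]

#: Cue vocabulary: class cues, the FreeMode question-mark cue, trial end.
MARKER_VOCABULARY = ("class1", "class2", "question", "trial_end")

#: Mapping from cue label to the integer class used everywhere downstream.
#: 0 encodes "unknown" (FreeMode question-mark trials).
CLASS_LABELS = {"class1": 1, "class2": 2, "question": 0}


class FormatError(ValueError):
    """Raised when a recording bundle on disk is malformed."""


@dataclass
class Marker:
    """A cue event: 0-based sample index plus a label from the vocabulary."""

    sample: int
    label: str

    def __post_init__(self) -> None:
        if self.sample < 0:
            raise ValueError(f"marker sample must be >= 0, got {self.sample}")
        if self.label not in MARKER_VOCABULARY:
            raise ValueError(
                f"marker label {self.label!r} not in vocabulary {MARKER_VOCABULARY}"
            )


@dataclass(frozen=True)
class BandDefinition:
    """A frequency band [lo, hi] in Hz with an optional name."""

    lo: float
    hi: float
    name: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.lo < self.hi):
            raise ValueError(f"need 0 <= lo < hi, got ({self.lo}, {self.hi})")

    def validate_for_fs(self, fs: float) -> None:
        if self.hi >= fs / 2:
            raise ValueError(
                f"band edge {self.hi} Hz is at or above Nyquist of fs={fs} Hz"
            )


@dataclass
class Recording:
    """Continuous EEG: ``signal`` is channels x samples in microvolts."""

    signal: np.ndarray
    fs: float
    channel_labels: list[str]
    markers: list[Marker] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=np.float64)
        if self.signal.ndim != 2:
            raise ValueError("signal must be 2-D (channels x samples)")
        if len(self.channel_labels) != self.signal.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} channel labels for "
                f"{self.signal.shape[0]} signal rows"
            )
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        for m in self.markers:
            if not (0 <= m.sample < self.n_samples):
                raise ValueError(
                    f"marker at sample {m.sample} outside [0, {self.n_samples})"
                )

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration(self) -> float:
        """Length in seconds."""
        return self.n_samples / self.fs


@dataclass
class EpochSet:
    """Epoched EEG: ``data`` is trials x channels x samples in microvolts.

    ``times`` holds per-sample latencies in ms relative to the cue;
    ``labels`` holds the per-trial class (1, 2, or 0 for unknown).
    ``excluded`` lists indices of selected markers that were dropped
    because their window exceeded the recording bounds.
    """

    data: np.ndarray
    times: np.ndarray
    labels: np.ndarray
    fs: float
    channel_labels: list[str]
    excluded: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.times = np.asarray(self.times, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.data.ndim != 3:
            raise ValueError("data must be 3-D (trials x channels x samples)")
        if self.data.shape[2] != self.times.size:
            raise ValueError("times length must match the sample dimension")
        if self.data.shape[0] != self.labels.size:
            raise ValueError("labels length must match the trial dimension")
        if self.times.size > 1:
            dt = np.diff(self.times)
            if np.any(dt <= 0) or not np.allclose(dt, 1000.0 / self.fs):
                raise ValueError("times must increase uniformly at 1000/fs ms")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("epoch data contains non-finite values")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    def time_mask(self, interval: tuple[float, float]) -> np.ndarray:
        """Boolean sample mask for the half-open interval [t0, t1) in ms."""
        t0, t1 = interval
        mask = (self.times >= t0) & (self.times < t1)
        if not mask.any():
            raise ValueError(
                f"interval {interval} ms selects no samples from "
                f"[{self.times[0]}, {self.times[-1]}] ms"
            )
        return mask

    def copy_with(self, data: np.ndarray) -> "EpochSet":
        return EpochSet(
            data=data,
            times=self.times.copy(),
            labels=self.labels.copy(),
            fs=self.fs,
            channel_labels=list(self.channel_labels),
            excluded=list(self.excluded),
        )


# ---------------------------------------------------------------------------
# Recording bundle IO
# ---------------------------------------------------------------------------

def write_recording(rec: Recording, path: str | Path) -> None:
    """Write *rec* as a recording bundle directory (lossless for float32)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    header = {
        "fs": rec.fs,
        "channel_labels": list(rec.channel_labels),
        "dtype": "float32",
        "n_channels": rec.n_channels,
        "n_samples": rec.n_samples,
        "units": "microvolts",
    }
    (path / "header.json").write_text(json.dumps(header, indent=1))
    # samples-major: sample index varies slowest on disk
    payload = np.ascontiguousarray(rec.signal.T, dtype="<f4")
    payload.tofile(path / "signal.bin")
    df = pd.DataFrame(
        {"sample": [m.sample for m in rec.markers],
         "label": [m.label for m in rec.markers]}
    )
    df.to_csv(path / "markers.csv", index=False)


_REQUIRED_HEADER = ("fs", "channel_labels", "dtype", "n_channels", "n_samples")


def read_recording(path: str | Path) -> Recording:
    """Read a recording bundle written by :func:`write_recording`."""
    path = Path(path)
    header_path = path / "header.json"
    if not header_path.exists():
        raise FormatError(f"missing header.json in {path}")
    try:
        header = json.loads(header_path.read_text())
    except json.JSONDecodeError as e:
        raise FormatError(f"corrupt header.json: {e}") from e
    for key in _REQUIRED_HEADER:
        if key not in header:
            raise FormatError(f"header.json missing field {key!r}")
    if header["dtype"] != "float32":
        raise FormatError(f"unsupported dtype {header['dtype']!r}")
    n_ch, n_s = int(header["n_channels"]), int(header["n_samples"])
    raw = np.fromfile(path / "signal.bin", dtype="<f4")
    if raw.size != n_ch * n_s:
        raise FormatError(
            f"signal.bin holds {raw.size} values, header declares "
            f"{n_ch} channels x {n_s} samples = {n_ch * n_s}"
        )
    signal = raw.reshape(n_s, n_ch).T
    markers_df = pd.read_csv(path / "markers.csv")
    markers = [Marker(int(r.sample), str(r.label)) for r in markers_df.itertuples()]
    return Recording(
        signal=signal,
        fs=float(header["fs"]),
        channel_labels=[str(c) for c in header["channel_labels"]],
        markers=markers,
    )


def read_csv_recording(
    path: str | Path, fs: float, markers: list[Marker] | None = None
) -> Recording:
    """Read a tiny CSV fixture: first row channel labels, one row per sample."""
    df = pd.read_csv(path)
    return Recording(
        signal=df.to_numpy(dtype=np.float64).T,
        fs=fs,
        channel_labels=[str(c) for c in df.columns],
        markers=markers or [],
    )


# ---------------------------------------------------------------------------
# Epoching
# ---------------------------------------------------------------------------

def epoch(
    rec: Recording,
    cue_labels: tuple[str, ...] | list[str],
    window: tuple[float, float],
) -> EpochSet:
    """Cut one epoch per marker whose label is in *cue_labels*.

    *window* is ``[t0, t1)`` in ms relative to the marker sample; the onset
    sample is included when ``t0 = 0``.  Markers whose window exceeds the
    recording bounds are excluded (never zero-padded), warned about, and
    listed in ``EpochSet.excluded``.
    """
    t0, t1 = window
    if t1 <= t0:
        raise ValueError(f"need t0 < t1, got {window}")
    offset = int(round(t0 * rec.fs / 1000.0))
    n_samp = int(round((t1 - t0) * rec.fs / 1000.0))
    times = t0 + np.arange(n_samp) * 1000.0 / rec.fs

    selected = [m for m in rec.markers if m.label in cue_labels]
    data, labels, excluded = [], [], []
    for i, m in enumerate(selected):
        start = m.sample + offset
        stop = start + n_samp
        if start < 0 or stop > rec.n_samples:
            excluded.append(i)
            continue
        data.append(rec.signal[:, start:stop])
        labels.append(CLASS_LABELS.get(m.label, 0))
    if excluded:
        warnings.warn(
            f"excluded {len(excluded)} marker(s) whose window exceeds the "
            f"recording bounds: indices {excluded}",
            stacklevel=2,
        )
    if not data:
        raise ValueError("no marker yields a complete epoch for this window")
    return EpochSet(
        data=np.stack(data),
        times=times,
        labels=np.asarray(labels),
        fs=rec.fs,
        channel_labels=list(rec.channel_labels),
        excluded=excluded,
    )
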