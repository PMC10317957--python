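"""EEG recording containers, file I/O and sliding-window segmentation.

Recordings are channels x samples matrices with a sampling rate, channel
labels and seizure-interval annotations (half-open ``[start_s, end_s)``
intervals in seconds). Two on-disk forms are supported:

* EDF (European Data Format), the standard 16-bit container for polygraphic
  EEG (see :mod:`mmbn.edf`);
* a plain whitespace-delimited channels x samples text matrix with a sidecar
  header carrying labels, sampling rate, state and annotations.

Windows are cut with a sliding window (default 1 s length, 0.5 s step,
matching common seizure-detection practice). Boundary windows that only
partially overlap a seizure interval are ambiguous; by default a window is
labelled seizure iff at least half of it lies inside an annotated interval,
and windows with a smaller but nonzero overlap are discarded so that no
mixed-state window enters training.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "EEGRecording",
    "WindowSample",
    "read_recording",
    "write_text_recording",
    "read_text_recording",
    "read_annotations",
    "segment_windows",
]


@dataclass
class EEGRecording:
    """Multichannel EEG signal with annotations.

    Attributes
    ----------
    signal : (n_channels, n_samples) float array, file units (typically uV)
    fs : sampling rate in Hz, shared by all channels
    channel_labels : one label per row of ``signal``
    seizure_intervals : half-open ``(start_s, end_s)`` intervals
    """

    signal: np.ndarray
    fs: float
    channel_labels: list = field(default_factory=list)
    seizure_intervals: list = field(default_factory=list)

    def __post_init__(self):
        self.signal = np.atleast_2d(np.asarray(self.signal, dtype=float))
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("signal contains NaN or Inf")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not self.channel_labels:
            self.channel_labels = [f"ch{i}" for i in range(self.signal.shape[0])]
        if len(self.channel_labels) != self.signal.shape[0]:
            raise ValueError("channel_labels length does not match signal rows")
        dur = self.duration
        for s, e in self.seizure_intervals:
            if not (0 <= s < e <= dur + 1e-9):
                raise ValueError(f"interval ({s}, {e}) outside [0, {dur}]")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def duration(self) -> float:
        return self.signal.shape[1] / self.fs

    def select_channels(self, labels) -> "EEGRecording":
        """Restrict to ``labels``, preserving the requested order."""
        pos = []
        for lab in labels:
            try:
                pos.append(self.channel_labels.index(lab))
            except ValueError:
                raise KeyError(f"channel {lab!r} not present in recording") from None
        return EEGRecording(
            signal=self.signal[pos],
            fs=self.fs,
            channel_labels=list(labels),
            seizure_intervals=list(self.seizure_intervals),
        )


@dataclass
class WindowSample:
    """One fixed-length segment with a binary state label (1 = seizure)."""

    data: np.ndarray
    label: int
    start_time: float

    def __post_init__(self):
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


def write_text_recording(rec: EEGRecording, path, state: str | None = None) -> None:
    """Write a recording as a text matrix plus a ``.json`` sidecar header."""
    path = Path(path)
    np.savetxt(path, rec.signal)
    header = {
        "fs": rec.fs,
        "channel_labels": rec.channel_labels,
        "seizure_intervals": [list(map(float, iv)) for iv in rec.seizure_intervals],
    }
    if state is not None:
        header["state"] = state
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(header, indent=1))


def read_text_recording(path, fs: float | None = None) -> EEGRecording:
    """Read a whitespace-delimited channels x samples matrix.

    A sidecar ``<path>.json`` header supplies fs, labels and annotations if
    present; otherwise ``fs`` must be given.
    """
    path = Path(path)
    signal = np.atleast_2d(np.loadtxt(path))
    sidecar = path.with_suffix(path.suffix + ".json")
    labels, intervals = [], []
    if sidecar.exists():
        header = json.loads(sidecar.read_text())
        fs = header.get("fs", fs)
        labels = header.get("channel_labels", [])
        intervals = [tuple(iv) for iv in header.get("seizure_intervals", [])]
    if fs is None:
        raise ValueError(f"no sampling rate: provide fs or a sidecar {sidecar.name}")
    return EEGRecording(signal=signal, fs=float(fs), channel_labels=labels, seizure_intervals=intervals)


def read_annotations(path) -> list:
    """Read seizure intervals from a two-column (start_s, end_s) text file."""
    arr = np.atleast_2d(np.loadtxt(path))
    if arr.size == 0:
        return []
    if arr.shape[1] != 2:
        raise ValueError("annotation file must have two columns: start_s end_s")
    return [(float(s), float(e)) for s, e in arr]


def read_recording(path, channels=None, fs: float | None = None) -> EEGRecording:
    """Read an EDF or text-matrix recording, optionally restricted to channels.

    The format is chosen by extension (``.edf`` vs anything else).
    """
    path = Path(path)
    if path.suffix.lower() == ".edf":
        from .edf import read_edf

        rec = read_edf(path)
    else:
        rec = read_text_recording(path, fs=fs)
    if channels is not None:
        rec = rec.select_channels(channels)
    return rec


def _overlap(a0: float, a1: float, b0: float, b1: float) -> float:
    return max(0.0, min(a1, b1) - max(a0, b0))


def segment_windows(
    rec: EEGRecording,
    win_s: float = 1.0,
    step_s: float = 0.5,
    min_overlap: float = 0.5,
) -> list:
    """Cut labelled sliding windows from a recording.

    Windows start at 0, step_s, 2*step_s, ... and are emitted only if fully
    inside the recording, so a duration-T recording yields
    ``floor((T - win_s)/step_s) + 1`` windows.

    Labelling: seizure (1) iff the window's overlap with any annotated
    interval is at least ``min_overlap`` of the window length; windows with a
    smaller but positive overlap are dropped as mixed-state.
    """
    if win_s <= 0 or step_s <= 0:
        raise ValueError("win_s and step_s must be positive")
    if not 0 < min_overlap <= 1:
        raise ValueError("min_overlap must be in (0, 1]")
    T = rec.duration
    if T + 1e-9 < win_s:
        raise ValueError(f"recording ({T} s) shorter than window ({win_s} s)")
    L = int(round(rec.fs * win_s))
    step = rec.fs * step_s
    windows = []
    i = 0
    while True:
        start_idx = int(round(i * step))
        if start_idx + L > rec.signal.shape[1]:
            break
        t0 = start_idx / rec.fs
        t1 = t0 + win_s
        ov = sum(_overlap(t0, t1, s, e) for s, e in rec.seizure_intervals)
        if ov >= min_overlap * win_s - 1e-12:
            label = 1
        elif ov > 1e-12:
            i += 1
            continue  # mixed-state boundary window
        else:
            label = 0
        windows.append(WindowSample(data=rec.signal[:, start_idx : start_idx + L], label=label, start_time=t0))
        i += 1
    return windows
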