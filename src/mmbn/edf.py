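"""Minimal EDF (European Data Format) reader and writer.

Implements the plain 16-bit EDF specification (Kemp et al. 1992): a 256-byte
fixed ASCII header, 256 bytes of ASCII metadata per signal, then data records
of little-endian 16-bit integers mapped linearly between each signal's
digital and physical ranges. This is sufficient to round-trip multichannel
EEG matrices; EDF+ annotation streams are not implemented — seizure
intervals travel in the same JSON sidecar used for text matrices.

Quantization: a signal spanning physical range ``[pmin, pmax]`` stored over
digital range ``[-32768, 32767]`` is reproduced to within one quantization
step ``(pmax - pmin) / 65535``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .io import EEGRecording

__all__ = ["read_edf", "write_edf"]

_DIG_MIN, _DIG_MAX = -32768, 32767


def _field(text: str, width: int) -> bytes:
    b = text.encode("ascii")
    if len(b) > width:
        raise ValueError(f"EDF field too long: {text!r} (max {width})")
    return b.ljust(width)


def _num(value, width: int) -> bytes:
    s = f"{value:.10g}"[:width]
    return _field(s, width)


def write_edf(rec: EEGRecording, path) -> None:
    """Write a recording as plain EDF with 1-second data records.

    Requires an integer sampling rate and an integer number of seconds of
    data. Each channel gets a symmetric physical range covering its data.
    """
    path = Path(path)
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    nch, nsamp = rec.signal.shape
    if nsamp % fs:
        raise ValueError("EDF writer requires a whole number of seconds")
    n_records = nsamp // fs

    # Per-channel symmetric physical range; degenerate (constant-zero)
    # channels get a unit range so the scale factor is well defined.
    amax = np.abs(rec.signal).max(axis=1)
    amax = np.where(amax > 0, amax, 1.0)
    pmin, pmax = -amax, amax

    header = b"".join(
        [
            _field("0", 8),
            _field("X X X X", 80),
            _field("Startdate X X X X", 80),
            _field("01.01.00", 8),
            _field("00.00.00", 8),
            _num(256 * (1 + nch), 8),
            _field("", 44),
            _num(n_records, 8),
            _num(1, 8),
            _num(nch, 4),
        ]
    )
    per_sig = b"".join(
        [
            b"".join(_field(lab[:16], 16) for lab in rec.channel_labels),
            b"".join(_field("", 80) for _ in range(nch)),
            b"".join(_field("uV", 8) for _ in range(nch)),
            b"".join(_num(pmin[c], 8) for c in range(nch)),
            b"".join(_num(pmax[c], 8) for c in range(nch)),
            b"".join(_num(_DIG_MIN, 8) for _ in range(nch)),
            b"".join(_num(_DIG_MAX, 8) for _ in range(nch)),
            b"".join(_field("", 80) for _ in range(nch)),
            b"".join(_num(fs, 8) for _ in range(nch)),
            b"".join(_field("", 32) for _ in range(nch)),
        ]
    )

    # physical -> digital, rounding to nearest level
    scale = (_DIG_MAX - _DIG_MIN) / (pmax - pmin)
    digital = np.rint((rec.signal - pmin[:, None]) * scale[:, None] + _DIG_MIN)
    digital = np.clip(digital, _DIG_MIN, _DIG_MAX).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(per_sig)
        for r in range(n_records):
            fh.write(digital[:, r * fs : (r + 1) * fs].tobytes())

    if rec.seizure_intervals:
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(
            json.dumps({"seizure_intervals": [list(map(float, iv)) for iv in rec.seizure_intervals]})
        )


def read_edf(path) -> EEGRecording:
    """Read a plain EDF file into an :class:`EEGRecording`.

    All signals must share one sampling rate (samples-per-record divided by
    the record duration); EDF permits mixed rates but mixed-rate files are
    rejected here.
    """
    path = Path(path)
    raw = path.read_bytes()
    if len(raw) < 256:
        raise ValueError(f"{path}: not an EDF file (truncated header)")

    def ascii_at(off, width):
        return raw[off : off + width].decode("ascii", errors="replace").strip()

    n_records = int(ascii_at(236, 8))
    record_dur = float(ascii_at(244, 8))
    nch = int(ascii_at(252, 4))
    off = 256

    def sig_fields(width, conv=str):
        nonlocal off
        vals = [conv(ascii_at(off + i * width, width)) for i in range(nch)]
        off += nch * width
        return vals

    labels = sig_fields(16)
    sig_fields(80)  # transducer
    sig_fields(8)  # physical dimension
    pmin = np.array(sig_fields(8, float))
    pmax = np.array(sig_fields(8, float))
    dmin = np.array(sig_fields(8, float))
    dmax = np.array(sig_fields(8, float))
    sig_fields(80)  # prefiltering
    spr = np.array(sig_fields(8, int))  # samples per record
    sig_fields(32)  # reserved

    rates = spr / record_dur
    if len(set(rates.tolist())) != 1:
        raise ValueError(f"{path}: per-channel sampling rates differ: {sorted(set(rates.tolist()))}")
    fs = float(rates[0])

    data = np.frombuffer(raw[off:], dtype="<i2")
    expected = n_records * int(spr.sum())
    if data.size < expected:
        raise ValueError(f"{path}: truncated data section")
    data = data[:expected].reshape(n_records, -1)

    signal = np.empty((nch, n_records * spr[0]), dtype=float)
    bounds = np.concatenate([[0], np.cumsum(spr)])
    scale = (pmax - pmin) / (dmax - dmin)
    for c in range(nch):
        dig = data[:, bounds[c] : bounds[c + 1]].reshape(-1).astype(float)
        signal[c] = (dig - dmin[c]) * scale[c] + pmin[c]

    intervals = []
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        intervals = [tuple(iv) for iv in json.loads(sidecar.read_text()).get("seizure_intervals", [])]
    return EEGRecording(signal=signal, fs=fs, channel_labels=labels, seizure_intervals=intervals)
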