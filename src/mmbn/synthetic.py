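"""Two-regime synthetic multichannel EEG with band-specific coupling.

The generator stands in for clinical scalp EEG so that every downstream
stage (band decomposition, connectivity networks, graph measures, the
classifier) is testable without external data. For each of the eight 8-Hz
bands ``b`` (spanning ``[8b, 8b+8)`` Hz) one shared band-limited Gaussian
driver is drawn; channel ``p``'s contribution in that band is

    coupling[b] * driver_b + (1 - coupling[b]) * independent band noise

so ``coupling[b]`` dials the inter-channel rank correlation inside band
``b``. Band contributions are summed and white Gaussian sensor noise is
added. Drivers are filtered noise, not sinusoids: pure tones produce tied
ranks and degenerate Spearman weights.

The two default regimes echo the low-frequency dominance of ictal EEG
without claiming physiological fidelity: the normal state couples weakly
(0.2) everywhere, the seizure state strongly (0.8) in the three bands below
24 Hz and moderately (0.4) above. No seizure morphology (spikes, spike-wave
complexes) or artifacts (EMG, eye blinks) are simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .io import EEGRecording, WindowSample, segment_windows

__all__ = ["SyntheticConfig", "generate_recording", "generate_dataset"]

N_BANDS = 8

_NORMAL_COUPLING = (0.2,) * 8
_SEIZURE_COUPLING = (0.8, 0.8, 0.8, 0.4, 0.4, 0.4, 0.4, 0.4)


@dataclass
class SyntheticConfig:
    """Parameters of the two-regime surrogate EEG generator.

    Attributes
    ----------
    n_channels : number of channels (default 23, a full scalp montage)
    fs : sampling rate in Hz (default 256)
    duration : seconds of signal per generated recording
    band_coupling_normal, band_coupling_seizure :
        eight coupling strengths in [0, 1], one per 8-Hz band
    noise_sd : white sensor-noise standard deviation, in units of the
        per-band driver standard deviation (default 0.5)
    seed : base seed; identical (seed, config, state) gives bit-identical
        output
    """

    n_channels: int = 23
    fs: float = 256.0
    duration: float = 10.0
    band_coupling_normal: tuple = _NORMAL_COUPLING
    band_coupling_seizure: tuple = _SEIZURE_COUPLING
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n_channels < 2:
            raise ValueError("need at least 2 channels")
        if not np.isfinite(self.fs) or self.fs <= 0:
            raise ValueError("fs must be positive and finite")
        if not np.isfinite(self.duration) or self.duration <= 0:
            raise ValueError("duration must be positive and finite")
        for name in ("band_coupling_normal", "band_coupling_seizure"):
            vec = np.asarray(getattr(self, name), dtype=float)
            if vec.shape != (N_BANDS,):
                raise ValueError(f"{name} must have {N_BANDS} entries")
            if not np.all(np.isfinite(vec)) or vec.min() < 0 or vec.max() > 1:
                raise ValueError(f"{name} entries must be finite and in [0, 1]")
            setattr(self, name, tuple(vec))
        if not np.isfinite(self.noise_sd) or self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative and finite")

    def coupling(self, state: str) -> np.ndarray:
        if state == "normal":
            return np.asarray(self.band_coupling_normal)
        if state == "seizure":
            return np.asarray(self.band_coupling_seizure)
        raise ValueError(f"state must be 'normal' or 'seizure', got {state!r}")


def _band_noise(rng: np.random.Generator, n: int, low: float, high: float, fs: float, n_series: int) -> np.ndarray:
    """Band-limited unit-variance Gaussian noise, shape (n_series, n)."""
    # generous padding swallows the filter transient
    pad = max(int(fs), 64)
    white = rng.standard_normal((n_series, n + 2 * pad))
    nyq = fs / 2.0
    lo = max(low, 0.25) / nyq
    hi = min(high, nyq * 0.995) / nyq
    sos = sps.butter(4, [lo, hi], btype="bandpass", output="sos")
    x = sps.sosfiltfilt(sos, white, axis=-1)[:, pad:-pad]
    sd = x.std(axis=-1, keepdims=True)
    return x / np.where(sd > 0, sd, 1.0)


def generate_recording(state: str, config: SyntheticConfig) -> EEGRecording:
    """Generate one recording in the given regime ('normal' or 'seizure').

    The annotation list marks the whole recording with its state: empty for
    normal, a single full-length interval for seizure.
    """
    coupling = config.coupling(state)
    n = int(round(config.fs * config.duration))
    # independent streams per state so the two regimes are not sample-coupled
    rng = np.random.default_rng([config.seed, {"normal": 0, "seizure": 1}[state]])
    bw = config.fs / (2 * N_BANDS) if config.fs < 128 else 8.0
    signal = np.zeros((config.n_channels, n))
    for b in range(N_BANDS):
        low, high = b * bw, (b + 1) * bw
        driver = _band_noise(rng, n, low, high, config.fs, 1)[0]
        indep = _band_noise(rng, n, low, high, config.fs, config.n_channels)
        signal += coupling[b] * driver[None, :] + (1.0 - coupling[b]) * indep
    signal += config.noise_sd * rng.standard_normal(signal.shape)
    intervals = [] if state == "normal" else [(0.0, config.duration)]
    labels = [f"SYN{i:02d}" for i in range(config.n_channels)]
    return EEGRecording(signal=signal, fs=config.fs, channel_labels=labels, seizure_intervals=intervals)


def generate_dataset(n_per_state: int, config: SyntheticConfig, win_s: float = 1.0) -> list:
    """Generate a balanced labelled window set, ``n_per_state`` per regime.

    Recordings are generated per state (fresh seeds per recording) and cut by
    the standard segmentation with step = win_s (non-overlapping), so window
    labels are exactly the generating regime. Returns a list of
    :class:`~mmbn.io.WindowSample`, normals first.
    """
    if n_per_state < 1:
        raise ValueError("n_per_state must be >= 1")
    out = []
    for state in ("normal", "seizure"):
        windows: list = []
        rec_i = 0
        while len(windows) < n_per_state:
            cfg = SyntheticConfig(
                n_channels=config.n_channels,
                fs=config.fs,
                duration=config.duration,
                band_coupling_normal=config.band_coupling_normal,
                band_coupling_seizure=config.band_coupling_seizure,
                noise_sd=config.noise_sd,
                seed=int(np.random.default_rng([config.seed, 977, rec_i]).integers(2**31)),
            )
            rec = generate_recording(state, cfg)
            windows.extend(segment_windows(rec, win_s=win_s, step_s=win_s))
            rec_i += 1
        out.extend(windows[:n_per_state])
    return out
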