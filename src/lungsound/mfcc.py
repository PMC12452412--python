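"""Mel-frequency cepstral coefficients for 3-second audio segments.

Pipeline: short frames -> FFT magnitude -> Mel-spaced triangular filterbank
-> log energies -> cosine transform -> per-coefficient mean over frames.
Defaults produce 14 coefficients per segment from 30 ms non-overlapping
Hamming-windowed frames.

The cosine-transform index starts at 1, excluding the DC term (overall
gain); with area-normalized filters this makes the coefficients invariant
to amplitude scaling of the waveform.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MFCCConfig",
    "frame_signal",
    "magnitude_spectrum",
    "mel_from_hz",
    "hz_from_mel",
    "mel_filterbank",
    "log_mel_energies",
    "dct_coefficients",
    "mfcc_mean_vector",
    "feature_names",
]


@dataclass(frozen=True)
class MFCCConfig:
    """MFCC extraction parameters.

    Frame length must be 20-40 ms. ``frame_hop`` equal to ``frame_length``
    gives non-overlapping frames (the default).
    """

    frame_length_ms: float = 30.0
    frame_hop_ms: float = 30.0
    n_filters: int = 20
    n_coeffs: int = 14
    fmin: float = 0.0
    fmax: float | None = None  # None -> sample_rate / 2
    window: str = "hamming"
    log_floor: float = 1e-12

    def __post_init__(self) -> None:
        if not (20.0 <= self.frame_length_ms <= 40.0):
            raise ValueError("frame_length_ms must be in [20, 40]")
        if self.frame_hop_ms <= 0:
            raise ValueError("frame_hop_ms must be positive")
        if self.n_coeffs > self.n_filters:
            raise ValueError("n_coeffs cannot exceed n_filters")
        if self.n_coeffs < 1 or self.n_filters < 1:
            raise ValueError("n_coeffs and n_filters must be positive")
        if self.log_floor <= 0:
            raise ValueError("log_floor must be positive")
        if self.window not in ("hamming", "hann", "rectangular"):
            raise ValueError(f"unknown window {self.window!r}")

    def resolve_fmax(self, sample_rate: float) -> float:
        fmax = sample_rate / 2 if self.fmax is None else self.fmax
        if not (self.fmin < fmax <= sample_rate / 2):
            raise ValueError("need fmin < fmax <= sample_rate/2")
        return fmax


def feature_names(n_coeffs: int = 14) -> list[str]:
    return [f"mfcc_{i:02d}" for i in range(1, n_coeffs + 1)]


def _window(name: str, length: int) -> np.ndarray:
    if name == "hamming":
        return np.hamming(length)
    if name == "hann":
        return np.hanning(length)
    return np.ones(length)


def frame_signal(
    samples: np.ndarray, sample_rate: float, config: MFCCConfig
) -> np.ndarray:
    """Slice a segment into windowed frames (rows of the returned 2-D array).

    Only complete frames are produced; the partial tail is dropped.
    """
    samples = np.asarray(samples, dtype=np.float64)
    frame_len = int(round(config.frame_length_ms * sample_rate / 1000.0))
    hop = int(round(config.frame_hop_ms * sample_rate / 1000.0))
    if frame_len > len(samples):
        raise ValueError(
            f"frame length {frame_len} exceeds segment length {len(samples)}"
        )
    n_frames = 1 + (len(samples) - frame_len) // hop
    idx = np.arange(frame_len)[None, :] + hop * np.arange(n_frames)[:, None]
    return samples[idx] * _window(config.window, frame_len)[None, :]


def magnitude_spectrum(frame: np.ndarray) -> np.ndarray:
    """Full DFT magnitudes |X[k]|, k = 0..N-1."""
    frame = np.asarray(frame, dtype=np.float64)
    if frame.size == 0:
        raise ValueError("frame is empty")
    return np.abs(np.fft.fft(frame))


def mel_from_hz(f):
    """Map frequency in Hz to the Mel scale: 2595 * log10(1 + f / 700)."""
    f = np.asarray(f, dtype=np.float64)
    if np.any(f < 0):
        raise ValueError("frequency must be non-negative")
    return 2595.0 * np.log10(1.0 + f / 700.0)


def hz_from_mel(m):
    m = np.asarray(m, dtype=np.float64)
    return 700.0 * (10.0 ** (m / 2595.0) - 1.0)


def mel_filterbank(
    n_filters: int,
    frame_len: int,
    sample_rate: float,
    fmin: float = 0.0,
    fmax: float | None = None,
) -> np.ndarray:
    """Area-normalized triangular filters on the one-sided FFT bin grid.

    Returns an ``(n_filters, frame_len // 2 + 1)`` weight matrix; each
    filter's weights sum to 1 so a flat power spectrum yields identical
    energies in every band.
    """
    if fmax is None:
        fmax = sample_rate / 2
    mel_edges = np.linspace(mel_from_hz(fmin), mel_from_hz(fmax), n_filters + 2)
    hz_edges = hz_from_mel(mel_edges)
    freqs = np.fft.rfftfreq(frame_len, d=1.0 / sample_rate)
    fb = np.zeros((n_filters, len(freqs)))
    for m in range(n_filters):
        left, center, right = hz_edges[m], hz_edges[m + 1], hz_edges[m + 2]
        up = (freqs - left) / max(center - left, 1e-12)
        down = (right - freqs) / max(right - center, 1e-12)
        fb[m] = np.maximum(0.0, np.minimum(up, down))
        total = fb[m].sum()
        if total > 0:
            fb[m] /= total
    return fb


def log_mel_energies(
    power_spectrum: np.ndarray, filterbank: np.ndarray, log_floor: float = 1e-12
) -> np.ndarray:
    """S_m = log(sum_k |X[k]|^2 H_m[k] + eps), finite for any input.

    ``power_spectrum`` may be a single spectrum or a (frames, bins) stack.
    """
    power_spectrum = np.atleast_2d(power_spectrum)
    if power_spectrum.shape[-1] != filterbank.shape[-1]:
        raise ValueError("spectrum length does not match filterbank bins")
    energies = power_spectrum @ filterbank.T
    return np.squeeze(np.log(energies + log_floor))


def dct_coefficients(log_energies: np.ndarray, n_coeffs: int) -> np.ndarray:
    """C(n) = sum_m S_m cos(pi n (m - 0.5) / M) for n = 1..n_coeffs."""
    log_energies = np.atleast_2d(log_energies)
    M = log_energies.shape[-1]
    if not (1 <= n_coeffs <= M):
        raise ValueError("need 1 <= n_coeffs <= number of filters")
    n = np.arange(1, n_coeffs + 1)[:, None]
    m = np.arange(1, M + 1)[None, :]
    basis = np.cos(np.pi * n * (m - 0.5) / M)  # (n_coeffs, M)
    return np.squeeze(log_energies @ basis.T)


def mfcc_mean_vector(
    samples: np.ndarray, sample_rate: float, config: MFCCConfig | None = None
) -> np.ndarray:
    """Per-segment MFCC vector: coefficient means over all frames."""
    if config is None:
        config = MFCCConfig()
    config.resolve_fmax(sample_rate)
    frames = frame_signal(samples, sample_rate, config)
    frame_len = frames.shape[1]
    power = np.abs(np.fft.rfft(frames, axis=1)) ** 2
    fb = mel_filterbank(
        config.n_filters, frame_len, sample_rate, config.fmin, config.fmax
    )
    S = log_mel_energies(power, fb, config.log_floor)  # (frames, M)
    C = dct_coefficients(S, config.n_coeffs)  # (frames, n_coeffs)
    return np.atleast_2d(C).mean(axis=0)
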