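"""Reading recordings, cutting them into fixed-length segments, and quality control.

Recordings are mono PCM WAV files. Each recording is split into
non-overlapping 3-second segments (trailing remainder discarded), and
segments failing simple spectral quality checks (clipping, out-of-band
energy) are excluded before feature extraction.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy import signal
from scipy.io import wavfile

__all__ = [
    "Recording",
    "Segment",
    "read_wav",
    "write_wav",
    "resample_recording",
    "segment_recording",
    "quality_filter",
]

#: default analysis band (Hz) used by the in-band energy QC check
DEFAULT_NOISE_BAND = (60.0, 1200.0)

DEFAULT_SEGMENT_LENGTH = 3.0


@dataclass
class Recording:
    """A single-site recording with its cohort metadata."""

    samples: np.ndarray
    sample_rate: float
    participant_id: str = ""
    site_id: str = ""
    label: int = 0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.samples.ndim != 1:
            raise ValueError("Recording requires mono (1-D) samples")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("Recording contains non-finite samples")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sample_rate


@dataclass
class Segment:
    """One fixed-length clip cut from a recording."""

    samples: np.ndarray
    sample_rate: float
    participant_id: str
    site_id: str
    label: int
    index: int
    qc_status: str = "kept"
    qc_reason: str = ""

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sample_rate


def quantize_int16(x: np.ndarray) -> np.ndarray:
    """Quantize float samples in [-1, 1) to int16 (scale 32768, clipped)."""
    q = np.round(np.asarray(x, dtype=np.float64) * 32768.0)
    return np.clip(q, -32768, 32767).astype(np.int16)


def write_wav(path: str | Path, samples: np.ndarray, sample_rate: int) -> None:
    """Write float samples as a 16-bit PCM mono WAV file."""
    wavfile.write(str(path), int(sample_rate), quantize_int16(samples))


def read_wav(
    path: str | Path,
    participant_id: str = "",
    site_id: str = "",
    label: int = 0,
) -> Recording:
    """Read a mono PCM WAV file, scaling samples to [-1, 1].

    Raises ``ValueError`` for multi-channel files or unsupported encodings.
    """
    rate, data = wavfile.read(str(path))
    if data.ndim != 1:
        raise ValueError(f"{path}: expected mono audio, got {data.ndim} channels")
    if data.dtype == np.int16:
        samples = data.astype(np.float64) / 32768.0
    elif data.dtype == np.int32:
        samples = data.astype(np.float64) / 2147483648.0
    elif data.dtype == np.uint8:
        samples = (data.astype(np.float64) - 128.0) / 128.0
    elif data.dtype in (np.float32, np.float64):
        samples = data.astype(np.float64)
    else:
        raise ValueError(f"{path}: unsupported WAV sample format {data.dtype}")
    return Recording(
        samples=samples,
        sample_rate=float(rate),
        participant_id=participant_id,
        site_id=site_id,
        label=label,
    )


def resample_recording(rec: Recording, target_rate: float) -> Recording:
    """Resample a recording to ``target_rate`` with a polyphase filter."""
    if rec.sample_rate == target_rate:
        return rec
    frac = Fraction(int(round(target_rate)), int(round(rec.sample_rate)))
    samples = signal.resample_poly(rec.samples, frac.numerator, frac.denominator)
    return Recording(
        samples=samples,
        sample_rate=float(target_rate),
        participant_id=rec.participant_id,
        site_id=rec.site_id,
        label=rec.label,
    )


def segment_recording(
    rec: Recording, segment_length: float = DEFAULT_SEGMENT_LENGTH
) -> list[Segment]:
    """Cut a recording into non-overlapping contiguous segments.

    Produces ``floor(duration / segment_length)`` segments; the trailing
    remainder is discarded. A recording shorter than one segment yields an
    empty list with a warning.
    """
    seg_samples = int(round(segment_length * rec.sample_rate))
    n = len(rec.samples)
    n_segments = n // seg_samples
    if n_segments == 0:
        warnings.warn(
            f"recording {rec.participant_id}/{rec.site_id} shorter than one "
            f"segment ({rec.duration:.2f} s < {segment_length} s); skipped",
            stacklevel=2,
        )
        return []
    return [
        Segment(
            samples=rec.samples[i * seg_samples : (i + 1) * seg_samples],
            sample_rate=rec.sample_rate,
            participant_id=rec.participant_id,
            site_id=rec.site_id,
            label=rec.label,
            index=i,
        )
        for i in range(n_segments)
    ]


def _clip_fraction(x: np.ndarray, threshold: float = 0.999) -> float:
    return float(np.mean(np.abs(x) >= threshold))


def _inband_energy_fraction(
    x: np.ndarray, sample_rate: float, band: tuple[float, float]
) -> float:
    """Fraction of total periodogram energy inside ``band`` (Hz)."""
    freqs = np.fft.rfftfreq(len(x), d=1.0 / sample_rate)
    power = np.abs(np.fft.rfft(x)) ** 2
    total = power.sum()
    if total == 0.0:
        return 0.0
    mask = (freqs >= band[0]) & (freqs <= band[1])
    return float(power[mask].sum() / total)


def quality_filter(
    segments: list[Segment],
    clip_fraction_max: float = 0.01,
    band_energy_min: float = 0.5,
    noise_band: tuple[float, float] = DEFAULT_NOISE_BAND,
) -> tuple[list[Segment], list[dict]]:
    """Exclude noisy/distorted segments by spectral analysis.

    A segment is rejected when its clipped-sample fraction exceeds
    ``clip_fraction_max`` ("clipping") or when the fraction of spectral
    energy inside ``noise_band`` falls below ``band_energy_min``
    ("out-of-band energy"). Returns the kept segments and a rejection log
    with one record per rejected segment.
    """
    kept: list[Segment] = []
    log: list[dict] = []
    for seg in segments:
        reason = ""
        if _clip_fraction(seg.samples) > clip_fraction_max:
            reason = "clipping"
        elif _inband_energy_fraction(seg.samples, seg.sample_rate, noise_band) < band_energy_min:
            reason = "out-of-band energy"
        if reason:
            seg.qc_status = "rejected"
            seg.qc_reason = reason
            log.append(
                {
                    "participant_id": seg.participant_id,
                    "site_id": seg.site_id,
                    "segment_index": seg.index,
                    "reason": reason,
                }
            )
        else:
            seg.qc_status = "kept"
            kept.append(seg)
    return kept, log
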