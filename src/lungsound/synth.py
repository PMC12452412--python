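"""Seeded synthetic respiratory-sound cohort generator.

Healthy participants are modelled as band-limited Gaussian noise modulated
by a periodic breathing envelope; asthmatic participants additionally carry
1-3 narrowband wheeze-like oscillations gated to the expiratory phase. The
model is a statistical stand-in with the acoustic contrast the feature
extractors target, not a physiological simulation.

The default cohort mirrors the study design this package implements:
120 participants (60 per class), six 15-second recordings each, i.e. 90 s
of audio per participant.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
from scipy import signal

from .audio_io import Recording, quantize_int16, write_wav

__all__ = [
    "SynthCohortConfig",
    "ParticipantRecord",
    "breathing_envelope",
    "expiratory_gate",
    "wheeze_component",
    "synthesize_participant",
    "iter_cohort_recordings",
    "generate_cohort",
    "MANIFEST_COLUMNS",
]

LABEL_ASTHMA = 1
LABEL_HEALTHY = 2

MANIFEST_COLUMNS = [
    "participant_id",
    "label",
    "site_id",
    "path",
    "sample_rate",
    "duration_s",
]

#: minimum envelope amplitude so no part of a breath cycle is digitally silent
ENVELOPE_FLOOR = 0.1


@dataclass(frozen=True)
class SynthCohortConfig:
    """Parameters of the synthetic cohort generator."""

    n_asthma: int = 60
    n_healthy: int = 60
    sample_rate: int = 4000
    site_count: int = 6
    site_duration: float = 15.0
    breathing_rate: float = 15.0
    wheeze_freq_range: tuple[float, float] = (100.0, 1000.0)
    wheeze_snr_db: float = 0.0
    noise_band: tuple[float, float] = (60.0, 1200.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_asthma < 0 or self.n_healthy < 0:
            raise ValueError("participant counts must be non-negative")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.site_count <= 0 or self.site_duration <= 0:
            raise ValueError("site_count and site_duration must be positive")
        if self.breathing_rate <= 0:
            raise ValueError("breathing_rate must be positive")
        nyquist = self.sample_rate / 2
        if not (0 < self.wheeze_freq_range[0] < self.wheeze_freq_range[1] < nyquist):
            raise ValueError("wheeze_freq_range must lie inside (0, sample_rate/2)")
        if not (0 <= self.noise_band[0] < self.noise_band[1] <= nyquist):
            raise ValueError("noise_band must lie inside [0, sample_rate/2]")

    @property
    def n_participants(self) -> int:
        return self.n_asthma + self.n_healthy

    @property
    def total_duration(self) -> float:
        """Total recorded seconds per participant."""
        return self.site_count * self.site_duration


@dataclass
class ParticipantRecord:
    participant_id: str
    label: int
    recordings: list[tuple[str, str]] = field(default_factory=list)  # (site_id, path)


def breathing_envelope(
    duration: float, rate: float, sample_rate: float, phase: float = 0.0
) -> np.ndarray:
    """Periodic inspiration/expiration amplitude modulation in [0, 1].

    Raised-cosine half-cycles: one full cycle spans ``60 / rate`` seconds,
    peaking mid-cycle. ``phase`` shifts the cycle start (in cycles).
    """
    if rate <= 0:
        raise ValueError("breathing rate must be positive")
    n = int(round(duration * sample_rate))
    t = np.arange(n) / sample_rate
    return np.sin(np.pi * (t * rate / 60.0 + phase)) ** 2


def expiratory_gate(
    duration: float, rate: float, sample_rate: float, phase: float = 0.0
) -> np.ndarray:
    """Boolean mask that is True during the expiratory half of each cycle."""
    if rate <= 0:
        raise ValueError("breathing rate must be positive")
    n = int(round(duration * sample_rate))
    t = np.arange(n) / sample_rate
    cycle_pos = (t * rate / 60.0 + phase) % 1.0
    return cycle_pos >= 0.5


def wheeze_component(
    duration: float,
    sample_rate: float,
    freq: float,
    snr_db: float,
    gate: np.ndarray,
    background_power: float = 1.0,
    phase: float = 0.0,
) -> np.ndarray:
    """Narrowband oscillation present only where ``gate`` is active.

    The realized power over the gated region is ``background_power``
    scaled by ``snr_db``. ``snr_db = -inf`` disables the component.
    """
    if not (0 < freq < sample_rate / 2):
        raise ValueError(f"wheeze frequency {freq} Hz outside (0, {sample_rate / 2}) Hz")
    n = int(round(duration * sample_rate))
    gate = np.asarray(gate, dtype=bool)
    if len(gate) != n:
        raise ValueError("gate length must match duration * sample_rate")
    if np.isneginf(snr_db) or not gate.any():
        return np.zeros(n)
    t = np.arange(n) / sample_rate
    tone = np.sin(2.0 * np.pi * freq * t + phase)
    gated = np.where(gate, tone, 0.0)
    current = float(np.mean(gated[gate] ** 2))
    if current == 0.0:
        return np.zeros(n)
    target = background_power * 10.0 ** (snr_db / 10.0)
    return gated * np.sqrt(target / current)


def _participant_rng(seed: int, index: int) -> np.random.Generator:
    """Independent per-participant stream derived from (master seed, index)."""
    return np.random.default_rng(np.random.SeedSequence([seed, index]))


def _bandpass_sos(config: SynthCohortConfig):
    low, high = config.noise_band
    low = max(low, 1e-3)
    return signal.butter(4, [low, high], btype="bandpass", fs=config.sample_rate, output="sos")


def _participant_ids(config: SynthCohortConfig) -> list[tuple[str, int]]:
    ids = [(f"A{i + 1:03d}", LABEL_ASTHMA) for i in range(config.n_asthma)]
    ids += [(f"H{i + 1:03d}", LABEL_HEALTHY) for i in range(config.n_healthy)]
    return ids


def synthesize_participant(
    config: SynthCohortConfig, index: int, participant_id: str, label: int
) -> list[np.ndarray]:
    """Generate one participant's per-site audio (list of float arrays).

    Wheeze frequencies and breathing-rate jitter are drawn once per
    participant; each site gets independent noise and breath phase.
    Samples are peak-normalized to 0.9 and quantized to the 16-bit grid so
    in-memory audio is identical to what a WAV round-trip would produce.
    """
    rng = _participant_rng(config.seed, index)
    rate = config.breathing_rate * rng.uniform(0.85, 1.15)
    n_wheeze = int(rng.integers(1, 4))
    wheeze_freqs = rng.uniform(*config.wheeze_freq_range, size=n_wheeze)
    sos = _bandpass_sos(config)
    fs = config.sample_rate
    out = []
    for _ in range(config.site_count):
        phase = rng.uniform(0.0, 1.0)
        env = breathing_envelope(config.site_duration, rate, fs, phase)
        env = ENVELOPE_FLOOR + (1.0 - ENVELOPE_FLOOR) * env
        noise = rng.standard_normal(int(round(config.site_duration * fs)))
        breath = signal.sosfilt(sos, noise) * env
        x = breath
        if label == LABEL_ASTHMA:
            gate = expiratory_gate(config.site_duration, rate, fs, phase)
            bg_power = float(np.mean(breath[gate] ** 2)) if gate.any() else float(
                np.mean(breath**2)
            )
            for f in wheeze_freqs:
                x = x + wheeze_component(
                    config.site_duration,
                    fs,
                    f,
                    config.wheeze_snr_db,
                    gate,
                    background_power=bg_power / n_wheeze,
                    phase=rng.uniform(0, 2 * np.pi),
                )
        peak = np.max(np.abs(x))
        if peak > 0:
            x = x * (0.9 / peak)
        out.append(quantize_int16(x).astype(np.float64) / 32768.0)
    return out


def iter_cohort_recordings(config: SynthCohortConfig) -> Iterator[Recording]:
    """Yield every (participant, site) recording of the cohort in memory."""
    for index, (pid, label) in enumerate(_participant_ids(config)):
        sites = synthesize_participant(config, index, pid, label)
        for s, samples in enumerate(sites):
            yield Recording(
                samples=samples,
                sample_rate=float(config.sample_rate),
                participant_id=pid,
                site_id=f"s{s + 1}",
                label=label,
            )


def generate_cohort(config: SynthCohortConfig, out_dir: str | Path) -> pd.DataFrame:
    """Write one mono WAV per (participant, site) plus a manifest CSV.

    Returns the manifest as a DataFrame; identical config + seed reproduces
    byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in iter_cohort_recordings(config):
        fname = f"{rec.participant_id}_{rec.site_id}.wav"
        write_wav(out_dir / fname, rec.samples, config.sample_rate)
        rows.append(
            {
                "participant_id": rec.participant_id,
                "label": rec.label,
                "site_id": rec.site_id,
                "path": fname,
                "sample_rate": config.sample_rate,
                "duration_s": config.site_duration,
            }
        )
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
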