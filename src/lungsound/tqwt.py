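"""Tunable Q-factor wavelet transform and sub-band descriptors.

The transform is an iterated two-channel oversampled filter bank realized
in the frequency domain. The quality factor ``Q`` sets frequency
selectivity, the redundancy ``r`` sets oversampling/band overlap, and
``J`` the decomposition depth; the derived scalings are

    beta = 2 / (Q + 1),    alpha = 1 - beta / r,

with transition bands shaped by the power-complementary function
``theta(w) = 0.5 (1 + cos w) sqrt(2 - cos w)``, which gives exact
(perfect) reconstruction.

Descriptors per sub-band: energy, mean/variance, Shannon entropy of the
energy-normalized sample distribution, peak amplitude and a nominal center
frequency. The default scalar feature is ``log(E_total + eps)``.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TQWTConfig",
    "SubbandSet",
    "TQWTFeatureSet",
    "max_levels",
    "tqwt_decompose",
    "tqwt_reconstruct",
    "subband_energy",
    "total_energy",
    "subband_stats",
    "shannon_entropy",
    "max_amplitude",
    "center_frequency",
    "analytic_center_frequencies",
    "tqwt_feature_vector",
    "feature_names",
]

LOG_FLOOR = 1e-12

#: smallest low-pass length allowed to start another decomposition level
_MIN_LOWPASS = 8


@dataclass(frozen=True)
class TQWTConfig:
    """Transform parameters; defaults suit transient-plus-oscillatory audio."""

    Q: float = 1.0
    r: float = 3.0
    J: int = 8

    def __post_init__(self) -> None:
        if self.Q < 1:
            raise ValueError("Q must be >= 1")
        if self.r <= 1:
            raise ValueError("redundancy r must be > 1")
        if self.J < 1:
            raise ValueError("J must be >= 1")

    @property
    def beta(self) -> float:
        return 2.0 / (self.Q + 1.0)

    @property
    def alpha(self) -> float:
        return 1.0 - self.beta / self.r


@dataclass
class SubbandSet:
    """J band-pass sub-bands (index 0..J-1) plus the final low-pass."""

    subbands: list[np.ndarray]
    config: TQWTConfig
    n_samples: int

    def __len__(self) -> int:
        return len(self.subbands)


def _subband_lengths(n: int, config: TQWTConfig) -> tuple[int, int]:
    n0 = 2 * int(round(config.alpha * n / 2.0))
    n1 = 2 * int(round(config.beta * n / 2.0))
    return n0, n1


def _level_feasible(n: int, config: TQWTConfig) -> bool:
    if n < _MIN_LOWPASS or n % 2:
        return False
    n0, n1 = _subband_lengths(n, config)
    t = (n0 + n1 - n) // 2 - 1
    return t >= 0 and n0 >= 4 and n1 >= 2


def max_levels(n_samples: int, config: TQWTConfig) -> int:
    """Maximum decomposition depth for a signal of ``n_samples`` points."""
    n, j = n_samples, 0
    while _level_feasible(n, config):
        n = _subband_lengths(n, config)[0]
        j += 1
    return j


def _plan(n_samples: int, config: TQWTConfig) -> list[tuple[int, int, int]]:
    """Per-level (N, N0, N1) lengths; raises if J is too deep."""
    if n_samples % 2:
        raise ValueError("signal length must be even")
    plan = []
    n = n_samples
    for _ in range(config.J):
        if not _level_feasible(n, config):
            raise ValueError(
                f"J={config.J} too deep for length {n_samples}; "
                f"maximum feasible J is {max_levels(n_samples, config)}"
            )
        n0, n1 = _subband_lengths(n, config)
        plan.append((n, n0, n1))
        n = n0
    return plan


def _transition(t: int) -> tuple[np.ndarray, np.ndarray]:
    """Low-pass and high-pass transition weights (power complementary)."""
    v = np.arange(1, t + 1) * np.pi / (t + 1)
    low = 0.5 * (1.0 + np.cos(v)) * np.sqrt(2.0 - np.cos(v))
    high = 0.5 * (1.0 - np.cos(v)) * np.sqrt(2.0 + np.cos(v))
    return low, high


def _afb(X: np.ndarray, n0: int, n1: int) -> tuple[np.ndarray, np.ndarray]:
    """One analysis stage on a unitary full-length DFT."""
    n = len(X)
    p = (n - n1) // 2
    t = (n0 + n1 - n) // 2 - 1
    s = (n - n0) // 2
    low, high = _transition(t)

    V0 = np.zeros(n0, dtype=complex)
    V0[0] = X[0]
    V0[1 : p + 1] = X[1 : p + 1]
    V0[p + 1 : p + t + 1] = X[p + 1 : p + t + 1] * low
    V0[n0 // 2 + 1 :] = np.conj(V0[1 : n0 // 2][::-1])

    V1 = np.zeros(n1, dtype=complex)
    V1[1 : t + 1] = X[p + 1 : p + t + 1] * high
    V1[t + 1 : t + s + 1] = X[p + t + 1 : p + t + s + 1]
    V1[n1 // 2] = X[n // 2]
    V1[n1 // 2 + 1 :] = np.conj(V1[1 : n1 // 2][::-1])
    return V0, V1


def _sfb(V0: np.ndarray, V1: np.ndarray, n: int) -> np.ndarray:
    """One synthesis stage (adjoint weights; exact inverse of ``_afb``)."""
    n0, n1 = len(V0), len(V1)
    p = (n - n1) // 2
    t = (n0 + n1 - n) // 2 - 1
    s = (n - n0) // 2
    low, high = _transition(t)

    Y = np.zeros(n, dtype=complex)
    Y[0] = V0[0]
    Y[1 : p + 1] = V0[1 : p + 1]
    Y[p + 1 : p + t + 1] = V0[p + 1 : p + t + 1] * low + V1[1 : t + 1] * high
    Y[p + t + 1 : p + t + s + 1] = V1[t + 1 : t + s + 1]
    Y[n // 2] = V1[n1 // 2]
    Y[n // 2 + 1 :] = np.conj(Y[1 : n // 2][::-1])
    return Y


def tqwt_decompose(samples: np.ndarray, config: TQWTConfig | None = None) -> SubbandSet:
    """Decompose a real signal into J band-pass sub-bands plus a low-pass.

    Unitary DFT scaling is used throughout, so the summed sub-band energy
    equals the input signal energy exactly.
    """
    if config is None:
        config = TQWTConfig()
    x = np.asarray(samples, dtype=np.float64)
    plan = _plan(len(x), config)
    X = np.fft.fft(x) / np.sqrt(len(x))
    subbands: list[np.ndarray] = []
    for _, n0, n1 in plan:
        V0, V1 = _afb(X, n0, n1)
        subbands.append(np.fft.ifft(V1).real * np.sqrt(n1))
        X = V0
    subbands.append(np.fft.ifft(X).real * np.sqrt(len(X)))
    return SubbandSet(subbands=subbands, config=config, n_samples=len(x))


def tqwt_reconstruct(sset: SubbandSet, config: TQWTConfig | None = None) -> np.ndarray:
    """Invert the filter bank; perfect reconstruction within roundoff."""
    if config is not None and config != sset.config:
        raise ValueError("config mismatch: sub-bands were produced with different parameters")
    config = sset.config
    plan = _plan(sset.n_samples, config)
    if len(sset.subbands) != config.J + 1:
        raise ValueError("sub-band count does not match config.J + 1")
    low = sset.subbands[-1]
    V0 = np.fft.fft(low) / np.sqrt(len(low))
    for (n, n0, n1), band in zip(reversed(plan), reversed(sset.subbands[:-1])):
        V1 = np.fft.fft(band) / np.sqrt(len(band))
        V0 = _sfb(V0, V1, n)
    return np.fft.ifft(V0).real * np.sqrt(sset.n_samples)


# ---------------------------------------------------------------------------
# sub-band descriptors


def subband_energy(band: np.ndarray) -> float:
    """E_j = sum_n s_j(n)^2."""
    band = np.asarray(band, dtype=np.float64)
    return float(np.sum(band**2))


def total_energy(energies) -> float:
    return float(np.sum(energies))


def subband_stats(band: np.ndarray) -> tuple[float, float]:
    """Arithmetic mean and population variance (divide by N_j)."""
    band = np.asarray(band, dtype=np.float64)
    if band.size == 0:
        raise ValueError("empty sub-band")
    mu = float(np.mean(band))
    return mu, float(np.mean((band - mu) ** 2))


def shannon_entropy(band: np.ndarray) -> float:
    """H_j = -sum p log p with p(n) = s(n)^2 / E_j; defined 0 for a zero band."""
    band = np.asarray(band, dtype=np.float64)
    e = np.sum(band**2)
    if e == 0.0:
        return 0.0
    p = band**2 / e
    p = p[p > 0]
    return float(-np.sum(p * np.log(p)))


def max_amplitude(band: np.ndarray) -> float:
    band = np.asarray(band, dtype=np.float64)
    if band.size == 0:
        raise ValueError("empty sub-band")
    return float(np.max(np.abs(band)))


def center_frequency(j: int, f_low: float, f_high: float) -> float:
    """Nominal center of band j: f_low + (f_high - f_low) / 2**j."""
    if f_low >= f_high:
        raise ValueError("need f_low < f_high")
    if j < 1:
        raise ValueError("band index starts at 1")
    return f_low + (f_high - f_low) / 2.0**j

def analytic_center_frequencies(config: TQWTConfig, sample_rate: float) -> np.ndarray:
    # actual band-pass centers of the filter bank, for diagnostics only
    j = np.arange(1, config.J + 1)
    return config.alpha ** (j - 1) * (2.0 - config.beta) / 4.0 * sample_rate


@dataclass
class TQWTFeatureSet:
    """All Table-style sub-band descriptors for one segment."""

    energies: np.ndarray
    total: float
    means: np.ndarray
    variances: np.ndarray
    entropies: np.ndarray
    peaks: np.ndarray
    center_freqs: np.ndarray
    band_lengths: np.ndarray
    f_low: float
    f_high: float
    scalar: float = 0.0

    def to_dict(self) -> dict[str, float]:
        out = {"tqwt_Etotal": self.scalar}
        for j in range(len(self.energies)):
            out[f"tqwt_E_{j + 1}"] = float(self.energies[j])
            out[f"tqwt_mu_{j + 1}"] = float(self.means[j])
            out[f"tqwt_var_{j + 1}"] = float(self.variances[j])
            out[f"tqwt_H_{j + 1}"] = float(self.entropies[j])
            out[f"tqwt_P_{j + 1}"] = float(self.peaks[j])
            out[f"tqwt_f_{j + 1}"] = float(self.center_freqs[j])
        return out


def feature_names(mode: str = "total_energy", J: int = 8) -> list[str]:
    if mode == "total_energy":
        return ["tqwt_Etotal"]
    names = ["tqwt_Etotal"]
    for j in range(1, J + 2):
        names += [f"tqwt_{stem}_{j}" for stem in ("E", "mu", "var", "H", "P", "f")]
    return names


def tqwt_feature_vector(
    samples: np.ndarray,
    sample_rate: float,
    config: TQWTConfig | None = None,
    mode: str = "total_energy",
    f_low: float = 0.0,
    f_high: float | None = None,
) -> TQWTFeatureSet:
    """Decompose a segment and compute every sub-band descriptor.

    ``scalar`` is the single summary feature used in the default combined
    vector: log(E_total + eps). ``mode`` only controls which columns the
    pipeline exports; the full set is always computed here.
    """
    if config is None:
        config = TQWTConfig()
    if mode not in ("total_energy", "full"):
        raise ValueError(f"unknown mode {mode!r}")
    if f_high is None:
        f_high = sample_rate / 2.0
    sset = tqwt_decompose(samples, config)
    bands = sset.subbands
    energies = np.array([subband_energy(b) for b in bands])
    stats = [subband_stats(b) for b in bands]
    feats = TQWTFeatureSet(
        energies=energies,
        total=total_energy(energies),
        means=np.array([s[0] for s in stats]),
        variances=np.array([s[1] for s in stats]),
        entropies=np.array([shannon_entropy(b) for b in bands]),
        peaks=np.array([max_amplitude(b) for b in bands]),
        center_freqs=np.array(
            [center_frequency(j, f_low, f_high) for j in range(1, len(bands) + 1)]
        ),
        band_lengths=np.array([len(b) for b in bands]),
        f_low=f_low,
        f_high=f_high,
    )
    feats.scalar = float(np.log(feats.total + LOG_FLOOR)) if feats.total > 0 else float(
        np.log(LOG_FLOOR)
    )
    return feats
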