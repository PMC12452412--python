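"""Shared fixtures and independent oracles for the test suite."""
from __future__ import annotations

import numpy as np
import pytest

from lungsound.audio_io import quality_filter, segment_recording
from lungsound.features import FeatureMatrix, build_feature_matrix
from lungsound.synth import SynthCohortConfig, iter_cohort_recordings


def build_cohort_matrix(config: SynthCohortConfig) -> FeatureMatrix:
    """Generate -> segment -> QC -> extract, entirely in memory."""
    segments = []
    for rec in iter_cohort_recordings(config):
        segments.extend(segment_recording(rec))
    kept, _ = quality_filter(segments, noise_band=config.noise_band)
    return build_feature_matrix(kept)


def relieff_bruteforce(X: np.ndarray, y: np.ndarray, k: int) -> np.ndarray:
    """Explicit double-loop ReliefF, independent of the vectorized path.

    Manhattan distance on range-normalized features; ties broken by lower
    sample index; every sample is an anchor.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    lo = X.min(axis=0)
    rng = X.max(axis=0) - lo
    rng[rng == 0] = 1.0
    Xn = (X - lo) / rng
    W = np.zeros(p)
    for i in range(n):
        dists = [float(np.sum(np.abs(Xn[i] - Xn[j]))) for j in range(n)]
        hits = sorted(
            (j for j in range(n) if y[j] == y[i] and j != i),
            key=lambda j: (dists[j], j),
        )[:k]
        misses = sorted(
            (j for j in range(n) if y[j] != y[i]), key=lambda j: (dists[j], j)
        )[:k]
        for f in range(p):
            W[f] += np.mean([abs(Xn[i, f] - Xn[j, f]) for j in misses])
            W[f] -= np.mean([abs(Xn[i, f] - Xn[j, f]) for j in hits])
    return W / n


SMALL_COHORT_KWARGS = dict(
    n_asthma=12, n_healthy=12, site_count=2, site_duration=9.0
)


@pytest.fixture(scope="session")
def small_matrix() -> FeatureMatrix:
    """Reduced cohort (24 participants, 144 segments) at the default SNR."""
    return build_cohort_matrix(SynthCohortConfig(seed=11, **SMALL_COHORT_KWARGS))


@pytest.fixture(scope="session")
def small_matrix_factory():
    cache: dict[float, FeatureMatrix] = {}

    def factory(wheeze_snr_db: float) -> FeatureMatrix:
        if wheeze_snr_db not in cache:
            cache[wheeze_snr_db] = build_cohort_matrix(
                SynthCohortConfig(
                    seed=11, wheeze_snr_db=wheeze_snr_db, **SMALL_COHORT_KWARGS
                )
            )
        return cache[wheeze_snr_db]

    return factory
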