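"""Combined feature matrix assembly, standardization, and ReliefF selection.

Each segment contributes a 15-dimensional row by default: 14 MFCC means
followed by the TQWT total-energy summary. ReliefF weights features by
contrast between nearest hits and misses (Manhattan distance on
range-normalized features, all samples as anchors); the top-k features by
weight feed the classifiers.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from . import mfcc as mfcc_mod
from . import tqwt as tqwt_mod
from .audio_io import Segment

__all__ = [
    "FeatureMatrix",
    "Standardizer",
    "ReliefFResult",
    "combine_features",
    "extract_features",
    "build_feature_matrix",
    "standardize",
    "relieff",
    "select_top_k",
    "topk_accuracy_sweep",
    "permutation_importance",
]

META_COLUMNS = ["participant_id", "label", "site_id", "segment_index"]


@dataclass
class FeatureMatrix:
    """Segments-by-features table with per-row identity metadata."""

    values: np.ndarray
    feature_names: list[str]
    meta: pd.DataFrame  # columns META_COLUMNS, one row per segment

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if self.values.shape[1] != len(self.feature_names):
            raise ValueError("feature_names length must match column count")
        if len(self.meta) != self.values.shape[0]:
            raise ValueError("meta rows must match value rows")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite values")

    @property
    def labels(self) -> np.ndarray:
        return self.meta["label"].to_numpy()

    @property
    def groups(self) -> np.ndarray:
        return self.meta["participant_id"].to_numpy()

    def to_frame(self) -> pd.DataFrame:
        df = self.meta.reset_index(drop=True).copy()
        for i, name in enumerate(self.feature_names):
            df[name] = self.values[:, i]
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FeatureMatrix":
        names = [c for c in df.columns if c not in META_COLUMNS]
        return cls(
            values=df[names].to_numpy(dtype=np.float64),
            feature_names=names,
            meta=df[META_COLUMNS].reset_index(drop=True),
        )


def combine_features(mfcc_vector: np.ndarray, tqwt_scalar: float | np.ndarray) -> np.ndarray:
    """Concatenate [mfcc_01..mfcc_NN, tqwt features] into one row."""
    mfcc_vector = np.atleast_1d(np.asarray(mfcc_vector, dtype=np.float64))
    tqwt_part = np.atleast_1d(np.asarray(tqwt_scalar, dtype=np.float64))
    if mfcc_vector.ndim != 1 or tqwt_part.ndim != 1:
        raise ValueError("inputs must be 1-D")
    return np.concatenate([mfcc_vector, tqwt_part])


def extract_features(
    segment: Segment,
    mfcc_config: mfcc_mod.MFCCConfig | None = None,
    tqwt_config: tqwt_mod.TQWTConfig | None = None,
    tqwt_mode: str = "total_energy",
) -> tuple[np.ndarray, list[str]]:
    """Per-segment combined feature row and its column names."""
    mfcc_config = mfcc_config or mfcc_mod.MFCCConfig()
    tqwt_config = tqwt_config or tqwt_mod.TQWTConfig()
    mvec = mfcc_mod.mfcc_mean_vector(segment.samples, segment.sample_rate, mfcc_config)
    tfeat = tqwt_mod.tqwt_feature_vector(
        segment.samples, segment.sample_rate, tqwt_config, mode=tqwt_mode
    )
    if tqwt_mode == "total_energy":
        tvals: np.ndarray | float = tfeat.scalar
    else:
        d = tfeat.to_dict()
        tvals = np.array(list(d.values()))
    names = mfcc_mod.feature_names(mfcc_config.n_coeffs) + tqwt_mod.feature_names(
        tqwt_mode, tqwt_config.J
    )
    return combine_features(mvec, tvals), names


def build_feature_matrix(
    segments: Iterable[Segment],
    mfcc_config: mfcc_mod.MFCCConfig | None = None,
    tqwt_config: tqwt_mod.TQWTConfig | None = None,
    tqwt_mode: str = "total_energy",
) -> FeatureMatrix:
    rows, meta = [], []
    names: list[str] = []
    for seg in segments:
        row, names = extract_features(seg, mfcc_config, tqwt_config, tqwt_mode)
        rows.append(row)
        meta.append(
            {
                "participant_id": seg.participant_id,
                "label": seg.label,
                "site_id": seg.site_id,
                "segment_index": seg.index,
            }
        )
    if not rows:
        raise ValueError("no segments to extract features from")
    return FeatureMatrix(
        values=np.vstack(rows),
        feature_names=names,
        meta=pd.DataFrame(meta, columns=META_COLUMNS),
    )


@dataclass
class Standardizer:
    """Replayable z-score transform fitted on training rows only."""

    mean: np.ndarray
    scale: np.ndarray
    constant_mask: np.ndarray  # features with zero SD: centered only

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=np.float64) - self.mean) / self.scale


def standardize(
    X: np.ndarray, fit_rows: np.ndarray | None = None
) -> tuple[np.ndarray, Standardizer]:
    """Z-score ``X`` using mean/SD estimated from ``fit_rows`` (bool/index mask).

    Constant features are centered only (scale 1) and flagged.
    """
    X = np.asarray(X, dtype=np.float64)
    fit = X if fit_rows is None else X[fit_rows]
    if len(fit) == 0:
        raise ValueError("fit_rows selects no rows")
    mean = fit.mean(axis=0)
    sd = fit.std(axis=0)
    constant = sd == 0.0
    scale = np.where(constant, 1.0, sd)
    tf = Standardizer(mean=mean, scale=scale, constant_mask=constant)
    return tf.transform(X), tf


@dataclass
class ReliefFResult:
    weights: np.ndarray
    ranking: np.ndarray  # feature indices, best first
    k_neighbors: int
    n_select: int

    @property
    def selected(self) -> np.ndarray:
        """Top-``n_select`` feature indices, best first."""
        return self.ranking[: self.n_select]

    def to_frame(self, feature_names: Sequence[str]) -> pd.DataFrame:
        rank_of = np.empty(len(self.weights), dtype=int)
        rank_of[self.ranking] = np.arange(1, len(self.weights) + 1)
        return pd.DataFrame(
            {
                "feature": list(feature_names),
                "weight": self.weights,
                "rank": rank_of,
                "selected": np.isin(np.arange(len(self.weights)), self.selected),
            }
        )


def _range_normalize(X: np.ndarray) -> np.ndarray:
    lo = X.min(axis=0)
    rng = X.max(axis=0) - lo
    rng = np.where(rng == 0.0, 1.0, rng)
    return (X - lo) / rng


def _k_nearest(dist_row: np.ndarray, candidates: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k nearest candidates; ties broken by lower index."""
    order = np.lexsort((candidates, dist_row[candidates]))
    return candidates[order[:k]]


def relieff(
    X: np.ndarray,
    y: np.ndarray,
    k_neighbors: int = 10,
    n_select: int = 10,
) -> ReliefFResult:
    """ReliefF feature weights for a binary problem.

    Every sample serves as an anchor; for each, the ``k_neighbors`` nearest
    same-class hits and nearest other-class misses (Manhattan distance on
    range-normalized features) contribute ``mean|diff to misses| -
    mean|diff to hits|`` per feature, averaged over anchors. Weights lie in
    [-1, 1]; ranking ties break toward the lower original index.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("relieff requires exactly two classes")
    for c in classes:
        if np.sum(y == c) < k_neighbors + 1:
            raise ValueError(
                f"class {c!r} needs at least k_neighbors + 1 = {k_neighbors + 1} samples"
            )
    n, p = X.shape
    Xn = _range_normalize(X)
    weights = np.zeros(p)
    idx_by_class = {c: np.flatnonzero(y == c) for c in classes}
    # chunked pairwise Manhattan distances to bound memory on large cohorts
    chunk = max(1, int(1e7 // max(n, 1)))
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        D = cdist(Xn[start:stop], Xn, metric="cityblock")
        for i in range(start, stop):
            drow = D[i - start]
            same = idx_by_class[y[i]]
            same = same[same != i]
            other = idx_by_class[classes[0] if y[i] == classes[1] else classes[1]]
            hits = _k_nearest(drow, same, k_neighbors)
            misses = _k_nearest(drow, other, k_neighbors)
            weights += np.abs(Xn[i] - Xn[misses]).mean(axis=0)
            weights -= np.abs(Xn[i] - Xn[hits]).mean(axis=0)
    weights /= n
    ranking = np.lexsort((np.arange(p), -weights))
    return ReliefFResult(
        weights=weights,
        ranking=ranking,
        k_neighbors=k_neighbors,
        n_select=min(n_select, p),
    )


def select_top_k(
    matrix: FeatureMatrix | np.ndarray, result: ReliefFResult, k: int = 10
) -> FeatureMatrix | np.ndarray:
    """Restrict the matrix to the k top-ranked features.

    Original column order is retained within the selection.
    """
    values = matrix.values if isinstance(matrix, FeatureMatrix) else np.asarray(matrix)
    if k > values.shape[1]:
        raise ValueError(f"k={k} exceeds feature count {values.shape[1]}")
    cols = np.sort(result.ranking[:k])
    if isinstance(matrix, FeatureMatrix):
        return FeatureMatrix(
            values=values[:, cols],
            feature_names=[matrix.feature_names[i] for i in cols],
            meta=matrix.meta,
        )
    return values[:, cols]


def topk_accuracy_sweep(
    X: np.ndarray,
    y: np.ndarray,
    fold_indices: Sequence[tuple[np.ndarray, np.ndarray]],
    k_values: Sequence[int],
    model_factory: Callable,
    k_neighbors: int = 10,
) -> dict[int, float]:
    """Mean CV accuracy for each selection size k.

    ReliefF and standardization are refitted on training rows within every
    fold (no selection leakage); the same per-fold ranking is reused across
    all k values.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    correct = {k: 0 for k in k_values}
    total = 0
    for train_idx, test_idx in fold_indices:
        Xs_train, tf = standardize(X[train_idx])
        Xs_test = tf.transform(X[test_idx])
        res = relieff(Xs_train, y[train_idx], k_neighbors=k_neighbors)
        total += len(test_idx)
        for k in k_values:
            cols = np.sort(res.ranking[:k])
            model = model_factory()
            model.fit(Xs_train[:, cols], y[train_idx])
            pred = model.predict(Xs_test[:, cols])
            correct[k] += int(np.sum(pred == y[test_idx]))
    return {k: correct[k] / total for k in k_values}


def permutation_importance(
    model,
    X: np.ndarray,
    y: np.ndarray,
    n_repeats: int = 10,
    seed: int = 0,
) -> np.ndarray:
    """Mean accuracy drop per feature when that column is shuffled."""
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    baseline = float(np.mean(model.predict(X) == y))
    drops = np.zeros(X.shape[1])
    for j in range(X.shape[1]):
        for _ in range(n_repeats):
            Xp = X.copy()
            Xp[:, j] = Xp[rng.permutation(len(X)), j]
            drops[j] += baseline - float(np.mean(model.predict(Xp) == y))
    return drops / n_repeats
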