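"""Core domain types for path-based feature ranking on 2D embeddings.

All containers are light, validated dataclasses around NumPy arrays.
Validation happens at construction time so downstream code can assume
finite, well-shaped data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "Embedding2D",
    "FeatureMatrix",
    "DrawnPath",
    "SampledPath",
    "BackProjection",
    "RankingConfig",
    "FeatureRanking",
    "RankingEntry",
    "Metric",
    "Normalization",
    "FFTWeighting",
]

# string enums: plain strings keep CLI/config round-trips trivial
Metric = str  # "autocorrelation" | "fft"
Normalization = str  # "none" | "zscore" | "minmax"
FFTWeighting = str  # "descending_magnitude" | "frequency_index"

METRICS = ("autocorrelation", "fft")
NORMALIZATIONS = ("none", "zscore", "minmax")
FFT_WEIGHTINGS = ("descending_magnitude", "frequency_index")


def _check_unique(names: Sequence[str], kind: str) -> None:
    seen: set[str] = set()
    for name in names:
        if name in seen:
            raise ValueError(f"duplicate {kind} id: {name!r}")
        seen.add(name)


def _as_float_matrix(values, name: str, ncols: int | None = None) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"{name} must be 2-dimensional, got shape {arr.shape}")
    if ncols is not None and arr.shape[1] != ncols:
        raise ValueError(f"{name} must have {ncols} columns, got {arr.shape[1]}")
    if not np.isfinite(arr).all():
        bad = np.argwhere(~np.isfinite(arr))[0]
        raise ValueError(
            f"{name} contains a non-finite value at row {bad[0]}, column {bad[1]}"
        )
    return arr


@dataclass(frozen=True)
class Embedding2D:
    """Per-sample 2D coordinates (e.g. a UMAP or t-SNE layout).

    Rows are paired one-to-one, by sample id, with the rows of a
    :class:`FeatureMatrix` holding the original high-dimensional data.
    """

    sample_ids: tuple[str, ...]
    coords: np.ndarray  # n x 2, embedding units

    def __init__(self, sample_ids: Sequence[str], coords) -> None:
        ids = tuple(str(s) for s in sample_ids)
        arr = _as_float_matrix(coords, "coords", ncols=2)
        if len(ids) != arr.shape[0]:
            raise ValueError(
                f"{len(ids)} sample ids but {arr.shape[0]} coordinate rows"
            )
        if arr.shape[0] < 2:
            raise ValueError("an embedding needs at least 2 samples")
        _check_unique(ids, "sample")
        object.__setattr__(self, "sample_ids", ids)
        object.__setattr__(self, "coords", arr)

    @property
    def n_samples(self) -> int:
        return self.coords.shape[0]


@dataclass(frozen=True)
class FeatureMatrix:
    """Samples x features numeric matrix: the original feature space.

    Missing or non-finite entries are rejected at construction; silent
    imputation would corrupt periodicity scores downstream.
    """

    sample_ids: tuple[str, ...]
    feature_names: tuple[str, ...]
    values: np.ndarray  # n x d

    def __init__(self, sample_ids: Sequence[str], feature_names: Sequence[str], values) -> None:
        ids = tuple(str(s) for s in sample_ids)
        names = tuple(str(f) for f in feature_names)
        arr = _as_float_matrix(values, "values")
        if len(ids) != arr.shape[0]:
            raise ValueError(f"{len(ids)} sample ids but {arr.shape[0]} rows")
        if len(names) != arr.shape[1]:
            raise ValueError(
                f"{len(names)} feature names but {arr.shape[1]} columns"
            )
        if arr.shape[1] < 1:
            raise ValueError("a feature matrix needs at least 1 feature")
        _check_unique(ids, "sample")
        _check_unique(names, "feature")
        object.__setattr__(self, "sample_ids", ids)
        object.__setattr__(self, "feature_names", names)
        object.__setattr__(self, "values", arr)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class DrawnPath:
    """An ordered polyline in embedding coordinates.

    Vertex order IS traversal order; the same set of vertices in a
    different order is a different path.
    """

    vertices: np.ndarray  # m x 2

    def __init__(self, vertices) -> None:
        arr = _as_float_matrix(vertices, "vertices", ncols=2)
        if arr.shape[0] < 2:
            raise ValueError("a path needs at least 2 vertices")
        seg = np.diff(arr, axis=0)
        if not (np.hypot(seg[:, 0], seg[:, 1]).sum() > 0):
            raise ValueError("zero-length path: all vertices coincide")
        object.__setattr__(self, "vertices", arr)

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    def length(self) -> float:
        seg = np.diff(self.vertices, axis=0)
        return float(np.hypot(seg[:, 0], seg[:, 1]).sum())


@dataclass(frozen=True)
class SampledPath:
    """A path resampled to ``n_bins`` arc-length-equidistant points.

    ``t`` holds the normalized arc-length position of each point in
    [0, 1]; ``n_bins`` is the sequence length fed to the ranking metrics.
    """

    points: np.ndarray  # n_bins x 2
    t: np.ndarray  # n_bins, strictly increasing 0..1

    def __init__(self, points, t) -> None:
        pts = _as_float_matrix(points, "points", ncols=2)
        tv = np.asarray(t, dtype=float)
        if tv.ndim != 1 or tv.shape[0] != pts.shape[0]:
            raise ValueError("t must be a vector matching points")
        if pts.shape[0] < 2:
            raise ValueError("a sampled path needs at least 2 points")
        if not (tv[0] == 0.0 and tv[-1] == 1.0 and np.all(np.diff(tv) > 0)):
            raise ValueError("t must increase strictly from 0 to 1")
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "t", tv)

    @property
    def n_bins(self) -> int:
        return self.points.shape[0]


@dataclass(frozen=True)
class BackProjection:
    """The result of reading the feature matrix along a sampled path.

    ``profiles[b, j]`` is feature ``j``'s value at the sample nearest to
    path bin ``b``; it equals ``values[bin_to_sample[b], j]`` exactly.
    ``selected_samples`` lists the distinct samples touched, so a caller
    can highlight the points that entered the computation.
    """

    bin_to_sample: np.ndarray  # n_bins ints, rows of the FeatureMatrix
    profiles: np.ndarray  # n_bins x d
    selected_samples: frozenset[int] = field(init=False)

    def __init__(self, bin_to_sample, profiles) -> None:
        idx = np.asarray(bin_to_sample)
        if idx.ndim != 1 or not np.issubdtype(idx.dtype, np.integer):
            raise ValueError("bin_to_sample must be a 1-d integer vector")
        prof = _as_float_matrix(profiles, "profiles")
        if prof.shape[0] != idx.shape[0]:
            raise ValueError("profiles must have one row per bin")
        object.__setattr__(self, "bin_to_sample", idx)
        object.__setattr__(self, "profiles", prof)
        object.__setattr__(self, "selected_samples", frozenset(int(i) for i in idx))

    @property
    def n_bins(self) -> int:
        return self.profiles.shape[0]

    @property
    def n_features(self) -> int:
        return self.profiles.shape[1]


@dataclass(frozen=True)
class RankingConfig:
    """Tunable knobs of the ranking pipeline.

    Defaults mirror the interactive tool this library re-implements:
    512 path bins, autocorrelation lag 22 (~sqrt(512)), top 100 features
    reported, no profile normalization, and the harmonic FFT score
    summed over magnitudes sorted in descending order.
    """

    n_bins: int = 512
    lag: int = 22
    metric: Metric = "fft"
    top_k: int = 100
    normalization: Normalization = "none"
    fft_weighting: FFTWeighting = "descending_magnitude"
    allow_non_pow2: bool = True  # fall back to a direct DFT off the fast path

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValueError("n_bins must be at least 2")
        if not (1 <= self.lag < self.n_bins):
            raise ValueError(
                f"lag must satisfy 1 <= lag < n_bins, got lag={self.lag}, n_bins={self.n_bins}"
            )
        if self.top_k < 1:
            raise ValueError("top_k must be positive")
        if self.metric not in METRICS:
            raise ValueError(f"metric must be one of {METRICS}, got {self.metric!r}")
        if self.normalization not in NORMALIZATIONS:
            raise ValueError(
                f"normalization must be one of {NORMALIZATIONS}, got {self.normalization!r}"
            )
        if self.fft_weighting not in FFT_WEIGHTINGS:
            raise ValueError(
                f"fft_weighting must be one of {FFT_WEIGHTINGS}, got {self.fft_weighting!r}"
            )
        if (
            self.metric == "fft"
            and not self.allow_non_pow2
            and (self.n_bins & (self.n_bins - 1)) != 0
        ):
            raise ValueError(
                "n_bins must be a power of 2 for the FFT fast path "
                "(set allow_non_pow2=True for the direct-DFT fallback)"
            )


@dataclass(frozen=True)
class RankingEntry:
    feature_name: str
    score: float
    rank: int  # 1-based, no gaps


@dataclass(frozen=True)
class FeatureRanking:
    """Features sorted by score descending; ties keep input order."""

    entries: tuple[RankingEntry, ...]
    metric: Metric
    params: RankingConfig

    def __post_init__(self) -> None:
        scores = [e.score for e in self.entries]
        if any(a < b for a, b in zip(scores, scores[1:])):
            raise ValueError("entries must be sorted by score descending")
        if [e.rank for e in self.entries] != list(range(1, len(self.entries) + 1)):
            raise ValueError("ranks must be 1..d with no gaps")

    def __len__(self) -> int:
        return len(self.entries)

    def top(self, k: int) -> tuple[RankingEntry, ...]:
        return self.entries[: min(k, len(self.entries))]

    def rank_of(self, feature_name: str) -> int:
        for e in self.entries:
            if e.feature_name == feature_name:
                return e.rank
        raise KeyError(feature_name)
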