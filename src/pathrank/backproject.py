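"""Back-projection: map path bins to nearest embedding samples.

The embedding and the path are first rescaled axis-independently so each
embedding axis spans [0, 1] — the geometry of a square display, which is
the frame users actually draw in. Nearest-neighbour lookup is exact
Euclidean in that frame, with ties broken by lowest sample index, so the
whole pipeline is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .models import BackProjection, DrawnPath, Embedding2D, FeatureMatrix, RankingConfig, SampledPath
from .paths import resample_path

__all__ = [
    "RescaledFrame",
    "rescale",
    "nearest_indices",
    "back_project",
    "run_backprojection",
    "repeat_backprojection",
]

_CHUNK = 4096  # bins per cdist block; bounds memory at ~n*32KB per block


@dataclass(frozen=True)
class RescaledFrame:
    """Per-axis (min, max) of the embedding defining the [0,1]^2 mapping.

    A constant axis (max == min) maps every value to 0.5.
    """

    x_min: float
    x_max: float
    y_min: float
    y_max: float

    @classmethod
    def from_coords(cls, coords: np.ndarray) -> "RescaledFrame":
        return cls(
            float(coords[:, 0].min()),
            float(coords[:, 0].max()),
            float(coords[:, 1].min()),
            float(coords[:, 1].max()),
        )

    def apply(self, points: np.ndarray) -> np.ndarray:
        out = np.empty_like(points, dtype=float)
        for axis, (lo, hi) in enumerate(((self.x_min, self.x_max), (self.y_min, self.y_max))):
            if hi > lo:
                out[:, axis] = (points[:, axis] - lo) / (hi - lo)
            else:
                out[:, axis] = 0.5
        return out


def rescale(
    emb: Embedding2D, path: DrawnPath | SampledPath
) -> tuple[np.ndarray, np.ndarray, RescaledFrame]:
    """Map embedding coords and path points by the embedding's per-axis min/max.

    Both are transformed by the same affine map, derived from the
    embedding only, so path points drawn beyond the data's bounding box
    land outside [0, 1] — which is fine.
    """
    frame = RescaledFrame.from_coords(emb.coords)
    path_points = path.vertices if isinstance(path, DrawnPath) else path.points
    return frame.apply(emb.coords), frame.apply(path_points), frame


def nearest_indices(sampled_points: np.ndarray, emb_coords: np.ndarray) -> np.ndarray:
    """Exact Euclidean nearest embedding sample for every sampled path point.

    Ties resolve to the lowest sample index (argmin's first minimum).
    Both inputs must already be in the same (rescaled) frame. Repeated
    indices across bins are expected whenever bins outnumber samples.
    """
    pts = np.atleast_2d(np.asarray(sampled_points, dtype=float))
    emb = np.atleast_2d(np.asarray(emb_coords, dtype=float))
    if pts.size == 0 or emb.size == 0:
        raise ValueError("empty input to nearest-neighbour search")
    out = np.empty(pts.shape[0], dtype=np.int64)
    for start in range(0, pts.shape[0], _CHUNK):
        block = pts[start : start + _CHUNK]
        out[start : start + block.shape[0]] = cdist(block, emb).argmin(axis=1)
    return out


def back_project(indices: np.ndarray, fm: FeatureMatrix) -> BackProjection:
    """Gather feature rows along the path: profiles[b, :] = values[indices[b], :]."""
    idx = np.asarray(indices)
    if idx.size and (idx.min() < 0 or idx.max() >= fm.n_samples):
        raise IndexError(
            f"bin index out of range: valid rows are 0..{fm.n_samples - 1}"
        )
    return BackProjection(idx, fm.values[idx])


def repeat_backprojection(bp: BackProjection, fm: FeatureMatrix, times: int) -> BackProjection:
    """The back-projection of a path re-traced ``times`` times, exactly.

    A perfect re-trace visits the same nearest samples in the same order
    again, so its bin sequence is the original tiled ``times`` times
    (``n_bins`` grows by the same factor). Under the FFT score this
    provably cannot change the ranking: the spectrum of a q-fold repeated
    sequence is the original's magnitudes scaled by q at multiples of q
    and zero elsewhere, so every feature's score scales by the same
    factor. Resampling a geometrically concatenated polyline
    (:func:`pathrank.paths.repeat_path`) only approximates this — the
    uniform arc grid of the doubled path is phase-shifted by up to half a
    bin relative to the original, which perturbs nearest-neighbour
    assignments; use this function when exact repetition is meant.
    """
    if times < 1:
        raise ValueError("times must be >= 1")
    return back_project(np.tile(bp.bin_to_sample, times), fm)


def run_backprojection(
    emb: Embedding2D,
    fm: FeatureMatrix,
    path: DrawnPath,
    cfg: RankingConfig | None = None,
) -> tuple[SampledPath, BackProjection]:
    """Full back-projection: rescale, resample, nearest-neighbour, gather.

    ``emb`` and ``fm`` must already be aligned (same sample order); use
    :func:`pathrank.io.align` first if in doubt.
    """
    if cfg is None:
        cfg = RankingConfig()
    if emb.sample_ids != fm.sample_ids:
        raise ValueError("embedding and feature matrix are not aligned; call align() first")
    emb_rescaled, path_rescaled, _ = rescale(emb, path)
    sampled = resample_path(DrawnPath(path_rescaled), cfg.n_bins)
    indices = nearest_indices(sampled.points, emb_rescaled)
    return sampled, back_project(indices, fm)
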