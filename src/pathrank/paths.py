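"""Polyline geometry: arc-length resampling and synthetic path builders.

A hand-drawn path arrives as an ordered vertex polyline whose vertex
density reflects pointer-event timing, not geometry. Resampling to
``n_bins`` arc-length-equidistant points normalizes that away, so a path
drawn slowly and the same path drawn quickly yield the same sequence.
"""

from __future__ import annotations

import numpy as np

from .models import DrawnPath, SampledPath

__all__ = ["resample_path", "zigzag_path", "repeat_path"]


def _clean_segments(vertices: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Drop zero-length segments (repeated vertices from raw pointer traces)."""
    seg = np.diff(vertices, axis=0)
    lengths = np.hypot(seg[:, 0], seg[:, 1])
    keep = lengths > 0
    # keep vertex i+1 iff segment i has positive length; vertex 0 always kept
    mask = np.concatenate([[True], keep])
    cleaned = vertices[mask]
    seg = np.diff(cleaned, axis=0)
    return cleaned, np.hypot(seg[:, 0], seg[:, 1])


def resample_path(path: DrawnPath, n_bins: int) -> SampledPath:
    """Resample a polyline to ``n_bins`` points equally spaced by arc length.

    The first and last sampled points are the path's endpoints exactly and
    consecutive points are ``L / (n_bins - 1)`` apart along the polyline
    (L = total length). Interpolation is linear within segments; no
    smoothing is applied.
    """
    if n_bins < 2:
        raise ValueError(f"n_bins must be at least 2, got {n_bins}")
    vertices, seg_len = _clean_segments(path.vertices)
    total = seg_len.sum()
    if not total > 0:
        raise ValueError("zero-length path: all vertices coincide")
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    # target arc positions; endpoints pinned exactly afterwards
    targets = np.linspace(0.0, total, n_bins)
    x = np.interp(targets, cum, vertices[:, 0])
    y = np.interp(targets, cum, vertices[:, 1])
    points = np.column_stack([x, y])
    points[0] = vertices[0]
    points[-1] = vertices[-1]
    t = np.linspace(0.0, 1.0, n_bins)
    t[0], t[-1] = 0.0, 1.0
    return SampledPath(points, t)


def zigzag_path(
    anchors_a: list[tuple[float, float]] | np.ndarray,
    anchors_b: list[tuple[float, float]] | np.ndarray,
    cycles: int = 1,
) -> DrawnPath:
    """Build a back-and-forth path alternating between two anchor sets.

    Visiting two regions alternately turns a between-region difference in
    any feature into a periodic signal along the path, which the ranking
    metrics are designed to detect — a cluster-discrimination recipe
    rather than a trajectory one. Anchors are cycled in order when a set
    has more than one point.
    """
    a = np.atleast_2d(np.asarray(anchors_a, dtype=float))
    b = np.atleast_2d(np.asarray(anchors_b, dtype=float))
    if a.size == 0 or b.size == 0:
        raise ValueError("anchor lists must be non-empty")
    if a.shape[1] != 2 or b.shape[1] != 2:
        raise ValueError("anchors must be 2D points")
    if cycles < 1:
        raise ValueError("cycles must be >= 1")
    verts = [a[0]]
    for c in range(cycles):
        verts.append(b[c % len(b)])
        verts.append(a[(c + 1) % len(a)])
    return DrawnPath(np.asarray(verts))


def repeat_path(path: DrawnPath, times: int) -> DrawnPath:
    """Concatenate ``times`` same-direction traversals of a path.

    The end of each copy is joined to the start of the next, modelling a
    user who re-traces the same stroke; repetition should not change
    which features rank highly.
    """
    if times < 1:
        raise ValueError("times must be >= 1")
    if times == 1:
        return path
    return DrawnPath(np.vstack([path.vertices] * times))
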