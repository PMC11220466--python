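"""Readers and writers for embeddings, feature matrices, paths and results.

Tabular inputs are CSV/TSV with a header row; the delimiter is inferred
from the file extension (``.tsv``/``.txt`` -> tab, otherwise comma) and
can always be overridden. Sparse feature matrices arrive as MatrixMarket
``.mtx`` plus plain-text sidecar files with one name per line, and are
densified on load: the contract is correctness at desk scale, not
minimal memory.
"""

from __future__ import annotations

import logging
import os
from pathlib import Path
from typing import IO, Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .models import BackProjection, DrawnPath, Embedding2D, FeatureMatrix, FeatureRanking, SampledPath

logger = logging.getLogger(__name__)

__all__ = [
    "read_embedding",
    "read_features",
    "read_features_mtx",
    "read_path",
    "align",
    "write_embedding",
    "write_features",
    "write_path",
    "write_ranking",
    "write_profiles",
    "write_bin_map",
]


def _infer_sep(source, sep: str | None) -> str:
    if sep is not None:
        return sep
    name = getattr(source, "name", None) or (source if isinstance(source, (str, os.PathLike)) else "")
    suffix = Path(str(name)).suffix.lower()
    return "\t" if suffix in {".tsv", ".txt", ".tab"} else ","


def _read_table(source, sep: str | None) -> pd.DataFrame:
    return pd.read_csv(
        source,
        sep=_infer_sep(source, sep),
        dtype={0: str},
        header=0,
        float_precision="round_trip",  # bit-exact CSV round-trips
    )


def _require_columns(df: pd.DataFrame, cols: Sequence[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(
            f"{what} is missing column(s) {missing}; found {list(df.columns)}"
        )


def _numeric_column(df: pd.DataFrame, col: str, what: str) -> np.ndarray:
    raw = df[col]
    vals = pd.to_numeric(raw, errors="coerce").to_numpy(dtype=float)
    bad = np.flatnonzero(~np.isfinite(vals))
    if bad.size:
        row = int(bad[0])
        raise ValueError(
            f"{what}: non-numeric or missing value in column {col!r} at data row {row}"
            f" (value {raw.iloc[row]!r})"
        )
    return vals


def read_embedding(
    source: str | os.PathLike | IO[str],
    *,
    id_col: str = "id",
    x_col: str = "x",
    y_col: str = "y",
    sep: str | None = None,
) -> Embedding2D:
    """Read a 2D embedding table (one row per sample: id, x, y)."""
    df = _read_table(source, sep)
    _require_columns(df, [id_col, x_col, y_col], "embedding table")
    ids = df[id_col].astype(str).tolist()
    x = _numeric_column(df, x_col, "embedding table")
    y = _numeric_column(df, y_col, "embedding table")
    return Embedding2D(ids, np.column_stack([x, y]))


def read_features(
    source: str | os.PathLike | IO[str],
    *,
    sep: str | None = None,
) -> FeatureMatrix:
    """Read a dense feature table: first column sample id, one column per feature."""
    df = _read_table(source, sep)
    if df.shape[1] < 2:
        raise ValueError("feature table needs an id column plus at least one feature")
    id_col = df.columns[0]
    ids = df[id_col].astype(str).tolist()
    names = [str(c) for c in df.columns[1:]]
    cols = [_numeric_column(df, c, "feature table") for c in df.columns[1:]]
    return FeatureMatrix(ids, names, np.column_stack(cols))


def _read_names(path: str | os.PathLike, what: str) -> list[str]:
    with open(path, "r", encoding="utf-8") as fh:
        names = [line.strip() for line in fh if line.strip()]
    if not names:
        raise ValueError(f"{what} sidecar {path!s} is empty")
    return names


def read_features_mtx(
    mtx_path: str | os.PathLike,
    features_path: str | os.PathLike,
    samples_path: str | os.PathLike,
    *,
    orientation: str = "samples_by_features",
) -> FeatureMatrix:
    """Read a sparse MatrixMarket feature matrix with name sidecars.

    ``orientation`` says how the MTX is laid out: ``samples_by_features``
    (rows are samples) or ``features_by_samples`` (rows are features, the
    common genomics convention); the latter is transposed on load.
    """
    if orientation not in ("samples_by_features", "features_by_samples"):
        raise ValueError(f"unknown orientation {orientation!r}")
    mat = scipy.io.mmread(os.fspath(mtx_path))
    dense = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat, dtype=float)
    if orientation == "features_by_samples":
        dense = dense.T
    features = _read_names(features_path, "feature")
    samples = _read_names(samples_path, "sample")
    if dense.shape != (len(samples), len(features)):
        raise ValueError(
            f"matrix is {dense.shape[0]} samples x {dense.shape[1]} features under "
            f"orientation {orientation!r}, but sidecars name {len(samples)} samples "
            f"and {len(features)} features"
        )
    return FeatureMatrix(samples, features, dense)


def read_path(
    source: str | os.PathLike | IO[str],
    *,
    x_col: str = "x",
    y_col: str = "y",
    sep: str | None = None,
) -> DrawnPath:
    """Read an ordered path of 2D vertices; row order is traversal order."""
    df = _read_table(source, sep)
    _require_columns(df, [x_col, y_col], "path table")
    x = _numeric_column(df, x_col, "path table")
    y = _numeric_column(df, y_col, "path table")
    return DrawnPath(np.column_stack([x, y]))


def align(emb: Embedding2D, fm: FeatureMatrix) -> tuple[Embedding2D, FeatureMatrix]:
    """Reorder the feature matrix to the embedding's sample order.

    Alignment is by sample id, not row position: real exports frequently
    reorder rows. The embedding's order wins.
    """
    emb_ids = set(emb.sample_ids)
    fm_ids = set(fm.sample_ids)
    if emb_ids != fm_ids:
        only_emb = sorted(emb_ids - fm_ids)[:10]
        only_fm = sorted(fm_ids - emb_ids)[:10]
        parts = []
        if only_emb:
            parts.append(f"only in embedding: {only_emb}")
        if only_fm:
            parts.append(f"only in features: {only_fm}")
        raise ValueError("sample id mismatch; " + "; ".join(parts))
    if emb.sample_ids == fm.sample_ids:
        return emb, fm
    pos = {s: i for i, s in enumerate(fm.sample_ids)}
    order = np.array([pos[s] for s in emb.sample_ids])
    return emb, FeatureMatrix(emb.sample_ids, fm.feature_names, fm.values[order])


# ---------------------------------------------------------------------------
# writers


def write_embedding(emb: Embedding2D, sink, *, sep: str | None = None) -> None:
    df = pd.DataFrame({"id": list(emb.sample_ids), "x": emb.coords[:, 0], "y": emb.coords[:, 1]})
    df.to_csv(sink, sep=_infer_sep(sink, sep), index=False, float_format="%.17g")


def write_features(fm: FeatureMatrix, sink, *, sep: str | None = None) -> None:
    df = pd.DataFrame(fm.values, columns=list(fm.feature_names))
    df.insert(0, "id", list(fm.sample_ids))
    df.to_csv(sink, sep=_infer_sep(sink, sep), index=False, float_format="%.17g")


def write_path(path: DrawnPath, sink, *, sep: str | None = None) -> None:
    df = pd.DataFrame({"x": path.vertices[:, 0], "y": path.vertices[:, 1]})
    df.to_csv(sink, sep=_infer_sep(sink, sep), index=False, float_format="%.17g")


def write_ranking(ranking: FeatureRanking, top_k: int, sink) -> None:
    """Write the top ``top_k`` ranking rows as TSV (rank, feature, score, metric).

    ``top_k`` larger than the number of features is clamped with a note.
    Scores are printed in full double precision (repr round-trip).
    """
    d = len(ranking)
    if top_k > d:
        logger.info("top_k=%d exceeds %d features; clamping", top_k, d)
    rows = ranking.top(top_k)
    df = pd.DataFrame(
        {
            "rank": [e.rank for e in rows],
            "feature": [e.feature_name for e in rows],
            "score": [repr(e.score) for e in rows],
            "metric": ranking.metric,
        }
    )
    df.to_csv(sink, sep="\t", index=False)


def write_profiles(
    bp: BackProjection,
    sp: SampledPath,
    feature_names: Sequence[str],
    features: Iterable[str],
    sample_ids: Sequence[str],
    sink,
) -> None:
    """Write per-bin profiles for selected features as TSV.

    Columns: bin, t, sample_id, then one column per requested feature —
    the plot-ready data behind per-feature trajectory displays.
    """
    features = list(features)
    index = {name: j for j, name in enumerate(feature_names)}
    unknown = [f for f in features if f not in index]
    if unknown:
        raise ValueError(
            f"unknown feature(s) {unknown}; available: {list(feature_names)[:20]}"
            + ("..." if len(feature_names) > 20 else "")
        )
    df = pd.DataFrame(
        {
            "bin": np.arange(bp.n_bins),
            "t": sp.t,
            "sample_id": [sample_ids[i] for i in bp.bin_to_sample],
        }
    )
    for f in features:
        df[f] = bp.profiles[:, index[f]]
    df.to_csv(sink, sep="\t", index=False)


def write_bin_map(bp: BackProjection, sp: SampledPath, sample_ids: Sequence[str], sink) -> None:
    """Audit dump of the bin -> sample mapping (the samples actually used)."""
    df = pd.DataFrame(
        {
            "bin": np.arange(bp.n_bins),
            "t": sp.t,
            "sample_index": bp.bin_to_sample,
            "sample_id": [sample_ids[i] for i in bp.bin_to_sample],
        }
    )
    df.to_csv(sink, sep="\t", index=False)
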