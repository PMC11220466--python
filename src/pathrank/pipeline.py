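"""One-call composition of the full draw-then-rank workflow."""

from __future__ import annotations

from .backproject import run_backprojection
from .io import align
from .metrics import rank_features
from .models import (
    BackProjection,
    DrawnPath,
    Embedding2D,
    FeatureMatrix,
    FeatureRanking,
    RankingConfig,
    SampledPath,
)

__all__ = ["rank_along_path"]


def rank_along_path(
    emb: Embedding2D,
    fm: FeatureMatrix,
    path: DrawnPath,
    cfg: RankingConfig | None = None,
) -> tuple[SampledPath, BackProjection, FeatureRanking]:
    """Align, back-project and rank in one call.

    Returns the resampled path, the back-projection along it, and the
    feature ranking under ``cfg`` (defaults: 512 bins, FFT score with
    descending-magnitude weighting).
    """
    if cfg is None:
        cfg = RankingConfig()
    emb, fm = align(emb, fm)
    sampled, bp = run_backprojection(emb, fm, path, cfg)
    ranking = rank_features(bp, fm.feature_names, cfg)
    return sampled, bp, ranking
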