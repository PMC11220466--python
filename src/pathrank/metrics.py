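"""Periodicity scores for feature profiles read along a path.

Two metrics are provided. The lag-k autocorrelation

    r_k = sum_{t=k+1..n} (x_t - xbar)(x_{t-k} - xbar) / sum_{t=1..n} (x_t - xbar)^2

measures how strongly a profile repeats at a fixed scale; it needs the
lag chosen in advance (default 22, close to sqrt of the default 512
bins). The FFT score is parameter-free: take the magnitudes |F_m| of the
discrete Fourier transform

    F_m = sum_{n=0..k-1} x_n [cos(2*pi*n*m/k) - i sin(2*pi*n*m/k)]

omit the constant m=0 term (we only care about periodic behaviour), and
form a harmonic sum S = sum_n m_(n) / n over the magnitudes sorted in
descending order, so a few large, slow oscillations score far higher
than many small, fast ones. An alternative weighting divides each
magnitude by its frequency index instead of its descending-sort position,
making the "slow motions dominate" rationale literal; both readings are
available via ``fft_weighting``.

Constant profiles score exactly 0 under both metrics: a feature that
does not vary along the path is definitionally non-discriminative.
"""

from __future__ import annotations

import numpy as np

from .models import (
    BackProjection,
    FeatureRanking,
    RankingConfig,
    RankingEntry,
)

__all__ = [
    "autocorrelation",
    "dft_magnitudes",
    "fft_score",
    "normalize_profile",
    "rank_features",
]


def _is_pow2(k: int) -> bool:
    return k >= 1 and (k & (k - 1)) == 0


def autocorrelation(x: np.ndarray, lag: int) -> float:
    """Lag-``lag`` autocorrelation of a sequence, in [-1, 1].

    Returns 0 for a constant sequence (zero variance).
    """
    x = np.asarray(x, dtype=float).ravel()
    n = x.shape[0]
    if not (1 <= lag < n):
        raise ValueError(f"lag must satisfy 1 <= lag < n, got lag={lag}, n={n}")
    if np.all(x == x[0]):  # constant: exactly 0, not 0/0
        return 0.0
    centered = x - x.mean()
    denom = float(centered @ centered)
    if denom == 0.0:
        return 0.0
    num = float(centered[lag:] @ centered[:-lag])
    return num / denom


def dft_magnitudes(x: np.ndarray, *, force_direct: bool = False) -> np.ndarray:
    """Non-DC DFT magnitudes |F_1| .. |F_{k-1}| of a real sequence.

    Power-of-2 lengths use the FFT fast path; other lengths (or
    ``force_direct``) evaluate the transform directly in O(k^2). For real
    input the result is conjugate-symmetric: m_j == m_{k-j}.
    """
    x = np.asarray(x, dtype=float).ravel()
    k = x.shape[0]
    if k < 2:
        raise ValueError(f"sequence length must be >= 2, got {k}")
    if _is_pow2(k) and not force_direct:
        spectrum = np.fft.fft(x)
    else:
        m = np.arange(k)
        # direct evaluation of the transform matrix; fine at desk scale
        spectrum = np.exp(-2j * np.pi * np.outer(m, m) / k) @ x.astype(complex)
    return np.abs(spectrum[1:])


def fft_score(
    x: np.ndarray,
    weighting: str = "descending_magnitude",
    *,
    force_direct: bool = False,
) -> float:
    """Harmonic sum of the non-DC spectral magnitudes of a profile.

    ``descending_magnitude`` (default): sort magnitudes descending and sum
    m_(n)/n, n = 1..k-1. ``frequency_index``: sum m_n/n over the frequency
    index without sorting. Non-negative; 0 iff the sequence is constant.
    The full spectrum (both conjugate-symmetric halves) is summed; this
    doubles every feature's score identically and cannot change rankings.
    """
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size >= 2 and np.all(arr == arr[0]):
        _harmonic_sum(np.zeros((1, 1)), weighting)  # still validate weighting
        return 0.0
    mags = dft_magnitudes(arr, force_direct=force_direct)
    return float(_harmonic_sum(mags[None, :], weighting)[0])


def _harmonic_sum(mags: np.ndarray, weighting: str) -> np.ndarray:
    """Row-wise harmonic sum over a (rows x k-1) magnitude array."""
    weights = 1.0 / np.arange(1, mags.shape[1] + 1)
    if weighting == "descending_magnitude":
        ordered = -np.sort(-mags, axis=1)
        return ordered @ weights
    if weighting == "frequency_index":
        return mags @ weights
    raise ValueError(f"unknown fft weighting {weighting!r}")


def normalize_profile(x: np.ndarray, mode: str = "none") -> np.ndarray:
    """Optional per-profile normalization: none (default), zscore, or minmax.

    Constant sequences map to all zeros under both non-trivial modes.
    """
    x = np.asarray(x, dtype=float)
    if mode == "none":
        return x
    if mode == "zscore":
        sd = x.std(axis=0)
        centered = x - x.mean(axis=0)
        return np.divide(centered, sd, out=np.zeros_like(centered), where=sd > 0)
    if mode == "minmax":
        lo, hi = x.min(axis=0), x.max(axis=0)
        span = hi - lo
        return np.divide(x - lo, span, out=np.zeros_like(x, dtype=float), where=span > 0)
    raise ValueError(f"unknown normalization {mode!r}")


def _score_columns(profiles: np.ndarray, cfg: RankingConfig) -> np.ndarray:
    constant = np.ptp(profiles, axis=0) == 0  # scored 0 under both metrics
    if cfg.metric == "autocorrelation":
        centered = profiles - profiles.mean(axis=0)
        denom = np.einsum("ij,ij->j", centered, centered)
        num = np.einsum("ij,ij->j", centered[cfg.lag :], centered[: -cfg.lag])
        scores = np.divide(num, denom, out=np.zeros_like(num), where=denom > 0)
    else:  # fft metric
        k = profiles.shape[0]
        if _is_pow2(k):
            spectrum = np.fft.fft(profiles, axis=0)
            mags = np.abs(spectrum[1:]).T
        else:
            m = np.arange(k)
            mags = np.abs(np.exp(-2j * np.pi * np.outer(m, m) / k) @ profiles)[1:].T
        scores = _harmonic_sum(mags, cfg.fft_weighting)
    scores[constant] = 0.0
    return scores


def rank_features(
    bp: BackProjection,
    feature_names,
    cfg: RankingConfig | None = None,
) -> FeatureRanking:
    """Score every feature's profile and sort descending.

    Normalization (if any) is applied per profile before scoring. Ties
    keep feature input order; ranks run 1..d with no gaps. The whole
    computation is deterministic.
    """
    if cfg is None:
        cfg = RankingConfig()
    names = [str(f) for f in feature_names]
    if len(names) != bp.n_features:
        raise ValueError(
            f"{len(names)} feature names for {bp.n_features} profile columns"
        )
    if cfg.metric == "autocorrelation" and cfg.lag >= bp.n_bins:
        raise ValueError(
            f"lag {cfg.lag} must be smaller than the profile length {bp.n_bins}"
        )
    profiles = normalize_profile(bp.profiles, cfg.normalization)
    scores = _score_columns(profiles, cfg)
    order = np.argsort(-scores, kind="stable")  # descending, ties keep input order
    entries = tuple(
        RankingEntry(names[j], float(scores[j]), rank)
        for rank, j in enumerate(order, start=1)
    )
    return FeatureRanking(entries=entries, metric=cfg.metric, params=cfg)
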