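"""Seeded generators for fixtures with known ground truth.

Three constructions cover the pipeline's intended use cases without any
downloads or external embedding tools:

* a Swiss-roll point cloud with its analytically "unrolled" 2D embedding
  (the latent angle and height), so the full pipeline runs end to end
  with a known latent parameter;
* a planted-trajectory matrix: samples ordered along a latent parameter
  u, a 2D curve embedding of u, a handful of signal features that are
  smooth or sinusoidal functions of u, and many noise features with
  matched marginal variance (so rankings reflect structure, not scale);
* two Gaussian clusters in 2D with marker features mean-shifted between
  them, the input for the back-and-forth (zigzag) cluster-comparison
  recipe.

Every generator is a pure function of its arguments including the seed.
Embeddings are analytic, never produced by UMAP/t-SNE, which keeps
recovery tests deterministic and dependency-free.
"""

from __future__ import annotations

import numpy as np

from .models import DrawnPath, Embedding2D, FeatureMatrix

__all__ = [
    "make_swiss_roll",
    "swiss_roll_embedding",
    "make_planted_trajectory",
    "make_two_cluster_spatial",
]


def make_swiss_roll(
    n: int = 500,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> tuple[FeatureMatrix, np.ndarray]:
    """Swiss-roll point cloud: (t cos t, h, t sin t) plus Gaussian noise.

    The roll angle t is uniform over [1.5*pi, 4.5*pi] and the height h
    uniform over [0, 10]. Returns the 3-feature matrix and the latent
    parameter per sample (the ground truth an embedding should recover).
    """
    if n < 10:
        raise ValueError(f"need at least 10 samples, got {n}")
    rng = np.random.default_rng(seed)
    t = np.sort(rng.uniform(1.5 * np.pi, 4.5 * np.pi, size=n))
    h = rng.uniform(0.0, 10.0, size=n)
    values = np.column_stack([t * np.cos(t), h, t * np.sin(t)])
    values += rng.normal(0.0, noise_sd, size=values.shape)
    ids = [f"s{i}" for i in range(n)]
    return FeatureMatrix(ids, ["roll_x", "height", "roll_z"], values), t


def swiss_roll_embedding(fm: FeatureMatrix, t: np.ndarray, h_col: str = "height") -> Embedding2D:
    """The analytically unrolled 2D embedding (t, h) of a Swiss roll.

    Uses the known latent parameter rather than any embedding algorithm,
    so the latent t is monotone along the first embedding axis by
    construction.
    """
    h = fm.values[:, fm.feature_names.index(h_col)]
    return Embedding2D(fm.sample_ids, np.column_stack([np.asarray(t, dtype=float), h]))


def _latent_curve(u: np.ndarray) -> np.ndarray:
    """A smooth, non-self-intersecting S-shaped 2D curve of the latent u."""
    x = 3.0 * u - 1.5
    y = np.sin(np.pi * u * 1.5) * 1.2
    return np.column_stack([x, y])


def make_planted_trajectory(
    n_samples: int = 500,
    n_features: int = 1000,
    n_signal: int = 10,
    signal_kind: str = "sinusoid",
    noise_sd: float = 0.1,
    seed: int = 0,
) -> tuple[Embedding2D, FeatureMatrix, DrawnPath, list[str]]:
    """Planted-signal fixture: few latent-driven features among many noise ones.

    Samples carry a latent parameter u ~ U(0, 1). The embedding places
    each sample on a smooth 2D curve of u plus small isotropic jitter
    (2% of the curve scale); the returned path traces the exact curve.
    Signal features are functions of u — sinusoids ``sin(2*pi*f*u + phi)``
    with frequencies cycling 1..5 (kind "sinusoid"), or monotone ramps of
    varying steepness (kind "smooth") — observed with Gaussian noise of
    sd ``noise_sd``. The remaining features are i.i.d. Gaussian noise
    whose marginal variance matches the signal features' total variance.
    Signal feature names (``sig_0`` ...) are returned for recovery tests.
    """
    if n_signal > n_features:
        raise ValueError("n_signal cannot exceed n_features")
    if n_samples < 10:
        raise ValueError(f"need at least 10 samples, got {n_samples}")
    if signal_kind not in ("sinusoid", "smooth"):
        raise ValueError(f"unknown signal kind {signal_kind!r}")
    rng = np.random.default_rng(seed)
    u = np.sort(rng.uniform(0.0, 1.0, size=n_samples))

    curve = _latent_curve(u)
    jitter_scale = 0.02 * (curve.max(axis=0) - curve.min(axis=0)).max()
    emb_coords = curve + rng.normal(0.0, jitter_scale, size=curve.shape)

    signals = np.empty((n_samples, n_signal))
    for j in range(n_signal):
        if signal_kind == "sinusoid":
            freq = 1 + j % 5
            phase = 2.0 * np.pi * j / max(n_signal, 1)
            clean = np.sin(2.0 * np.pi * freq * u + phase)
            clean_var = 0.5  # variance of a unit sinusoid over full cycles
        else:
            power = 1.0 + j % 3
            clean = np.sign(1 - 2 * (j % 2)) * u**power
            clean_var = float(np.var(clean))
        signals[:, j] = clean + rng.normal(0.0, noise_sd, size=n_samples)

    # noise features: marginal variance matched to the signal features'
    matched_sd = float(np.sqrt((0.5 if signal_kind == "sinusoid" else clean_var) + noise_sd**2)) if n_signal else 1.0
    noise = rng.normal(0.0, matched_sd, size=(n_samples, n_features - n_signal))

    values = np.column_stack([signals, noise]) if n_signal else noise
    signal_names = [f"sig_{j}" for j in range(n_signal)]
    noise_names = [f"noise_{j}" for j in range(n_features - n_signal)]
    ids = [f"s{i}" for i in range(n_samples)]
    fm = FeatureMatrix(ids, signal_names + noise_names, values)
    emb = Embedding2D(ids, emb_coords)
    path = DrawnPath(_latent_curve(np.linspace(0.0, 1.0, 200)))
    return emb, fm, path, signal_names


def make_two_cluster_spatial(
    n_per_cluster: int = 150,
    separation: float = 6.0,
    n_features: int = 500,
    n_marker: int = 10,
    seed: int = 0,
    marker_shift: float = 3.0,
) -> tuple[Embedding2D, FeatureMatrix, np.ndarray]:
    """Two adjacent 2D clusters with mean-shifted marker features.

    Clusters are unit-variance Gaussian blobs centred ``separation``
    apart on the x axis. Marker features differ in mean by
    ``marker_shift`` between clusters; all other features are standard
    normal in both. Returns the embedding, the matrix (markers first,
    named ``marker_0`` ...) and the 0/1 cluster label per sample.
    Designed to be consumed by :func:`pathrank.paths.zigzag_path` +
    :func:`pathrank.metrics.rank_features`.
    """
    if n_marker > n_features:
        raise ValueError("n_marker cannot exceed n_features")
    if n_per_cluster < 5:
        raise ValueError("need at least 5 samples per cluster")
    rng = np.random.default_rng(seed)
    n = 2 * n_per_cluster
    labels = np.repeat([0, 1], n_per_cluster)
    centers = np.array([[0.0, 0.0], [separation, 0.0]])
    coords = centers[labels] + rng.normal(0.0, 1.0, size=(n, 2))

    values = rng.normal(0.0, 1.0, size=(n, n_features))
    values[:, :n_marker] += np.where(labels[:, None] == 1, marker_shift, 0.0)

    ids = [f"c{labels[i]}_{i}" for i in range(n)]
    names = [f"marker_{j}" for j in range(n_marker)] + [
        f"bg_{j}" for j in range(n_features - n_marker)
    ]
    return Embedding2D(ids, coords), FeatureMatrix(ids, names, values), labels
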