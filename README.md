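# pathrank

Rank original features by how periodically they behave along a path
drawn on a 2D embedding.

Low-dimensional embeddings (PCA, t-SNE, UMAP) make large biological
datasets visible, but their axes say nothing directly about the original
features. Given a trajectory of interest — a differentiation branch in a
single-cell map, a border between two spatial-transcriptomics clusters —
an analyst wants to know *which genes (features) drive position along
that trajectory*. `pathrank` answers this headlessly: you supply the
embedding, the paired feature matrix, and an ordered polyline of path
vertices in embedding coordinates; it back-projects the path to the
original space and sorts the features.

The pipeline:

1. **Rescale** each embedding axis independently to [0, 1] (the geometry
   of a square display) and apply the same map to the path.
2. **Resample** the path to `n_bins` points equally spaced by arc length
   (default 512), normalizing away drawing speed and vertex density.
3. **Back-project**: each path point takes the feature vector of its
   exact Euclidean nearest embedding sample, giving each feature a
   length-`n_bins` *profile* along the path.
4. **Score** every profile for periodicity and sort descending:

   * lag-*k* autocorrelation (default *k* = 22 ≈ √512):

     r_k = Σ_{t=k+1..n} (x_t − x̄)(x_{t−k} − x̄) / Σ_{t=1..n} (x_t − x̄)²

   * FFT score: take the DFT magnitudes m₁..m_{k−1} (the constant m₀
     term is omitted) and form the harmonic sum S = Σₙ m₍ₙ₎ · 1/n over
     magnitudes sorted descending — parameter-free, and dominated by a
     few large, slow oscillations rather than many small fast ones.

A feature that varies smoothly or periodically along the path scores
high; i.i.d. noise spreads its spectral energy thinly and scores low.
A path that zigzags back and forth between two clusters turns any
between-cluster difference into a periodic profile, so the same scores
also find cluster markers without labels.

## Worked example

```python
from pathrank import RankingConfig, rank_along_path, synthetic

emb, fm, path, signal_names = synthetic.make_planted_trajectory(
    n_samples=500, n_features=1000, n_signal=10, signal_kind="sinusoid", seed=7
)
sampled, bp, ranking = rank_along_path(emb, fm, path, RankingConfig(metric="fft"))
for e in ranking.top(5):
    print(f"rank {e.rank}  {e.feature_name}  score {e.score:.1f}")
```

prints

```
rank 1  sig_6  score 452.6
rank 2  sig_7  score 445.5
rank 3  sig_2  score 442.2
rank 4  sig_1  score 442.0
rank 5  sig_3  score 420.7
```

All ten planted sinusoidal features land in the top 20 of the 1000
(median noise-feature score: 255.8): the ranking recovers exactly the
features that are functions of the latent trajectory parameter. The
`examples/` directory has three narrative scripts — a planted
trajectory, a Swiss-roll walkthrough, and zigzag cluster-marker
discovery — each printing the numbers it computes.

## Command line

```bash
pathrank rank --embedding emb.csv --features expr.csv --path path.csv \
    --metric fft --bins 512 --top 100 --out results/run
pathrank demo --demo planted --seed 1 --out results/demo
```

`rank` writes `PREFIX.ranking.tsv` (rank, feature, score, metric),
`PREFIX.profiles.tsv` (per-bin values of the top features — plot-ready),
`PREFIX.bins.tsv` (bin → sample map), and `PREFIX.manifest.json`
(parameters + input checksums). Outputs are byte-identical for identical
inputs and flags. Feature matrices may also be MatrixMarket `.mtx` with
`--feature-names`/`--sample-names` sidecars. A non-power-of-2 `--bins`
with the FFT metric warns and uses a direct DFT instead of the fast path.

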