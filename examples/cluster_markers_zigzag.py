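"""Find features discriminating two clusters with a back-and-forth path.

A path that zigzags between two clusters converts any between-cluster
difference into a periodic profile: a feature that is high in one
cluster and low in the other oscillates once per crossing. The
periodicity metrics then surface cluster markers without any labels or
differential testing.
"""

from pathrank import rank_along_path, synthetic, zigzag_path

emb, fm, labels = synthetic.make_two_cluster_spatial(
    n_per_cluster=150, separation=6.0, n_features=500, n_marker=10, seed=0
)
centroid_a = emb.coords[labels == 0].mean(axis=0)
centroid_b = emb.coords[labels == 1].mean(axis=0)
path = zigzag_path([tuple(centroid_a)], [tuple(centroid_b)], cycles=8)

sampled, bp, ranking = rank_along_path(emb, fm, path)
print("top 12 features along the zigzag path (FFT score):")
for e in ranking.top(12):
    flag = "MARKER" if e.feature_name.startswith("marker_") else ""
    print(f"  rank {e.rank:>2}  {e.feature_name:<10}  score {e.score:7.1f}  {flag}")

top20 = {e.feature_name for e in ranking.top(20)}
markers = {f for f in fm.feature_names if f.startswith("marker_")}
print(f"\nmarkers recovered in the top 20: {len(top20 & markers)}/{len(markers)}")
# The 16 cluster crossings plant a ~8-cycle oscillation in every marker's
# profile; background features have no mean shift and stay near the noise
# floor.
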