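# Methods

## The model

`pathrank` treats a user-supplied path on a 2D embedding as a hypothesis
about a 1D manifold in the original feature space. Reading each feature
along the path produces a sequence (its *profile*), and the question
"which features determine position along this path" becomes a
signal-detection problem on those sequences: features coupled to the
latent coordinate vary smoothly or periodically along it, while features
unrelated to it look like white noise. The scores are a fast filter —
ranks only, with no distributional assumptions, no significance
machinery and no learned model.

Assumptions worth stating: the embedding preserves enough local
neighbourhood structure that nearest-neighbour back-projection is
meaningful; samples are dense enough along the drawn path that adjacent
bins usually map to nearby samples; and the path's traversal order is
meaningful (the same vertices in reverse give the reversed profiles —
harmless for the spectra, but the profile outputs differ).

## Pipeline geometry

**Rescaling.** Each embedding axis is mapped linearly to [0, 1] using
that axis's own min/max, and the identical transform is applied to the
path. This mirrors drawing on a square display and deliberately changes
the metric when the axes have unequal ranges: distances are measured in
display geometry, not native embedding units. A constant axis maps to
0.5. Path points outside the data's bounding box simply land outside
[0, 1].

**Resampling.** The vertex polyline is resampled to `n_bins` points at
equal arc-length spacing `L/(n_bins − 1)`, endpoints inclusive —
endpoints are semantically meaningful (trajectory start/end) so both are
represented exactly. Interpolation is linear within segments, with no
smoothing of hand-drawn jitter. Repeated identical vertices (common in
raw pointer traces) are dropped, not errors; a path whose vertices all
coincide is an error. `n_bins` defaults to 512; the FFT metric's fast
path wants a power of 2, and other lengths fall back to a direct O(k²)
DFT with a warning — a performance concern, not a correctness one.

**Nearest neighbour.** Each sampled point takes the index of its exact
Euclidean nearest embedding sample in the rescaled frame, computed by a
blocked all-pairs distance scan (`scipy.spatial.distance.cdist` +
`argmin`). Exactness keeps the pipeline deterministic and testable
against a brute-force oracle; at the intended scale (≤ ~10⁵ samples,
512 bins) speed is not a constraint. Ties break to the lowest sample
index; duplicate embedding points resolve to the first occurrence.
Consecutive bins mapping to the same sample are kept — the metric input
is always exactly `n_bins` long.

## Scores

**Autocorrelation** at lag k (default 22, close to √512) measures
repetition at one scale. It is offset- and scale-invariant by
construction, bounded in [−1, 1], and for an exactly periodic,
per-period zero-mean sequence of period p (n a multiple of p) equals
(n − p)/n at lag p — e.g. 510/512 for the alternating ±1 sequence at
n = 512. The lag must be chosen in advance, so this metric suits users
with a scale hypothesis.

**FFT score** is the parameter-free default: the harmonic sum
S = Σₙ m₍ₙ₎/n over the non-DC magnitudes sorted descending. Sorting
descending means the weights 1, 1/2, 1/3… attach to the largest
magnitudes, so a profile concentrated in a few sinusoids outscores one
with the same energy spread across many. The DC term m₀ is omitted —
only periodic behaviour matters. Both conjugate-symmetric halves of the
spectrum are summed; this doubles every score identically and cannot
affect the ranking. The score scales linearly with the profile
(S(c·x) = |c|·S(x)), so scores reflect variance as well as shape;
optional z-score or min–max profile normalization (off by default, as
raw values are what the interactive workflow scores) removes the scale
dependence when features live on wildly different scales.

The sum-over-descending-magnitudes formula and the "lower frequencies
weigh more" rationale pull in different directions; both readings are
implemented. `descending_magnitude` (default) is the literal formula;
`frequency_index` divides each magnitude by its frequency index without
sorting, making low frequencies dominate explicitly. Neither is asserted
to be the uniquely correct reading.

**Degenerate inputs.** Constant profiles score exactly 0 under both
metrics (constancy is detected by value comparison, not by a variance
threshold, so non-representable constants like 4.2 still return exactly
0 rather than a 0/0 roundoff artifact). Ties in the final ranking keep
feature input order; ranks run 1..d with no gaps.

## Re-tracing invariance

Repeating a path should not change the ranking. For the FFT score this
is a theorem about sequence repetition: if a profile x of length k is
repeated q times, the DFT of the repetition is q·X at multiples of q and
zero elsewhere, so the sorted magnitude list is the original's scaled by
q padded with zeros, and every feature's harmonic sum scales by exactly
q — the order, including ties, is untouched.

The theorem applies to the *bin sequence*, and
`backproject.repeat_backprojection` implements exactly that (the bin →
sample sequence tiled q times). Re-tracing modelled purely geometrically
— concatenating the polyline q times (`paths.repeat_path`) and
resampling with q·n_bins points — only approximates it: under the
endpoint-inclusive convention the uniform arc grid of the concatenated
path is phase-shifted by up to half a bin relative to the original, so a
fraction of bins snap to different (adjacent) samples and scores of
near-tied noise features can reorder. Both routes are provided;
invariance claims are tested on the exact route, and the geometric route
is tested for its geometric contract only.

## Synthetic fixtures

The generators produce the study conditions used throughout the tests;
all are pure functions of their arguments, seed included.

* **Swiss roll** (default n = 500, noise sd 0.05): points
  (t·cos t, h, t·sin t), t uniform on [1.5π, 4.5π], h uniform on
  [0, 10]. The companion embedding is the analytic unrolling (t, h) —
  no embedding algorithm runs in the test path, so recovery checks are
  deterministic.
* **Planted trajectory** (defaults 500 samples × 1000 features, 10
  signal features, observation noise sd 0.1): latent u ~ U(0, 1) sorted;
  embedding is a smooth S-curve of u plus isotropic jitter at 2% of the
  curve scale; signal features are sinusoids sin(2πfu + φ) with
  frequencies cycling 1..5 (or monotone ramps for the "smooth" kind);
  the remaining features are i.i.d. Gaussian with marginal variance
  matched to the signal features' (sinusoid variance 1/2 plus noise
  variance), so rankings reflect structure, not scale. The returned path
  traces the exact noise-free curve.
* **Two clusters** (defaults 150 per cluster, separation 6, 500
  features, 10 markers with mean shift 3): unit-variance Gaussian blobs;
  markers differ in mean between clusters, everything else is standard
  normal in both. Consumed by `zigzag_path` between the cluster
  centroids (8 cycles in the examples), which plants one oscillation per
  crossing in every marker's profile.

What these fixtures do **not** emulate: count noise (negative binomial,
dropout), batch effects, embedding distortions from a real UMAP/t-SNE
run, or correlated noise features. Passing the recovery tests shows the
geometry and scoring machinery work as specified; it does not certify
performance on real single-cell or spatial data, where signal shapes are
less clean and the embedding itself can mislead.

## Numerical choices

* Exact CSV round-trips: floats are written with `%.17g` and parsed with
  pandas' round-trip parser.
* Resampling tolerance 1e-9 relative on arc spacing; endpoints exact by
  pinning.
* DFT fast path (`numpy.fft`) and the direct O(k²) fallback agree to
  1e-8 relative; the autocorrelation implementation matches a literal
  double-loop evaluation to 1e-12.
* Missing or non-finite values are hard load errors, never imputed.
* Sparse MTX input is densified on load; the target scale is
  desk-sized matrices, not out-of-core data.
* No randomness exists anywhere in the pipeline itself; CLI outputs,
  manifest included, are byte-identical across reruns (the manifest
  records parameters and input checksums, deliberately no timestamp).

## Problem sizes

Tests and the acceptance script run the planted fixture at its default
500 × 1000 size (10–20 seeds where a rate is measured), nearest-
neighbour checks at 500 embedding points × 512 bins, and oracle
comparisons at sequence lengths 8–512 — sizes chosen so the full suite
completes in seconds while still exercising the default 512-bin
pipeline.

## Known limitations

* Back-projection is hard nearest-neighbour; no kernel-weighted
  averaging over k > 1 neighbours, and no out-of-sample inversion of the
  embedding.
* Scores are unnormalized ranks with no p-values; the variance of a
  feature directly inflates its FFT score unless normalization is
  enabled.
* The autocorrelation metric requires a sensible lag; the default 22 is
  a heuristic tied to the default 512 bins.
* AnnData/HDF5 containers are not parsed; export to CSV/MTX first.
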