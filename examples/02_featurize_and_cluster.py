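"""From waveforms to clustered 2-D embedding to path length.

Synthesizes three distinct syllable types (20 renditions each), runs the
imaging featurization (STFT -> blue-white-red spectrogram -> 28x28x3 ->
2352-vector), z-scores, embeds in 2-D, clusters with k-means and the
density method, and computes the bird's minimum path length.
"""

import numpy as np

from songpath import (
    FeatureMatrix,
    SyllableSpec,
    centroids,
    cluster_syllables,
    embed_2d,
    featurize_waveform,
    min_path_length,
    synth_syllable,
    zscore_matrix,
)

types = [
    dict(f0_start_hz=700, f0_end_hz=900, n_harmonics=3),
    dict(f0_start_hz=2600, f0_end_hz=2600, n_harmonics=1),
    dict(f0_start_hz=5200, f0_end_hz=3800, noise_fraction=0.3),
]
X, ids = [], []
for ti, params in enumerate(types):
    for j in range(20):
        spec = SyllableSpec(id=f"type{ti}_{j}", duration_s=0.08,
                            rng_seed=100 * ti + j, **params)
        X.append(featurize_waveform(synth_syllable(spec)))
        ids.append(spec.id)

m = zscore_matrix(FeatureMatrix(X=np.array(X), ids=ids))
print(f"feature matrix: {m.n} syllables x {m.X.shape[1]} pixel features")

e = embed_2d(m, seed=42)  # UMAP; method="pca" is the manifold-free fallback
km = cluster_syllables(e, method="kmeans", k=3)
db = cluster_syllables(e, method="density", min_cluster_size=5)
print(f"k-means found {km.k} clusters, density method found {db.k} "
      f"({np.sum(db.labels == -1)} noise syllables)")

cs = centroids(e, km)
for metric in ("euclidean", "manhattan", "cosine", "chebyshev"):
    res = min_path_length(cs, metric=metric)
    print(f"  {metric:<10} min path = {res.min_path:8.3f}  "
          f"(best order {res.argmin_order} of {res.n_orders_considered})")
# The minimum path length is the bird-level song-complexity score: the
# shortest route through all syllable-cluster centroids in embedding space.
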