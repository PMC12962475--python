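"""2-D embedding, clustering, and centroid extraction for syllables.

The z-scored pixel feature matrix is projected to two dimensions (UMAP
by default, with a PCA fallback that keeps the rest of the pipeline
usable without the manifold step), clustered either by k-means or by
the density-based HDBSCAN method, and reduced to per-cluster centroids
that feed the path-length metric.

Cluster ids are relabeled by descending cluster size (ties broken by
first occurrence in row order) so repeated runs and both clustering
methods produce comparable label sets; density-method noise keeps the
conventional label -1 and is excluded from centroids.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from sklearn.cluster import HDBSCAN, KMeans
from sklearn.decomposition import PCA

from .featurize import FeatureMatrix

__all__ = [
    "Embedding2D",
    "Clustering",
    "CentroidSet",
    "embed_2d",
    "cluster_syllables",
    "centroids",
    "stability_report",
]

MIN_ROWS_FOR_EMBEDDING = 10


@dataclass(frozen=True)
class Embedding2D:
    """Per-syllable 2-D coordinates plus the parameters that made them."""

    coords: np.ndarray  # (n, 2)
    method: str  # "umap" | "pca"
    seed: int
    n_neighbors: int
    min_dist: float

    def __post_init__(self) -> None:
        c = np.asarray(self.coords, dtype=np.float64)
        if c.ndim != 2 or c.shape[1] != 2:
            raise ValueError(f"coords must be (n, 2), got {c.shape}")
        if not np.all(np.isfinite(c)):
            raise ValueError("embedding coordinates must be finite")
        object.__setattr__(self, "coords", c)

    @property
    def n(self) -> int:
        return self.coords.shape[0]


@dataclass(frozen=True)
class Clustering:
    """Cluster labels per syllable; -1 marks density-method noise."""

    labels: np.ndarray
    k: int
    method: str  # "kmeans" | "density"

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels, dtype=int)
        object.__setattr__(self, "labels", lab)
        non_noise = lab[lab >= 0]
        if self.k < 1:
            raise ValueError("clustering must contain at least one cluster")
        if non_noise.size and (non_noise.max() >= self.k):
            raise ValueError("labels inconsistent with k")


@dataclass(frozen=True)
class CentroidSet:
    """k cluster centroids in the 2-D embedding space."""

    centroids: np.ndarray  # (k, 2)
    cluster_sizes: np.ndarray  # (k,)
    aggregation: str  # "arithmetic" | "geometric"

    def __post_init__(self) -> None:
        c = np.asarray(self.centroids, dtype=np.float64)
        if c.ndim != 2 or c.shape[1] != 2 or c.shape[0] < 1:
            raise ValueError(f"centroids must be (k>=1, 2), got {c.shape}")
        if not np.all(np.isfinite(c)):
            raise ValueError("centroids must be finite")
        object.__setattr__(self, "centroids", c)
        object.__setattr__(
            self, "cluster_sizes", np.asarray(self.cluster_sizes, dtype=int)
        )

    @property
    def k(self) -> int:
        return self.centroids.shape[0]

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "cluster_id": np.arange(self.k),
                "x": self.centroids[:, 0],
                "y": self.centroids[:, 1],
                "size": self.cluster_sizes,
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, aggregation: str = "arithmetic") -> "CentroidSet":
        df = pd.read_csv(path).sort_values("cluster_id")
        return cls(
            centroids=df[["x", "y"]].to_numpy(dtype=np.float64),
            cluster_sizes=df["size"].to_numpy(dtype=int),
            aggregation=aggregation,
        )


def embed_2d(
    m: FeatureMatrix,
    seed: int = 42,
    n_neighbors: int = 15,
    min_dist: float = 0.1,
    method: str = "umap",
) -> Embedding2D:
    """Project a z-scored feature matrix to two dimensions.

    ``method="umap"`` runs UMAP with a fixed ``random_state`` so repeated
    calls are identical; ``method="pca"`` substitutes the first two
    principal components, which keeps every downstream stage exercisable
    without the manifold step (and is deterministic by construction).
    ``n_neighbors`` is shrunk with a warning when the matrix has fewer
    rows than neighbors.
    """
    if not m.zscored:
        raise ValueError("feature matrix must be z-scored before embedding")
    if m.n < MIN_ROWS_FOR_EMBEDDING:
        raise ValueError(
            f"need >= {MIN_ROWS_FOR_EMBEDDING} syllables to embed, got {m.n}"
        )
    if n_neighbors >= m.n:
        new = m.n - 1
        warnings.warn(
            f"n_neighbors={n_neighbors} >= n rows ({m.n}); shrinking to {new}",
            RuntimeWarning,
            stacklevel=2,
        )
        n_neighbors = new

    if method == "umap":
        import umap  # deferred: slow numba-backed import

        with warnings.catch_warnings():
            # umap warns that random_state disables parallelism; intended
            warnings.simplefilter("ignore")
            reducer = umap.UMAP(
                n_components=2,
                n_neighbors=n_neighbors,
                min_dist=min_dist,
                random_state=seed,
            )
            coords = np.asarray(reducer.fit_transform(m.X), dtype=np.float64)
    elif method == "pca":
        coords = PCA(n_components=2, random_state=seed).fit_transform(m.X)
    else:
        raise ValueError(f"unknown embedding method {method!r}")

    m.embedding = coords.copy()  # appended to the feature matrix
    return Embedding2D(
        coords=coords,
        method=method,
        seed=seed,
        n_neighbors=n_neighbors,
        min_dist=min_dist,
    )


def _relabel_by_size(labels: np.ndarray) -> tuple[np.ndarray, int]:
    """Relabel clusters 0..k-1 by descending size; keep -1 as noise.

    Ties in size break by first occurrence in row order, making the
    labeling invariant to how the backend numbered the clusters.
    """
    out = np.full_like(labels, -1)
    ids = [c for c in pd.unique(labels) if c >= 0]
    sizes = {c: int((labels == c).sum()) for c in ids}
    first = {c: int(np.argmax(labels == c)) for c in ids}
    order = sorted(ids, key=lambda c: (-sizes[c], first[c]))
    for new, old in enumerate(order):
        out[labels == old] = new
    return out, len(order)


def cluster_syllables(
    e: Embedding2D,
    method: str = "kmeans",
    k: int | None = None,
    min_cluster_size: int = 5,
    seed: int = 0,
) -> Clustering:
    """Cluster the 2-D embedding by k-means or density (HDBSCAN).

    k-means requires ``k``; the density method discovers the number of
    clusters and may assign noise (-1).  Either way labels are renumbered
    by descending cluster size for determinism.
    """
    X = e.coords
    if method == "kmeans":
        if k is None:
            raise ValueError("k-means requires k")
        if k > e.n:
            raise ValueError(f"k={k} exceeds number of points {e.n}")
        raw = KMeans(n_clusters=k, random_state=seed, n_init=10).fit_predict(X)
    elif method == "density":
        raw = HDBSCAN(min_cluster_size=min_cluster_size, copy=True).fit_predict(X)
        if not np.any(raw >= 0):
            raise ValueError(
                "density clustering found no clusters (all noise); "
                "lower min_cluster_size"
            )
    else:
        raise ValueError(f"unknown clustering method {method!r}")
    labels, k_found = _relabel_by_size(np.asarray(raw, dtype=int))
    return Clustering(labels=labels, k=k_found, method=method)


def centroids(
    e: Embedding2D, c: Clustering, aggregation: str = "arithmetic", shift: bool = True
) -> CentroidSet:
    """Per-cluster centroid of embedding coordinates.

    ``arithmetic`` (default) is the coordinate mean.  ``geometric``
    computes the per-axis geometric mean; because embedding coordinates
    can be negative (where a geometric mean is undefined), coordinates
    are first shifted per axis so the global minimum sits at +1, the
    geometric mean is taken, and the shift is subtracted back.  Already
    strictly positive axes are used as-is.  With ``shift=False``,
    non-positive coordinates are rejected instead.  Noise points
    (label -1) are excluded.
    """
    if c.labels.shape[0] != e.n:
        raise ValueError("clustering does not match embedding size")
    X = e.coords
    cents = np.empty((c.k, 2))
    sizes = np.empty(c.k, dtype=int)

    if aggregation == "arithmetic":
        for j in range(c.k):
            pts = X[c.labels == j]
            cents[j] = pts.mean(axis=0)
            sizes[j] = len(pts)
    elif aggregation == "geometric":
        offsets = np.zeros(2)
        for ax in range(2):
            lo = X[c.labels >= 0, ax].min()
            if lo <= 0:
                if not shift:
                    raise ValueError(
                        "geometric mean undefined for non-positive coordinates; "
                        "enable shift=True (shifts axis minimum to +1) or use "
                        "arithmetic aggregation"
                    )
                offsets[ax] = 1.0 - lo
        for j in range(c.k):
            pts = X[c.labels == j] + offsets
            cents[j] = np.exp(np.mean(np.log(pts), axis=0)) - offsets
            sizes[j] = len(pts)
    else:
        raise ValueError(f"unknown aggregation {aggregation!r}")
    return CentroidSet(centroids=cents, cluster_sizes=sizes, aggregation=aggregation)


def stability_report(
    m: FeatureMatrix,
    bird_ids: Sequence[str],
    seeds: Sequence[int],
    method: str = "umap",
    cluster_method: str = "kmeans",
    k: int | None = 5,
    min_cluster_size: int = 5,
    metric: str = "euclidean",
) -> dict:
    """Stability of per-bird path lengths across repeated embeddings.

    For each seed the full matrix is re-embedded; each bird's rows are
    clustered and its minimum path length computed.  The report contains
    the per-seed, per-bird path lengths and the pairwise Spearman rank
    correlations between seeds (how consistently the embeddings rank the
    birds).  With a single bird the correlation is undefined and
    reported as NaN.
    """
    from .pathmetric import min_path_length  # local: avoids import cycle

    bird_ids = [str(b) for b in bird_ids]
    if len(bird_ids) != m.n:
        raise ValueError("bird_ids must label every feature-matrix row")
    if len(seeds) < 2:
        raise ValueError("need >= 2 seeds to assess stability")
    birds = list(dict.fromkeys(bird_ids))
    ids_arr = np.asarray(bird_ids)

    rows = []
    for seed in seeds:
        e = embed_2d(m, seed=seed, method=method)
        lengths = []
        for bird in birds:
            mask = ids_arr == bird
            sub = Embedding2D(
                coords=e.coords[mask],
                method=e.method,
                seed=e.seed,
                n_neighbors=e.n_neighbors,
                min_dist=e.min_dist,
            )
            kb = min(k, int(mask.sum())) if k is not None else None
            clus = cluster_syllables(
                sub,
                method=cluster_method,
                k=kb,
                min_cluster_size=min_cluster_size,
            )
            cs = centroids(sub, clus)
            lengths.append(min_path_length(cs, metric=metric).min_path)
        rows.append(lengths)
    # duplicate seeds kept as separate rows (they must agree exactly)
    table = pd.DataFrame(rows, index=pd.Index(seeds, name="seed"), columns=birds)

    n_seeds = len(seeds)
    corr = np.full((n_seeds, n_seeds), np.nan)
    for i in range(n_seeds):
        for j in range(n_seeds):
            if len(birds) < 2:
                continue  # rank correlation undefined for a single bird
            a = table.iloc[i].to_numpy()
            b = table.iloc[j].to_numpy()
            if np.array_equal(a, b):
                corr[i, j] = 1.0  # spearmanr is NaN for constant ties
            else:
                corr[i, j] = spearmanr(a, b).statistic
    return {
        "path_lengths": table,
        "spearman": pd.DataFrame(corr, index=list(seeds), columns=list(seeds)),
        "mean_offdiag_spearman": (
            float(np.nanmean(corr[~np.eye(n_seeds, dtype=bool)]))
            if len(birds) >= 2
            else float("nan")
        ),
    }
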