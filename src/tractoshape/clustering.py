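"""k-means clustering of the isomap embedding and cluster average shapes.

The number of clusters is not chosen automatically: practitioners increase
k until the clusters exhibit distinctly different average shapes (k = 2
separates flat from curved bundles; around k = 5 finer families emerge).
:func:`sweep_k` provides inertia and silhouette diagnostics to support that
choice.

The per-cluster average shape is computed the way atlas prototypes are
built: the member nearest the cluster center in embedding space acts as the
reference; all members are rigidly aligned to it (allowing point-order
reversal) and averaged pointwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from tractoshape.alignment import align_to_reference, pca_align
from tractoshape.geometry import PointCloud
from tractoshape.manifold import Embedding, isomap_embed
from tractoshape.shape_distance import distance_matrix


@dataclass(frozen=True)
class ShapeClustering:
    """k-means partition of an embedding, with provenance for averaging."""

    k: int
    ids: tuple[str, ...]
    labels: np.ndarray
    centers: np.ndarray
    inertia: float
    seed: int
    embedding_coords: np.ndarray
    average_shapes: tuple[PointCloud, ...] = field(default=())

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=int)
        coords = np.asarray(self.embedding_coords, dtype=float)
        if labels.shape != (len(self.ids),):
            raise ValueError("labels must match ids")
        present = np.unique(labels)
        if not np.array_equal(present, np.arange(self.k)):
            raise ValueError(f"cluster indices must be 0..k-1 all non-empty, got {present}")
        sse = float(
            np.sum((coords - np.asarray(self.centers)[labels]) ** 2)
        )
        if abs(sse - self.inertia) > 1e-9 * max(1.0, sse):
            raise ValueError(f"inertia {self.inertia} != recomputed SSE {sse}")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "ids", tuple(self.ids))

    def label_of(self, cloud_id: str) -> int:
        return int(self.labels[self.ids.index(cloud_id)])

    def members(self, cluster_id: int) -> np.ndarray:
        return np.flatnonzero(self.labels == cluster_id)


def kmeans(emb: Embedding, k: int, seed: int = 0, n_init: int = 10) -> ShapeClustering:
    """Best-of-``n_init`` k-means++ on the embedding coordinates.

    Deterministic for a fixed ``(seed, n_init)``. ``k`` must not exceed the
    number of embedded clouds.
    """
    n = len(emb.ids)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_init, random_state=seed)
    labels = km.fit_predict(emb.coordinates)
    # relabel clusters by first appearance so labelings are order-canonical
    remap: dict[int, int] = {}
    for lab in labels:
        if lab not in remap:
            remap[int(lab)] = len(remap)
    labels = np.array([remap[int(lab)] for lab in labels])
    centers = np.empty_like(km.cluster_centers_)
    for old, new in remap.items():
        centers[new] = km.cluster_centers_[old]
    return ShapeClustering(
        k=k,
        ids=emb.ids,
        labels=labels,
        centers=centers,
        inertia=float(km.inertia_),
        seed=seed,
        embedding_coords=emb.coordinates,
    )


def average_shape(
    clouds: Sequence[PointCloud],
    clustering: ShapeClustering,
    cluster_id: int,
) -> PointCloud:
    """Pointwise mean of the cluster members after rigid alignment.

    The reference is the member whose embedding coordinates lie nearest the
    cluster center (ties toward the lowest index); every member is aligned
    to it with flip allowed, then averaged pointwise.
    """
    members = clustering.members(cluster_id)
    if members.size == 0:
        raise ValueError(f"cluster {cluster_id} is empty")
    if len(clouds) != len(clustering.ids):
        raise ValueError("clouds must parallel clustering.ids")
    center = clustering.centers[cluster_id]
    d2 = np.sum((clustering.embedding_coords[members] - center) ** 2, axis=1)
    ref = clouds[members[int(np.argmin(d2))]]
    stack = []
    for idx in members:
        aligned, _, _ = align_to_reference(clouds[idx], ref, allow_flip=True)
        stack.append(aligned.points)
    return PointCloud(
        np.mean(stack, axis=0), source_id=f"cluster{cluster_id}_average"
    )


def average_shapes(
    clouds: Sequence[PointCloud], clustering: ShapeClustering
) -> ShapeClustering:
    """Return a copy of ``clustering`` with all per-cluster averages attached."""
    shapes = tuple(average_shape(clouds, clustering, c) for c in range(clustering.k))
    return ShapeClustering(
        k=clustering.k,
        ids=clustering.ids,
        labels=clustering.labels,
        centers=clustering.centers,
        inertia=clustering.inertia,
        seed=clustering.seed,
        embedding_coords=clustering.embedding_coords,
        average_shapes=shapes,
    )


def composition_table(
    labels: Mapping[str, int],
    annotations: Mapping[str, str],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cluster-by-category composition: (row-percentage table, count table).

    Rows are clusters, columns annotation categories (e.g. empirical shape
    labels); each percentage row sums to 100. Ids missing an annotation fall
    into an ``"unannotated"`` column.
    """
    ids = list(labels)
    cats = [annotations.get(i, "unannotated") for i in ids]
    counts = pd.crosstab(
        pd.Series([labels[i] for i in ids], name="cluster"),
        pd.Series(cats, name="category"),
    )
    pct = counts.div(counts.sum(axis=1), axis=0) * 100.0
    return pct, counts


def sweep_k(
    emb: Embedding, k_range: Sequence[int], seed: int = 0, n_init: int = 10
) -> pd.DataFrame:
    """Inertia and mean silhouette for each k; no automatic choice imposed."""
    n = len(emb.ids)
    rows = []
    for k in k_range:
        if not 2 <= k <= n - 1:
            raise ValueError(f"k={k} outside [2, {n - 1}]")
        clustering = kmeans(emb, k, seed=seed, n_init=n_init)
        sil = float(silhouette_score(emb.coordinates, clustering.labels))
        rows.append({"k": k, "inertia": clustering.inertia, "silhouette": sil})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class JointGroupResult:
    """Pooled two-group shape analysis output."""

    embedding: Embedding
    clustering: ShapeClustering
    group_of: dict[str, str]
    group_composition: pd.DataFrame  # clusters x groups, % of each group's total


def joint_group_analysis(
    groups: Mapping[str, Sequence[PointCloud]],
    n_neighbors: int = 4,
    n_dims: int = 2,
    k: int = 2,
    seed: int = 0,
    n_init: int = 10,
    prealigned: bool = False,
    disconnected: str = "bridge",
) -> JointGroupResult:
    """Pool several groups (e.g. species), embed and cluster them together.

    Every cloud is PCA-aligned (unless ``prealigned``), the pooled distance
    matrix is embedded with isomap and clustered with k-means; for each
    cluster the percentage of each group's total membership is reported, so
    each *column* of ``group_composition`` sums to 100.
    """
    for name, clouds in groups.items():
        if len(clouds) == 0:
            raise ValueError(f"group {name!r} is empty")
    pooled: list[PointCloud] = []
    group_of: dict[str, str] = {}
    for name, clouds in groups.items():
        for i, c in enumerate(clouds):
            uid = f"{name}/{c.source_id or i}"
            pts = c.points if prealigned else pca_align(c)[0].points
            pooled.append(PointCloud(pts, source_id=uid))
            group_of[uid] = name
    D = distance_matrix(pooled)
    emb = isomap_embed(D, n_neighbors=n_neighbors, n_dims=n_dims, disconnected=disconnected)
    clustering = kmeans(emb, k, seed=seed, n_init=n_init)
    rows = pd.Series(
        {i: clustering.labels[j] for j, i in enumerate(clustering.ids)}, name="cluster"
    )
    cols = pd.Series({i: group_of[i] for i in clustering.ids}, name="group")
    counts = pd.crosstab(rows, cols)
    pct = counts.div(counts.sum(axis=0), axis=1) * 100.0
    return JointGroupResult(
        embedding=emb,
        clustering=clustering,
        group_of=group_of,
        group_composition=pct,
    )
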