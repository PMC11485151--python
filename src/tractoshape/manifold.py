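"""Isomap embedding of a fiber-shape distance matrix.

Standard isomap: a symmetrized k-nearest-neighbor graph is
built on the distance matrix, all-pairs shortest-path (geodesic) distances
are computed on that graph, and classical MDS (double-centering of squared
geodesics, top eigenpairs) yields low-dimensional coordinates. Two output
dimensions retain the dominant shape variability of fiber bundles; the
neighbor count defaults to 4.

The embedding's fit is summarized by the residual variance
``1 - r^2`` between geodesic and embedded Euclidean distances.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, shortest_path

from tractoshape.shape_distance import DistanceMatrix


@dataclass(frozen=True)
class Embedding:
    """Low-dimensional isomap coordinates plus diagnostics.

    ``coordinates`` is N x d (axes ordered by eigenvalue, signs fixed so the
    largest-magnitude loading on each axis is positive). ``component_map``
    records the connected component of every *input* id; when the graph is
    disconnected and the largest component was embedded, ``ids`` covers only
    the embedded clouds.
    """

    coordinates: np.ndarray
    ids: tuple[str, ...]
    n_neighbors: int
    n_dims: int
    eigenvalues: np.ndarray
    residual_variance: float
    component_map: dict[str, int]

    def __post_init__(self) -> None:
        C = np.asarray(self.coordinates, dtype=float)
        if C.shape != (len(self.ids), self.n_dims):
            raise ValueError("coordinate shape does not match ids/n_dims")
        if not np.all(np.isfinite(C)):
            raise ValueError("non-finite embedding coordinates")
        object.__setattr__(self, "coordinates", C)
        object.__setattr__(self, "ids", tuple(self.ids))


def knn_graph(D: DistanceMatrix, n_neighbors: int) -> nx.Graph:
    """Symmetrized (union) k-nearest-neighbor graph weighted by distance.

    Each node is joined to its ``n_neighbors`` nearest others; distance ties
    are broken toward the lower index, so the graph is deterministic.
    """
    n = D.n
    if not 1 <= n_neighbors < n:
        raise ValueError(f"n_neighbors must be in [1, {n - 1}], got {n_neighbors}")
    G = nx.Graph()
    G.add_nodes_from(range(n))
    V = D.values
    for i in range(n):
        order = np.argsort(V[i], kind="stable")  # stable sort -> lower index wins ties
        neighbors = [j for j in order if j != i][:n_neighbors]
        for j in neighbors:
            G.add_edge(i, int(j), weight=float(V[i, j]))
    return G


def geodesic_distances(graph: nx.Graph) -> np.ndarray:
    """All-pairs shortest-path lengths; ``inf`` between components."""
    n = graph.number_of_nodes()
    A = nx.to_scipy_sparse_array(graph, nodelist=range(n), weight="weight", format="csr")
    return shortest_path(csr_matrix(A), method="D", directed=False)


def _classical_mds(G: np.ndarray, n_dims: int) -> tuple[np.ndarray, np.ndarray]:
    n = G.shape[0]
    G2 = G**2
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    B = -0.5 * J @ G2 @ J
    B = (B + B.T) / 2.0
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals, kind="stable")[::-1]
    evals = evals[order][:n_dims]
    evecs = evecs[:, order][:, :n_dims]
    scale = np.max(np.abs(evals)) if evals.size else 1.0
    tol = 1e-9 * max(scale, 1.0)
    if np.any(evals < -tol):
        raise ArithmeticError(
            f"negative eigenvalue {evals.min():.3g} among the top {n_dims}: "
            "geodesic matrix too far from Euclidean"
        )
    evals = np.clip(evals, 0.0, None)
    coords = evecs * np.sqrt(evals)
    # deterministic signs: largest-|loading| entry of each axis made positive
    for j in range(coords.shape[1]):
        col = coords[:, j]
        if col[np.argmax(np.abs(col))] < 0:
            coords[:, j] *= -1.0
    return coords, evals


def _residual_variance(geodesic: np.ndarray, coords: np.ndarray) -> float:
    n = geodesic.shape[0]
    iu = np.triu_indices(n, k=1)
    g = geodesic[iu]
    diff = coords[:, None, :] - coords[None, :, :]
    e = np.sqrt(np.sum(diff**2, axis=-1))[iu]
    if g.size < 2 or np.std(g) == 0 or np.std(e) == 0:
        return 0.0
    r = float(np.corrcoef(g, e)[0, 1])
    return max(0.0, 1.0 - r * r)


def isomap_embed(
    D: DistanceMatrix,
    n_neighbors: int = 4,
    n_dims: int = 2,
    disconnected: str = "error",
) -> Embedding:
    """Embed a distance matrix with isomap.

    Parameters
    ----------
    D:
        Flip-invariant distance matrix over the centroid clouds.
    n_neighbors:
        Neighborhood size of the k-NN graph (default 4).
    n_dims:
        Output dimensionality (default 2).
    disconnected:
        ``"error"`` (default) raises when the k-NN graph splits into several
        components; ``"largest_component"`` embeds the largest component and
        records the component of every input id in ``component_map``;
        ``"bridge"`` joins the components by repeatedly adding the single
        shortest edge between two components (a minimum-spanning bridge),
        so every cloud stays in the embedding.
    """
    if disconnected not in ("error", "largest_component", "bridge"):
        raise ValueError(f"unknown disconnected policy {disconnected!r}")
    n = D.n
    if n < n_dims + 1:
        raise ValueError(f"need at least n_dims+1 = {n_dims + 1} clouds, got {n}")
    G = knn_graph(D, n_neighbors)
    A = nx.to_scipy_sparse_array(G, nodelist=range(n), weight="weight", format="csr")
    n_comp, labels = connected_components(csr_matrix(A), directed=False)
    component_map = {D.ids[i]: int(labels[i]) for i in range(n)}
    if n_comp > 1 and disconnected == "bridge":
        # join components with their shortest mutual edge, smallest first
        while True:
            n_comp, labels = connected_components(
                nx.to_scipy_sparse_array(G, nodelist=range(n), weight="weight"),
                directed=False,
            )
            if n_comp == 1:
                break
            best = None
            for a in range(n_comp):
                ia = np.flatnonzero(labels == a)
                for b in range(a + 1, n_comp):
                    ib = np.flatnonzero(labels == b)
                    sub = D.values[np.ix_(ia, ib)]
                    r, c = np.unravel_index(np.argmin(sub), sub.shape)
                    if best is None or sub[r, c] < best[0]:
                        best = (float(sub[r, c]), int(ia[r]), int(ib[c]))
            G.add_edge(best[1], best[2], weight=best[0])
        component_map = {i: 0 for i in D.ids}
    if n_comp > 1:
        if disconnected == "error":
            sizes = np.bincount(labels)
            raise ValueError(
                f"k-NN graph has {n_comp} components (sizes {sizes.tolist()}); "
                "increase n_neighbors or use disconnected='largest_component'"
            )
        keep = np.flatnonzero(labels == np.argmax(np.bincount(labels)))
        sub = DistanceMatrix(D.values[np.ix_(keep, keep)], [D.ids[i] for i in keep])
        geo = geodesic_distances(knn_graph(sub, min(n_neighbors, sub.n - 1)))
        ids = sub.ids
    else:
        geo = geodesic_distances(G)
        ids = D.ids
    coords, evals = _classical_mds(geo, n_dims)
    rv = _residual_variance(geo, coords)
    return Embedding(
        coordinates=coords,
        ids=ids,
        n_neighbors=n_neighbors,
        n_dims=n_dims,
        eigenvalues=evals,
        residual_variance=rv,
        component_map=component_map,
    )
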