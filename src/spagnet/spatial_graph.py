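"""Spatially local weighted graph over spots.

Neighbourhoods come from spot coordinates (Euclidean kNN; for 3-D
multi-slice data spots are projected into the common x-y plane and
neighbours are drawn from the same or adjacent slices).  Edge weights come
from PCA embeddings of expression:

    D_ij = exp(2 - dist(U_i, U_j) / (|U_i| * |U_j|)),   B_ij = D_ij / sum_i D_ij

so each column of B is normalised to 1 over its neighbour support.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.spatial import cKDTree

from .data_io import ExpressionMatrix, SpotCoordinates

#: default neighbour counts per platform class: 10 suits Visium-like arrays,
#: 30 suits near-cellular platforms (Slide-seqV2 / Stereo-seq).
DEFAULT_K_VISIUM = 10
DEFAULT_K_HIGHRES = 30
DEFAULT_N_PCS = 50


@dataclass
class PCAEmbedding:
    """Top principal components of expression, spots on columns (K x N)."""

    U: np.ndarray

    @property
    def n_pcs(self) -> int:
        return self.U.shape[0]

    @property
    def n_spots(self) -> int:
        return self.U.shape[1]


@dataclass
class SpatialGraph:
    """Column-stochastic neighbour weight matrix B with its support."""

    B: np.ndarray
    neighbor_sets: list[np.ndarray]
    k: int

    @property
    def n_spots(self) -> int:
        return self.B.shape[0]

    def symmetric_adjacency(self, binary: bool = True) -> np.ndarray:
        """Symmetrised spatial weights, e.g. for Moran's I."""
        w = (self.B > 0).astype(np.float64) if binary else self.B
        return np.maximum(w, w.T)


def pca_embedding(expr: ExpressionMatrix, n_pcs: int = DEFAULT_N_PCS,
                  seed: int = 0) -> PCAEmbedding:
    """PCA of spots (observations) over genes (features), K x N output."""
    from sklearn.decomposition import PCA

    x = expr.values.T  # spots x genes
    n_pcs = min(n_pcs, min(x.shape) - 1)
    if n_pcs < 1:
        raise ValueError("need at least 2 genes and 2 spots for PCA")
    model = PCA(n_components=n_pcs, svd_solver="full", random_state=seed)
    return PCAEmbedding(model.fit_transform(x).T)


def knn_neighbors(coords: SpotCoordinates, k: int) -> list[np.ndarray]:
    """k nearest neighbours of each spot (self excluded).

    2-D: plain Euclidean kNN.  3-D: distances are computed in the common
    x-y plane after projecting along z, and candidates are restricted to
    spots whose slice index differs by at most 1.  Distance ties are broken
    by spot index.
    """
    n = coords.n_spots
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of spots {n}")
    if k < 1:
        raise ValueError("k must be positive")
    if not coords.is_3d:
        return _knn_plane(coords.coords, np.arange(n), np.arange(n), k)

    xy = coords.coords[:, :2]
    slices = coords.slice_id
    neighbor_sets: list[np.ndarray] = [np.empty(0, dtype=int)] * n
    for s in np.unique(slices):
        query_idx = np.flatnonzero(slices == s)
        cand_idx = np.flatnonzero(np.abs(slices - s) <= 1)
        if len(cand_idx) - 1 < k:
            raise ValueError(
                f"slice {s}: only {len(cand_idx) - 1} adjacent-slice candidates "
                f"for k={k}")
        for i, nb in zip(query_idx,
                         _knn_plane(xy, query_idx, cand_idx, k)):
            neighbor_sets[i] = nb
    return neighbor_sets


def _knn_plane(points: np.ndarray, query_idx: np.ndarray,
               cand_idx: np.ndarray, k: int) -> list[np.ndarray]:
    """Exact kNN of query points among candidates, self excluded,
    ties broken by (distance, original spot index)."""
    tree = cKDTree(points[cand_idx])
    # k+1 in case the query itself is among candidates
    dist, pos = tree.query(points[query_idx], k=min(k + 1, len(cand_idx)))
    dist = np.atleast_2d(dist)
    pos = np.atleast_2d(pos)
    out: list[np.ndarray] = []
    for row, qi in enumerate(query_idx):
        ids = cand_idx[pos[row]]
        # deterministic tie-break: sort by (distance, spot index)
        order = np.lexsort((ids, np.round(dist[row], decimals=12)))
        ids = ids[order]
        ids = ids[ids != qi][:k]
        out.append(np.asarray(ids, dtype=int))
    return out


def build_spatial_graph(embed: PCAEmbedding,
                        neighbors: list[np.ndarray],
                        k: int | None = None,
                        metric: str = "euclidean",
                        normalize: bool = True) -> SpatialGraph:
    """Weighted adjacency B from PCA similarity on the kNN support.

    `metric='euclidean'` uses the Euclidean distance between embeddings in
    the exponent (the default reading); `metric='cosine'` replaces it with
    the inner product, an alternative reading of the bracket notation.
    With `normalize=True` (default) embedding columns are rescaled to unit
    length first, so the exponent 2 - dist/(|U_i||U_j|) spans its full
    [0, 2] range (the distance becomes the chord distance) and the weights
    are invariant to the embedding's overall scale.
    The self-weight is excluded; columns are normalised over neighbours.
    """
    u = embed.U
    n = u.shape[1]
    if len(neighbors) != n:
        raise ValueError("neighbor sets do not match embedding columns")
    norms = np.linalg.norm(u, axis=0)
    zero = np.flatnonzero(norms == 0)
    if len(zero):
        raise ValueError(f"zero-norm embedding for spot(s) {zero.tolist()}")
    if normalize:
        u = u / norms
        norms = np.ones(n)
    if k is None:
        k = max(len(nb) for nb in neighbors)

    d = np.zeros((n, n), dtype=np.float64)
    for j, nb in enumerate(neighbors):
        if metric == "euclidean":
            sim = np.linalg.norm(u[:, nb] - u[:, [j]], axis=0)
        elif metric == "cosine":
            sim = u[:, nb].T @ u[:, j]
        else:
            raise ValueError(f"unknown metric {metric!r}")
        d[nb, j] = np.exp(2.0 - sim / (norms[nb] * norms[j]))
    col_sum = d.sum(axis=0)
    b = d / col_sum[np.newaxis, :]
    return SpatialGraph(B=b, neighbor_sets=[np.asarray(nb) for nb in neighbors],
                        k=k)


def save_graph(graph: SpatialGraph, path) -> None:
    """Serialise B as a compressed sparse triplet archive."""
    coo = sparse.coo_matrix(graph.B)
    np.savez_compressed(path, row=coo.row, col=coo.col, data=coo.data,
                        shape=np.asarray(coo.shape), k=np.asarray(graph.k))


def load_graph(path) -> SpatialGraph:
    with np.load(path) as z:
        b = sparse.coo_matrix((z["data"], (z["row"], z["col"])),
                              shape=tuple(z["shape"])).toarray()
        k = int(z["k"])
    neighbor_sets = [np.flatnonzero(b[:, j]) for j in range(b.shape[1])]
    return SpatialGraph(B=b, neighbor_sets=neighbor_sets, k=k)
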