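"""PCA embedding and shared-nearest-neighbor graph clustering.

Clustering follows the standard single-cell recipe: a k-nearest-neighbor
graph in PC space is converted to a shared-nearest-neighbor (SNN) graph with
Jaccard edge weights, weak edges are pruned, and communities are found by
modularity optimization with a resolution parameter.
"""

from __future__ import annotations

import random
import warnings

import igraph as ig
import leidenalg
import numpy as np
import scipy.sparse as sp
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .datatypes import Clustering, Embedding, ScaledMatrix

SNN_PRUNE = 1.0 / 15.0


def pca(sm: "ScaledMatrix | np.ndarray", n_pcs: int = 30) -> Embedding:
    """Project cells onto the top principal components of the HVG panel.

    Accepts a ScaledMatrix (genes x cells; restricted to its ``hvg_mask``) or
    a raw cells x features array.  The sign of each PC is fixed so that the
    loading with the largest magnitude is positive, making embeddings
    reproducible across runs.
    """
    if isinstance(sm, ScaledMatrix):
        x = sm.values[sm.hvg_mask].T  # cells x genes
    else:
        x = np.asarray(sm, dtype=float)
    n_cells, n_feat = x.shape
    if n_pcs > min(n_cells, n_feat):
        raise ValueError(
            f"n_pcs={n_pcs} exceeds min(cells={n_cells}, features={n_feat})"
        )
    solver = "full" if min(n_cells, n_feat) < 200 else "randomized"
    model = PCA(n_components=n_pcs, svd_solver=solver, random_state=0)
    scores = model.fit_transform(x)
    loadings = model.components_.T  # features x n_pcs
    # deterministic sign: largest-|loading| entry positive per PC
    flip_idx = np.argmax(np.abs(loadings), axis=0)
    signs = np.sign(loadings[flip_idx, np.arange(n_pcs)])
    signs[signs == 0] = 1.0
    return Embedding(
        scores=scores * signs,
        n_pcs=n_pcs,
        loadings=loadings * signs,
        explained_variance=model.explained_variance_,
    )


def snn_graph(scores: np.ndarray, k_neighbors: int = 20,
              prune: float = SNN_PRUNE) -> sp.csr_matrix:
    """Jaccard-weighted shared-nearest-neighbor graph over cells in PC space.

    Neighbor sets of size ``k_neighbors`` include the cell itself (the
    convention of the standard single-cell toolchain); edges with Jaccard
    similarity below ``prune`` are removed.
    """
    n = scores.shape[0]
    if k_neighbors >= n:
        raise ValueError(f"k_neighbors={k_neighbors} requires more than "
                         f"{k_neighbors} cells, got {n}")
    nn = NearestNeighbors(n_neighbors=k_neighbors, algorithm="auto")
    nn.fit(scores)
    _, idx = nn.kneighbors(scores)
    rows = np.repeat(np.arange(n), k_neighbors)
    adj = sp.csr_matrix(
        (np.ones(n * k_neighbors), (rows, idx.ravel())), shape=(n, n)
    )
    shared = adj @ adj.T  # |intersection| of neighbor sets
    shared = shared.tocoo()
    inter = shared.data
    jac = inter / (2 * k_neighbors - inter)
    keep = (jac >= prune) & (shared.row != shared.col)
    snn = sp.csr_matrix(
        (jac[keep], (shared.row[keep], shared.col[keep])), shape=(n, n)
    )
    return snn


def _graph_from_snn(snn: sp.csr_matrix) -> ig.Graph:
    coo = sp.triu(snn, k=1).tocoo()
    edges = list(zip(coo.row.tolist(), coo.col.tolist()))
    g = ig.Graph(n=snn.shape[0], edges=edges)
    g.es["weight"] = coo.data.tolist()
    return g


def _canonical_labels(membership: np.ndarray) -> np.ndarray:
    """Relabel communities by order of first occurrence (contiguous from 0)."""
    labels = np.asarray(membership, dtype=int)
    seen: dict = {}
    out = np.empty_like(labels)
    for i, lab in enumerate(labels):
        if lab not in seen:
            seen[lab] = len(seen)
        out[i] = seen[lab]
    return out


def cluster_snn(snn: sp.csr_matrix, resolution: float, seed: int = 0,
                algorithm: str = "louvain") -> Clustering:
    """Modularity-based community detection on a prebuilt SNN graph."""
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    g = _graph_from_snn(snn)
    if g.ecount() == 0:
        warnings.warn("SNN graph has no edges; every cell is its own cluster")
        return Clustering(labels=np.arange(snn.shape[0]), resolution=resolution)
    if algorithm == "louvain":
        state = random.getstate()
        try:
            ig.set_random_number_generator(random.Random(seed))
            comm = g.community_multilevel(weights="weight",
                                          resolution=resolution)
        finally:
            ig.set_random_number_generator(random)
            random.setstate(state)
        membership = np.array(comm.membership)
    elif algorithm == "leiden":
        part = leidenalg.find_partition(
            g,
            leidenalg.RBConfigurationVertexPartition,
            weights="weight",
            resolution_parameter=resolution,
            seed=seed,
        )
        membership = np.array(part.membership)
    else:
        raise ValueError(f"unknown algorithm {algorithm!r}")
    return Clustering(labels=_canonical_labels(membership), resolution=resolution)


def cluster_to_n_groups(emb: Embedding, n_target: int, k_neighbors: int = 20,
                        seed: int = 0, algorithm: str = "louvain",
                        resolutions=None) -> Clustering:
    """Clustering whose community count best matches ``n_target``.

    Scans a resolution grid in ascending order and keeps the partition whose
    cluster count is closest to the target (ties favor the lower resolution).
    Used when scoring type recovery against an annotation with a known number
    of populations, where a fixed resolution would arbitrarily over- or
    under-partition.
    """
    if resolutions is None:
        resolutions = [round(0.1 * i, 10) for i in range(1, 21)]
    snn = snn_graph(emb.scores, k_neighbors=k_neighbors)
    best = None
    for r in resolutions:
        cl = cluster_snn(snn, r, seed=seed, algorithm=algorithm)
        gap = abs(cl.n_clusters - n_target)
        if best is None or gap < best[0]:
            best = (gap, cl)
        if gap == 0:
            break
    return best[1]


def graph_cluster(emb: Embedding, resolution: float, k_neighbors: int = 20,
                  seed: int = 0, algorithm: str = "louvain") -> Clustering:
    """Cluster cells from an embedding: kNN -> SNN (Jaccard, pruned) -> Louvain.

    Deterministic given ``seed``.  Use :func:`snn_graph` + :func:`cluster_snn`
    directly to reuse one graph across a grid of resolutions.
    """
    snn = snn_graph(emb.scores, k_neighbors=k_neighbors)
    return cluster_snn(snn, resolution, seed=seed, algorithm=algorithm)
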