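"""Integration quality metrics.

Four complementary views of an integrated embedding: how intermixed the
batches are (mixing metric, lower is better), how well each dataset's own
neighborhood structure survives integration (local structure metric, higher
is better), how well annotated cell types separate (average silhouette
width), and how well clustering of the integrated data recovers annotated
types (adjusted Rand index).  Neighbor search is exact so all values are
deterministic.
"""

from __future__ import annotations

import numpy as np
from sklearn.metrics import adjusted_rand_score, silhouette_score
from sklearn.neighbors import NearestNeighbors

from .datatypes import Embedding


def _scores(emb: "Embedding | np.ndarray") -> np.ndarray:
    return emb.scores if isinstance(emb, Embedding) else np.asarray(emb, float)


def mixing_metric(emb: "Embedding | np.ndarray", batch_labels,
                  k: int = 5, k_max: int = 300) -> float:
    """Neighborhood-rank statistic of batch intermixing (lower = better).

    For each cell, within its ``k_max`` nearest neighbors (Euclidean, self
    excluded) take the 1-based rank at which the ``k``-th neighbor from each
    batch appears (``k_max + 1`` if a batch contributes fewer than ``k``
    neighbors); the cell's score is the median of these ranks over batches,
    and the metric is the mean over cells.
    """
    x = _scores(emb)
    batches = np.asarray(batch_labels)
    if k_max < k:
        raise ValueError(f"k_max={k_max} must be >= k={k}")
    uniq, counts = np.unique(batches, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("mixing metric needs at least 2 batches")
    small = uniq[counts < k]
    if small.size:
        raise ValueError(f"batches smaller than k={k}: {small.tolist()}")
    n = x.shape[0]
    k_eff = min(k_max, n - 1)
    nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(x)
    _, idx = nn.kneighbors(x)
    idx = idx[:, 1:]  # drop self
    neighbor_batches = batches[idx]
    per_cell = np.empty(n)
    for i in range(n):
        ranks = []
        for b in uniq:
            hits = np.flatnonzero(neighbor_batches[i] == b)
            ranks.append(hits[k - 1] + 1 if hits.size >= k else k_eff + 1)
        per_cell[i] = np.median(ranks)
    return float(per_cell.mean())


def local_structure_metric(emb_orig_per_dataset, emb_integrated,
                           batch_labels, k: int = 20) -> float:
    """Mean preserved fraction of each cell's within-batch k-neighborhood.

    For every cell, its ``k`` nearest same-batch neighbors are found in the
    original per-dataset embedding and in the integrated embedding; the
    cell's score is |intersection| / k.  1.0 means the integrated embedding
    reproduces every within-dataset neighborhood exactly.

    ``emb_orig_per_dataset`` is a list of embeddings, one per batch in the
    order of ``np.unique(batch_labels)``, each covering exactly that batch's
    cells in their within-batch order.
    """
    xi = _scores(emb_integrated)
    batches = np.asarray(batch_labels)
    uniq = np.unique(batches)
    if len(uniq) != len(emb_orig_per_dataset):
        raise ValueError("one original embedding per batch is required")
    total = 0.0
    n_cells = 0
    for b, emb_o in zip(uniq, emb_orig_per_dataset):
        cells = np.flatnonzero(batches == b)
        xo = _scores(emb_o)
        if xo.shape[0] != cells.size:
            raise ValueError(f"original embedding for batch {b!r} covers "
                             f"{xo.shape[0]} cells, batch has {cells.size}")
        if cells.size <= k:
            raise ValueError(f"batch {b!r} has {cells.size} cells, need > k={k}")
        nn_o = NearestNeighbors(n_neighbors=k + 1).fit(xo)
        _, io = nn_o.kneighbors(xo)
        nn_i = NearestNeighbors(n_neighbors=k + 1).fit(xi[cells])
        _, ii = nn_i.kneighbors(xi[cells])
        for j in range(cells.size):
            so = set(io[j, 1:].tolist())
            si = set(ii[j, 1:].tolist())
            total += len(so & si) / k
        n_cells += cells.size
    return total / n_cells


def silhouette_asw(emb: "Embedding | np.ndarray", type_labels) -> float:
    """Average silhouette width of annotated types (Euclidean, PC space)."""
    x = _scores(emb)
    labels = np.asarray(type_labels)
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("silhouette needs at least 2 types")
    if np.any(counts < 2):
        raise ValueError("every type needs at least 2 cells")
    return float(silhouette_score(x, labels, metric="euclidean"))


def ari(labels_1, labels_2) -> float:
    """Adjusted Rand index between two partitions (chance-corrected)."""
    a = np.asarray(labels_1)
    b = np.asarray(labels_2)
    if a.shape != b.shape:
        raise ValueError(f"label lengths differ: {a.shape} vs {b.shape}")
    return float(adjusted_rand_score(a, b))


def cross_batch_neighbor_fraction(emb: "Embedding | np.ndarray", batch_labels,
                                  k: int = 10) -> float:
    """Mean fraction of cross-batch cells among each cell's k nearest neighbors."""
    x = _scores(emb)
    batches = np.asarray(batch_labels)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(x)
    _, idx = nn.kneighbors(x)
    idx = idx[:, 1:]
    other = batches[idx] != batches[:, None]
    return float(other.mean())
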