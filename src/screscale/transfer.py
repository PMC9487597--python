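"""Label transfer and match scores on the integrated embedding.

Annotations travel from the anchor dataset to the query dataset by majority
vote among each query cell's nearest anchor cells.  The match score flags
query cells whose type may be absent from the anchor data: it is the ratio of
a cell's mean distance to its nearest same-batch cells over its mean distance
to its nearest anchor cells, so cells far from everything in the anchor
dataset score low.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.neighbors import NearestNeighbors

from .datatypes import Embedding


@dataclass
class TransferResult:
    """Transferred labels plus the per-cell evidence behind them."""

    labels: np.ndarray
    neighbor_votes: list
    match_score: np.ndarray
    unknown_mask: np.ndarray


def _scores(emb) -> np.ndarray:
    return emb.scores if isinstance(emb, Embedding) else np.asarray(emb, float)


def transfer_labels(emb_integrated, batch_labels, anchor_batch,
                    anchor_types, k: int = 10) -> TransferResult:
    """Annotate query cells by the modal type of their k nearest anchor cells.

    ``anchor_types`` holds one type label per anchor cell (in the anchor
    cells' order within ``batch_labels``).  Vote ties are broken by the type
    of the single nearest anchor cell.
    """
    x = _scores(emb_integrated)
    batches = np.asarray(batch_labels)
    anchor_cells = np.flatnonzero(batches == anchor_batch)
    query_cells = np.flatnonzero(batches != anchor_batch)
    types = np.asarray(anchor_types, dtype=object)
    if types.shape[0] != anchor_cells.size:
        raise ValueError(f"{types.shape[0]} anchor type labels for "
                         f"{anchor_cells.size} anchor cells")
    untyped = np.flatnonzero(
        np.array([t is None or (isinstance(t, float) and np.isnan(t)) or t == ""
                  for t in types]))
    if untyped.size:
        raise ValueError(f"untyped anchor cells at positions {untyped[:10].tolist()}")
    if anchor_cells.size < k:
        raise ValueError(f"anchor batch has {anchor_cells.size} cells, need >= k={k}")
    nn = NearestNeighbors(n_neighbors=k).fit(x[anchor_cells])
    _, idx = nn.kneighbors(x[query_cells])
    labels = np.empty(query_cells.size, dtype=object)
    votes: list = []
    for i in range(query_cells.size):
        neigh_types = types[idx[i]]
        uniq, counts = np.unique(neigh_types.astype(str), return_counts=True)
        top = counts.max()
        winners = set(uniq[counts == top])
        if len(winners) == 1:
            labels[i] = next(iter(winners))
        else:
            labels[i] = str(neigh_types[0])  # nearest anchor cell decides
        votes.append(dict(zip(uniq.tolist(), counts.tolist())))
    score = match_score(x, batches, anchor_batch, k=k)
    return TransferResult(
        labels=labels,
        neighbor_votes=votes,
        match_score=score,
        unknown_mask=np.zeros(query_cells.size, dtype=bool),
    )


def match_score(emb_integrated, batch_labels, anchor_batch,
                k: int = 10) -> np.ndarray:
    """Per-query-cell presence score; lower = less likely present in anchor.

    score = (mean distance to k nearest same-batch cells, self excluded)
          / (mean distance to k nearest anchor-batch cells).
    Scale-invariant: multiplying all coordinates by c > 0 leaves it unchanged.
    """
    x = _scores(emb_integrated)
    batches = np.asarray(batch_labels)
    anchor_cells = np.flatnonzero(batches == anchor_batch)
    query_cells = np.flatnonzero(batches != anchor_batch)
    if anchor_cells.size < k or query_cells.size < k + 1:
        raise ValueError(f"both batches need at least k={k} neighbors available")
    nn_q = NearestNeighbors(n_neighbors=k + 1).fit(x[query_cells])
    d_same, _ = nn_q.kneighbors(x[query_cells])
    num = d_same[:, 1:].mean(axis=1)  # self excluded
    nn_a = NearestNeighbors(n_neighbors=k).fit(x[anchor_cells])
    d_cross, _ = nn_a.kneighbors(x[query_cells])
    den = d_cross.mean(axis=1)
    eps = np.finfo(float).eps
    if np.any(den < eps):
        warnings.warn("coincident anchor neighbors; match-score denominator "
                      "floored at machine epsilon")
        den = np.maximum(den, eps)
    return num / den


def flag_unknown(scores: np.ndarray, threshold: float) -> np.ndarray:
    """Cells whose match score falls below the user-chosen threshold."""
    return np.asarray(scores, dtype=float) < threshold
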