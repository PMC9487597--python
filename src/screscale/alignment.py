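"""Cluster alignment between two datasets in a joint PC space.

The anchor dataset's clusters are queried against the other dataset's
clusters.  A pair is accepted when the squared distance between cluster
centers is below the 75% quantile of the query cluster's own squared
center-distances.  Anchor clusters left unaligned get a second chance via a
subsampling retry: the over-represented side is subsampled to match the other
side's cluster proportion, its whole dataset is re-scaled by the per-gene
standard deviation on that subset, and the criterion is re-tested in the
recomputed joint embedding.  This is evaluated on a scratch copy — only the
alignment decisions persist; final scaling factors are computed later from
the composition-matched subsets.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .datatypes import AlignmentMap, Clustering, Embedding, RetryRecord, ScaledMatrix
from .embedding import pca


@dataclass
class ClusterCenters:
    """Per-cluster mean positions in the joint embedding plus sizes."""

    centers: np.ndarray  # n_clusters x n_pcs
    cluster_sizes: np.ndarray

    @property
    def n_clusters(self) -> int:
        return self.centers.shape[0]


def cluster_centers(emb_joint: "Embedding | np.ndarray", clustering: Clustering,
                    which_cells: np.ndarray) -> ClusterCenters:
    """Mean joint-embedding position of each cluster's member cells.

    ``which_cells`` maps the clustering's cells into rows of the joint
    embedding (the clustering covers one dataset, the embedding both).
    """
    scores = emb_joint.scores if isinstance(emb_joint, Embedding) else emb_joint
    rows = scores[np.asarray(which_cells, dtype=int)]
    labels = clustering.labels
    n_clusters = clustering.n_clusters
    centers = np.zeros((n_clusters, rows.shape[1]))
    sizes = np.zeros(n_clusters, dtype=int)
    for c in range(n_clusters):
        members = rows[labels == c]
        if members.shape[0] == 0:
            raise ValueError(f"cluster {c} has no member cells")
        centers[c] = members.mean(axis=0)
        sizes[c] = members.shape[0]
    return ClusterCenters(centers=centers, cluster_sizes=sizes)


def quantile_criterion(center_a: np.ndarray, query_cells: np.ndarray,
                       query_center: np.ndarray) -> bool:
    """Is the anchor center inside the query cluster's 75%-quantile spread?

    True iff ||center_a - query_center||^2 is strictly below the 75% quantile
    (linear interpolation) of the query cells' squared distances to their own
    center.
    """
    query_cells = np.atleast_2d(np.asarray(query_cells, dtype=float))
    if query_cells.shape[0] < 2:
        warnings.warn(
            "quantile criterion on a single-cell query cluster: the spread "
            "quantile is 0, the criterion can only hold for coincident centers"
        )
    d2 = float(np.sum((np.asarray(center_a) - np.asarray(query_center)) ** 2))
    radii = np.sum((query_cells - np.asarray(query_center)) ** 2, axis=1)
    q75 = float(np.quantile(radii, 0.75))  # type-7 linear interpolation
    return d2 < q75


def candidate_queries(anchor_center: np.ndarray, query_centers: ClusterCenters,
                      m: int = 5) -> list:
    """Up to ``m`` query clusters by ascending squared center distance.

    Ties are broken by the smaller cluster id.
    """
    d2 = np.sum((query_centers.centers - np.asarray(anchor_center)) ** 2, axis=1)
    order = sorted(range(query_centers.n_clusters), key=lambda c: (d2[c], c))
    return order[:m]


def retry_subsample_size(n_cluster: int, N_dataset: int, p_target: float) -> int:
    """Largest subsample of the cluster whose within-subset proportion <= target.

    The subset is the subsampled cluster plus all other cells of its dataset,
    so n' solves n' / (N - n + n') <= p, giving
    n' = floor(p * (N - n) / (1 - p)).
    """
    if not 0 < p_target < 1:
        raise ValueError("p_target must lie in (0, 1)")
    if n_cluster / N_dataset < p_target:
        raise ValueError(
            "cluster is not over-represented: its proportion "
            f"{n_cluster / N_dataset:.4f} <= target {p_target:.4f}"
        )
    n_prime = math.floor(p_target * (N_dataset - n_cluster) / (1.0 - p_target))
    if n_prime < 1:
        raise ValueError(
            f"cluster of size {n_cluster} cannot be subsampled to proportion "
            f"{p_target:.4g} in a dataset of {N_dataset} cells"
        )
    return n_prime


def _joint_embedding(values_anchor: np.ndarray, values_query: np.ndarray,
                     n_pcs: int) -> np.ndarray:
    """PC scores of the column-concatenated (anchor then query) scaled data."""
    joint = np.concatenate([values_anchor, values_query], axis=1).T
    return pca(joint, n_pcs=n_pcs).scores


def _subset_rescaled(values: np.ndarray, cluster_cells: np.ndarray,
                     keep: np.ndarray) -> np.ndarray:
    """Re-scale a dataset by per-gene sd over (subsampled cluster + rest)."""
    n_cells = values.shape[1]
    mask = np.ones(n_cells, dtype=bool)
    mask[cluster_cells] = False
    mask[keep] = True
    s = values[:, mask].std(axis=1, ddof=1)
    zero = s == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} genes constant on retry subset; "
                      "left un-rescaled")
        s[zero] = 1.0
    return values / s[:, None]


def _pass_one(anchor_centers: ClusterCenters, query_centers: ClusterCenters,
              joint_scores: np.ndarray, query_offset: int,
              query_labels: np.ndarray, clusters: "list[int]",
              m_candidates: int = 5) -> dict:
    """Steps 1-3: nearest candidate query cluster passing the criterion."""
    accepted = {}
    for a in clusters:
        for b in candidate_queries(anchor_centers.centers[a], query_centers,
                                   m=m_candidates):
            q_cells = joint_scores[query_offset + np.flatnonzero(query_labels == b)]
            if quantile_criterion(anchor_centers.centers[a], q_cells,
                                  query_centers.centers[b]):
                accepted[a] = b
                break
    return accepted


def align_clusters(scaled_anchor: ScaledMatrix, scaled_query: ScaledMatrix,
                   anchor_clustering: Clustering, query_clustering: Clustering,
                   n_pcs: int = 30, seed: int = 0,
                   joint_scores: "np.ndarray | None" = None) -> AlignmentMap:
    """Align anchor clusters to query clusters, with the subsampling retry.

    Both matrices must share identical gene panels (same order).  If
    ``joint_scores`` (PC scores of the concatenated data, anchor cells first)
    is provided it is used for the first pass; retries always recompute the
    joint embedding from re-scaled scratch copies.
    """
    if not np.array_equal(scaled_anchor.gene_ids, scaled_query.gene_ids):
        raise ValueError("anchor and query gene panels differ")
    va, vq = scaled_anchor.values, scaled_query.values
    n_a, n_q = va.shape[1], vq.shape[1]
    if joint_scores is None:
        joint_scores = _joint_embedding(va, vq, n_pcs)
    anchor_idx = np.arange(n_a)
    query_idx = n_a + np.arange(n_q)
    ac = cluster_centers(joint_scores, anchor_clustering, anchor_idx)
    qc = cluster_centers(joint_scores, query_clustering, query_idx)
    la, lq = anchor_clustering.labels, query_clustering.labels

    accepted = _pass_one(ac, qc, joint_scores, n_a, lq,
                         list(range(ac.n_clusters)))

    retry_log: list = []
    unaligned = [a for a in range(ac.n_clusters) if a not in accepted]
    for a in unaligned:
        for b in candidate_queries(ac.centers[a], qc, m=5):
            p_a = ac.cluster_sizes[a] / n_a
            p_b = qc.cluster_sizes[b] / n_q
            if p_a > p_b:
                side, values, labels, n_cells, cluster, p = (
                    "anchor", va, la, n_a, a, p_b)
            elif p_b > p_a:
                side, values, labels, n_cells, cluster, p = (
                    "query", vq, lq, n_q, b, p_a)
            else:
                # proportions already match; nothing to subsample
                continue
            cluster_cells = np.flatnonzero(labels == cluster)
            try:
                n_prime = retry_subsample_size(len(cluster_cells), n_cells, p)
            except ValueError:
                retry_log.append(RetryRecord(a, b, "none", 0, False))
                continue
            rng = np.random.default_rng([abs(seed), a, b])
            keep = rng.choice(cluster_cells, size=n_prime, replace=False)
            rescaled = _subset_rescaled(values, cluster_cells, keep)
            if side == "anchor":
                scratch = _joint_embedding(rescaled, vq, n_pcs)
            else:
                scratch = _joint_embedding(va, rescaled, n_pcs)
            ac2 = cluster_centers(scratch, anchor_clustering, anchor_idx)
            qc2 = cluster_centers(scratch, query_clustering, query_idx)
            q_cells = scratch[n_a + np.flatnonzero(lq == b)]
            ok = quantile_criterion(ac2.centers[a], q_cells, qc2.centers[b])
            retry_log.append(RetryRecord(a, b, side, n_prime, ok))
            if ok:
                accepted[a] = b
                break

    pairs = sorted(accepted.items())
    groups: dict = {}
    for a, b in pairs:
        groups.setdefault(b, []).append(a)
    merged = [sorted(g) for b, g in sorted(groups.items()) if len(g) > 1]
    still_unaligned = [a for a in range(ac.n_clusters) if a not in accepted]
    return AlignmentMap(
        pairs=[(int(a), int(b)) for a, b in pairs],
        merged_anchor_groups=merged,
        unaligned_anchor_clusters=still_unaligned,
        retry_log=retry_log,
    )
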