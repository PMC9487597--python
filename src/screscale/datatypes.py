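"""In-memory containers shared across the pipeline.

All matrices are stored genes x cells; cell indices are 0-based throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import scipy.sparse as sp


def _as_str_array(ids: Sequence[str]) -> np.ndarray:
    arr = np.asarray(ids, dtype=object)
    return arr.astype(str).astype(object)


def _check_unique(ids: np.ndarray, what: str) -> None:
    uniq, counts = np.unique(ids.astype(str), return_counts=True)
    dups = uniq[counts > 1]
    if dups.size:
        raise ValueError(f"duplicate {what}: {', '.join(dups[:10].tolist())}")


@dataclass
class CountMatrix:
    """Raw counts (reads for plate chemistry, UMIs for droplet chemistry).

    ``values`` is genes x cells, dense ndarray or scipy sparse (sparse storage
    is preserved as read from Matrix Market input).
    """

    values: "np.ndarray | sp.spmatrix"
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    platform: str = ""

    def __post_init__(self) -> None:
        self.gene_ids = _as_str_array(self.gene_ids)
        self.cell_ids = _as_str_array(self.cell_ids)
        n_genes, n_cells = self.values.shape
        if n_genes != len(self.gene_ids) or n_cells != len(self.cell_ids):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} gene ids x {len(self.cell_ids)} cell ids"
            )
        _check_unique(self.gene_ids, "gene ids")
        _check_unique(self.cell_ids, "cell ids")
        mn = self.values.min() if not sp.issparse(self.values) else self.values.min()
        if mn < 0:
            raise ValueError("count matrix contains negative entries")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def dense(self) -> np.ndarray:
        if sp.issparse(self.values):
            return np.asarray(self.values.todense(), dtype=float)
        return np.asarray(self.values, dtype=float)


@dataclass
class NormalizedMatrix:
    """Log-normalized expression: ln(1 + count / librarysize * scale_factor).

    Zeros are preserved (an entry is 0 iff the count was 0).  The source
    counts are kept so variance-stabilized gene selection can use them.
    """

    values: "np.ndarray | sp.spmatrix"
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    platform: str = ""
    scale_factor: float = 10_000.0
    counts: Optional["np.ndarray | sp.spmatrix"] = None

    def __post_init__(self) -> None:
        if self.scale_factor <= 0:
            raise ValueError("scale_factor must be positive")
        self.gene_ids = _as_str_array(self.gene_ids)
        self.cell_ids = _as_str_array(self.cell_ids)

    def dense(self) -> np.ndarray:
        if sp.issparse(self.values):
            return np.asarray(self.values.todense(), dtype=float)
        return np.asarray(self.values, dtype=float)


@dataclass
class ScaledMatrix:
    """Per-gene unit-variance expression Y (sample variance 1, ddof=1, uncentered).

    Genes with zero pre-scaling variance are all-zero rows.  ``hvg_mask``
    marks the highly variable genes used for embedding.
    """

    values: np.ndarray
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    platform: str = ""
    hvg_mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = _as_str_array(self.gene_ids)
        self.cell_ids = _as_str_array(self.cell_ids)
        if self.hvg_mask is None:
            self.hvg_mask = np.ones(self.values.shape[0], dtype=bool)
        else:
            self.hvg_mask = np.asarray(self.hvg_mask, dtype=bool)
            if self.hvg_mask.shape[0] != self.values.shape[0]:
                raise ValueError("hvg_mask length does not match gene count")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def restrict_genes(self, gene_ids: Sequence[str]) -> "ScaledMatrix":
        """Return a copy restricted to ``gene_ids`` in the given order."""
        index = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in gene_ids if g not in index]
        if missing:
            raise KeyError(f"genes absent from matrix: {missing[:10]}")
        rows = np.array([index[g] for g in gene_ids], dtype=int)
        return ScaledMatrix(
            values=self.values[rows].copy(),
            gene_ids=np.asarray(list(gene_ids), dtype=object),
            cell_ids=self.cell_ids.copy(),
            platform=self.platform,
            hvg_mask=self.hvg_mask[rows].copy(),
        )


@dataclass
class Embedding:
    """PC scores for cells (cells x n_pcs) plus loadings and variances."""

    scores: np.ndarray
    n_pcs: int
    loadings: Optional[np.ndarray] = None
    explained_variance: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape[1] != self.n_pcs:
            raise ValueError("scores width does not match n_pcs")
        if self.explained_variance is not None:
            ev = np.asarray(self.explained_variance, dtype=float)
            if np.any(np.diff(ev) > 1e-10):
                raise ValueError("explained_variance must be non-increasing")
            self.explained_variance = ev

    @property
    def n_cells(self) -> int:
        return self.scores.shape[0]


@dataclass
class Clustering:
    """Graph-community labels, one per cell, contiguous integers from 0."""

    labels: np.ndarray
    resolution: float
    n_clusters: int = 0
    sizes: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        uniq = np.unique(self.labels)
        if not np.array_equal(uniq, np.arange(len(uniq))):
            raise ValueError("cluster ids must be contiguous integers from 0")
        self.n_clusters = len(uniq)
        self.sizes = np.bincount(self.labels, minlength=self.n_clusters)


@dataclass
class RetryRecord:
    """One subsampling retry attempt during cluster alignment."""

    anchor_cluster: int
    query_cluster: int
    subsampled_side: str  # "anchor" | "query" | "none"
    subsample_size: int
    accepted: bool


@dataclass
class AlignmentMap:
    """Accepted (anchor cluster, query cluster) pairs plus merge records."""

    pairs: list = field(default_factory=list)
    merged_anchor_groups: list = field(default_factory=list)
    unaligned_anchor_clusters: list = field(default_factory=list)
    retry_log: list = field(default_factory=list)

    def __post_init__(self) -> None:
        anchors = [a for a, _ in self.pairs]
        if len(anchors) != len(set(anchors)):
            raise ValueError("an anchor cluster appears in more than one pair")

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def groups_by_query(self) -> dict:
        """Anchor clusters grouped by the query cluster they aligned to."""
        groups: dict = {}
        for a, b in self.pairs:
            groups.setdefault(b, []).append(a)
        return {b: sorted(g) for b, g in sorted(groups.items())}

    def to_dict(self) -> dict:
        return {
            "pairs": [[int(a), int(b)] for a, b in self.pairs],
            "merged_anchor_groups": [
                [int(a) for a in g] for g in self.merged_anchor_groups
            ],
            "unaligned_anchor_clusters": [
                int(a) for a in self.unaligned_anchor_clusters
            ],
            "retry_log": [
                {
                    "anchor_cluster": int(r.anchor_cluster),
                    "query_cluster": int(r.query_cluster),
                    "subsampled_side": r.subsampled_side,
                    "subsample_size": int(r.subsample_size),
                    "accepted": bool(r.accepted),
                }
                for r in self.retry_log
            ],
        }


@dataclass
class ScalingFactors:
    """Per-gene standard deviations from the composition-matched subsets."""

    s_anchor: np.ndarray
    s_query: np.ndarray
    subset_anchor_idx: np.ndarray
    subset_query_idx: np.ndarray

    def __post_init__(self) -> None:
        self.s_anchor = np.asarray(self.s_anchor, dtype=float)
        self.s_query = np.asarray(self.s_query, dtype=float)
        if np.any(self.s_anchor <= 0) or np.any(self.s_query <= 0):
            raise ValueError("scaling factors must be strictly positive")


@dataclass
class IntegrationResult:
    """Integrated matrix over the union of cells plus the search provenance."""

    integrated: ScaledMatrix
    batch_labels: np.ndarray
    chosen_resolutions: Optional[tuple]
    alignment: Optional[AlignmentMap]
    factors: Optional[ScalingFactors]
    mixing_score: float
    baseline_used: bool
    search_trace: list = field(default_factory=list)
    anchor_name: str = ""
    query_name: str = ""
    merge_history: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.batch_labels = np.asarray(self.batch_labels, dtype=object)
        if len(self.batch_labels) != self.integrated.n_cells:
            raise ValueError("batch_labels length does not match cell count")
        if self.baseline_used and self.factors is not None:
            raise ValueError("baseline result must not carry scaling factors")
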