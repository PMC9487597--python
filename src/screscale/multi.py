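"""Sequential pairwise integration of three or more datasets.

Pairs with more shared highly variable genes integrate first: a larger
overlap means more clusters are likely to align, which gives better-grounded
scaling factors.  After each merge the integrated result re-enters the queue
as a single dataset at the scaled-matrix stage, with its variable genes
recomputed on the re-scaled values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import RunConfig
from .datatypes import CountMatrix, IntegrationResult, ScaledMatrix
from .integration import integrate_scaled, preprocess_counts
from .preprocess import lognormalize, select_hvg


@dataclass
class IntegrationPlan:
    """A binary merge tree over the input datasets plus the evidence for it."""

    order: list = field(default_factory=list)  # [(name_i, name_j, similarity)]
    similarity: np.ndarray = None
    names: list = field(default_factory=list)


def _dataset_hvgs(datasets, n_hvg: int, method: str = "vst") -> list:
    hvgs = []
    for ds in datasets:
        nm = lognormalize(ds)
        hvgs.append(select_hvg(nm, n=n_hvg, method=method))
    return hvgs


def similarity_matrix(datasets, n_hvg: int = 4000,
                      hvg_method: str = "vst") -> np.ndarray:
    """Pairwise counts of shared highly variable genes between datasets."""
    if len(datasets) < 2:
        raise ValueError("need at least 2 datasets")
    hvgs = _dataset_hvgs(datasets, n_hvg, hvg_method)
    n = len(hvgs)
    sim = np.zeros((n, n), dtype=int)
    for i in range(n):
        sim[i, i] = len(hvgs[i])
        for j in range(i + 1, n):
            sim[i, j] = sim[j, i] = len(set(hvgs[i]) & set(hvgs[j]))
    return sim


def plan_order(sim: np.ndarray, names=None) -> IntegrationPlan:
    """Greedy merge order from a static similarity matrix.

    Repeatedly merges the most similar pair (ties: smallest id pair); a
    merged node's similarity to the rest is the maximum over its members
    (single linkage).  :func:`integrate_many` refines this by recomputing
    shared-gene counts on the actual merged data after every step.
    """
    sim = np.asarray(sim)
    n = sim.shape[0]
    if n < 2 or sim.shape[0] != sim.shape[1]:
        raise ValueError("similarity matrix must be square with >= 2 datasets")
    if names is None:
        names = [str(i) for i in range(n)]
    idx_of = {str(name): i for i, name in enumerate(names)}

    def group_sim(group_a, group_b) -> int:
        return max(int(sim[idx_of[a], idx_of[b]])
                   for a in group_a for b in group_b)

    groups = [(str(names[i]),) for i in range(n)]
    order = []
    while len(groups) > 1:
        best = None
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                cand = (group_sim(groups[i], groups[j]), -i, -j)
                if best is None or cand > best[0]:
                    best = (cand, i, j)
        (best_sim, _, _), i, j = best
        order.append((groups[i], groups[j], best_sim))
        merged = groups[i] + groups[j]
        groups = [g for k, g in enumerate(groups) if k not in (i, j)]
        groups.append(merged)
    return IntegrationPlan(order=order, similarity=sim,
                           names=[str(x) for x in names])


def _reunit(sm: ScaledMatrix) -> ScaledMatrix:
    """Bring an integrated matrix back to per-gene unit variance.

    An intermediate re-enters the pipeline as one dataset, so it goes through
    the same scaling contract as any input.  This also removes scale drift
    from factors estimated on a small aligned subpopulation (genes nearly
    constant on the matched subset get inflated dataset-wide; re-unit-scaling
    makes intermediates mutually comparable again).  Within-intermediate
    structure is untouched — it is one constant per gene.
    """
    sd = sm.values.std(axis=1, ddof=1, keepdims=True)
    nonconst = sd.ravel() > 0
    values = sm.values.copy()
    values[nonconst] /= sd[nonconst]
    values[~nonconst] = 0.0
    return ScaledMatrix(values=values, gene_ids=sm.gene_ids,
                        cell_ids=sm.cell_ids, platform=sm.platform,
                        hvg_mask=sm.hvg_mask)


def _intermediate_hvgs(sm: ScaledMatrix, n_hvg: int) -> list:
    """Variable genes of an integrated matrix: top genes by variance."""
    var = sm.values.var(axis=1, ddof=1)
    gene_ids = sm.gene_ids.astype(str)
    order = sorted(range(len(gene_ids)), key=lambda i: (-var[i], gene_ids[i]))
    return [gene_ids[i] for i in order[:min(n_hvg, len(gene_ids))]]


def integrate_many(datasets, config: "RunConfig | None" = None
                   ) -> IntegrationResult:
    """Integrate >= 2 datasets by greedy sequential pairwise merging.

    At every round the pair of current items (datasets or intermediates) with
    the most shared variable genes is integrated.  The final result's batch
    labels give each cell's dataset of origin, recovered through cell ids.
    """
    cfg = config or RunConfig()
    if len(datasets) < 2:
        raise ValueError("need at least 2 datasets")
    items = []
    origin: dict = {}
    for d, ds in enumerate(datasets):
        if isinstance(ds, CountMatrix):
            sm, hvg = preprocess_counts(ds, cfg)
        else:
            sm, hvg = ds, _intermediate_hvgs(ds, cfg.n_hvg)
        name = sm.platform or f"dataset{d}"
        sm.platform = name
        for c in sm.cell_ids.astype(str):
            origin[c] = name
        items.append({"name": name, "scaled": sm, "hvg": hvg})

    history = []
    while len(items) > 1:
        best = None
        for i in range(len(items)):
            for j in range(i + 1, len(items)):
                overlap = len(set(items[i]["hvg"]) & set(items[j]["hvg"]))
                cand = (overlap, -i, -j)
                if best is None or cand > best[0]:
                    best = (cand, i, j)
        _, i, j = best
        a, b = items[i], items[j]
        result = integrate_scaled(a["scaled"], b["scaled"], cfg)
        history.append({
            "merged": (a["name"], b["name"]),
            "shared_hvg": len(set(a["hvg"]) & set(b["hvg"])),
            "baseline_used": result.baseline_used,
            "mixing": result.mixing_score,
            "chosen_resolutions": result.chosen_resolutions,
        })
        merged_sm = result.integrated
        merged_sm.platform = f"({a['name']}+{b['name']})"
        hvg = _intermediate_hvgs(merged_sm, cfg.n_hvg)
        new_item = {
            "name": merged_sm.platform,
            "scaled": _reunit(merged_sm),
            "hvg": hvg,
        }
        items = [it for k, it in enumerate(items) if k not in (i, j)]
        items.append(new_item)
        last_result = result

    final = last_result
    # per-cell dataset of origin (cell ids are stable through concatenation
    # unless a collision forced prefixing; strip any such prefixes)
    labels = []
    for c in final.integrated.cell_ids.astype(str):
        key = c if c in origin else c.split(":", 1)[-1]
        labels.append(origin.get(key, "unknown"))
    final.batch_labels = np.asarray(labels, dtype=object)
    final.merge_history = history
    return final
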