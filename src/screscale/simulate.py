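"""Synthetic multi-platform scRNA-seq data with controlled type compositions.

The generator emulates the setting the integration pipeline targets: several
cell types with type-specific mean expression programs, datasets that differ
in sequencing depth (read counts for plate chemistry vs shallower UMI counts
for droplet chemistry), optional droplet-style dropout, and — crucially —
per-dataset cell-type composition vectors that can be made unequal, which is
the distortion the re-scaling procedure corrects.

Counts are negative binomial (gamma-Poisson) around each cell's library-size-
scaled type program, so even dropout-free data is overdispersed.  Everything
is deterministic given the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.special import expit

from .datatypes import CountMatrix

_PRESETS = ("equal_composition", "skewed_composition", "disjoint_types",
            "rare_type", "multi_tissue")


@dataclass
class SimulationConfig:
    """Everything needed to generate one family of synthetic datasets.

    compositions[d][t] is the proportion of type ``t`` in dataset ``d`` (each
    row sums to 1).  ``depths`` are mean library sizes; ``dropout`` entries
    are ``None`` or ``(midpoint, slope)`` of a logistic keep-probability in
    the log expected count.
    """

    n_genes: int = 1500
    type_names: tuple = ("type0", "type1")
    compositions: tuple = ((0.5, 0.5), (0.5, 0.5))
    n_cells: tuple = (2000, 2000)
    depths: tuple = (300_000.0, 100_000.0)
    dropout: tuple = (None, (0.0, 1.5))
    platforms: Optional[tuple] = None
    dispersion: float = 0.6
    burst_prob: float = 0.5
    marker_fraction: float = 0.1
    marker_fold: float = 8.0
    marker_off_level: float = 0.0
    library_sigma: float = 0.35
    seed: int = 0
    programs: Optional[np.ndarray] = None  # types x genes mean vectors

    def __post_init__(self) -> None:
        n_ds = len(self.compositions)
        if not (len(self.n_cells) == len(self.depths) == len(self.dropout) == n_ds):
            raise ValueError("compositions, n_cells, depths and dropout must "
                             "have one entry per dataset")
        for comp in self.compositions:
            if len(comp) != len(self.type_names):
                raise ValueError("each composition needs one proportion per type")
            if abs(sum(comp) - 1.0) > 1e-8 or any(p < 0 for p in comp):
                raise ValueError(f"composition {comp} is not a proportion vector")
        if any(d <= 0 for d in self.depths):
            raise ValueError("depths must be positive")
        if self.platforms is None:
            self.platforms = tuple(f"dataset{d}" for d in range(n_ds))
        if self.programs is not None:
            self.programs = np.asarray(self.programs, dtype=float)
            if self.programs.shape != (len(self.type_names), self.n_genes):
                raise ValueError("programs must be types x genes")

    @property
    def n_datasets(self) -> int:
        return len(self.compositions)


@dataclass
class SyntheticTruth:
    """Ground truth behind a simulated dataset family."""

    type_label: np.ndarray
    dataset_label: np.ndarray
    programs: np.ndarray
    per_dataset_types: list = field(default_factory=list)


def _make_programs(cfg: SimulationConfig,
                   rng: np.random.Generator) -> "tuple[np.ndarray, np.ndarray]":
    """Log-normal base program with disjoint marker blocks per type.

    Returns (programs, marker_mask).  Marker genes are constitutively
    expressed (no bursting) — canonical type markers are robust within their
    type, which is what makes them markers.
    """
    n_types = len(cfg.type_names)
    n_markers = max(1, int(round(cfg.marker_fraction * cfg.n_genes)))
    if cfg.programs is not None:
        mask = np.zeros(cfg.n_genes, dtype=bool)
        spread = cfg.programs.max(axis=0) > 2 * np.maximum(
            cfg.programs.min(axis=0), 1e-12)
        mask[spread] = True
        return cfg.programs, mask
    base = rng.lognormal(mean=0.0, sigma=1.0, size=cfg.n_genes)
    if n_markers * n_types > cfg.n_genes:
        raise ValueError("marker_fraction too large for disjoint marker sets")
    order = rng.permutation(cfg.n_genes)
    programs = np.tile(base, (n_types, 1))
    marker_mask = np.zeros(cfg.n_genes, dtype=bool)
    for t in range(n_types):
        markers = order[t * n_markers:(t + 1) * n_markers]
        # markers are near-exclusive: high in their own type, near-silent
        # elsewhere (the on/off pattern of canonical cell-type markers)
        programs[:, markers] = base[markers] * cfg.marker_off_level
        programs[t, markers] = base[markers] * cfg.marker_fold
        marker_mask[markers] = True
    return programs, marker_mask


def _allocate_types(comp, n_cells: int) -> np.ndarray:
    """Deterministic largest-remainder allocation of cells to types."""
    raw = np.asarray(comp, dtype=float) * n_cells
    counts = np.floor(raw).astype(int)
    remainder = raw - counts
    short = n_cells - counts.sum()
    for t in np.argsort(-remainder)[:short]:
        counts[t] += 1
    return np.repeat(np.arange(len(comp)), counts)


def simulate_pair(cfg: SimulationConfig) -> "tuple[list, SyntheticTruth]":
    """Generate one CountMatrix per dataset plus the ground truth.

    Per cell: the type follows the dataset's composition (deterministic
    largest-remainder counts, shuffled order); the library size is lognormal
    with mean equal to the dataset depth; gene counts are negative binomial
    around the library-scaled type program; droplet-style dropout keeps each
    count with probability logistic in the log expected count.
    """
    rng = np.random.default_rng(cfg.seed)
    programs, marker_mask = _make_programs(cfg, rng)
    gene_ids = np.array([f"g{i:05d}" for i in range(cfg.n_genes)], dtype=object)
    datasets: list = []
    all_types: list = []
    all_ds: list = []
    per_ds_types: list = []
    for d in range(cfg.n_datasets):
        n = cfg.n_cells[d]
        types = _allocate_types(cfg.compositions[d], n)
        rng.shuffle(types)
        lib = cfg.depths[d] * rng.lognormal(
            mean=-cfg.library_sigma ** 2 / 2.0, sigma=cfg.library_sigma, size=n)
        p = programs[types]  # cells x genes
        p = p / p.sum(axis=1, keepdims=True)
        mu = p * lib[:, None]
        # transcriptional bursting: a gene is "on" in a fraction of cells;
        # conditional mean is inflated so the marginal mean stays mu.  This
        # biological zero-inflation is shared across platforms.
        if cfg.burst_prob < 1.0:
            on = rng.random(mu.shape) < cfg.burst_prob
            on[:, marker_mask] = True  # markers are constitutively expressed
            scale = np.ones(cfg.n_genes)
            scale[~marker_mask] = 1.0 / cfg.burst_prob
            mu = np.where(on, mu * scale, 0.0)
        shape = 1.0 / cfg.dispersion
        with np.errstate(invalid="ignore"):
            lam = rng.gamma(shape=shape, scale=mu / shape)
        lam = np.nan_to_num(lam, nan=0.0)
        counts = rng.poisson(lam).astype(float)
        if cfg.dropout[d] is not None:
            midpoint, slope = cfg.dropout[d]
            keep_p = expit(slope * (np.log(mu + 1e-12) - midpoint))
            counts *= rng.random(mu.shape) < keep_p
        # a cell with zero total count has no library size; resample unlikely
        # empties onto the highest-mean gene instead
        empty = counts.sum(axis=1) == 0
        if empty.any():
            counts[empty, np.argmax(mu[empty], axis=1)] = 1
        cell_ids = np.array(
            [f"{cfg.platforms[d]}_c{j:05d}" for j in range(n)], dtype=object)
        datasets.append(CountMatrix(
            values=counts.T,  # genes x cells
            gene_ids=gene_ids,
            cell_ids=cell_ids,
            platform=cfg.platforms[d],
        ))
        type_names = np.asarray(cfg.type_names, dtype=object)
        per_ds_types.append(type_names[types])
        all_types.append(type_names[types])
        all_ds.append(np.full(n, cfg.platforms[d], dtype=object))
    truth = SyntheticTruth(
        type_label=np.concatenate(all_types),
        dataset_label=np.concatenate(all_ds),
        programs=programs,
        per_dataset_types=per_ds_types,
    )
    return datasets, truth


def scenario(name: str, **overrides) -> SimulationConfig:
    """Documented simulation presets for the canonical integration scenarios.

    * ``equal_composition`` — two types, 50/50 in both datasets; depth differs
      3x between the plate-like and droplet-like dataset.  Re-scaling should
      be (close to) a no-op here.
    * ``skewed_composition`` — 50/50 vs 80/20 over the same two types: the
      composition skew that distorts unit-variance scaling.
    * ``disjoint_types`` — each dataset has two private types and none shared;
      nothing should align and nothing should be forced to mix.
    * ``rare_type`` — a type at 0.4% frequency present in both datasets, the
      label-transfer stress case.
    * ``multi_tissue`` — four datasets sharing one immune-like type, each with
      one exclusive type.
    """
    if name == "equal_composition":
        cfg = SimulationConfig(
            type_names=("type0", "type1"),
            compositions=((0.5, 0.5), (0.5, 0.5)),
            platforms=("plate", "droplet"),
        )
    elif name == "skewed_composition":
        cfg = SimulationConfig(
            type_names=("type0", "type1"),
            compositions=((0.5, 0.5), (0.8, 0.2)),
            platforms=("plate", "droplet"),
        )
    elif name == "disjoint_types":
        cfg = SimulationConfig(
            type_names=("type0", "type1", "type2", "type3"),
            compositions=((0.5, 0.5, 0.0, 0.0), (0.0, 0.0, 0.5, 0.5)),
            platforms=("plate", "droplet"),
        )
    elif name == "rare_type":
        cfg = SimulationConfig(
            type_names=("type0", "type1", "rare"),
            compositions=((0.55, 0.446, 0.004), (0.55, 0.446, 0.004)),
            platforms=("plate", "droplet"),
        )
    elif name == "multi_tissue":
        comps = []
        for d in range(4):
            row = [0.3, 0.0, 0.0, 0.0, 0.0]
            row[d + 1] = 0.7
            comps.append(tuple(row))
        cfg = SimulationConfig(
            type_names=("immune", "tissueA", "tissueB", "tissueC", "tissueD"),
            compositions=tuple(comps),
            n_cells=(800, 800, 800, 800),
            depths=(300_000.0, 100_000.0, 100_000.0, 100_000.0),
            dropout=(None, (0.0, 1.5), (0.0, 1.5), (0.0, 1.5)),
            platforms=("tissueA_ds", "tissueB_ds", "tissueC_ds", "tissueD_ds"),
        )
    else:
        raise ValueError(f"unknown scenario {name!r}; available: {_PRESETS}")
    if overrides:
        import dataclasses
        cfg = dataclasses.replace(cfg, **overrides)
    return cfg
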