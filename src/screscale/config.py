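"""Run configuration: one validated object threaded through the pipeline."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    """All tunable parameters of the integration pipeline.

    A single global ``seed`` fans out to per-stage seeds through a
    counter-based derivation (see :meth:`stage_seed`), so adding a stage does
    not perturb the randomness of earlier stages.
    """

    scale_factor: float = 10_000.0
    n_hvg: int = 4000
    hvg_method: str = "vst"  # or "dispersion"
    n_pcs: int = 30
    k_neighbors: int = 20
    cluster_algorithm: str = "louvain"  # or "leiden"
    resolution_range: tuple = (0.1, 2.0)
    resolution_step: float = 0.1
    seed: int = 0
    n_workers: int = 1
    emit_all_genes: bool = False
    # metric overrides
    mixing_k: int = 5
    mixing_k_max: int = 300
    local_k: int = 20
    ari_resolution: float = 1.0
    transfer_k: int = 10

    def __post_init__(self) -> None:
        if self.scale_factor <= 0:
            raise ValueError("scale_factor must be positive")
        if self.n_hvg <= 0 or self.n_pcs <= 0 or self.k_neighbors <= 0:
            raise ValueError("n_hvg, n_pcs and k_neighbors must be positive")
        if self.hvg_method not in ("vst", "dispersion"):
            raise ValueError(f"unknown hvg_method {self.hvg_method!r}")
        if self.cluster_algorithm not in ("louvain", "leiden"):
            raise ValueError(f"unknown cluster_algorithm {self.cluster_algorithm!r}")
        lo, hi = self.resolution_range
        if not (0 < lo <= hi):
            raise ValueError("resolution_range must satisfy 0 < lo <= hi")
        if self.resolution_step <= 0:
            raise ValueError("resolution_step must be positive")
        if self.mixing_k_max < self.mixing_k:
            raise ValueError("mixing_k_max must be >= mixing_k")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "resolution_range" in d:
            d = dict(d)
            d["resolution_range"] = tuple(d["resolution_range"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["resolution_range"] = list(d["resolution_range"])
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def stage_seed(self, stage: int) -> int:
        """Derived per-stage seed; stable under adding later stages."""
        blob = f"{self.seed}:{stage}".encode()
        return int.from_bytes(hashlib.sha256(blob).digest()[:4], "big") % (2**31)

    def resolutions(self) -> list:
        """The resolution grid values along one axis."""
        lo, hi = self.resolution_range
        vals = []
        r = lo
        while r <= hi + 1e-9:
            vals.append(round(r, 10))
            r += self.resolution_step
        return vals
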