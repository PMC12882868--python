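"""Pipeline configuration.

All numeric knobs of the funnel live in one dataclass so that every report can
echo the exact parameter set that produced it. Defaults follow the published
screening conventions: Pearson threshold 0.85 (the minimum adopted by the
PhytoMine co-expression service), 50 kb tandem-duplication window, alignment
trimming at gap fraction 0.5 with a 10% column-retention floor, five atlas
clusters, two internode clusters, a shortlist floor of 11 annotated target
genes, and alpha = 0.05 for the validation statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Any


@dataclass
class PipelineConfig:
    r_min: float = 0.85
    tandem_gap_bp: int = 50_000
    gap_threshold: float = 0.5
    min_conserve: float = 0.10
    k_atlas: int = 5
    k_internode: int = 2
    min_targets: int = 11
    alpha: float = 0.05
    nterm_limit: int = 200
    max_inter_repeat_gap: int = 30
    pssm_threshold_fraction: float = 0.45
    n_bootstrap: int = 100
    min_support: float = 50.0
    distance: str = "correlation"
    linkage: str = "average"
    internode_mode: str = "cocluster_with_terminal"
    log2p1: bool = False
    welch: bool = False
    seed: int = 0
    extras: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (-1.0 < self.r_min <= 1.0):
            raise ValueError(f"r_min must be in (-1, 1], got {self.r_min}")
        if self.tandem_gap_bp <= 0:
            raise ValueError("tandem_gap_bp must be positive")
        if not (0.0 < self.gap_threshold <= 1.0):
            raise ValueError("gap_threshold must be in (0, 1]")
        if not (0.0 < self.min_conserve <= 1.0):
            raise ValueError("min_conserve must be in (0, 1]")
        if self.k_atlas < 2 or self.k_internode < 2:
            raise ValueError("cluster counts must be >= 2")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        if not (0.0 < self.pssm_threshold_fraction < 1.0):
            raise ValueError("pssm_threshold_fraction must be in (0, 1)")
        if self.min_targets < 0:
            raise ValueError("min_targets must be >= 0")
        if self.distance not in ("correlation", "euclidean"):
            raise ValueError(f"unknown distance {self.distance!r}")
        if self.linkage not in ("average", "complete", "ward"):
            raise ValueError(f"unknown linkage {self.linkage!r}")
        if self.internode_mode not in ("cocluster_with_terminal", "peak_zone"):
            raise ValueError(f"unknown internode_mode {self.internode_mode!r}")

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__ if f != "extras"}
        kwargs = {k: v for k, v in d.items() if k in known}
        extras = {k: v for k, v in d.items() if k not in known}
        return cls(**kwargs, extras=extras)
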