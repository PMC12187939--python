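"""Pipeline configuration.

Collects the numeric thresholds used across the pipeline in one dataclass so
every stage reads the same constants and a YAML file can override them.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path
from typing import Union

import yaml


@dataclass
class PipelineConfig:
    """Thresholds and window sizes applied across the pipeline.

    Attributes
    ----------
    promoter_window_bp : int
        Half-width of the promoter window around the TSS (±1 kb).
    link_resolution_bp : int
        Bin size for aligning link anchors (5 kb contact-map resolution).
    n_shuffles : int
        Number of genome-wide link shuffles for the empirical null.
    shuffle_alpha : float
        A link is significant when its bin pair recurs in fewer than this
        fraction of shuffles (strict <).
    ccscore_min : float
        Minimum contact-count score for a candidate link (inclusive).
    consensus_min_conditions : int
        Conditions (of 4) a nascent-transcription peak must pass.
    consensus_logfc_max : float
        Strict upper bound on per-condition log fold change (knockdown-
        responsive means logFC < 0).
    consensus_p_max : float
        Strict upper bound on per-condition p-value.
    chronos_dependent_max : float
        Lines with combined dependency below this are NRF2-dependent.
    """

    promoter_window_bp: int = 1000
    link_resolution_bp: int = 5000
    n_shuffles: int = 1000
    shuffle_alpha: float = 0.05
    ccscore_min: float = 1.0
    consensus_min_conditions: int = 3
    consensus_logfc_max: float = 0.0
    consensus_p_max: float = 0.1
    chronos_dependent_max: float = -0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("promoter_window_bp", "link_resolution_bp", "n_shuffles",
                     "consensus_min_conditions"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not (0.0 < self.shuffle_alpha < 1.0):
            raise ValueError("shuffle_alpha must be in (0, 1)")
        if self.ccscore_min < 0:
            raise ValueError("ccscore_min must be non-negative")

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)
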