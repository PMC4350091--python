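"""Pipeline configuration with YAML round-trip."""

from __future__ import annotations

import os
from dataclasses import asdict, dataclass, field

import yaml

from .core import ConfigError


@dataclass
class PipelineConfig:
    """All thresholds, seeds and paths for one pipeline run.

    Defaults hold the standard operating points: LRT call threshold 24,
    per-sample minimum depth 8, filter alpha 1e-5, MAF stratum bounds
    1% / 5%, 10,000 single-marker permutations, adaptive permutation
    ``r_stop = 10`` / ``b_max = 100000``, and nominal alpha 0.05.
    """

    lrt_threshold: float = 24.0
    min_depth: int = 8
    filter_alpha: float = 1e-5
    qc_alpha: float = 1e-5
    rare_maf: float = 0.01
    lowfreq_maf: float = 0.05
    nominal_alpha: float = 0.05
    permutations: int = 10_000
    r_stop: int = 10
    b_max: int = 100_000
    min_pathway_genes: int = 10
    seed: int = 0
    paths: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        positive = (
            "lrt_threshold", "min_depth", "filter_alpha", "qc_alpha",
            "rare_maf", "lowfreq_maf", "nominal_alpha", "permutations",
            "r_stop", "b_max",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if not self.rare_maf < self.lowfreq_maf <= 0.5:
            raise ConfigError("require rare_maf < lowfreq_maf <= 0.5")
        if self.r_stop > self.b_max:
            raise ConfigError("r_stop cannot exceed b_max")
        for alpha in (self.filter_alpha, self.qc_alpha, self.nominal_alpha):
            if alpha >= 1:
                raise ConfigError("significance thresholds must be < 1")

    def to_yaml(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys: {', '.join(sorted(unknown))}")
        return cls(**data)
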