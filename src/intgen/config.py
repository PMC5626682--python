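"""Run configuration: thresholds, network parameters and the global seed."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import yaml


@dataclass
class StudyConfig:
    """All tunable thresholds of the pipeline.

    Defaults are the study-wide conventions: DE rejection at FDR <= 1%,
    enrichment and ASE at FDR < 5%, module over/under-enrichment calls at
    fold > 2 / fold < 0.6, a 201-gene sliding window (100 flanking genes a
    side), FDR scores capped at +/-50, ASE sites supported by >= 30 reads,
    a signed-network soft power of 12 and 1 Mb CNV recurrence bins.
    """

    fdr_de: float = 0.01
    fdr_enrich: float = 0.05
    fdr_ase: float = 0.05
    over_fold: float = 2.0
    under_fold: float = 0.6
    window_flank: int = 100
    fdr_score_cap: float = 50.0
    min_ase_depth: int = 30
    soft_power: float = 12.0
    min_module_size: int = 30
    merge_height: float = 0.99
    cnv_bin: int = 1_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fdr_de", "fdr_enrich", "fdr_ase"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if not self.over_fold > 1.0 > self.under_fold:
            raise ValueError(
                f"need over_fold > 1 > under_fold, got {self.over_fold}, {self.under_fold}"
            )
        if self.window_flank < 1:
            raise ValueError("window_flank must be >= 1")
        if self.fdr_score_cap <= 0:
            raise ValueError("fdr_score_cap must be positive")
        if self.min_ase_depth < 1:
            raise ValueError("min_ase_depth must be >= 1")
        if self.soft_power < 1:
            raise ValueError("soft_power must be >= 1")
        if self.min_module_size < 1:
            raise ValueError("min_module_size must be >= 1")
        if not 0.0 <= self.merge_height <= 1.0:
            raise ValueError("merge_height must lie in [0, 1]")
        if self.cnv_bin < 1:
            raise ValueError("cnv_bin must be >= 1 bp")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "StudyConfig":
        """Load a config file, applying keyword overrides (CLI flags win)."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data.update(overrides)
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        """Short stable digest of the resolved configuration."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha1(blob).hexdigest()[:12]
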