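"""Run configuration: every tunable of the pipeline with its default.

Defaults follow the analysis protocol: 32 gray levels, co-occurrence
distances 1–5 voxels, region selection at >900 voxels (solo) / >1000 voxels
(best of a homologous pair), bounded inverse-distance similarity, per-subject
feature normalization, Bonferroni family = regions within each measure, and
a 1.5-SD region-deviation threshold. The configuration is serialized into
every output directory so a run can be reproduced exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    gray_levels: int = 32
    distances: tuple[int, ...] = (1, 2, 3, 4, 5)
    min_solo: int = 900
    min_pair: int = 1000
    similarity_variant: str = "bounded"  # "bounded" (1/(1+d)) or "inverse" (1/d)
    feature_norm_scope: str = "subject"  # "subject" or "cohort"
    bonferroni_family: str = "regions"  # "regions" (per measure) or "global"
    deviation_threshold: float = 1.5
    deviation_sd_mode: str = "pooled"  # "pooled" or "region_means"
    edge_sd_mode: str = "edge_means"  # "edge_means" or "pooled"
    seed: int = 0
    input_dir: str = "."
    output_dir: str = "out"

    def __post_init__(self) -> None:
        self.distances = tuple(int(d) for d in self.distances)
        if self.gray_levels < 2:
            raise ValueError("gray_levels must be >= 2")
        if any(d < 1 for d in self.distances):
            raise ValueError("distances must be >= 1")
        if self.similarity_variant not in ("bounded", "inverse"):
            raise ValueError("similarity_variant must be 'bounded' or 'inverse'")
        if self.feature_norm_scope not in ("subject", "cohort"):
            raise ValueError("feature_norm_scope must be 'subject' or 'cohort'")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["distances"] = list(self.distances)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
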