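"""Analysis configuration shared across pipeline stages.

Defaults follow the published 4C analysis settings: a 20-read minimum mean
count for fragments entering the statistical candidate set, a 5-fragment
running-mean window, z >= 1.96 with BH FDR <= 0.1 for interaction calls,
HMM window k = 5 fragments, nominal p < 0.05 for differential fragments,
a 1-Mb SNP window around each viewpoint, >= 10 reads per (SNP, library)
sample for the allelic tally, and a 0.5 binomial null proportion.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, fields
from pathlib import Path

import yaml


@dataclass
class AnalysisConfig:
    min_count: int = 20
    smooth_window: int = 5
    z_thresh: float = 1.96
    fdr_thresh: float = 0.1
    hmm_k: int = 5
    diff_p: float = 0.05
    snp_window: int = 1_000_000
    min_snp_cov: int = 10
    null_prop: float = 0.5
    exclusion_halfwidth: int = 2500

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) <= 0:
                raise ValueError(f"{f.name} must be positive")
        if not 0 < self.null_prop < 1:
            raise ValueError("null_prop must lie in (0, 1)")
        if self.smooth_window % 2 == 0:
            raise ValueError("smooth_window must be odd")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)
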