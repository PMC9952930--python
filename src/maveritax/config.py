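"""Run configuration: every threshold of the workflow in one place.

Defaults are the operating values of the published demarcation and QC
criteria; each is documented where it is used. The full configuration is
serialized into every report header so a run can be audited and replayed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    # marker detection
    marker_min_score: float = 40.0
    marker_max_evalue: float = 0.01
    class_mcp_min_score: float = 50.0
    plv_min_score: float = 50.0
    min_profile_coverage: float = 0.60
    # genome QC
    dtr_min_len: int = 10
    dtr_max_len: int = 5000
    min_intergenic: int = 1000
    gc_window: int = 100
    gc_delta: float = 0.05
    gc_flank: int = 2000
    min_host_flank: int = 2000
    min_checkv: float = 90.0
    min_linear_complete: int = 25000
    # family assignment
    family_floor_bitscore: float = 50.0
    family_max_evalue: float = 1e-3
    # vOTU dereplication
    votu_min_ani: float = 95.0
    votu_min_af: float = 0.85
    # gwAAI grouping
    aai_min_cov: float = 0.50
    aai_max_evalue: float = 1e-5
    aai_min_norm_score: float = 0.05
    mcl_inflation: float = 1.1
    profile_mcl_inflation: float = 5.0
    profile_min_group: int = 10
    # run control
    seed: int = 42
    threads: int = 1
    verbosity: int = 1

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def header_lines(self, version: str) -> list[str]:
        lines = [f"# maveritax {version}", f"# config_hash={self.config_hash()}"]
        lines += [f"# {k}={v}" for k, v in sorted(self.to_dict().items())]
        return lines
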