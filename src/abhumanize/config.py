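"""Run configuration: one declarative object shared by the workflows and CLI."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, Field, field_validator

from .errors import ConfigurationError


class RunConfig(BaseModel):
    """All tunable knobs of the pipeline, round-trippable through YAML."""

    scheme: str = "imgt"
    pool_fasta: str | None = None
    pool_table: str | None = None

    # canonical classification thresholds
    d_interface: float = 4.5
    d_near: float = 6.0
    r_buried: float = 0.20

    # interaction-class distance cutoffs (A)
    hbond_cutoff: float = 3.5
    hydrophobic_cutoff: float = 5.0
    salt_bridge_cutoff: float = 4.0
    pi_pi_cutoff: float = 6.5

    # humanness / immunogenicity
    rank_threshold: float = 1.0
    min_prevalence: float = 0.01
    k: int = Field(default=20, ge=1)

    seed: int = 0
    outdir: str = "results"

    @field_validator(
        "d_interface", "d_near", "r_buried", "hbond_cutoff", "hydrophobic_cutoff",
        "salt_bridge_cutoff", "pi_pi_cutoff", "rank_threshold", "min_prevalence",
    )
    @classmethod
    def _positive(cls, v: float, info):
        if v <= 0:
            raise ValueError(f"{info.field_name} must be positive")
        return v

    def contact_cutoffs(self) -> dict[str, float]:
        return {
            "hbond": self.hbond_cutoff,
            "hydrophobic": self.hydrophobic_cutoff,
            "salt_bridge": self.salt_bridge_cutoff,
            "pi_pi": self.pi_pi_cutoff,
        }

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise ConfigurationError(f"config file not found: {path}")
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        try:
            return cls(**data)
        except Exception as exc:
            raise ConfigurationError(f"invalid config {path}: {exc}") from exc
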