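"""YAML run configuration.

All analysis parameters are configuration defaults rather than hard-coded
constants: 5 A contact cutoff, last-500-ns analysis window sampled every
0.1 ns, 1 A RMSD-fluctuation stability threshold, and per-replica durations
of 50 ns equilibration + 1000 ns production.  Sensitivity re-analysis (e.g.
a cutoff sweep) therefore needs no code change.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, field_validator

from .errors import ConfigError


class RunConfig(BaseModel):
    """Validated pipeline configuration with the analysis defaults."""

    model_config = ConfigDict(extra="forbid")

    # inputs
    fasta: Optional[str] = None
    alignment: Optional[str] = None
    alignment_format: Literal["fasta", "clustal"] = "fasta"
    replicates: list[str] = Field(default_factory=list)  # multi-model PDB paths
    demo: bool = False          # run on generated synthetic replicates
    demo_replicates: int = 3

    # analysis window and thresholds
    last_ns: float = 500.0
    stride_ns: float = 0.1
    cutoff_A: float = 5.0
    rmsd_threshold_A: float = 1.0
    equilibration_ns: float = 50.0
    production_ns: float = 1000.0

    # selections and options
    selection: Literal["heavy", "ca", "all"] = "heavy"
    com_atoms: Literal["heavy", "all"] = "heavy"
    dielectric: float = 4.0
    seed: int = 0
    output_dir: str = "efca_out"

    @field_validator("last_ns", "stride_ns", "cutoff_A", "rmsd_threshold_A",
                     "equilibration_ns", "production_ns", "dielectric")
    @classmethod
    def _positive(cls, v, info):
        if v <= 0:
            raise ValueError(f"{info.field_name} must be positive, got {v}")
        return v

    @property
    def per_replica_total_ns(self) -> float:
        return self.equilibration_ns + self.production_ns


def validate_config(raw: dict | None, strict: bool = True) -> RunConfig:
    """Validate a raw mapping into a :class:`RunConfig`.

    An empty/missing mapping yields the full defaults.  In strict mode
    unknown keys are rejected; otherwise they are dropped.
    """
    raw = dict(raw or {})
    if not strict:
        raw = {k: v for k, v in raw.items() if k in RunConfig.model_fields}
    try:
        return RunConfig(**raw)
    except ValidationError as exc:
        raise ConfigError(str(exc)) from exc


def load_config(path: str | Path, strict: bool = True) -> RunConfig:
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text())
    if raw is not None and not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    return validate_config(raw, strict=strict)
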