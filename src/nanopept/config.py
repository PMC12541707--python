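"""Run configuration: a schema-validated structured file.

One YAML file drives a whole invocation (design, build, fixtures, analysis);
unknown keys are rejected so typos fail loudly.  The canonical-JSON SHA-256
hash of a config is embedded in every output for reproducibility.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .scoring import ScoringParams

__all__ = ["RunConfig", "ScoringConfig", "DesignConfig", "AnalysisConfig",
           "FixtureConfig"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ScoringConfig(_Strict):
    gauss_weight: float = -0.045
    gauss_width: float = Field(0.8, gt=0)
    repulsion_weight: float = 0.8
    hydrophobic_weight: float = -0.035
    hydrophobic_d_on: float = 0.0
    hydrophobic_d_off: float = 2.5
    h_bond_weight: float = -0.6
    h_bond_d_on: float = -0.6
    h_bond_d_off: float = 0.0
    zn_weight: float = -2.0
    zn_ideal: float = Field(2.1, gt=0)
    zn_tolerance: float = Field(0.4, gt=0)
    cutoff: float = Field(8.0, gt=0)

    def to_params(self) -> ScoringParams:
        return ScoringParams(**self.model_dump())


class DesignConfig(_Strict):
    budget: int = Field(500, ge=1)
    stall_length: int = Field(200, ge=1)
    temperature: float = Field(1.0, gt=0)
    n_poses: int = Field(4, ge=1)
    n_pocket_units: int = Field(1, ge=1)
    start_sequence: str = "FFWH"
    c_terminus: str = "amide"


class AnalysisConfig(_Strict):
    cluster_cutoff: float = Field(4.5, gt=0)
    probe_radius: float = Field(1.4, gt=0)
    sasa_points: int = Field(960, ge=100)
    hbond_max_distance: float = Field(3.5, gt=0)
    axis_max_angle: float = Field(30.0, gt=0)
    min_hbonds: int = Field(2, ge=1)
    zn_census_cutoff: float = Field(3.0, gt=0)


class FixtureConfig(_Strict):
    n_peptides: int = Field(8, ge=0)
    n_drugs: int = Field(4, ge=0)
    min_zn: int = Field(1, ge=0)
    box: float = Field(70.0, gt=0)
    min_separation: float = Field(5.0, gt=0)


class RunConfig(_Strict):
    """Top-level configuration; all sections optional with defaults."""

    scoring: ScoringConfig = ScoringConfig()
    design: DesignConfig = DesignConfig()
    analysis: AnalysisConfig = AnalysisConfig()
    fixtures: FixtureConfig = FixtureConfig()
    seed: int = 0
    output_dir: str = "nanopept_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(), fh, sort_keys=True)

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
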