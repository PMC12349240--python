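"""Tabular readers/writers, the run configuration schema and run manifests.

Occurrence tables are CSV with mandatory columns species, lon, lat
(extra columns ride along); rows with unparseable or out-of-bounds
coordinates are rejected into a sidecar report rather than silently dropped.
Configuration files are YAML or JSON validated against a typed schema whose
defaults are the study's settings (2.5′ grids, two 8000-point pseudo-absence
sets, ten runs per learner, TSS cutoff 0.55, suitability breaks 0.2/0.4/0.6,
five-record species minimum). Every pipeline run can be described by a
manifest recording the config hash and per-stage seeds.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator


@dataclass
class OccurrenceReadResult:
    occurrences: pd.DataFrame
    rejected: pd.DataFrame
    n_duplicates: int


def read_occurrences(path: str | Path) -> OccurrenceReadResult:
    """Read and validate an occurrence CSV (species, lon, lat)."""
    df = pd.read_csv(path)
    missing = {"species", "lon", "lat"} - set(df.columns)
    if missing:
        raise ValueError(f"occurrence file is missing columns: {sorted(missing)}")
    lon = pd.to_numeric(df["lon"], errors="coerce")
    lat = pd.to_numeric(df["lat"], errors="coerce")
    bad = lon.isna() | lat.isna() | (lon.abs() > 180) | (lat.abs() > 90)
    rejected = df.loc[bad].copy()
    kept = df.loc[~bad].copy()
    kept["lon"] = lon[~bad]
    kept["lat"] = lat[~bad]
    n_before = len(kept)
    kept = kept.drop_duplicates().reset_index(drop=True)
    return OccurrenceReadResult(
        occurrences=kept,
        rejected=rejected.reset_index(drop=True),
        n_duplicates=n_before - len(kept),
    )


class RunConfig(BaseModel):
    """Typed pipeline configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    resolution_arcmin: float = Field(2.5, gt=0)
    n_pa_per_set: int = Field(8000, ge=1)
    n_pa_sets: int = Field(2, ge=1)
    n_runs: int = Field(10, ge=1)
    tss_min: float = Field(0.55, ge=-1, le=1)
    breaks: tuple[float, float, float] = (0.2, 0.4, 0.6)
    min_n: int = Field(5, ge=1)
    presence_threshold: float = Field(0.2, ge=0, lt=1)
    r_max: float = Field(0.7, gt=0, le=1)
    vif_max: float = Field(5.0, gt=1)
    learners: tuple[str, ...] = ("glm", "rf", "gbm")
    seed: int = 0

    @field_validator("breaks")
    @classmethod
    def _breaks_increasing(cls, v):
        if not (0 < v[0] < v[1] < v[2] < 1):
            raise ValueError("breaks must be strictly increasing within (0,1)")
        return v


def validate_config(path: str | Path) -> RunConfig:
    """Load a YAML/JSON config file, inject defaults, reject unknown keys."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    return RunConfig(**data)


def config_hash(cfg: RunConfig) -> str:
    payload = json.dumps(cfg.model_dump(), sort_keys=True, default=list)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def stage_seed(root_seed: int, stage: str) -> int:
    """Named 31-bit substream seed derived from the root seed."""
    digest = hashlib.sha256(stage.encode()).digest()
    tag = int.from_bytes(digest[:4], "big")
    return int(np.random.SeedSequence([root_seed, tag]).generate_state(1)[0] % (2**31))


@dataclass
class RunManifest:
    """Reproducibility record for one pipeline run."""

    tool_version: str
    config: dict
    config_digest: str
    seeds: dict = field(default_factory=dict)
    input_digests: dict = field(default_factory=dict)
    decisions: list = field(default_factory=list)
    timings_s: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, sort_keys=True,
                                         default=str))

    @staticmethod
    def from_json(path: str | Path) -> "RunManifest":
        return RunManifest(**json.loads(Path(path).read_text()))


def file_digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def build_manifest(cfg: RunConfig, inputs: dict[str, str | Path] | None = None,
                   stages=("simulate", "indexes", "profile", "sdm", "dynamics")) -> RunManifest:
    from . import __version__

    return RunManifest(
        tool_version=__version__,
        config=json.loads(cfg.model_dump_json()),  # JSON-stable round trip
        config_digest=config_hash(cfg),
        seeds={s: stage_seed(cfg.seed, s) for s in stages},
        input_digests={k: file_digest(v) for k, v in (inputs or {}).items()},
    )
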