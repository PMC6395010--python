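"""Schema-versioned pipeline configuration.

A single YAML file drives both simulation and analysis, so that an
end-to-end run is one-command reproducible.  Unknown keys are rejected,
every seed is explicit, and a config round-trips through serialization
losslessly (the config hash recorded in run logs is stable).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field

SCHEMA_VERSION = 1


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimulateConfig(_Section):
    shape: tuple[int, int, int] = (32, 16, 8)
    n_regions: int = 4
    n_sources: int = 4
    probe: str = "gcamp6f"
    duration_s: float = 20.0
    frame_rate_hz: float = 25.0
    voxel_size_um: tuple[float, float, float] = (3.0, 3.0, 6.0)
    baseline: float = 100.0
    amplitude: float = 25.0
    motion_amp_voxels: float = 0.0
    gaussian_sd: float = 2.0
    poisson_scale: float = 0.0
    bleach_fraction_30s: float | None = None  # probe default when unset


class PreprocessConfig(_Section):
    discard_initial_s: float = 5.0  # excitation-onset transient
    motion_correct: bool = True
    motion_reference: str = "mean"
    detrend_window_s: float = 20.0
    kalman_gain: float = 0.5
    svd_removal: str = "off"  # off | auto
    highpass_window_s: float | None = None
    dff_baseline: str = "mean"


class SourcesConfig(_Section):
    n_presvd: int = 2
    n_components: int | None = None  # None: 2x shoulder rule
    fallback_n: int = 20
    seed: int = 0
    max_iter: int = 500
    tol: float = 1.0e-4
    mask_k: float = 3.0


class AtlasConfig(_Section):
    artifact_rule: str = "or"
    max_regions: int = 5
    max_objects: int = 200
    connectivity: int = 26
    presence_fraction: float = 0.005


class MapstatsConfig(_Section):
    r_min: float = 0.1
    stimulus_window_s: float = 1.0
    xcorr_max_lag_s: float = 0.5
    kernel_decay_s: float | None = None  # probe default when unset


class PipelineConfig(_Section):
    schema_version: int = SCHEMA_VERSION
    seed: int = 0
    simulate: SimulateConfig = Field(default_factory=SimulateConfig)
    preprocess: PreprocessConfig = Field(default_factory=PreprocessConfig)
    sources: SourcesConfig = Field(default_factory=SourcesConfig)
    atlas: AtlasConfig = Field(default_factory=AtlasConfig)
    mapstats: MapstatsConfig = Field(default_factory=MapstatsConfig)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls.model_validate(raw)
        if cfg.schema_version != SCHEMA_VERSION:
            raise ValueError(f"unsupported schema_version {cfg.schema_version}")
        return cfg

    def to_yaml(self, path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.model_dump(mode="json"), sort_keys=True))
        return path

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]
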