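"""Pipeline configuration: YAML loading, validation, profiles, seed policy.

A single global seed drives every stage; per-stage seeds are derived by
stable hashing of (seed, stage name, repeat index), so reruns with the same
config reproduce all deterministic artifacts. Two profiles are exposed:
``desk`` (small sizes suitable for CPU runs; the test default) and ``paper``
(the published GPU-scale hyperparameters).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class PhantomConfig(_Strict):
    image_size: int = Field(64, ge=8)
    counts: dict[str, int] | Literal["study_original"] = "study_original"
    rotation_deg: float = Field(15.0, ge=0)
    gain_range: float = Field(0.20, ge=0, lt=1)
    noise_sigma: float = Field(4.0, ge=0)


class DDPMConfig(_Strict):
    epochs: int = Field(10, ge=1)
    steps: int | None = Field(None, ge=1)
    learning_rate: float = Field(1e-4, gt=0)
    batch_size: int = Field(16, ge=1)
    input_size: int = Field(32, ge=8)
    T: int = Field(200, ge=1)
    s: float = Field(0.008, gt=0)
    base_channels: int = Field(16, ge=1)
    samples_per_class: int = Field(8, ge=1)


class CurationConfig(_Strict):
    enabled: bool = True
    sharpness_quantile: float = Field(0.05, ge=0, le=1)
    require_two_folds: bool = True


class ExperimentsConfig(_Strict):
    scenarios: list[str] = ["synthetic_only", "mix10", "mix50"]
    tasks: list[str] = ["binary", "multiclass"]
    repeats: int = Field(3, ge=2)
    batch_size: int = Field(16, ge=1)
    learning_rate: float = Field(1e-4, gt=0)
    epochs: int = Field(20, ge=1)
    validation_fraction: float = Field(0.2, gt=0, lt=1)
    backbone: str = "desk-cnn4"
    warm_start: str | None = None
    base_channels: int = Field(16, ge=1)


class EvalConfig(_Strict):
    averaging: Literal["macro", "weighted"] = "macro"
    fid_components: int = Field(16, ge=2)
    compute_fid: bool = True


class PipelineConfig(_Strict):
    profile: Literal["desk", "paper"] = "desk"
    seed: int = Field(0, ge=0)
    output_root: str = "vfaug_output"
    phantom: PhantomConfig = PhantomConfig()
    ddpm: DDPMConfig = DDPMConfig()
    curation: CurationConfig = CurationConfig()
    experiments: ExperimentsConfig = ExperimentsConfig()
    evaluation: EvalConfig = EvalConfig()

    @model_validator(mode="after")
    def _apply_profile(self) -> "PipelineConfig":
        if self.profile == "paper" and not getattr(self, "_profile_applied", False):
            object.__setattr__(self, "_profile_applied", True)
            # The study's published DDPM listing (GPU scale).
            self.ddpm.epochs = 1024
            self.ddpm.steps = 10_000
            self.ddpm.batch_size = 32
            self.ddpm.input_size = 256
            self.ddpm.T = 10_000
            self.ddpm.base_channels = 64
            self.phantom.image_size = 256
            self.experiments.repeats = 10
        return self

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.model_dump(), sort_keys=True).encode()
        ).hexdigest()[:12]

    def dump_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(), sort_keys=True))


def load_config(path: str | Path | None = None,
                overrides: dict | None = None) -> PipelineConfig:
    """Load and validate a YAML config; an empty/missing body means defaults.

    Unknown keys and invalid values raise a descriptive validation error
    naming the offending key.
    """
    data: dict = {}
    if path is not None:
        p = Path(path)
        if not p.exists():
            raise FileNotFoundError(f"config file not found: {p}")
        loaded = yaml.safe_load(p.read_text())
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValueError("config file must contain a YAML mapping")
        data = loaded
    if overrides:
        data = _deep_merge(data, overrides)
    return PipelineConfig(**data)


def _deep_merge(base: dict, extra: dict) -> dict:
    out = dict(base)
    for k, v in extra.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = v
    return out
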