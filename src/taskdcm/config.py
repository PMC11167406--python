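"""Single configuration object for the whole pipeline, YAML/JSON backed."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .cohort import GroupSpec, HemodynamicParameters, default_group_mean
from .dcm import PriorSpec, VLOptions
from .protocol import ProtocolParams, RTParams


@dataclass(frozen=True)
class GroupSpecConfig:
    """GroupSpec minus the mean matrices (those come from the planted-edge
    defaults or from explicit arrays supplied in code)."""

    sd_a: float = 0.02
    sd_self: float = 0.05
    sd_b: float = 0.08
    sd_c: float = 0.08
    noise_sd: float = 0.1
    global_amp: float = 0.5
    motion_amp: float = 0.15
    nuisance_amp: float = 0.1
    n_subjects: int = 20
    n_motion: int = 6
    voxel_spacing_mm: float = 4.0
    peak_jitter_sd_mm: float = 2.5
    weight_fwhm_mm: float = 10.0

    def build(self, mean=None) -> GroupSpec:
        return GroupSpec(
            mean=mean if mean is not None else default_group_mean(),
            **dataclasses.asdict(self),
        )


@dataclass(frozen=True)
class GLMConfig:
    prewhiten_ar1: bool = False
    cluster_forming_p: float = 0.01
    n_permutations: int = 200
    highpass_cutoff_s: float = 128.0
    model_instructions: bool = False


@dataclass(frozen=True)
class GridConfig:
    gsr_levels: tuple[str, ...] = ("with", "without")
    design_levels: tuple[str, ...] = ("AllTrials", "STrials", "Blocks")
    contrast_levels: tuple[str, ...] = ("Anti", "AntiPlusPro")
    thresholding_levels: tuple[str, ...] = ("corrected", "uncorrected")


@dataclass(frozen=True)
class PipelineConfig:
    protocol: ProtocolParams = field(default_factory=ProtocolParams)
    rt: RTParams = field(default_factory=RTParams)
    error_rate: float = 0.03
    group: GroupSpecConfig = field(default_factory=GroupSpecConfig)
    hemo: HemodynamicParameters = field(default_factory=HemodynamicParameters)
    glm: GLMConfig = field(default_factory=GLMConfig)
    priors: PriorSpec = field(default_factory=PriorSpec)
    vl: VLOptions = field(default_factory=VLOptions)
    grid: GridConfig = field(default_factory=GridConfig)
    #: generative ("ground truth") stimulus binding of the simulated cohorts
    truth_design: str = "AllTrials"
    truth_contrast: str = "Anti"
    ev_threshold_percent: float = 10.0
    seed: int = 0


def _coerce(ftype, value):
    """Best-effort coercion of YAML scalars/lists into dataclass field types."""
    import typing

    origin = typing.get_origin(ftype)
    if dataclasses.is_dataclass(ftype) and isinstance(value, dict):
        return _from_dict(ftype, value)
    if origin is tuple and isinstance(value, (list, tuple)):
        return tuple(value)
    if ftype is float and value is not None:
        return float(value)
    if ftype is int and value is not None:
        return int(value)
    return value


def _from_dict(cls, d: dict):
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name in d:
            kwargs[f.name] = _coerce(f.type if not isinstance(f.type, str) else
                                     _resolve_type(cls, f.name), d[f.name])
    return cls(**kwargs)


def _resolve_type(cls, name):
    import typing

    hints = typing.get_type_hints(cls)
    return hints.get(name, object)


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return _from_dict(PipelineConfig, data)


def dump_config(config: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_jsonable(dataclasses.asdict(config)), fh,
                       sort_keys=False)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if hasattr(obj, "item"):
        return obj.item()
    return obj


def config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(_jsonable(dataclasses.asdict(config)), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]
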