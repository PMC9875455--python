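"""YAML configuration loading for the command-line interface."""

from __future__ import annotations

import math
from pathlib import Path

import yaml

from .phantom import PhantomSpec
from .study import Condition, JitterSpec, StudyConfig

__all__ = ["phantom_spec_from_dict", "study_config_from_dict", "load_yaml"]

_TUPLE_FIELDS = {"grid_shape", "voxel_size", "eigenvalues", "center"}


def load_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def phantom_spec_from_dict(d: dict) -> PhantomSpec:
    kwargs = dict(d)
    if str(kwargs.get("snr", "")).lower() in {"inf", "infinity"}:
        kwargs["snr"] = math.inf
    for key in _TUPLE_FIELDS & kwargs.keys():
        if kwargs[key] is not None:
            kwargs[key] = tuple(kwargs[key])
    return PhantomSpec(**kwargs)


def study_config_from_dict(d: dict) -> StudyConfig:
    kwargs = dict(d)
    if "base_spec" in kwargs:
        kwargs["base_spec"] = phantom_spec_from_dict(kwargs["base_spec"])
    if "jitter" in kwargs:
        kwargs["jitter"] = JitterSpec(**kwargs["jitter"])
    if "conditions" in kwargs:
        kwargs["conditions"] = tuple(Condition(**c) for c in kwargs["conditions"])
    if "shells" in kwargs:
        kwargs["shells"] = tuple(float(b) for b in kwargs["shells"])
    return StudyConfig(**kwargs)
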