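"""YAML configuration loading for design specs, generative parameters and
model lists, plus JSON provenance sidecars."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import yaml

from .design import DesignSpec
from .lmm import ModelSpec
from .simulate import GenerativeParams


def _filtered_kwargs(cls, mapping: dict) -> dict:
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(mapping) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} fields: {sorted(unknown)}")
    out = {}
    for k, v in mapping.items():
        if isinstance(v, list):
            v = tuple(v)
        out[k] = v
    return out


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def design_from_dict(d: dict | None) -> DesignSpec:
    return DesignSpec(**_filtered_kwargs(DesignSpec, d or {}))


def params_from_dict(d: dict | None) -> GenerativeParams:
    return GenerativeParams(**_filtered_kwargs(GenerativeParams, d or {}))


def model_specs_from_dict(d: dict) -> list[ModelSpec]:
    """``{name: [term, ...], ...}`` -> validated ModelSpecs."""
    specs = []
    for name, terms in d.items():
        spec = ModelSpec(name=name, fixed_terms=tuple(terms))
        spec.validate()
        specs.append(spec)
    return specs


def write_provenance(path: str | Path, **fields) -> None:
    """JSON sidecar recording seeds and parameters next to an output."""
    payload = {}
    for k, v in fields.items():
        if dataclasses.is_dataclass(v) and not isinstance(v, type):
            v = dataclasses.asdict(v)
        payload[k] = v
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=str)
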