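"""Pipeline configuration: one serialisable object holding every knob.

Defaults reproduce the documented conventions of each stage (search
schemes, ANI fragment filters, AAI/POCP thresholds, HGT rule parameters,
fold weights, delineation thresholds). ``to_yaml``/``from_yaml`` round-trip
through a single human-readable file.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field, fields, is_dataclass

import yaml

from .align import SchemeSpec, SearchParams
from .decision import DelineationThresholds
from .fold import FoldParams
from .hgt import HgtParams
from .metrics import AaiParams, AniParams, PocpParams
from .phylo import P_DISTANCE


@dataclass
class PipelineConfig:
    seed: int = 0
    thresholds: DelineationThresholds = field(default_factory=DelineationThresholds)
    ani: AniParams = field(default_factory=AniParams)
    aai: AaiParams = field(default_factory=AaiParams)
    pocp: PocpParams = field(default_factory=PocpParams)
    hgt: HgtParams = field(default_factory=HgtParams)
    fold: FoldParams = field(default_factory=FoldParams)
    bootstrap_reps: int = 100
    distance_model: str = P_DISTANCE
    motif_file: str | None = None

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


def _build(cls, data):
    if data is None:
        return None
    kwargs = {}
    for f in fields(cls):
        if f.name not in data:
            continue
        value = data[f.name]
        if f.name == "scheme":
            kwargs[f.name] = _build(SchemeSpec, value)
        elif f.name == "search":
            kwargs[f.name] = _build(SearchParams, value)
        else:
            kwargs[f.name] = value
    return cls(**kwargs)


_NESTED = {
    "thresholds": DelineationThresholds,
    "ani": AniParams,
    "aai": AaiParams,
    "pocp": PocpParams,
    "hgt": HgtParams,
    "fold": FoldParams,
}


def config_from_dict(data: dict) -> PipelineConfig:
    kwargs = {}
    for f in fields(PipelineConfig):
        if f.name not in data:
            continue
        if f.name in _NESTED:
            kwargs[f.name] = _build(_NESTED[f.name], data[f.name])
        else:
            kwargs[f.name] = data[f.name]
    return PipelineConfig(**kwargs)


def from_yaml(text: str) -> PipelineConfig:
    return config_from_dict(yaml.safe_load(text) or {})
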