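"""Run configuration: one validated record of every experiment knob.

Defaults mirror the reference experimental setting: MMSP frame features
(true-mean variant), TPMM temporal pooling, both streams fused, 1 fps frame
sampling, linear SVM with C = 1.  The full config is echoed verbatim into
every results file so runs are reproducible from their outputs alone.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .errors import SchemaError

_ENUMS = {
    "backbone_provider": ("vgg16", "mock"),
    "backbone_layer": ("pool5", "fc7"),
    "spatial_mode": ("true_mean", "paper_literal"),
    "temporal_pooling": ("tpmm", "max", "mean"),
    "streams": ("appearance", "motion", "both"),
    "normalization": ("per_modality_then_fused", "after_concat"),
    "magnitude_norm": ("per_frame", "fixed"),
}


@dataclass
class RunConfig:
    backbone_provider: str = "mock"
    backbone_layer: str = "pool5"
    spatial_mode: str = "true_mean"
    temporal_pooling: str = "tpmm"
    streams: str = "both"
    target_fps: float = 1.0
    svm_cost: float = 1.0
    normalization: str = "per_modality_then_fused"
    magnitude_norm: str = "per_frame"
    magnitude_cap: float | None = None
    sample_offset: int = 0
    seed: int = 0
    cache_dir: str = "cache"

    def __post_init__(self) -> None:
        for name, allowed in _ENUMS.items():
            value = getattr(self, name)
            if value not in allowed:
                raise SchemaError(
                    f"config key {name!r}: {value!r} not in {allowed}"
                )
        if self.target_fps <= 0:
            raise SchemaError("target_fps must be positive")
        if self.svm_cost <= 0:
            raise SchemaError("svm_cost must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        if not isinstance(raw, dict):
            raise SchemaError(f"config file {path} is not a key/value mapping")
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise SchemaError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        return path
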