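"""Pipeline configuration: defaults reproduce the published parameter set.

A bare run uses fuzzifier/typicality 1.5, membership/typicality weights
0.5/0.5, 30 nests over cluster counts [1000, 2500], expected accuracy
0.99, alpha 0.1, Levy exponent 1.5, discovery probability 0.25, tolerance
0.001, 100 generations, and staging thresholds (0.05, 0.1, 0.3) with
brown tolerance 0.007.  YAML (or an equivalent JSON mapping) overrides any
subset of fields.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .fknn import FknnConfig
from .model_selection import CSConfig
from .segmentation import SegmentationConfig
from .staging import StageThresholds
from .upfc import UPFCParams


@dataclass
class PipelineConfig:
    upfc: UPFCParams = field(default_factory=UPFCParams)
    cuckoo: CSConfig = field(default_factory=CSConfig)
    fknn: FknnConfig = field(default_factory=FknnConfig)
    thresholds: StageThresholds = field(default_factory=StageThresholds)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    seed: int | None = None

    _SECTIONS = {
        "upfc": UPFCParams,
        "cuckoo": CSConfig,
        "fknn": FknnConfig,
        "thresholds": StageThresholds,
        "segmentation": SegmentationConfig,
    }

    @classmethod
    def from_mapping(cls, data: dict) -> "PipelineConfig":
        kwargs = {}
        data = dict(data or {})
        for name, section_cls in cls._SECTIONS.items():
            section = data.pop(name, None)
            if section is not None:
                valid = {f.name for f in dataclasses.fields(section_cls)}
                unknown = set(section) - valid
                if unknown:
                    raise ValueError(f"unknown keys in '{name}': {sorted(unknown)}")
                if "bounds" in section:
                    section["bounds"] = tuple(section["bounds"])
                kwargs[name] = section_cls(**section)
        seed = data.pop("seed", None)
        if data:
            raise ValueError(f"unknown config sections: {sorted(data)}")
        return cls(seed=seed, **kwargs)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_mapping(yaml.safe_load(Path(path).read_text()) or {})

    def to_mapping(self) -> dict:
        out = {name: dataclasses.asdict(getattr(self, name)) for name in self._SECTIONS}
        out["cuckoo"]["bounds"] = list(out["cuckoo"]["bounds"])
        out["seed"] = self.seed
        return out

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_mapping(), sort_keys=False))

    def with_seed(self, seed) -> "PipelineConfig":
        cfg = dataclasses.replace(self)
        if seed is not None:
            cfg.seed = int(seed)
            cfg.cuckoo = dataclasses.replace(cfg.cuckoo, seed=int(seed))
        return cfg
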