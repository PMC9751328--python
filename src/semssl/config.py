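"""Hierarchical run configuration with deterministic per-stage seeding.

A :class:`RunConfig` mirrors the pipeline stages; every stochastic stage
receives a seed derived from the global seed and the stage name, so a
whole run is reproducible from one integer and stage reruns are stable
regardless of execution order.
"""

from __future__ import annotations

import zlib
from dataclasses import asdict, dataclass, field, fields, replace
from pathlib import Path
from typing import Dict, Optional

import yaml

from .patches import SplitPlan
from .preprocess import PreprocessConfig
from .ssl import AugmentPolicy, PretrainConfig
from .downstream import ProbeConfig
from .synthetic import SceneSpec


def derive_seed(global_seed: int, stage: str) -> int:
    """Stable stage seed below 2**31."""
    return (int(global_seed) * 0x9E3779B1 + zlib.crc32(stage.encode())) & 0x7FFFFFFF


@dataclass
class SynthConfig:
    """Desk-scale study conditions: 512x512 frames of a heavily crowded
    biofilm (large corrosion crusts and dense cell clusters can fully
    occlude a 64x64 window), acquired at the high-magnification end of the
    emulated instrument so no super-resolution is triggered."""

    n_images: int = 12
    scene: SceneSpec = field(default_factory=lambda: SceneSpec(
        width=512, height=512, n_cells=60, n_clusters=8,
        cluster_size_range=(4, 10), n_byproduct_blobs=22,
        byproduct_radius_range=(16, 96), meta_strip_height=40,
        magnification_label=2300.0, scale_um=2.0))


@dataclass
class PatchifyConfig:
    kernel: int = 64
    stride: Optional[int] = None     # None -> derived from overlap preset
    overlap: float = 0.5             # 0.5 -> stride = kernel/2
    min_fraction: float = 0.01
    split: SplitPlan = field(default_factory=SplitPlan)

    def resolved_stride(self) -> int:
        if self.stride is not None:
            return int(self.stride)
        return max(1, int(round(self.kernel * (1.0 - self.overlap))))


@dataclass
class EvaluateConfig:
    folds: int = 10
    scheme: str = "repeated_split"   # or "kfold"


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "runs/default"
    log_level: str = "info"
    synth: SynthConfig = field(default_factory=SynthConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    patchify: PatchifyConfig = field(default_factory=PatchifyConfig)
    ssl: PretrainConfig = field(default_factory=PretrainConfig)
    # the fine-tune pool handed to this stage is already the 10% labeled
    # share of the data, so by default all of it is used
    downstream: ProbeConfig = field(default_factory=lambda: ProbeConfig(
        mode="finetune", label_fraction=1.0))
    evaluate: EvaluateConfig = field(default_factory=EvaluateConfig)

    def stage_seed(self, stage: str) -> int:
        return derive_seed(self.seed, stage)

    def to_dict(self) -> Dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, raw: Dict) -> "RunConfig":
        def build(dc_type, data):
            if data is None:
                return dc_type()
            kwargs = {}
            for f in fields(dc_type):
                if f.name not in data:
                    continue
                val = data[f.name]
                sub = {"scene": SceneSpec, "split": SplitPlan,
                       "augment": AugmentPolicy}.get(f.name)
                if sub is not None and isinstance(val, dict):
                    val = build(sub, val)
                elif isinstance(val, list):
                    val = tuple(val)
                kwargs[f.name] = val
            return dc_type(**kwargs)

        cfg = cls()
        simple = {f.name for f in fields(cls)
                  if f.name in ("seed", "out_dir", "log_level")}
        sections = {"synth": SynthConfig, "preprocess": PreprocessConfig,
                    "patchify": PatchifyConfig, "ssl": PretrainConfig,
                    "downstream": ProbeConfig, "evaluate": EvaluateConfig}
        updates = {}
        for key, val in (raw or {}).items():
            if key in simple:
                updates[key] = val
            elif key in sections:
                updates[key] = build(sections[key], val)
            else:
                raise KeyError(f"unknown config section {key!r}")
        return replace(cfg, **updates)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
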