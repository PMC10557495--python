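"""Pipeline configuration.

Every tunable named in the other modules lives here with its default, so a
run's effective configuration can be serialized next to its outputs and a
rerun with the same config + seed reproduces the outputs.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml


@dataclass
class PhantomConfig:
    depth: int = 3
    shape: tuple[int, int, int] = (112, 112, 112)
    spacing: tuple[float, float, float] = (0.8, 0.8, 0.8)  # mm, (z, y, x)
    root_radius: float = 3.5          # mm
    taper_exponent: float = 3.0       # Murray's law
    length_factor_range: tuple[float, float] = (4.0, 10.0)  # branch length = k * radius
    angle_range: tuple[float, float] = (20.0, 50.0)         # degrees off parent axis
    asymmetry: float = 0.0            # flow-split imbalance, 0 = symmetric bifurcations
    n_adhesions: int = 0
    min_gap: float = 2.0              # mm surface clearance; must exceed the voxel diagonal
                                      # (sqrt(3) * spacing) or 26-connected masks can touch
    companion_bronchi: bool = True
    companion_max_radius: float = 5.0  # mm; arterial branches thinner than this get a bronchus
    companion_offset_factor: float = 1.5
    companion_radius_factor: float = 0.8
    vessel_mean: float = 50.0         # HU-like
    parenchyma_mean: float = -800.0
    bronchus_mean: float = -950.0
    noise_sigma: float = 20.0
    artery_shift: float = 0.0         # contrast-mode emulation: artery intensity offset


@dataclass
class TopologyConfig:
    scales: tuple[float, ...] = (1.0, 2.0, 3.0, 4.0)  # mm, Hessian scale search
    vesselness_threshold: float = 0.05  # fraction of max response
    speed_exponent: float = 1.0         # F = dmap**exponent
    background_speed: float = 0.0       # >0 lets repair tracing bridge mask gaps
    confidence_window: int = 5
    confidence_threshold: float = 0.1
    search_radius_factor: float = 1.5   # x median inter-particle spacing
    min_terminal_time_quantile: float = 0.0


@dataclass
class TwinPipeConfig:
    patch_size: tuple[int, int, int] = (32, 32, 3)
    window: tuple[float, float] = (-1000.0, 400.0)  # HU-like clamp before normalization
    tubule_scale_threshold: float = 2.5  # voxels; branches thinner than this are "tubule"
    n_neighbors: int = 2
    conv_channels: tuple[int, int] = (8, 16)
    attention_dim: int = 8
    feature_dim: int = 16
    gcn_hidden: int = 16
    learning_rate: float = 1e-3
    momentum: float = 0.9
    batch_size: int = 128
    epochs: int = 150
    blend_lambda: float = 1.0  # mutual-correction weight when the tubule pipe is more extreme


@dataclass
class OptimizerConfig:
    trunk_generations: int = 2   # K: subtree roots start after this many bifurcation levels
    min_branch_particles: int = 3  # n_min confidence damping
    prune_descendants: bool = True  # pruned branches carry their distal subtree
    mode: str = "full"           # particle | branch | subtree | full


@dataclass
class ReconstructConfig:
    dilation_factor: float = 1.25  # scale-ball radius multiplier when painting


@dataclass
class PipelineConfig:
    seed: int = 0
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    topology: TopologyConfig = field(default_factory=TopologyConfig)
    twinpipe: TwinPipeConfig = field(default_factory=TwinPipeConfig)
    optimizer: OptimizerConfig = field(default_factory=OptimizerConfig)
    reconstruct: ReconstructConfig = field(default_factory=ReconstructConfig)
    classifier: str = "oracle"   # oracle | twinpipe
    oracle_flip_noise: float = 0.0
    stages: tuple[str, ...] = ("phantom", "topology", "classify", "optimize", "reconstruct", "evaluate")

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        def build(tp, val):
            if dataclasses.is_dataclass(tp) and isinstance(val, dict):
                kw = {}
                for f in dataclasses.fields(tp):
                    if f.name in val:
                        v = val[f.name]
                        kw[f.name] = tuple(v) if isinstance(v, list) else v
                return tp(**kw)
            return val

        kw: dict[str, Any] = {}
        for f in dataclasses.fields(cls):
            if f.name in d:
                sub = f.default_factory() if f.default_factory is not dataclasses.MISSING else None  # type: ignore[misc]
                if sub is not None:
                    kw[f.name] = build(type(sub), d[f.name])
                else:
                    v = d[f.name]
                    kw[f.name] = tuple(v) if isinstance(v, list) else v
        return cls(**kw)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
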