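"""Run configuration: simulation, model, core schedule, sketching, output."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import yaml

from .approx import SketchConfig
from .simulate import SimConfig

__all__ = ["CoreConfig", "RunConfig"]


@dataclass(frozen=True)
class CoreConfig:
    """Core schedule: eigenvalue threshold fixing the benchmark core, and the
    nested sizes as fractions of it (largest first)."""

    eigen_threshold: float = 0.99
    schedule_fractions: tuple = (1.0, 0.8, 0.6, 0.4, 0.2)

    def __post_init__(self) -> None:
        if not (0.0 < self.eigen_threshold <= 1.0):
            raise ValueError("eigen_threshold must be in (0, 1]")
        fr = tuple(self.schedule_fractions)
        if len(fr) == 0 or any(not (0.0 < f <= 1.0) for f in fr):
            raise ValueError("schedule fractions must be in (0, 1]")
        if any(b >= a for a, b in zip(fr, fr[1:])):
            raise ValueError("schedule fractions must be strictly descending")


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce one core-reduction study."""

    simulation: SimConfig = field(default_factory=SimConfig)
    heritability: Optional[float] = None  # analysis h2; defaults to simulation h2
    tau: float = 1.0
    omega: float = 1.0
    blend_alpha: float = 0.95
    cores: CoreConfig = field(default_factory=CoreConfig)
    sketch: Optional[SketchConfig] = None
    output_dir: str = "apyrel_out"
    replicates: int = 5
    seeds: Optional[tuple] = None  # default: base seed + replicate index
    h2_alternative: Optional[float] = None

    @property
    def analysis_h2(self) -> float:
        return self.heritability if self.heritability is not None else self.simulation.heritability

    def replicate_seeds(self) -> list[int]:
        if self.seeds is not None:
            if len(self.seeds) != self.replicates:
                raise ValueError("seeds list length must equal replicates")
            return [int(s) for s in self.seeds]
        return [int(self.simulation.seed) + i for i in range(self.replicates)]

    def replace(self, **kwargs) -> "RunConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["simulation"]["maf_range"] = list(self.simulation.maf_range)
        d["cores"]["schedule_fractions"] = list(self.cores.schedule_fractions)
        if self.seeds is not None:
            d["seeds"] = list(self.seeds)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "simulation" in d and isinstance(d["simulation"], dict):
            sim = dict(d["simulation"])
            if "maf_range" in sim:
                sim["maf_range"] = tuple(sim["maf_range"])
            d["simulation"] = SimConfig(**sim)
        if "cores" in d and isinstance(d["cores"], dict):
            cores = dict(d["cores"])
            if "schedule_fractions" in cores:
                cores["schedule_fractions"] = tuple(cores["schedule_fractions"])
            d["cores"] = CoreConfig(**cores)
        if d.get("sketch") is not None and isinstance(d["sketch"], dict):
            d["sketch"] = SketchConfig(**d["sketch"])
        if d.get("seeds") is not None:
            d["seeds"] = tuple(d["seeds"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
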