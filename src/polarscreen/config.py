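"""Pipeline configuration: one YAML file with named blocks per stage.

Defaults mirror the optimized workflow: the robust-setpoint extraction
factors, a 17.0 min HILIC retention cutoff, a three-sample detection
frequency, +-10 ppm database matching, and a strict log D < 0 polarity
filter at pH 7.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .doe import FactorSpec, default_factor_specs
from .extraction import FactorSettings

__all__ = ["DoEConfig", "CascadeConfig", "PipelineConfig", "load_config", "save_config"]


@dataclass
class DoEConfig:
    design_preset: str = "screening"  # "screening" (PB-12) or "paper" (PB-24 + 4 centers)
    n_center: int = 3
    resolution: int = 8
    iterations: int = 1000
    acceptance: float = 0.01
    seed: int = 0
    target_percentile: float = 10.0
    limit_percentile: float = 90.0
    factor_ranges: dict = field(default_factory=dict)  # name -> [low, high]

    def factor_specs(self) -> list[FactorSpec]:
        specs = []
        for spec in default_factor_specs():
            if spec.name in self.factor_ranges:
                low, high = self.factor_ranges[spec.name]
                spec = FactorSpec(spec.name, float(low), float(high), integer=spec.integer)
            specs.append(spec)
        return specs

    def design_args(self) -> dict:
        if self.design_preset == "paper":
            return {"base": 24, "n_center": 4}
        return {"base": 12, "n_center": self.n_center}


@dataclass
class CascadeConfig:
    rt_cutoff_min: float = 17.0
    min_samples: int = 3
    match_tolerance_ppm: float = 10.0
    logd_threshold: float = 0.0
    blank_tolerance_ppm: Optional[float] = None  # defaults to F4 when None
    mass_spread_limit_ppm: float = 10.0
    gaussian_r2_min: float = 0.8
    apply_quality_filter: bool = True


@dataclass
class PipelineConfig:
    campaign_dir: str = "campaign"
    compound_db: Optional[str] = None  # None -> packaged reference database
    factors: FactorSettings = field(default_factory=FactorSettings)
    doe: DoEConfig = field(default_factory=DoEConfig)
    cascade: CascadeConfig = field(default_factory=CascadeConfig)
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "campaign_dir": self.campaign_dir,
            "compound_db": self.compound_db,
            "seed": self.seed,
            "factors": asdict(self.factors),
            "doe": asdict(self.doe),
            "cascade": asdict(self.cascade),
        }


def load_config(path: str | Path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    factors_raw = dict(raw.get("factors", {}))
    for key in ("isotope_spacing_tolerance", "adducts"):
        if key in factors_raw and isinstance(factors_raw[key], list):
            factors_raw[key] = tuple(factors_raw[key])
    return PipelineConfig(
        campaign_dir=raw.get("campaign_dir", "campaign"),
        compound_db=raw.get("compound_db"),
        seed=int(raw.get("seed", 0)),
        factors=FactorSettings(**factors_raw),
        doe=DoEConfig(**raw.get("doe", {})),
        cascade=CascadeConfig(**raw.get("cascade", {})),
    )


def save_config(config: PipelineConfig, path: str | Path) -> None:
    data = config.to_dict()
    data["factors"]["isotope_spacing_tolerance"] = list(
        data["factors"]["isotope_spacing_tolerance"]
    )
    data["factors"]["adducts"] = list(data["factors"]["adducts"])
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
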