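"""Pipeline configuration (YAML-serialisable)."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    """End-to-end pipeline settings.

    The synthetic pipeline generates ``n_control_eyes`` + ``n_treated_eyes``
    sections of ``section_length_um`` each, measures them, grades every
    region, fits the density model, quantifies markers, simulates and
    analyses cortical batteries, and runs the group statistics.
    """

    output_dir: str = "orrquant_out"
    seed: int = 0
    px_per_um: float = 2.0
    region_length_um: float = 250.0
    sample_interval_um: float = 50.0
    cutoff_mild_moderate: float = 0.35
    cutoff_moderate_severe: float = 0.2
    sd_multiplier: float = 2.0
    dab_od_threshold: float = 0.15
    dab_rule: str = "deconvolution"
    cortical_noise_floor: float = 5.0
    n_control_eyes: int = 2
    n_treated_eyes: int = 2
    section_length_um: float = 3000.0
    n_electrodes_per_group: int = 8
    cortical_channels: int = 24
    alpha: float = 0.05
    extra: dict = field(default_factory=dict)

    def validate(self) -> None:
        for name in ("px_per_um", "region_length_um", "sample_interval_um",
                     "section_length_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.sample_interval_um > self.region_length_um:
            raise ValueError("sample interval cannot exceed the region length")
        if not (self.cutoff_mild_moderate > self.cutoff_moderate_severe > 0):
            raise ValueError("group cutoffs must decrease strictly and stay positive")
        if self.sd_multiplier <= 0:
            raise ValueError("sd_multiplier must be positive")
        if self.section_length_um < self.region_length_um:
            raise ValueError("sections must hold at least one region")

    @property
    def cutoffs(self) -> tuple[float, float]:
        return (self.cutoff_mild_moderate, self.cutoff_moderate_severe)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {k: v for k, v in data.items() if k in cls.__dataclass_fields__}
        unknown = {k: v for k, v in data.items()
                   if k not in cls.__dataclass_fields__}
        cfg = cls(**known)
        cfg.extra.update(unknown)
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))
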