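"""Pipeline configuration: the constants of the analysis, serializable to YAML.

Defaults follow the study conventions the pipeline implements: a 5 mm
plausibility ceiling for cortical thickness (sulcus detection), 8 mm FWHM
Gaussian smoothing before voxelwise statistics, an uncorrected one-sided
p < 0.001 voxel threshold, and 18-connected cluster extraction.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import yaml


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    # Laplace solver
    laplace_tolerance: float = 1e-6
    laplace_max_iterations: int = 10_000
    relaxation_factor: float = 1.9
    # length transport / streamlines
    transport_tolerance_mm: float = 1e-3
    transport_max_iterations: int = 5000
    streamline_step_factor: float = 0.25   # RK4 step = factor * min(spacing)
    # sulcus detection & correction
    sulci_threshold_mm: float = 5.0
    sulci_cone_degrees: float = 60.0
    sulci_iterations: int = 1
    # group statistics
    smoothing_fwhm_mm: float = 8.0
    alpha: float = 0.001
    cluster_connectivity: int = 18
    multiple_comparison: str | None = None  # None | 'bonferroni' | 'fdr'
    # reproducibility
    seed: int = 0

    def __post_init__(self):
        if self.laplace_tolerance <= 0 or self.transport_tolerance_mm <= 0:
            raise ConfigError("tolerances must be positive")
        if self.sulci_threshold_mm <= 0:
            raise ConfigError("sulci threshold must be positive")
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must be in (0, 1)")
        if self.cluster_connectivity not in (6, 18, 26):
            raise ConfigError("cluster connectivity must be 6, 18 or 26")
        if not 0 < self.relaxation_factor < 2:
            raise ConfigError("relaxation factor must be in (0, 2)")
        if self.streamline_step_factor <= 0:
            raise ConfigError("streamline step factor must be positive")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)
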