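"""Configuration objects for simulation, QC, and the pipeline.

All configs are plain dataclasses that validate on construction and can be
round-tripped through JSON or YAML documents (``from_dict`` / ``to_dict``).
Every stochastic stage takes its seed from the config; identical config and
seed yield bit-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import yaml

__all__ = [
    "BaselineMixture",
    "SimulationConfig",
    "QCThresholds",
    "PipelineConfig",
]


@dataclass
class BaselineMixture:
    """Two-component beta-distribution mixture for baseline methylation.

    Infinium beta values are bimodal: a largely unmethylated mode (CpG
    islands/promoters) and a largely methylated mode (gene bodies,
    intergenic DNA).  Components are parameterized by mean and
    concentration; component k draws Beta(mean_k * conc_k, (1-mean_k) * conc_k).
    """

    weights: tuple[float, float] = (0.55, 0.45)
    means: tuple[float, float] = (0.10, 0.85)
    concentrations: tuple[float, float] = (20.0, 20.0)

    def validate(self) -> None:
        if len(self.weights) != 2 or len(self.means) != 2 or len(self.concentrations) != 2:
            raise ValueError("baseline mixture needs exactly two components")
        if not np.isclose(sum(self.weights), 1.0):
            raise ValueError("mixture weights must sum to 1")
        if any(w < 0 for w in self.weights):
            raise ValueError("mixture weights must be non-negative")
        if any(not 0.0 < m < 1.0 for m in self.means):
            raise ValueError("mixture means must lie in (0, 1)")
        if any(c <= 0 for c in self.concentrations):
            raise ValueError("mixture concentrations must be positive")


@dataclass
class SimulationConfig:
    """Design and effect parameters for the synthetic methylation experiment.

    Defaults mirror a single high-LET exposure series: 4 doses x 4 time
    points x 3 biological replicates = 48 samples, probes on one synthetic
    chromosome, planted dose effects of 0.05 beta-units/Gy at low-baseline
    sites (``fe_like``), and culture drift of 0.001 beta-units/day.
    """

    seed: int
    n_probes: int = 20_000
    doses: Sequence[float] = (0.0, 0.1, 0.3, 1.0)
    time_points: Sequence[float] = (2.0, 20.0, 40.0, 56.0)
    n_replicates: int = 3
    series: str = "sim"

    baseline_mixture: BaselineMixture = field(default_factory=BaselineMixture)
    #: set to fix every probe's latent baseline at one value (overrides mixture)
    baseline_constant: float | None = None

    n_dose_probes: int = 200
    dose_effect: float = 0.05  # beta-units per Gy (magnitude)
    effect_profile: str = "fe_like"  # fe_like | si_like | x_like
    n_drift_probes: int = 500
    drift_rate: float = 0.001  # beta-units per day
    n_both_probes: int = 0  # probes carrying both a dose and a drift effect

    chip_sd: float = 0.01
    row_sd: float = 0.005
    residual_sd: float = 0.02
    total_intensity: float = 10_000.0
    detection_fail_rate: float = 0.002
    chip_capacity: int = 12  # 6 rows x 2 columns

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("n_probes", "n_replicates", "n_dose_probes", "n_drift_probes", "n_both_probes"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_dose_probes + self.n_drift_probes + self.n_both_probes > self.n_probes:
            raise ValueError("planted probe counts exceed n_probes")
        if not 0.0 <= self.detection_fail_rate <= 1.0:
            raise ValueError("detection_fail_rate must be in [0, 1]")
        for name in ("chip_sd", "row_sd", "residual_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("dose_effect", "drift_rate", "total_intensity", "chip_sd", "row_sd", "residual_sd"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.total_intensity <= 0:
            raise ValueError("total_intensity must be positive")
        if self.effect_profile not in ("fe_like", "si_like", "x_like"):
            raise ValueError(f"unknown effect_profile {self.effect_profile!r}")
        if self.chip_capacity < 2 or self.chip_capacity % 2:
            raise ValueError("chip_capacity must be a positive even number")
        if self.baseline_constant is not None and not 0.0 < self.baseline_constant < 1.0:
            raise ValueError("baseline_constant must be in (0, 1)")
        if isinstance(self.baseline_mixture, BaselineMixture):
            self.baseline_mixture.validate()

    @property
    def n_samples(self) -> int:
        return len(self.doses) * len(self.time_points) * self.n_replicates

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "baseline_mixture" in d and isinstance(d["baseline_mixture"], dict):
            bm = {k: tuple(v) if isinstance(v, list) else v for k, v in d["baseline_mixture"].items()}
            d["baseline_mixture"] = BaselineMixture(**bm)
        return cls(**d)

    @classmethod
    def from_file(cls, path: str) -> "SimulationConfig":
        return cls.from_dict(_load_document(path))


@dataclass
class QCThresholds:
    """Quality-control cutoffs for intensity-to-beta processing.

    Boundary semantics are strict inequalities: a data point is failed when
    its detection p-value is *greater than* ``detection_alpha``; a probe is
    dropped when its missing fraction is *greater than* ``probe_missing_frac``;
    a sample is dropped when its call rate is *below* ``sample_call_rate``,
    its average intensity is *below* ``sample_min_intensity`` AU, or below
    ``sample_median_frac`` of the experiment-wide median sample intensity.
    """

    detection_alpha: float = 0.001
    probe_missing_frac: float = 0.10
    sample_call_rate: float = 0.95
    sample_min_intensity: float = 2000.0
    sample_median_frac: float = 0.50

    def __post_init__(self) -> None:
        if not 0.0 < self.detection_alpha < 1.0:
            raise ValueError("detection_alpha must be in (0, 1)")
        for name in ("probe_missing_frac", "sample_call_rate", "sample_median_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.sample_min_intensity < 0:
            raise ValueError("sample_min_intensity must be >= 0")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "QCThresholds":
        return cls(**d)


@dataclass
class PipelineConfig:
    """End-to-end pipeline configuration: stage toggles plus per-stage blocks."""

    simulation: SimulationConfig
    qc: QCThresholds = field(default_factory=QCThresholds)

    # stage toggles
    run_preprocess: bool = True
    run_ewas: bool = True
    run_annotation: bool = True
    run_signature: bool = True

    # EWAS block
    holm_alpha: float = 0.05
    uncorrected_alpha: float = 0.001

    # annotation block
    shore_width: int = 2000
    profile_flank: int = 2500
    bin_width: int = 20

    # signature block
    n_resamples: int = 1000
    signature_detection_alpha: float = 0.05
    signature_n_pairs: int = 18
    signature_delta: float = 0.3
    signature_size: int = 800
    signature_pool_probes: int = 20_000

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        d["simulation"] = SimulationConfig.from_dict(d["simulation"])
        if "qc" in d and isinstance(d["qc"], dict):
            d["qc"] = QCThresholds.from_dict(d["qc"])
        return cls(**d)

    @classmethod
    def from_file(cls, path: str) -> "PipelineConfig":
        return cls.from_dict(_load_document(path))


def _load_document(path: str) -> dict:
    """Load a JSON or YAML config document."""
    with open(path) as fh:
        text = fh.read()
    if path.endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)
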