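"""Pipeline configuration: one YAML file determines every output.

The config carries the study layout (start date, pigs, days), the generator
truths (movement model, barn climate, radio propagation and detection
noise/dropout), the analysis switches, and the master seed.  Every
stochastic stage derives its own child seed from the master seed through a
``numpy`` SeedSequence, so a config fully determines all artifacts.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import yaml

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "load_config", "save_config"]


@dataclass
class TruthConfig:
    """Parameters of the hourly-movement generative model (cm/h scale)."""

    sigma2_pig: float = 15_773.0
    sigma2_res: float = 38_884.0
    rho: float = 0.19
    day_effect_sd: float = 40.0
    interaction_amplitude: float = 30.0
    diurnal_peak: float = 1025.5
    diurnal_trough: float = 666.0
    diurnal_peak_hour: int = 15
    diurnal_trough_hour: int = 1


@dataclass
class EnvConfig:
    """Barn-climate generator parameters."""

    temp_mean: float = 16.05
    temp_sd: float = 1.55
    rh_mean: float = 71.05
    rh_sd: float = 4.66
    pm_base_mean: float = 9.76
    pm_cross_correlation: float = 0.98
    records_per_day_min: int = 80
    records_per_day_max: int = 97


@dataclass
class RadioConfig:
    """Path-loss truth, detection noise and calibration layout."""

    tx_power: float = -50.0
    n: float = 2.0
    rssi_noise_sd: float = 0.5
    dropout_prob: float = 0.7
    min_distance: float = 0.1
    calibration_distances: tuple = (0.5, 1.0, 2.0, 3.0, 5.0, 7.0)
    calibration_replicates: int = 10


@dataclass
class AnalysisConfig:
    ci_level: float = 0.95
    r_threshold: float = 0.95
    n_starts: int = 3


@dataclass
class PipelineConfig:
    study_start: dt.date = dt.date(2023, 2, 2)
    n_pigs: int = 16
    n_days: int = 20
    seed: int = 0
    tz_offset_hours: int = 1
    pig_baseline_cv: float = 0.15
    truth: TruthConfig = field(default_factory=TruthConfig)
    env: EnvConfig = field(default_factory=EnvConfig)
    radio: RadioConfig = field(default_factory=RadioConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)

    def child_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the master seed."""
        ss = np.random.SeedSequence([self.seed, zlib.crc32(stage.encode())])
        seed = int(ss.generate_state(1)[0] % (2**31))
        logger.info("seed for stage %r: %d", stage, seed)
        return seed

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["study_start"] = self.study_start.isoformat()
        d["radio"]["calibration_distances"] = list(
            self.radio.calibration_distances
        )
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if isinstance(d.get("study_start"), str):
            d["study_start"] = dt.date.fromisoformat(d["study_start"])
        for key, sub in (
            ("truth", TruthConfig),
            ("env", EnvConfig),
            ("radio", RadioConfig),
            ("analysis", AnalysisConfig),
        ):
            if key in d and isinstance(d[key], dict):
                d[key] = sub(**d[key])
        if isinstance(d.get("radio"), RadioConfig):
            d["radio"] = dataclasses.replace(
                d["radio"],
                calibration_distances=tuple(d["radio"].calibration_distances),
            )
        return cls(**d)


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        return PipelineConfig.from_dict(yaml.safe_load(fh) or {})


def save_config(config: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
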