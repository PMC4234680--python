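"""Pipeline configuration: every tunable of the analysis chain in one place.

Defaults follow the screening methodology: a 2-min/1-min sliding window,
SpO2 artifact rules (out of [50, 100]% or >4 percentage-point jumps),
Savitzky-Golay PPG smoothing (order 3, frame 11), pulse-interval censoring
to [0.33, 1.5] s, 4 Hz uniform resampling, AR spectra (MDL-selected order
for SpO2, fixed order 16 for pulse rate variability), and an SpO2
modulation band of 0.005-0.1 Hz.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    # Windowing
    window_s: float = 120.0
    hop_s: float = 60.0

    # SpO2 artifact rules (percent / percentage points)
    spo2_min: float = 50.0
    spo2_max: float = 100.0
    spo2_max_jump: float = 4.0
    spo2_resolution: float = 0.1

    # PPG filtering and quality gate
    sg_order: int = 3
    sg_frame: int = 11
    baseline_frame: int = 127          # samples (~2 s) for median detrending
    sqi_threshold: float = 0.7
    min_valid_fraction: float = 0.5

    # SpO2 time-domain / nonlinear features
    delta_block_s: float = 12.0        # block length of the delta index
    desat_depth: float = 2.0           # percentage points below baseline
    desat_min_s: float = 3.0           # minimum event duration
    desat_baseline_s: float = 60.0     # running-median baseline horizon
    sat_threshold: float = 92.0        # cumulative-time-below threshold (92 or 94)
    apen_m: int = 1
    apen_r_factor: float = 0.25        # tolerance r = factor * window SD
    ctm_rho: float = 0.25              # radius in SpO2 % units

    # SpO2 AR spectrum / modulation band
    ar_max_order: int = 30
    n_grid: int = 256
    band_lo: float = 0.005
    band_hi: float = 0.1
    band_halfwidth: float = 0.01
    max_missing_fraction: float = 0.2
    max_interp_gap_s: float = 5.0

    # Pulse-to-pulse intervals / PRV
    ppi_min: float = 0.33
    ppi_max: float = 1.5
    resample_fs: float = 4.0
    prv_ar_order: int = 16
    prv_n_grid: int = 256
    vlf_band: tuple[float, float] = (0.01, 0.04)
    lf_band: tuple[float, float] = (0.04, 0.15)
    hf_band: tuple[float, float] = (0.15, 0.4)
    max_gap_s: float = 3.0
    refractory_s: float = 0.25
    min_coverage: float = 0.5          # valid-interval coverage of the window

    # Overnight aggregation / labels
    min_windows: int = 60              # ~1 h of valid windows at 1-min hop
    ahi_threshold: float = 5.0

    # Group statistics / screening
    alpha: float = 0.05
    lda_prior_sdb: float = 0.4
    max_features: int = 15
    n_folds: int = 4
    consensus_min: int = 3

    def replace(self, **kwargs) -> "PipelineConfig":
        return dataclasses.replace(self, **kwargs)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Load a config from YAML or JSON; unknown keys raise."""
        text = Path(path).read_text()
        data = yaml.safe_load(text) if str(path).endswith((".yml", ".yaml")) else json.loads(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("vlf_band", "lf_band", "hf_band"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_file(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        for key in ("vlf_band", "lf_band", "hf_band"):
            data[key] = list(data[key])
        text = (
            yaml.safe_dump(data, sort_keys=False)
            if str(path).endswith((".yml", ".yaml"))
            else json.dumps(data, indent=2)
        )
        Path(path).write_text(text)

    @property
    def t_below_name(self) -> str:
        """Feature name of the cumulative-time-below statistic, e.g. 't92'."""
        return f"t{int(round(self.sat_threshold))}"


DEFAULT_CONFIG = PipelineConfig()
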