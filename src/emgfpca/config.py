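"""Run configuration for the EMG-FPCA pipeline.

The defaults are the protocol's reference settings: 20-450 Hz
4th-order zero-phase band-pass, 50 Hz notch with harmonics, 15 Hz linear
envelope, a 101-point 0-100% cycle grid, a third-order (3-harmonic) Fourier
basis with roughness penalty lambda = e^-7, component retention at
cumulative variance >= 85% with an eigenvalue floor of 1, and alpha = 0.05
with Benjamini-Hochberg FDR control.  An empty config file therefore runs
the reference analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .exceptions import ConfigurationError

#: canonical long-format column names used across all stages
CANONICAL_COLUMNS = ("subject", "group", "leg", "muscle", "trial", "sample", "value")

#: accepted group / leg tokens
GROUPS = ("elite", "sub_elite")
LEGS = ("supporting", "kicking")

#: the eight instrumented lower-limb muscles
DEFAULT_MUSCLES = (
    "rectus_femoris",
    "biceps_femoris",
    "gluteus_maximus",
    "vastus_lateralis",
    "tibialis_anterior",
    "gastrocnemius_medialis",
    "semitendinosus",
    "adductor_longus",
)


@dataclass
class AnalysisConfig:
    """All tunable settings of the pipeline, with the reference defaults."""

    # -- conditioning filters ------------------------------------------------
    band_low_hz: float = 20.0
    band_high_hz: float = 450.0
    band_order: int = 4          # design order; applied forward-backward
    notch_base_hz: float = 50.0
    notch_harmonics: int = 3     # 50, 100, 150 Hz
    notch_q: float = 30.0
    apply_notch: bool = True

    # -- linear envelope -----------------------------------------------------
    envelope_cutoff_hz: float = 15.0
    envelope_order: int = 4

    # -- cycle grid ----------------------------------------------------------
    grid_len: int = 101          # 0..100% in 1% steps
    max_norm_trials: int | None = None   # None -> all valid trials

    # -- functional basis & FPCA --------------------------------------------
    basis_order: int = 3         # harmonics -> 2*3+1 = 7 basis functions
    smoothing: float = math.exp(-7.0)
    register: bool = True
    ev_floor: float = 1.0
    cum_floor: float = 0.85
    envelope_multiplier: float = 2.0   # c in mean +/- c*sqrt(mu_k)*xi_k

    # -- inference -----------------------------------------------------------
    alpha: float = 0.05
    fdr_method: str = "bh"
    omega_elite: float = 0.0     # iEMG weighting coefficients
    omega_sub: float = 0.0
    f_enter: float = 3.84        # stepwise discriminant thresholds
    f_remove: float = 2.71

    # -- phases (cycle fractions splitting P1..P4) ---------------------------
    phase_boundaries: tuple[float, float, float] = (25.0, 50.0, 75.0)

    # -- reproducibility -----------------------------------------------------
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.band_low_hz < self.band_high_hz:
            raise ConfigurationError("band edges must satisfy 0 < low < high")
        if self.band_order < 2 or self.band_order % 2:
            raise ConfigurationError("band_order must be even and >= 2")
        if not 10.0 <= self.envelope_cutoff_hz <= 15.0:
            raise ConfigurationError("envelope cutoff must lie in [10, 15] Hz")
        if self.grid_len < 5:
            raise ConfigurationError("grid_len must be >= 5")
        if self.basis_order < 1:
            raise ConfigurationError("basis_order must be >= 1")
        if self.smoothing < 0:
            raise ConfigurationError("smoothing penalty must be >= 0")
        if not 0 < self.cum_floor <= 1:
            raise ConfigurationError("cum_floor must be in (0, 1]")
        if not 0 < self.alpha < 1:
            raise ConfigurationError("alpha must be in (0, 1)")
        b = tuple(float(x) for x in self.phase_boundaries)
        if len(b) != 3 or not (0.0 < b[0] < b[1] < b[2] < 100.0):
            raise ConfigurationError(
                "phase_boundaries must be three increasing fractions in (0, 100)"
            )
        self.phase_boundaries = b

    # -- grid helpers --------------------------------------------------------
    @property
    def grid(self):
        import numpy as np

        return np.linspace(0.0, 100.0, self.grid_len)

    # -- serialization -------------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["phase_boundaries"] = list(self.phase_boundaries)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        if "phase_boundaries" in d:
            d = dict(d)
            d["phase_boundaries"] = tuple(d["phase_boundaries"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ConfigurationError("config file must contain a mapping")
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
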