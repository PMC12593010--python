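"""Raw surface EMG to amplitude- and time-normalized cycle envelopes.

The chain is the standard linear-envelope recipe for ballistic tasks:

1. DC-offset and linear-drift removal.
2. Zero-phase band-pass, 20-450 Hz, 4th-order Butterworth design applied
   forward-backward (effective order 8, zero phase lag).
3. Notch at mains frequency and harmonics (50/100/150 Hz by default).
4. Full-wave rectification and zero-phase low-pass at 15 Hz (the linear
   envelope); negative filter ringing is clipped at zero.
5. Time normalization of the cycle segment onto a fixed 0-100% grid by
   linear interpolation.
6. Amplitude normalization of each subject-muscle-leg trial set by its
   single maximum, so the set's peak is exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal

from .config import AnalysisConfig
from .exceptions import ConfigurationError, DataError, NormalizationError
from .io import EmgRecording


@dataclass
class FilterSpec:
    """One filter of the conditioning chain."""

    kind: str                    # bandpass | lowpass | notch
    edges: tuple[float, ...]     # Hz
    order: int = 4
    zero_phase: bool = True

    def validate(self, fs: float) -> None:
        if self.kind not in ("bandpass", "lowpass", "notch"):
            raise ConfigurationError(f"unknown filter kind {self.kind!r}")
        for e in self.edges:
            if not 0 < e < fs / 2:
                raise ConfigurationError(
                    f"filter edge {e} Hz outside (0, {fs / 2}) for fs={fs}"
                )
        if self.zero_phase and (self.order < 2 or self.order % 2):
            raise ConfigurationError("zero-phase filters need an even order >= 2")


@dataclass
class NormalizedCurve:
    """An envelope resampled onto the common 0-100% cycle grid."""

    grid: np.ndarray
    values: np.ndarray
    subject_id: str
    group: str
    leg: str
    muscle: str
    trial: int

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.grid.shape != self.values.shape:
            raise ValueError("grid and values must have the same length")
        if np.any(self.values < 0):
            raise ValueError("envelope values must be nonnegative")

    @property
    def key(self) -> tuple:
        return (self.subject_id, self.group, self.leg, self.muscle, self.trial)


# ---------------------------------------------------------------------------
# conditioning
# ---------------------------------------------------------------------------

def condition_raw(rec: EmgRecording, cfg: AnalysisConfig) -> EmgRecording:
    """Remove offset/drift, band-pass, and notch-filter a raw trial.

    All filters are applied forward-backward (zero phase).  The band edge
    of 450 Hz requires fs > 900 Hz.
    """
    if rec.stage != "raw":
        raise DataError(f"condition_raw expects stage='raw', got {rec.stage!r}")
    if rec.fs <= 2 * cfg.band_high_hz:
        raise ConfigurationError(
            f"fs={rec.fs} too low for band edge {cfg.band_high_hz} Hz "
            f"(need fs > {2 * cfg.band_high_hz})"
        )
    x = rec.samples
    if np.any(~np.isfinite(x)):
        raise DataError("raw samples contain NaN or infinite values")

    # offset + linear drift
    x = signal.detrend(x, type="linear")

    sos = signal.butter(
        cfg.band_order,
        [cfg.band_low_hz, cfg.band_high_hz],
        btype="bandpass",
        fs=rec.fs,
        output="sos",
    )
    x = signal.sosfiltfilt(sos, x)

    if cfg.apply_notch:
        for h in range(1, cfg.notch_harmonics + 1):
            f0 = cfg.notch_base_hz * h
            if f0 >= rec.fs / 2:
                break
            b, a = signal.iirnotch(f0, cfg.notch_q, fs=rec.fs)
            x = signal.filtfilt(b, a, x)

    return rec.replace(samples=x)


def linear_envelope(
    rec: EmgRecording,
    cutoff: float = 15.0,
    order: int = 4,
) -> EmgRecording:
    """Full-wave rectify and low-pass to a linear envelope.

    ``cutoff`` must lie in the 10-15 Hz range conventional for ballistic
    movements (default 15 Hz).  Negative ringing is clipped at zero so the
    envelope stays a valid intensity curve.
    """
    if rec.stage != "raw":
        raise DataError(f"linear_envelope expects stage='raw', got {rec.stage!r}")
    if cutoff >= rec.fs / 2:
        raise ConfigurationError(f"cutoff {cutoff} Hz >= Nyquist ({rec.fs / 2} Hz)")
    if not 10.0 <= cutoff <= 15.0:
        raise ConfigurationError("envelope cutoff must lie in [10, 15] Hz")
    sos = signal.butter(order, cutoff, btype="lowpass", fs=rec.fs, output="sos")
    env = signal.sosfiltfilt(sos, np.abs(rec.samples))
    return rec.replace(samples=np.clip(env, 0.0, None), stage="envelope")


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def time_normalize(
    rec: EmgRecording,
    start: int,
    end: int,
    grid_len: int = 101,
) -> NormalizedCurve:
    """Resample the cycle segment ``[start, end]`` onto the 0-100% grid.

    Linear interpolation; the segment endpoints map exactly onto 0% and
    100%.  ``end`` is inclusive.
    """
    if rec.stage != "envelope":
        raise DataError(f"time_normalize expects stage='envelope', got {rec.stage!r}")
    n = rec.samples.size
    if not 0 <= start < end <= n - 1:
        raise DataError(f"invalid cycle bounds [{start}, {end}] for length {n}")
    if end - start < 4:
        raise DataError("cycle too short: fewer than 4 samples between events")
    seg = rec.samples[start : end + 1]
    grid = np.linspace(0.0, 100.0, grid_len)
    src = np.linspace(0.0, 100.0, seg.size)
    values = np.interp(grid, src, seg)
    return NormalizedCurve(
        grid=grid,
        values=values,
        subject_id=rec.subject_id,
        group=rec.group,
        leg=rec.leg,
        muscle=rec.muscle,
        trial=rec.trial,
    )


def amplitude_normalize(
    curves: Sequence[NormalizedCurve],
    max_trials: int | None = None,
) -> list[NormalizedCurve]:
    """Divide a subject-muscle-leg trial set by its single maximum.

    The normalizing constant is the maximum over all supplied trials (or
    over the first ``max_trials`` trials if restricted), so the set's peak
    is exactly 1.  Idempotent: applying it twice equals applying it once.
    """
    if not curves:
        raise DataError("amplitude_normalize needs at least one curve")
    ref = curves[0]
    for c in curves[1:]:
        if (c.subject_id, c.group, c.leg, c.muscle) != (
            ref.subject_id,
            ref.group,
            ref.leg,
            ref.muscle,
        ):
            raise DataError(
                "amplitude_normalize expects one subject-muscle-leg trial set"
            )
    pool = curves if max_trials is None else sorted(curves, key=lambda c: c.trial)[:max_trials]
    peak = max(float(np.max(c.values)) for c in pool)
    if peak <= 0:
        raise NormalizationError("all-zero trial set: normalization undefined")
    return [
        NormalizedCurve(
            grid=c.grid,
            values=c.values / peak,
            subject_id=c.subject_id,
            group=c.group,
            leg=c.leg,
            muscle=c.muscle,
            trial=c.trial,
        )
        for c in curves
    ]
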