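"""Synthetic two-group EMG cohorts with known ground truth.

Curves follow the same low-rank functional model the analysis assumes:

    x_ij(t) = clip>=0( mean(t) + sum_k (z_ijk + b_ik + delta_k 1[elite]) xi_k(t)
                       + eps_ij(t) )

optionally composed with a random monotone, endpoint-preserving time warp
t -> t + a sin(pi t / 100).  Here z are trial-level latent scores, b are
subject random offsets, delta_k is the group shift along mode k, and eps is
white trial noise on the grid.  The modes xi_k are orthonormal under the
trapezoidal inner product on [0, 100], so injected score variances are on
the same scale as the eigenvalues the functional PCA reports.

``simulate_raw`` wraps each envelope in a surface-EMG carrier: zero-mean
noise band-limited to 20-450 Hz with unit rectified mean, multiplied by the
target envelope, plus a 50 Hz mains sinusoid and a DC offset.  This
exercises the full conditioning chain.

Defaults emulate the study design: two groups of 10 subjects, 6 valid
trials each, 8 muscles per leg, 2000 Hz raw sampling, a group shift of 1
on the first mode, subject SD 0.5 and trial-noise SD 0.25.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import json
import numpy as np
from scipy import signal as sps

from .config import DEFAULT_MUSCLES
from .exceptions import ConfigurationError
from .gridops import apply_sine_warp, orthonormalize_modes, trapezoid_weights
from .io import EmgRecording


def default_modes(grid: np.ndarray, n_modes: int = 2) -> np.ndarray:
    """First Fourier harmonics of the cycle, orthonormalized on the grid."""
    t = grid / grid[-1]
    cands = []
    for k in range(1, n_modes + 1):
        cands.append(np.sin(2 * np.pi * k * t))
        cands.append(np.cos(2 * np.pi * k * t))
    return orthonormalize_modes(np.array(cands[:n_modes]), grid)


def bump_mean(
    grid: np.ndarray,
    centers: Sequence[float],
    widths: Sequence[float],
    heights: Sequence[float],
    baseline: float,
) -> np.ndarray:
    """Sum-of-Gaussian-bumps mean envelope (multi-peak, nonnegative)."""
    m = np.full_like(grid, float(baseline))
    for c, w, h in zip(centers, widths, heights, strict=True):
        m += h * np.exp(-0.5 * ((grid - c) / w) ** 2)
    return m


@dataclass
class SimulationParams:
    """Full generative description of a synthetic cohort."""

    n_per_group: int = 10
    n_trials: int = 6
    muscles: tuple[str, ...] = DEFAULT_MUSCLES
    legs: tuple[str, ...] = ("supporting", "kicking")
    grid_len: int = 101

    # mean envelope: bumps at the four phase landmarks
    bump_centers: tuple[float, ...] = (12.5, 37.5, 62.5, 87.5)
    bump_widths: tuple[float, ...] = (6.0, 8.0, 7.0, 6.0)
    bump_heights: tuple[float, ...] = (0.45, 0.6, 0.35, 0.3)
    baseline: float = 0.3

    # functional modes and score model
    modes: np.ndarray | None = None          # (n_modes, grid_len); default harmonics
    n_modes: int = 2
    score_sd: tuple[float, ...] | float = 1.0   # trial-level latent score SD per mode
    group_effect: tuple[float, ...] | float = (1.0, 0.0)  # elite shift per mode
    subject_sd: float = 0.5
    trial_sd: float = 0.25
    jitter_sd: float = 1.0                   # % cycle; sine-warp amplitude SD

    # raw-signal synthesis
    raw_mode: bool = False
    fs: float = 2000.0
    cycle_duration_s: float = 1.6
    mains_amp: float = 0.05
    dc_offset: float = 0.1

    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 1 or self.n_trials < 1:
            raise ValueError("n_per_group and n_trials must be >= 1")
        for name in ("subject_sd", "trial_sd", "jitter_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        grid = self.grid
        if self.modes is None:
            self.modes = default_modes(grid, self.n_modes)
        else:
            self.modes = np.atleast_2d(np.asarray(self.modes, dtype=float))
            if self.modes.shape[1] != self.grid_len:
                raise ConfigurationError("modes must be sampled on the cycle grid")
            w = trapezoid_weights(grid)
            gram = (self.modes * w) @ self.modes.T
            if not np.allclose(gram, np.eye(len(self.modes)), atol=1e-8):
                raise ConfigurationError(
                    "modes must be mutually orthonormal on the grid (tol 1e-8); "
                    "use orthonormalize_modes()"
                )
        self.n_modes = len(self.modes)
        self.score_sd = self._per_mode(self.score_sd, "score_sd")
        self.group_effect = self._per_mode(self.group_effect, "group_effect", signed=True)
        if np.any(self.mean_curve < 0):
            raise ValueError("mean curve must be nonnegative on the grid")

    def _per_mode(self, v, name: str, signed: bool = False) -> np.ndarray:
        arr = np.atleast_1d(np.asarray(v, dtype=float))
        if arr.size == 1:
            arr = np.repeat(arr, self.n_modes)
        if arr.size < self.n_modes:
            arr = np.concatenate([arr, np.zeros(self.n_modes - arr.size)])
        arr = arr[: self.n_modes]
        if not signed and np.any(arr < 0):
            raise ValueError(f"{name} must be >= 0")
        return arr

    @property
    def grid(self) -> np.ndarray:
        return np.linspace(0.0, 100.0, self.grid_len)

    @property
    def mean_curve(self) -> np.ndarray:
        return bump_mean(
            self.grid, self.bump_centers, self.bump_widths, self.bump_heights,
            self.baseline,
        )


@dataclass
class SyntheticCohort:
    """Generated recordings plus the latent truth that produced them."""

    recordings: list[EmgRecording]
    truth: dict = field(default_factory=dict)
    params: SimulationParams | None = None


def _subject_ids(params: SimulationParams) -> list[tuple[str, str]]:
    ids = []
    for g, tag in (("elite", "E"), ("sub_elite", "S")):
        for i in range(params.n_per_group):
            ids.append((f"{tag}{i + 1:02d}", g))
    return ids


def simulate_envelopes(params: SimulationParams) -> SyntheticCohort:
    """Generate envelope-stage recordings on the cycle grid.

    Every (muscle, leg) channel gets independent draws from the same score
    model; the truth dict stores, per channel, the trial scores ``z``, the
    subject offsets ``b``, the warp amplitudes and the noiseless curves.
    """
    rng = np.random.default_rng(params.seed)
    grid = params.grid
    mean = params.mean_curve
    subjects = _subject_ids(params)
    n_subj = len(subjects)
    K = params.n_modes

    recordings: list[EmgRecording] = []
    truth: dict = {
        "subjects": [s for s, _ in subjects],
        "groups": [g for _, g in subjects],
        "grid": grid,
        "mean": mean,
        "modes": params.modes,
        "channels": {},
    }
    for muscle in params.muscles:
        for leg in params.legs:
            b = rng.normal(0.0, params.subject_sd, size=(n_subj, K))
            z = rng.normal(0.0, 1.0, size=(n_subj, params.n_trials, K)) * params.score_sd
            eps = rng.normal(0.0, params.trial_sd,
                             size=(n_subj, params.n_trials, params.grid_len))
            warps = (
                rng.normal(0.0, params.jitter_sd, size=(n_subj, params.n_trials))
                if params.jitter_sd > 0
                else np.zeros((n_subj, params.n_trials))
            )
            scores = np.empty_like(z)
            for i, (sid, group) in enumerate(subjects):
                shift = params.group_effect if group == "elite" else 0.0
                for j in range(params.n_trials):
                    scores[i, j] = z[i, j] + b[i] + shift
                    curve = mean + scores[i, j] @ params.modes + eps[i, j]
                    if warps[i, j] != 0.0:
                        curve = apply_sine_warp(grid, curve, warps[i, j])
                    curve = np.clip(curve, 0.0, None)
                    recordings.append(
                        EmgRecording(
                            subject_id=sid,
                            group=group,
                            leg=leg,
                            muscle=muscle,
                            trial=j + 1,
                            fs=float(params.grid_len - 1),
                            samples=curve,
                            stage="envelope",
                        )
                    )
            truth["channels"][(muscle, leg)] = {
                "scores": scores,
                "subject_offsets": b,
                "warps": warps,
            }
    return SyntheticCohort(recordings=recordings, truth=truth, params=params)


def band_limited_carrier(
    rng: np.random.Generator, n: int, fs: float,
    low: float = 20.0, high: float = 450.0,
) -> np.ndarray:
    """Zero-mean noise strictly band-limited to [low, high] Hz, with unit
    rectified mean.  Sharp (spectral) band-limiting keeps the carrier
    inside the conditioning pass-band, so the analysis filters do not
    re-attenuate it."""
    spec = np.fft.rfft(rng.standard_normal(n))
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    spec[(freqs < low) | (freqs > high)] = 0.0
    x = np.fft.irfft(spec, n=n)
    return x / np.mean(np.abs(x))


def simulate_raw(params: SimulationParams) -> SyntheticCohort:
    """Generate raw-stage recordings: envelope-modulated carriers.

    raw(t) = envelope(t) * carrier(t) + mains sinusoid + DC offset.
    The truth stores the target envelope sampled at the raw timeline.
    """
    if not params.raw_mode:
        raise ValueError("params.raw_mode must be set for simulate_raw")
    if params.fs < 2 * 450.0:
        raise ValueError(
            f"fs={params.fs} cannot represent the 20-450 Hz carrier band "
            "(need fs >= 900 Hz)"
        )
    env_cohort = simulate_envelopes(params)
    rng = np.random.default_rng(params.seed + 1)
    n = int(round(params.fs * params.cycle_duration_s))
    t = np.arange(n) / params.fs
    cycle_pct = t / params.cycle_duration_s * 100.0
    grid = params.grid

    raw_recs: list[EmgRecording] = []
    target_envelopes: dict = {}
    for rec in env_cohort.recordings:
        env_t = np.interp(cycle_pct, grid, rec.samples)
        carrier = band_limited_carrier(rng, n, params.fs)
        raw = (
            env_t * carrier
            + params.mains_amp * np.sin(2 * np.pi * 50.0 * t)
            + params.dc_offset
        )
        raw_recs.append(rec.replace(samples=raw, fs=params.fs, stage="raw"))
        target_envelopes[rec.key] = env_t
    truth = dict(env_cohort.truth)
    truth["target_envelopes"] = target_envelopes
    truth["cycle_pct"] = cycle_pct
    return SyntheticCohort(recordings=raw_recs, truth=truth, params=params)


def write_truth_json(cohort: SyntheticCohort, path: str | Path) -> None:
    """Serialize the latent truth (scores, offsets, warps) to JSON."""
    truth = cohort.truth
    doc = {
        "subjects": truth["subjects"],
        "groups": truth["groups"],
        "grid": np.asarray(truth["grid"]).tolist(),
        "mean": np.asarray(truth["mean"]).tolist(),
        "modes": np.asarray(truth["modes"]).tolist(),
        "channels": {
            f"{m}|{l}": {
                "scores": ch["scores"].tolist(),
                "subject_offsets": ch["subject_offsets"].tolist(),
                "warps": ch["warps"].tolist(),
            }
            for (m, l), ch in truth["channels"].items()
        },
    }
    Path(path).write_text(json.dumps(doc))
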