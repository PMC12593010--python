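"""Integrated EMG (iEMG) per curve and per movement phase, and the
weighted between-group difference statistic dIEMG.

iEMG is the trapezoidal area under the normalized envelope, in units of
%-cycle x normalized amplitude; a constant envelope of 1 over the full
cycle integrates to 100.  Phase boundaries (P1|P2, P2|P3, P3|P4) are cycle
fractions; boundary points shared by adjacent phases are split so the four
phase integrals sum exactly to the full-cycle integral.

The weighted group-difference statistic is

    dIEMG = [M_e (1 + w_e) - M_s (1 + w_s)] / [M_e (1 + w_e)]

where M_e and M_s are the elite and sub-elite mean iEMG and w are
nonnegative weighting coefficients (default 0, giving the plain relative
difference).  With equal weights the coefficients cancel.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError
from .preprocessing import NormalizedCurve

PHASES = ("P1", "P2", "P3", "P4")


@dataclass(frozen=True)
class PhaseDefinition:
    """Three cycle fractions splitting [0, 100] into P1..P4."""

    boundaries: tuple[float, float, float] = (25.0, 50.0, 75.0)

    def __post_init__(self) -> None:
        b1, b2, b3 = self.boundaries
        if not 0.0 < b1 < b2 < b3 < 100.0:
            raise ConfigurationError(
                "phase boundaries must satisfy 0 < b1 < b2 < b3 < 100"
            )

    @property
    def edges(self) -> tuple[float, ...]:
        return (0.0, *self.boundaries, 100.0)


@dataclass(frozen=True)
class DeltaIemgConfig:
    """Weighting coefficients for the group-difference statistic."""

    omega_elite: float = 0.0
    omega_sub: float = 0.0

    def __post_init__(self) -> None:
        if self.omega_elite < 0 or self.omega_sub < 0:
            raise ConfigurationError("weighting coefficients must be >= 0")


def _trapz_segment(grid: np.ndarray, values: np.ndarray, lo: float, hi: float) -> float:
    """Trapezoidal integral of the piecewise-linear curve over [lo, hi].

    Boundary points that fall between grid nodes are inserted by linear
    interpolation, so adjacent segments partition the full integral exactly.
    """
    pts = np.unique(np.concatenate([[lo, hi], grid[(grid > lo) & (grid < hi)]]))
    vals = np.interp(pts, grid, values)
    return float(np.trapezoid(vals, pts))


def integrate_envelope(
    curve: NormalizedCurve,
    phases: PhaseDefinition = PhaseDefinition(),
) -> dict[str, float]:
    """iEMG over each phase and the full cycle.

    Returns a dict with keys ``P1``..``P4`` and ``full``; the phase values
    sum to the full-cycle value to within 1e-9.
    """
    edges = phases.edges
    out: dict[str, float] = {}
    for name, lo, hi in zip(PHASES, edges[:-1], edges[1:]):
        out[name] = _trapz_segment(curve.grid, curve.values, lo, hi)
    out["full"] = float(np.trapezoid(curve.values, curve.grid))
    return out


def iemg_table(
    curves: Iterable[NormalizedCurve],
    phases: PhaseDefinition = PhaseDefinition(),
) -> pd.DataFrame:
    """Long iEMG table: one row per (subject, muscle, leg, trial, phase)."""
    rows = []
    for c in curves:
        vals = integrate_envelope(c, phases)
        for phase, v in vals.items():
            rows.append(
                {
                    "subject": c.subject_id,
                    "group": c.group,
                    "leg": c.leg,
                    "muscle": c.muscle,
                    "trial": c.trial,
                    "phase": phase,
                    "iemg": v,
                }
            )
    return pd.DataFrame(rows)


def delta_iemg(
    mean_elite: float,
    mean_sub: float,
    cfg: DeltaIemgConfig = DeltaIemgConfig(),
) -> float:
    """Weighted relative iEMG difference, normalized by the weighted elite
    mean.  Lies in (-inf, 1]; 0 for identical groups, 1 when the sub-elite
    mean vanishes.  Invariant under common rescaling of both means.
    """
    we = mean_elite * (1.0 + cfg.omega_elite)
    ws = mean_sub * (1.0 + cfg.omega_sub)
    if we <= 0:
        raise ZeroDivisionError(
            "weighted elite mean iEMG must be positive for dIEMG"
        )
    return (we - ws) / we


def delta_iemg_table(
    iemg: pd.DataFrame,
    cfg: DeltaIemgConfig = DeltaIemgConfig(),
) -> pd.DataFrame:
    """dIEMG per (muscle, leg, phase) from group-mean iEMG values."""
    rows = []
    for (muscle, leg, phase), g in iemg.groupby(["muscle", "leg", "phase"]):
        means = g.groupby("group")["iemg"].mean()
        if "elite" not in means or "sub_elite" not in means:
            continue
        rows.append(
            {
                "muscle": muscle,
                "leg": leg,
                "phase": phase,
                "mean_elite": means["elite"],
                "mean_sub_elite": means["sub_elite"],
                "delta_iemg": delta_iemg(means["elite"], means["sub_elite"], cfg),
            }
        )
    return pd.DataFrame(rows)
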