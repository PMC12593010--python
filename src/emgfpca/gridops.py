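"""Shared grid-level numerics: quadrature weights, orthonormalization and
the one-parameter sine time warp used for phase jitter and registration."""

from __future__ import annotations

import numpy as np

from .exceptions import ConfigurationError


def trapezoid_weights(grid: np.ndarray) -> np.ndarray:
    """Quadrature weights w such that sum_t w_t f_t = trapezoid(f, grid)."""
    w = np.empty_like(np.asarray(grid, dtype=float))
    w[1:-1] = (grid[2:] - grid[:-2]) / 2.0
    w[0] = (grid[1] - grid[0]) / 2.0
    w[-1] = (grid[-1] - grid[-2]) / 2.0
    return w


def orthonormalize_modes(modes: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Gram-Schmidt with respect to the trapezoidal inner product on the grid."""
    w = trapezoid_weights(grid)
    out: list[np.ndarray] = []
    for m in np.atleast_2d(np.asarray(modes, dtype=float)):
        v = m.copy()
        for u in out:
            v -= np.sum(w * v * u) * u
        norm = np.sqrt(np.sum(w * v * v))
        if norm < 1e-10:
            raise ConfigurationError("modes are linearly dependent on the grid")
        out.append(v / norm)
    return np.array(out)


def apply_sine_warp(grid: np.ndarray, values: np.ndarray, a: float) -> np.ndarray:
    """Evaluate a curve at the warped time t + a sin(pi t / T).

    The warp preserves both endpoints and is monotone for |a| < T/pi.
    """
    T = grid[-1]
    warped_t = np.clip(grid + a * np.sin(np.pi * grid / T), grid[0], T)
    return np.interp(warped_t, grid, values)
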