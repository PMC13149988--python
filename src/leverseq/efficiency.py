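"""Sequence-efficiency scoring with a positively skewed Gaussian.

The score of a single kinematic variable x is

    S(x) = 2 * phi(x | mu, sigma) * Phi(x | mu, alpha)

with

    phi(x | mu, sigma) = (2*pi)^(-1/2) * exp(-(x - mu)^2 / (2 sigma^2))
    Phi(x | mu, alpha) = 1/2 * [1 + erf(alpha * (x - mu) / sqrt(2))]

Note two deliberate departures from a textbook skew-normal density, kept
because they define the score: phi carries no 1/sigma prefactor, and the
CDF argument is alpha*(x - mu) with no division by sigma. S is therefore a
unimodal positive score, not a normalized density.

Sequence efficiency combines press count (x_LEV) and press frequency
(x_Hz):

    efficiency(x_LEV, x_Hz) = 100 * S(x_LEV) * S(x_Hz)

With the defaults mu=2, sigma=4, alpha=0.5 the efficiency over integer
press counts and frequencies 1..12 peaks at 4 presses at 4 Hz. (On a
continuous axis the maximum of S sits near 4.13; the integer-grid argmax
is 4.)
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import erf

__all__ = ["EfficiencyParams", "skew_component", "seq_efficiency", "efficiency_map"]


@dataclass(frozen=True)
class EfficiencyParams:
    """Parameters of the skewed-Gaussian score.

    mu: location of the symmetric factor; sigma: its spread; alpha: skew of
    the CDF factor; scale: leading constant on the combined score.
    """

    mu: float = 2.0
    sigma: float = 4.0
    alpha: float = 0.5
    scale: float = 100.0

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.scale <= 0:
            raise ValueError("scale must be > 0")


_INV_SQRT_2PI = 1.0 / math.sqrt(2.0 * math.pi)


def skew_component(x, p: EfficiencyParams = EfficiencyParams()):
    """Evaluate S(x); accepts scalars or arrays, NaN propagates."""
    x = np.asarray(x, dtype=float)
    gauss = _INV_SQRT_2PI * np.exp(-((x - p.mu) ** 2) / (2.0 * p.sigma**2))
    cdf = 0.5 * (1.0 + erf(p.alpha * (x - p.mu) / math.sqrt(2.0)))
    out = 2.0 * gauss * cdf
    return float(out) if out.ndim == 0 else out


def seq_efficiency(x_lev, x_hz, p: EfficiencyParams = EfficiencyParams()):
    """Efficiency = scale * S(x_lev) * S(x_hz); NaN inputs yield NaN."""
    out = p.scale * np.asarray(skew_component(x_lev, p)) * np.asarray(skew_component(x_hz, p))
    return float(out) if out.ndim == 0 else out


def efficiency_map(lev_grid, hz_grid, p: EfficiencyParams = EfficiencyParams()) -> np.ndarray:
    """Efficiency over a grid: entry (i, j) scores (lev_grid[i], hz_grid[j]).

    The map is the rank-1 outer product of the two marginal score vectors.
    """
    lev_grid = np.asarray(lev_grid, dtype=float)
    hz_grid = np.asarray(hz_grid, dtype=float)
    if lev_grid.size == 0 or hz_grid.size == 0:
        raise ValueError("grids must be non-empty")
    return p.scale * np.outer(skew_component(lev_grid, p), skew_component(hz_grid, p))
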