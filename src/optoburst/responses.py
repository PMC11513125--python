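"""Input-output response functions linking repressor concentration to burst rates.

The burst frequency is a repressive Hill function of nuclear repressor
concentration ``c``::

    k_on(c) = kon0 * K_D**H / (c**H + K_D**H)

where ``kon0`` is the maximum burst frequency (1/min), ``K_D`` the
concentration midpoint (au) and ``H`` the Hill coefficient (sharpness).

The burst-duration response is a decreasing Hill function of ``c`` for
``k_off`` with a strictly positive floor, so that burst duration
(``1/k_off``) increases moderately with repressor concentration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

__all__ = ["HillResponse", "DurationResponse", "kon_response", "koff_response"]


@dataclass(frozen=True)
class HillResponse:
    """Microscopic parameters of the burst-frequency input-output function."""

    kon0: float  # maximum burst frequency, 1/min
    K_D: float   # concentration midpoint, au
    H: float     # Hill coefficient, dimensionless

    def __post_init__(self) -> None:
        if not (self.kon0 > 0 and self.K_D > 0 and self.H > 0):
            raise ValueError("kon0, K_D and H must all be positive")

    def __call__(self, c):
        return kon_response(c, self)


@dataclass(frozen=True)
class DurationResponse:
    """Parameters of the burst-duration (k_off) response to repressor.

    ``k_off`` decreases from ``koff_base`` at zero repressor toward
    ``koff_floor`` at saturating repressor, so mean burst duration
    increases by a factor ``koff_base / koff_floor``.
    """

    koff_base: float   # k_off at c = 0, 1/min
    koff_floor: float  # k_off at saturating c, 1/min
    K_D_off: float     # midpoint, au
    H_off: float       # sharpness

    def __post_init__(self) -> None:
        if not (self.koff_floor > 0 and self.K_D_off > 0 and self.H_off > 0):
            raise ValueError("koff_floor, K_D_off and H_off must be positive")
        if self.koff_base < self.koff_floor:
            raise ValueError("koff_base must be >= koff_floor")

    def __call__(self, c):
        return koff_response(c, self)


def _hill_repression(c, K_D: float, H: float):
    """K_D**H / (c**H + K_D**H), evaluated stably in log space."""
    scalar = np.ndim(c) == 0
    c = np.atleast_1d(np.asarray(c, dtype=float))
    if np.any(c < 0):
        raise ValueError("concentration must be non-negative")
    out = np.empty_like(c)
    pos = c > 0
    # 1 / (1 + (c/K_D)**H) written as a logistic in log-concentration,
    # which cannot overflow for large c**H
    z = H * (np.log(c[pos]) - np.log(K_D))
    out[pos] = expit(-z)
    out[~pos] = 1.0
    return float(out[0]) if scalar else out


def kon_response(c, p: HillResponse):
    """Burst frequency (1/min) at repressor concentration ``c`` (au)."""
    return p.kon0 * _hill_repression(c, p.K_D, p.H)


def koff_response(c, d: DurationResponse):
    """Burst termination rate (1/min) at repressor concentration ``c`` (au)."""
    return d.koff_floor + (d.koff_base - d.koff_floor) * _hill_repression(
        c, d.K_D_off, d.H_off
    )
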