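"""Numba inner loops for stochastic promoter simulation.

The telegraph process is simulated with fixed-step Bernoulli switching:
in each step of length ``dt`` the promoter switches with probability
``1 - exp(-k * dt)``, evaluating the (possibly time-varying) rate at the
left edge of the step.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["telegraph_paths"]


@njit(cache=False)
def telegraph_paths(kon, koff, dt_min, u, s0):
    """Simulate an ensemble of two-state promoter paths.

    Parameters
    ----------
    kon, koff : float64[n, T]
        Switching rates per minute at each step (left-edge values).
    dt_min : float
        Step length in minutes.
    u : float64[n, T]
        Pre-drawn uniforms, one per (path, step).
    s0 : int8[n]
        Initial promoter state for each path (state during the first step).

    Returns
    -------
    int8[n, T] : promoter state during each step (0 = OFF, 1 = ON).
    """
    n, T = kon.shape
    states = np.empty((n, T), dtype=np.int8)
    for i in range(n):
        s = s0[i]
        for t in range(T):
            states[i, t] = s
            if s == 0:
                p = 1.0 - np.exp(-kon[i, t] * dt_min)
            else:
                p = 1.0 - np.exp(-koff[i, t] * dt_min)
            if u[i, t] < p:
                s = 1 - s
    return states
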