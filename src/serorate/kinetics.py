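"""Deterministic two-phase antibody trajectory after seroconversion.

The antibody concentration rises log-linearly from baseline ``y0`` to peak
``y1`` at time ``t1`` (days), then wanes following the decay ODE

    dy/dt = -alpha * y**r,   y(t1) = y1,

whose solution is a power-law for shape ``r > 1`` and an exponential for
``r = 1``:

    r > 1:  y(t) = y1 * (1 + (r-1) * alpha * y1**(r-1) * (t-t1)) ** (-1/(r-1))
    r = 1:  y(t) = y1 * exp(-alpha * (t-t1))

Larger ``r`` makes the decay slow down as the concentration falls
(long-lived low-level antibody).  Note that ``alpha`` carries units
``concentration**(1-r) / day`` — its numeric value is *not* comparable
across different ``r`` and is never rescaled automatically.

Times exactly at ``t1`` are assigned to the rise branch (the two branches
agree there by construction; fixing the branch keeps evaluation
deterministic).
"""

from __future__ import annotations

import numpy as np

from .data_model import SeroresponseDraw, SerorateError

__all__ = ["growth_rate", "antibody_level", "time_to_level"]


class KineticsError(SerorateError):
    pass


def growth_rate(draw: SeroresponseDraw) -> float:
    """Log-linear growth rate mu = ln(y1/y0) / t1 of the rise phase (1/day)."""
    return float(np.log(draw.y1 / draw.y0) / draw.t1)


def _level_arrays(t, y0, y1, t1, alpha, r, mu):
    """Vectorized trajectory; all kinetics parameters broadcast against t."""
    t = np.asarray(t, dtype=float)
    rise = y0 * np.exp(mu * np.minimum(t, t1))
    dt = np.maximum(t - t1, 0.0)
    with np.errstate(over="ignore"):
        decay = np.where(
            r > 1.0,
            y1 * np.power(1.0 + (r - 1.0) * alpha * y1 ** np.where(r > 1, r - 1.0, 0.0) * dt,
                          -1.0 / np.maximum(r - 1.0, 1e-300)),
            y1 * np.exp(-alpha * dt),
        )
    return np.where(t <= t1, rise, decay)


def antibody_level(t, draw: SeroresponseDraw):
    """Antibody concentration at time ``t`` (days) since seroconversion.

    ``t`` may be a scalar or array; must be >= 0.  Continuous at ``t1`` and
    strictly positive for all finite ``t``.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise KineticsError("t must be ≥ 0")
    out = _level_arrays(t_arr, draw.y0, draw.y1, draw.t1, draw.alpha, draw.r,
                        growth_rate(draw))
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def _decay_time_arrays(y, y1, t1, alpha, r):
    """Vectorized inverse of the decay branch: time at which level y is reached."""
    y = np.asarray(y, dtype=float)
    if r > 1.0:
        return t1 + (y ** (1.0 - r) - y1 ** (1.0 - r)) / (alpha * (r - 1.0))
    return t1 + np.log(y1 / y) / alpha


def time_to_level(y, draw: SeroresponseDraw):
    """Unique time tau >= t1 on the decay branch with antibody_level(tau) == y.

    Requires ``0 < y <= y1`` (levels above the peak are never attained while
    waning).
    """
    y_arr = np.asarray(y, dtype=float)
    if np.any(y_arr <= 0) or np.any(y_arr > draw.y1):
        raise KineticsError("y must satisfy 0 < y ≤ y1 on the decay branch")
    out = _decay_time_arrays(y_arr, draw.y1, draw.t1, draw.alpha, draw.r)
    return float(out) if np.isscalar(y) or y_arr.ndim == 0 else out
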