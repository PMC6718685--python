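"""The neuron map, RRO feedback term, extrema, and attractor-merging analysis.

The reduced one-dimensional dynamics is

    z(t+1) = F(z(t)) = F_a(z(t)) - k * F_b(z(t)),

where ``F_g`` is the threshold-linear activation saturating at +/-1 with gain
``g``.  With the Gaussian-window RRO feedback the iterated map becomes
``F(z) + K*u(z)``.

Attractor merging
-----------------
For the studied parameter range the map is odd with a chaotic sub-attractor
on each side of z = 0.  An orbit trapped on the positive side ranges up to
``f_max``, the local-maximum *value* of the map, so it escapes to the
negative side exactly when the image of that value is negative.  Merging of
the two sub-attractors (chaos-chaos intermittency) therefore occurs iff

    full_map(f_max) < 0   and   full_map(f_min) > 0,

with ``f_max``/``f_min`` the local maximum/minimum values of the full map
(feedback included).  The critical internal gain ``a`` and critical feedback
strength ``K`` are the bisection roots of this condition flip.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .errors import BracketingError, InvalidParameterError, NoExtremumError
from .params import DEFAULT_B, DEFAULT_K_RATIO, FeedbackParams, MapParams

__all__ = [
    "activation",
    "map_F",
    "rro_u",
    "full_map",
    "ExtremaResult",
    "find_extrema",
    "merging_condition",
    "critical_a",
    "critical_K",
]


def activation(x, gain: float):
    """Threshold-linear activation: clip(gain * x, -1, 1).

    Odd in ``x``; saturates at +/-1 beyond the threshold 1/gain.
    Accepts scalars or arrays.
    """
    gain = float(gain)
    if not math.isfinite(gain) or gain <= 0:
        raise InvalidParameterError(f"gain must be finite and > 0, got {gain}")
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise InvalidParameterError("activation input must be finite")
    out = np.clip(gain * x, -1.0, 1.0)
    return out if out.ndim else float(out)


def map_F(z, p: MapParams):
    """Reduced map F(z) = F_a(z) - k * F_b(z); odd, bounded by 1 + k."""
    za = activation(z, p.a)
    zb = activation(z, p.b)
    return za - p.k * zb


def rro_u(z, fb: FeedbackParams):
    """RRO feedback kernel u(z) = -(z - z_d) * exp(-(z - z_d)^2 / (2 sigma^2)).

    Odd about ``z_d`` with extrema at ``z_d +/- sigma`` of magnitude
    ``sigma * exp(-1/2)``.
    """
    z = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z)):
        raise InvalidParameterError("rro_u input must be finite")
    d = z - fb.z_d
    out = -d * np.exp(-(d * d) / (2.0 * fb.sigma**2))
    return out if out.ndim else float(out)


def full_map(z, p: MapParams, fb: FeedbackParams):
    """The iterated map F(z) + K * u(z); odd when z_d = 0."""
    return map_F(z, p) + fb.K * rro_u(z, fb)


@dataclass(frozen=True)
class ExtremaResult:
    """Local extrema of the full map and the merging-condition values.

    ``f_max``/``f_min`` are the local maximum/minimum *values* of the map
    (the highest/lowest state an orbit trapped on one side can reach),
    attained at locations ``z_max``/``z_min``.  ``value_at_max`` and
    ``value_at_min`` are the map images ``full_map(f_max)`` and
    ``full_map(f_min)`` whose signs decide attractor merging.
    """

    f_max: float
    f_min: float
    z_max: float
    z_min: float
    value_at_max: float
    value_at_min: float


def find_extrema(p: MapParams, fb: FeedbackParams, n_grid: int = 10001) -> ExtremaResult:
    """Locate the interior local extrema of the full map.

    A dense grid on [-(1+k), 1+k] brackets the strict local maximum at
    positive location (z > z_d) and the strict local minimum at negative
    location (z < z_d); each bracket is refined by bounded scalar
    minimization to ~1e-10.  Saturated plateaus of the piecewise-linear map
    are flat and never register as strict extrema.

    Raises
    ------
    NoExtremumError
        If no strict interior extremum exists on the required half-axis.
    """
    L = p.z_bound
    x = np.linspace(-L, L, n_grid)
    y = full_map(x, p, fb)
    interior = slice(1, -1)
    is_max = (y[1:-1] > y[:-2]) & (y[1:-1] > y[2:]) & (x[interior] > fb.z_d)
    is_min = (y[1:-1] < y[:-2]) & (y[1:-1] < y[2:]) & (x[interior] < fb.z_d)
    idx_max = np.flatnonzero(is_max) + 1
    idx_min = np.flatnonzero(is_min) + 1
    if idx_max.size == 0 or idx_min.size == 0:
        raise NoExtremumError(
            f"no interior local extremum on [{-L}, {L}] for a={p.a}, K={fb.K}"
        )
    i = idx_max[np.argmax(y[idx_max])]
    j = idx_min[np.argmin(y[idx_min])]

    def _refine(lo: float, hi: float, sign: float) -> tuple[float, float]:
        res = minimize_scalar(
            lambda z: sign * float(full_map(z, p, fb)),
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-12},
        )
        return float(res.x), sign * float(res.fun)

    z_max, f_max = _refine(x[i - 1], x[i + 1], -1.0)
    z_min, f_min = _refine(x[j - 1], x[j + 1], 1.0)
    return ExtremaResult(
        f_max=f_max,
        f_min=f_min,
        z_max=z_max,
        z_min=z_min,
        value_at_max=float(full_map(f_max, p, fb)),
        value_at_min=float(full_map(f_min, p, fb)),
    )


def merging_condition(p: MapParams, fb: FeedbackParams) -> bool:
    """True iff the two chaotic sub-attractors are merged.

    The condition is full_map(f_max) < 0 and full_map(f_min) > 0: the image
    of the highest reachable state falls below the separating point and
    vice versa, so chaos-chaos intermittency occurs.
    """
    ex = find_extrema(p, fb)
    return ex.value_at_max < 0.0 and ex.value_at_min > 0.0


def _bisect_flag(flag, lo: float, hi: float, tol: float) -> float:
    f_lo, f_hi = flag(lo), flag(hi)
    if f_lo == f_hi:
        raise BracketingError(
            f"merging condition identical ({f_lo}) at both bracket ends [{lo}, {hi}]"
        )
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if flag(mid) == f_lo:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def critical_a(
    K: float = 0.0,
    bracket: tuple[float, float] = (5.9, 6.1),
    tol: float = 1e-6,
    b: float = DEFAULT_B,
    k: float = DEFAULT_K_RATIO,
) -> float:
    """Critical excitatory gain at which attractor merging switches on.

    The feedback width follows the sigma = 1/a convention, so the controller
    is rebuilt at every trial gain.
    """

    def flag(a: float) -> bool:
        p = MapParams(a=a, b=b, k=k)
        return merging_condition(p, FeedbackParams.for_map(p, K=K))

    return _bisect_flag(flag, *bracket, tol)


def critical_K(
    p: MapParams,
    bracket: tuple[float, float] = (-0.15, 0.0),
    tol: float = 1e-6,
    z_d: float = 0.0,
) -> float:
    """Critical RRO feedback strength for attractor merging at fixed map params."""

    def flag(K: float) -> bool:
        return merging_condition(p, FeedbackParams.for_map(p, K=K, z_d=z_d))

    return _bisect_flag(flag, *bracket, tol)
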