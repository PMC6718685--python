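"""Trajectory simulation, binarization, and chaos-chaos intermittency rate."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from . import _kernels
from .errors import InvalidParameterError
from .map_core import activation
from .params import DriveParams, FeedbackParams, MapParams

__all__ = [
    "Trajectory",
    "step_2d",
    "simulate",
    "binarize",
    "intermittency_probability",
]


@dataclass
class Trajectory:
    """A simulated orbit of the effective neural potential.

    Attributes
    ----------
    z : ndarray
        Retained state series z(t), t = t0 .. t0 + T - 1.
    Z : ndarray
        Binarized series, +1 where z >= 0, else -1.
    S : ndarray
        Sinusoidal drive S(t) aligned sample-for-sample with ``z``.
    t0 : int
        Number of discarded transient iterations; the drive phase uses the
        absolute index so S keeps its phase across the cut.
    meta : dict
        Full generating parameter set (including the noise seed).
    """

    z: np.ndarray
    Z: np.ndarray
    S: np.ndarray
    t0: int
    meta: dict[str, Any] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.z)


def step_2d(x: float, y: float, p: MapParams) -> tuple[float, float]:
    """One synchronous update of the excitatory/inhibitory pair.

    x(t+1) = F_a(w_EE x - w_EI y), y(t+1) = F_b(w_IE x - w_II y).
    Under the weight-ratio constraint, z = x - k*y follows the reduced map.
    """
    xn = activation(p.w_EE * x - p.w_EI * y, p.a)
    yn = activation(p.w_IE * x - p.w_II * y, p.b)
    return float(xn), float(yn)


def simulate(
    p: MapParams,
    fb: FeedbackParams | None = None,
    drive: DriveParams | None = None,
    z0: float = 0.2,
    T: int = 200_000,
    transient: int = 10_000,
) -> Trajectory:
    """Iterate z(t+1) = F(z) + K u(z) + S(t) + D xi(t) and return the orbit.

    ``transient`` leading iterations are discarded; ``T`` samples are
    retained together with the simultaneous drive values.  The Gaussian
    noise realization is reproducible from ``drive.seed``.
    """
    if T <= 0:
        raise InvalidParameterError(f"T must be > 0, got {T}")
    if transient < 0:
        raise InvalidParameterError(f"transient must be >= 0, got {transient}")
    fb = fb if fb is not None else FeedbackParams.for_map(p)
    drive = drive if drive is not None else DriveParams()
    total = transient + T
    if drive.D > 0:
        rng = np.random.default_rng(drive.seed)
        noise = rng.standard_normal(total)
    else:
        noise = np.zeros(total)
    out_z = np.empty(T)
    out_s = np.empty(T)
    _kernels.iterate(
        float(z0), int(transient), int(T),
        p.a, p.b, p.k, fb.K, fb.z_d, fb.sigma,
        drive.A, drive.Omega, drive.D, noise, out_z, out_s,
    )
    if not np.all(np.isfinite(out_z)):  # cannot occur for finite parameters
        raise RuntimeError("non-finite state encountered during simulation")
    meta = {
        "a": p.a, "b": p.b, "k": p.k,
        "K": fb.K, "z_d": fb.z_d, "sigma": fb.sigma,
        "A": drive.A, "Omega": drive.Omega, "D": drive.D, "seed": drive.seed,
        "z0": float(z0), "T": int(T), "transient": int(transient),
    }
    return Trajectory(z=out_z, Z=binarize(out_z), S=out_s, t0=transient, meta=meta)


def binarize(z: np.ndarray) -> np.ndarray:
    """Sign-binarize a state series: +1 where z >= 0, -1 otherwise."""
    z = np.asarray(z)
    if not np.all(np.isfinite(z)):
        raise InvalidParameterError("binarize input must be finite")
    return np.where(z >= 0, 1, -1).astype(np.int64)


def intermittency_probability(traj: Trajectory | np.ndarray) -> float:
    """Occurrence probability of chaos-chaos intermittency, P_t = f_cc / T.

    f_cc counts the sign changes of the binarized series between consecutive
    retained samples; the result lies in [0, 1).
    """
    Z = traj.Z if isinstance(traj, Trajectory) else binarize(np.asarray(traj))
    T = len(Z)
    if T < 2:
        raise InvalidParameterError(f"need at least 2 samples, got {T}")
    f_cc = int(np.count_nonzero(Z[1:] != Z[:-1]))
    return f_cc / T
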