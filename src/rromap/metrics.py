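"""Signal-response correlation C(tau) and Lyapunov exponent estimation."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .errors import InvalidParameterError, UndefinedCorrelationError
from .params import DriveParams, FeedbackParams, MapParams

__all__ = [
    "CorrelationResult",
    "LyapunovConfig",
    "default_tau_grid",
    "cross_correlation",
    "lyapunov",
]


@dataclass(frozen=True)
class CorrelationResult:
    """Normalized delayed cross-correlation between drive and binarized state.

    C(tau) = C_SZ(tau) / sqrt(C_SS * C_ZZ) with
    C_SZ(tau) = <(S(t+tau) - <S>)(Z(t) - <Z>)> and the (co)variances taken
    over the overlapping window at each delay.
    """

    tau_grid: np.ndarray
    C: np.ndarray
    max_C: float
    argmax_tau: int


@dataclass(frozen=True)
class LyapunovConfig:
    """Perturbation-growth estimator settings.

    M restarts, each cloning the state, offsetting by d0, and evolving both
    copies tau steps under identical forcing; lambda is the mean of
    ln(d(tau)/d0)/tau.
    """

    M: int = 100_000
    tau: int = 1
    d0: float = 1e-8

    def __post_init__(self) -> None:
        if self.M < 1 or self.tau < 1 or not self.d0 > 0:
            raise InvalidParameterError(
                f"require M >= 1, tau >= 1, d0 > 0 (got M={self.M}, tau={self.tau}, d0={self.d0})"
            )


def default_tau_grid(Omega: float, n: int = 64) -> np.ndarray:
    """n distinct integer delays spanning one drive period [0, 1/Omega)."""
    if not Omega > 0:
        raise InvalidParameterError("Omega must be > 0 for a delay grid")
    period = 1.0 / Omega
    grid = np.unique(np.floor(np.linspace(0.0, period, n, endpoint=False)).astype(np.int64))
    return grid


def cross_correlation(S, Z, tau_grid=None, Omega: float | None = None) -> CorrelationResult:
    """Normalized cross-correlation of the drive with the binarized response.

    Parameters
    ----------
    S, Z : array-like, equal length
        Drive and response series on the same clock.
    tau_grid : array-like of int, optional
        Delays to evaluate; defaults to 64 delays over one drive period
        (requires ``Omega``).

    Raises
    ------
    UndefinedCorrelationError
        If S or Z is constant on any overlap window (e.g. no intermittency).
    """
    S = np.asarray(S, dtype=float)
    Z = np.asarray(Z, dtype=float)
    if S.shape != Z.shape or S.ndim != 1:
        raise InvalidParameterError("S and Z must be equal-length 1-D series")
    if tau_grid is None:
        if Omega is None:
            raise InvalidParameterError("either tau_grid or Omega must be given")
        tau_grid = default_tau_grid(Omega)
    tau_grid = np.asarray(tau_grid, dtype=np.int64)
    n = len(S)
    if n <= int(tau_grid.max()) + 1:
        raise InvalidParameterError(
            f"series length {n} too short for max delay {int(tau_grid.max())}"
        )
    C = np.empty(len(tau_grid))
    for i, tau in enumerate(tau_grid):
        s = S[tau : n]
        z = Z[: n - tau]
        ms = s.mean()
        mz = z.mean()
        c_sz = float(s @ z) / len(s) - ms * mz
        c_ss = float(s @ s) / len(s) - ms * ms
        c_zz = float(z @ z) / len(z) - mz * mz
        if c_ss <= 0.0 or c_zz <= 0.0:
            raise UndefinedCorrelationError(
                f"zero variance at delay {int(tau)} (C_SS={c_ss:.3g}, C_ZZ={c_zz:.3g})"
            )
        C[i] = c_sz / np.sqrt(c_ss * c_zz)
    imax = int(np.argmax(C))
    return CorrelationResult(
        tau_grid=tau_grid, C=C, max_C=float(C[imax]), argmax_tau=int(tau_grid[imax])
    )


def lyapunov(
    p: MapParams,
    fb: FeedbackParams | None = None,
    drive: DriveParams | None = None,
    z0: float = 0.2,
    cfg: LyapunovConfig = LyapunovConfig(),
    transient: int = 10_000,
) -> float:
    """Largest Lyapunov exponent of the driven map via perturbed restarts.

    Reference and perturbed orbits share the identical noise realization, so
    the estimate reflects state-space divergence only.  With tau = 1 and no
    noise this converges to the orbit average of ln|map'(z)|.
    """
    fb = fb if fb is not None else FeedbackParams.for_map(p)
    drive = drive if drive is not None else DriveParams()
    total = transient + cfg.M * cfg.tau
    if drive.D > 0:
        rng = np.random.default_rng(drive.seed)
        noise = rng.standard_normal(total)
    else:
        noise = np.zeros(total)
    return float(
        _kernels.lyapunov_sum(
            float(z0), int(transient), int(cfg.M), int(cfg.tau), float(cfg.d0),
            p.a, p.b, p.k, fb.K, fb.z_d, fb.sigma,
            drive.A, drive.Omega, drive.D, noise,
        )
    )
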