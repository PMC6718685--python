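"""Parameter sweeps: bifurcation scans, resonance curves, and response surfaces.

Every sweep returns a :class:`SweepResult` carrying a long-form table (one
row per grid point, initial condition or trial), the per-trial seeds, and
full provenance, so that any scan can be regenerated exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .dynamics import intermittency_probability, simulate
from .errors import InvalidParameterError, NoThresholdError, UndefinedCorrelationError
from .map_core import find_extrema, merging_condition
from .metrics import LyapunovConfig, cross_correlation, lyapunov
from .params import DriveParams, FeedbackParams, MapParams

__all__ = [
    "SweepResult",
    "bifurcation_scan",
    "response_curve",
    "response_surface",
    "find_threshold",
    "find_peak",
]

_SEED_MAX = 2**31 - 1


def _spawn_seeds(seed: int | None, n: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(0, _SEED_MAX, size=n)


def _draw_z0(rng: np.random.Generator) -> float:
    # magnitude away from both the unstable origin and the saturation region
    return float(rng.choice([-1.0, 1.0]) * rng.uniform(0.1, 0.2))


@dataclass
class SweepResult:
    """Labeled grid of swept parameter(s) against the recorded metrics."""

    axis1_name: str
    axis1_grid: np.ndarray
    table: pd.DataFrame
    axis2_name: str | None = None
    axis2_grid: np.ndarray | None = None
    points: pd.DataFrame | None = None
    trials: int = 1
    seeds: list[int] = field(default_factory=list)
    provenance: dict[str, Any] = field(default_factory=dict)

    def summary(self, column: str = "max_C") -> pd.DataFrame:
        """Mean and sd of ``column`` per grid point (NaN-aware)."""
        keys = [self.axis1_name] + ([self.axis2_name] if self.axis2_name else [])
        g = self.table.groupby(keys, sort=False)[column]
        out = g.agg(["mean", "std", "count"]).reset_index()
        return out


def _resolve_point(
    param: str, value: float, p: MapParams, fb: FeedbackParams
) -> tuple[MapParams, FeedbackParams]:
    if param == "a":
        p2 = MapParams(a=value, b=p.b, k=p.k)
        return p2, FeedbackParams.for_map(p2, K=fb.K, z_d=fb.z_d)
    if param == "K":
        return p, FeedbackParams(K=value, z_d=fb.z_d, sigma=fb.sigma)
    raise InvalidParameterError(f"unsupported scan parameter {param!r}")


def bifurcation_scan(
    param: str,
    grid,
    p: MapParams,
    fb: FeedbackParams | None = None,
    T: int = 100_000,
    transient: int = 10_000,
    seed: int | None = 0,
    lyap_M: int = 100_000,
    n_attractor: int = 200,
) -> SweepResult:
    """Scan ``a``, ``K`` or ``D`` and record attractor structure and indices.

    At each grid value the map is iterated from one negative and one
    positive initial condition (z0 = -0.3, +0.3).  Recorded per run:
    P_t, the Lyapunov exponent, the merging-condition values
    full_map(f_max) and full_map(f_min), and the last ``n_attractor``
    retained states (in ``SweepResult.points``) for the bifurcation
    diagram.  Failures at individual points are recorded, not raised.
    """
    if param not in ("a", "K", "D"):
        raise InvalidParameterError(f"param must be one of a, K, D; got {param!r}")
    fb = fb if fb is not None else FeedbackParams.for_map(p)
    grid = np.asarray(grid, dtype=float)
    seeds = _spawn_seeds(seed, len(grid))
    rows: list[dict[str, Any]] = []
    pts: list[pd.DataFrame] = []
    for value, pt_seed in zip(grid, seeds):
        if param == "D":
            p_i, fb_i, D_i = p, fb, float(value)
        else:
            (p_i, fb_i), D_i = _resolve_point(param, float(value), p, fb), 0.0
        for z0 in (-0.2, 0.2):
            row: dict[str, Any] = {param: float(value), "z0": z0, "seed": int(pt_seed)}
            try:
                drive = DriveParams(D=D_i, seed=int(pt_seed))
                traj = simulate(p_i, fb_i, drive, z0=z0, T=T, transient=transient)
                ex = find_extrema(p_i, fb_i)
                row.update(
                    P_t=intermittency_probability(traj),
                    lyap=lyapunov(
                        p_i, fb_i, drive, z0=z0,
                        cfg=LyapunovConfig(M=lyap_M), transient=transient,
                    ),
                    value_at_max=ex.value_at_max,
                    value_at_min=ex.value_at_min,
                    merged=bool(ex.value_at_max < 0 and ex.value_at_min > 0),
                )
                pts.append(
                    pd.DataFrame(
                        {param: float(value), "z0": z0, "z": traj.z[-n_attractor:]}
                    )
                )
            except Exception as err:  # record, keep scanning
                row["error"] = f"{type(err).__name__}: {err}"
            rows.append(row)
    return SweepResult(
        axis1_name=param,
        axis1_grid=grid,
        table=pd.DataFrame(rows),
        points=pd.concat(pts, ignore_index=True) if pts else None,
        trials=2,
        seeds=[int(s) for s in seeds],
        provenance={
            "kind": "bifurcation_scan", "param": param, "grid": grid.tolist(),
            "a": p.a, "b": p.b, "k": p.k, "K": fb.K, "z_d": fb.z_d, "sigma": fb.sigma,
            "T": T, "transient": transient, "seed": seed, "lyap_M": lyap_M,
        },
    )


def response_curve(
    param: str,
    grid,
    p: MapParams,
    drive: DriveParams,
    fb: FeedbackParams | None = None,
    trials: int = 10,
    T: int = 200_000,
    transient: int = 10_000,
    seed: int | None = 0,
) -> SweepResult:
    """Trial-averaged max_tau C(tau) along a feedback (K) or noise (D) axis.

    Each trial draws an independent noise seed and an initial condition with
    random sign and magnitude uniform in [0.1, 0.5].  Points where the
    response is constant (no chaos-chaos intermittency) are recorded as NaN.
    """
    if param not in ("K", "D"):
        raise InvalidParameterError(f"param must be K or D, got {param!r}")
    if not (drive.A > 0 and drive.Omega > 0):
        raise InvalidParameterError("response_curve requires a drive with A > 0, Omega > 0")
    fb = fb if fb is not None else FeedbackParams.for_map(p)
    grid = np.asarray(grid, dtype=float)
    seeds = _spawn_seeds(seed, len(grid) * trials)
    z0_rng = np.random.default_rng(None if seed is None else seed + 1)
    rows = []
    for i, value in enumerate(grid):
        if param == "K":
            p_i, fb_i = _resolve_point("K", float(value), p, fb)
            d_i = drive
        else:
            p_i, fb_i = p, fb
            d_i = DriveParams(A=drive.A, Omega=drive.Omega, D=float(value))
        for j in range(trials):
            s = int(seeds[i * trials + j])
            z0 = _draw_z0(z0_rng)
            d_trial = DriveParams(A=d_i.A, Omega=d_i.Omega, D=d_i.D, seed=s)
            traj = simulate(p_i, fb_i, d_trial, z0=z0, T=T, transient=transient)
            row = {param: float(value), "trial": j, "seed": s, "z0": z0,
                   "P_t": intermittency_probability(traj)}
            try:
                res = cross_correlation(traj.S, traj.Z, Omega=d_i.Omega)
                row["max_C"] = res.max_C
                row["argmax_tau"] = res.argmax_tau
            except UndefinedCorrelationError:
                row["max_C"] = np.nan
            rows.append(row)
    return SweepResult(
        axis1_name=param,
        axis1_grid=grid,
        table=pd.DataFrame(rows),
        trials=trials,
        seeds=[int(s) for s in seeds],
        provenance={
            "kind": "response_curve", "param": param, "grid": grid.tolist(),
            "a": p.a, "b": p.b, "k": p.k, "K": fb.K, "z_d": fb.z_d, "sigma": fb.sigma,
            "A": drive.A, "Omega": drive.Omega, "D": drive.D,
            "trials": trials, "T": T, "transient": transient, "seed": seed,
        },
    )


def response_surface(
    axis1: str,
    axis1_grid,
    A_grid,
    p: MapParams,
    drive: DriveParams,
    fb: FeedbackParams | None = None,
    trials: int = 10,
    T: int = 200_000,
    transient: int = 10_000,
    seed: int | None = 0,
) -> SweepResult:
    """2-D grid of trial-mean max_tau C(tau) over (K|D|Omega) x amplitude A.

    Per axis1 value the column ``merged_no_drive`` marks whether attractor
    merging occurs without the sinusoid: analytically for the K axis, by a
    drive-free noisy run for the D axis, and from the base parameters for
    the Omega axis.
    """
    if axis1 not in ("K", "D", "Omega"):
        raise InvalidParameterError(f"axis1 must be K, D or Omega, got {axis1!r}")
    fb = fb if fb is not None else FeedbackParams.for_map(p)
    axis1_grid = np.asarray(axis1_grid, dtype=float)
    A_grid = np.asarray(A_grid, dtype=float)
    seeds = _spawn_seeds(seed, len(axis1_grid) * len(A_grid) * trials)
    z0_rng = np.random.default_rng(None if seed is None else seed + 1)
    merge_rng = np.random.default_rng(None if seed is None else seed + 2)
    rows = []
    idx = 0
    for v1 in axis1_grid:
        if axis1 == "K":
            p_i, fb_i = _resolve_point("K", float(v1), p, fb)
            D_i, Om_i = drive.D, drive.Omega
            merged_no_drive = merging_condition(p_i, fb_i)
        elif axis1 == "D":
            p_i, fb_i = p, fb
            D_i, Om_i = float(v1), drive.Omega
            if D_i > 0:
                probe = simulate(
                    p_i, fb_i, DriveParams(D=D_i, seed=int(merge_rng.integers(_SEED_MAX))),
                    z0=0.2, T=T, transient=transient,
                )
                merged_no_drive = intermittency_probability(probe) > 0
            else:
                merged_no_drive = merging_condition(p_i, fb_i)
        else:  # Omega axis: merging without drive is a property of the base point
            p_i, fb_i = p, fb
            D_i, Om_i = drive.D, float(v1)
            merged_no_drive = merging_condition(p_i, fb_i)
        for A in A_grid:
            for j in range(trials):
                s = int(seeds[idx]); idx += 1
                z0 = _draw_z0(z0_rng)
                d_trial = DriveParams(A=float(A), Omega=Om_i, D=D_i, seed=s)
                traj = simulate(p_i, fb_i, d_trial, z0=z0, T=T, transient=transient)
                row = {axis1: float(v1), "A": float(A), "trial": j, "seed": s,
                       "z0": z0, "merged_no_drive": bool(merged_no_drive),
                       "P_t": intermittency_probability(traj)}
                try:
                    res = cross_correlation(traj.S, traj.Z, Omega=Om_i)
                    row["max_C"] = res.max_C
                except UndefinedCorrelationError:
                    row["max_C"] = np.nan
                rows.append(row)
    return SweepResult(
        axis1_name=axis1,
        axis1_grid=axis1_grid,
        axis2_name="A",
        axis2_grid=A_grid,
        table=pd.DataFrame(rows),
        trials=trials,
        seeds=[int(s) for s in seeds],
        provenance={
            "kind": "response_surface", "axis1": axis1,
            "axis1_grid": axis1_grid.tolist(), "A_grid": A_grid.tolist(),
            "a": p.a, "b": p.b, "k": p.k, "K": fb.K, "z_d": fb.z_d, "sigma": fb.sigma,
            "A": drive.A, "Omega": drive.Omega, "D": drive.D,
            "trials": trials, "T": T, "transient": transient, "seed": seed,
        },
    )


def find_threshold(
    sweep: SweepResult,
    column: str = "P_t",
    threshold: float = 0.0,
    agg: str = "max",
) -> float:
    """First axis1 grid value at which ``agg(column) > threshold``.

    ``agg`` aggregates over the runs at each grid point ('max': the
    predicate holds in *either* run).  Warns and returns the first onset if
    the predicate flips more than once along the axis.
    """
    g = sweep.table.groupby(sweep.axis1_name, sort=False)[column].agg(agg)
    g = g.reindex(sweep.axis1_grid)
    holds = (g > threshold).to_numpy()
    if not holds.any() or holds.all():
        raise NoThresholdError(
            f"predicate {column} > {threshold} {'always' if holds.all() else 'never'} holds"
        )
    flips = np.count_nonzero(np.diff(holds.astype(int)) != 0)
    if flips > 1:
        warnings.warn(
            f"predicate flips {flips} times along {sweep.axis1_name}; returning first onset",
            stacklevel=2,
        )
    return float(sweep.axis1_grid[int(np.argmax(holds))])


def find_peak(sweep: SweepResult, column: str = "max_C") -> tuple[float, float]:
    """Grid argmax of the trial-mean metric along axis1.

    Ties are broken toward the grid value of smallest magnitude (the
    weakest control).  Requires at least 3 grid points with a defined mean.
    """
    means = sweep.table.groupby(sweep.axis1_name, sort=False)[column].mean()
    means = means.reindex(sweep.axis1_grid)
    valid = means.notna()
    if valid.sum() < 3:
        raise NoThresholdError(f"fewer than 3 valid grid points for {column}")
    best = means[valid].max()
    candidates = means.index[valid & (means >= best - 0.0)].to_numpy()
    at = candidates[np.argmin(np.abs(candidates))] if len(candidates) > 1 else candidates[0]
    return float(at), float(best)
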