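"""Numba-compiled iteration kernels.

The map is iterated hundreds of millions of times in the sweep experiments,
so the inner loops are compiled.  All kernels take the scalar parameters
explicitly; randomness is supplied as a pre-drawn noise array so that the
same realization can be shared between reference and perturbed orbits.
"""

import numpy as np
from numba import njit

TWO_PI = 2.0 * np.pi


@njit(cache=True, inline="always")
def _step(z, a, b, k, K, z_d, inv2s2):
    fa = a * z
    if fa > 1.0:
        fa = 1.0
    elif fa < -1.0:
        fa = -1.0
    fbv = b * z
    if fbv > 1.0:
        fbv = 1.0
    elif fbv < -1.0:
        fbv = -1.0
    d = z - z_d
    u = -d * np.exp(-d * d * inv2s2)
    return fa - k * fbv + K * u


@njit(cache=True)
def iterate(z0, transient, T, a, b, k, K, z_d, sigma, A, omega, D, noise, out_z, out_s):
    """Iterate z(t+1) = F(z) + K u(z) + S(t) + D xi(t) from t = 0.

    The drive phase runs on the absolute iteration index, including the
    discarded transient, so retained windows of different lengths share a
    common clock.  ``noise`` must have length >= transient + T.
    Retained samples t = transient .. transient+T-1 are written to ``out_z``
    with the simultaneous drive value in ``out_s``.
    """
    inv2s2 = 1.0 / (2.0 * sigma * sigma)
    z = z0
    total = transient + T
    for t in range(total):
        s = A * np.sin(TWO_PI * omega * t) if A > 0.0 else 0.0
        if t >= transient:
            out_z[t - transient] = z
            out_s[t - transient] = s
        z = _step(z, a, b, k, K, z_d, inv2s2) + s + D * noise[t]


@njit(cache=True)
def lyapunov_sum(z0, transient, M, tau, d0, a, b, k, K, z_d, sigma, A, omega, D, noise):
    """Mean log divergence rate from M perturbed restarts of length tau.

    At each restart the state is cloned, offset by d0, and both copies are
    evolved tau steps under the identical drive and noise (common-noise
    convention), so the accumulated log ratio measures state-space
    divergence only.  Returns lambda = sum(ln(d_k/d0)) / (tau * M).
    ``noise`` must have length >= transient + M*tau.
    """
    inv2s2 = 1.0 / (2.0 * sigma * sigma)
    z = z0
    for t in range(transient):
        s = A * np.sin(TWO_PI * omega * t) if A > 0.0 else 0.0
        z = _step(z, a, b, k, K, z_d, inv2s2) + s + D * noise[t]
    acc = 0.0
    t_abs = transient
    tiny = 1e-300
    for _ in range(M):
        zp = z + d0
        for _ in range(tau):
            s = A * np.sin(TWO_PI * omega * t_abs) if A > 0.0 else 0.0
            common = s + D * noise[t_abs]
            z = _step(z, a, b, k, K, z_d, inv2s2) + common
            zp = _step(zp, a, b, k, K, z_d, inv2s2) + common
            t_abs += 1
        d = abs(zp - z)
        if d < tiny:
            d = tiny
        acc += np.log(d / d0)
    return acc / (tau * M)
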