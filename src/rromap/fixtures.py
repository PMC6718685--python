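"""Deterministic toy series for exercising the metrics.

These are not model orbits: they are hand-constructed signals with known
correlation, intermittency and contraction properties, used to unit-test
the metric implementations against independent oracles.
"""

from __future__ import annotations

import numpy as np

__all__ = ["make_fixtures"]


def make_fixtures(seed: int = 0, n: int = 2000) -> dict[str, dict[str, np.ndarray]]:
    """Build the standard metric fixtures.

    Returns a dict of named fixtures, each a dict of series:

    - ``aligned``: sinusoid S plus its sign-binarization Z (high correlation
      at zero delay), with a small seeded jitter in the sign flips.
    - ``independent``: sinusoid S with an independent random +/-1 series.
    - ``constant``: all-positive state series (P_t = 0, undefined C).
    - ``alternating``: strictly alternating +/-1 series of length 100
      (P_t = 99/100).
    - ``contracting``: orbit of the linear toy map z -> 0.5 z from z0 = 1
      (Lyapunov exponent ln 0.5 < 0).
    """
    rng = np.random.default_rng(seed)
    t = np.arange(n)
    S = 0.05 * np.sin(2 * np.pi * 0.01 * t)
    Z_aligned = np.where(S + 1e-4 * rng.standard_normal(n) >= 0, 1, -1)
    Z_indep = rng.choice([-1, 1], size=n)
    alternating = np.empty(100, dtype=np.int64)
    alternating[::2] = 1
    alternating[1::2] = -1
    contracting = 1.0 * 0.5 ** np.arange(64)
    return {
        "aligned": {"S": S, "Z": Z_aligned.astype(np.int64)},
        "independent": {"S": S, "Z": Z_indep.astype(np.int64)},
        "constant": {"z": np.full(100, 0.2)},
        "alternating": {"Z": alternating},
        "contracting": {"z": contracting},
    }
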