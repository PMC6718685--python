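import numpy as np
import pytest

from rromap import FeedbackParams, MapParams


@pytest.fixture(scope="session")
def p596():
    """Map at a = 5.96: separated chaotic sub-attractors (no feedback)."""
    return MapParams(a=5.96)


@pytest.fixture(scope="session")
def p603():
    """Map at a = 6.03: merged chaotic attractor (no feedback)."""
    return MapParams(a=6.03)


@pytest.fixture(scope="session")
def fb0(p596):
    return FeedbackParams.for_map(p596)


def brute_force_correlation(S, Z, tau_grid):
    """Independent direct evaluation of the normalized delayed correlation.

    Straight transcription of the defining time averages on the overlapping
    window at each delay; used as the oracle for cross_correlation.
    """
    S = np.asarray(S, dtype=float)
    Z = np.asarray(Z, dtype=float)
    n = len(S)
    out = []
    for tau in tau_grid:
        m = n - int(tau)
        s_win = [S[t + tau] for t in range(m)]
        z_win = [Z[t] for t in range(m)]
        s_mean = sum(s_win) / m
        z_mean = sum(z_win) / m
        c_sz = sum((s_win[t] - s_mean) * (z_win[t] - z_mean) for t in range(m)) / m
        c_ss = sum((sv - s_mean) ** 2 for sv in s_win) / m
        c_zz = sum((zv - z_mean) ** 2 for zv in z_win) / m
        out.append(c_sz / np.sqrt(c_ss * c_zz))
    return np.asarray(out)
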