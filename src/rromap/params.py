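"""Parameter containers for the excitatory/inhibitory neuron map.

The model is a pair of threshold-linear neurons whose two-dimensional
dynamics collapses, under the weight-ratio constraint
``w_EI/w_EE = w_II/w_IE = k``, onto a one-dimensional map for the
effective neural potential ``z = x - k*y``.  Three dataclasses hold the
three independent ingredients: the map itself (:class:`MapParams`), the
Gaussian-shaped reduced-region-of-orbit (RRO) feedback controller
(:class:`FeedbackParams`), and the external forcing -- weak sinusoid plus
additive white Gaussian noise (:class:`DriveParams`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import InvalidParameterError

#: Default inhibitory gain.
DEFAULT_B = 3.42
#: Default inhibition ratio (w_EI/w_EE = w_II/w_IE).
DEFAULT_K_RATIO = 1.3811

_WEIGHT_RTOL = 1e-12


def _require_finite(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise InvalidParameterError(f"{name} must be finite, got {value!r}")
    return value


@dataclass(frozen=True)
class MapParams:
    """Internal parameters of the neuron map.

    Parameters
    ----------
    a : float
        Excitatory gain (> 0); 1/a is the excitatory activation threshold.
    b : float
        Inhibitory gain (> 0); 1/b is the inhibitory activation threshold.
    k : float
        Inhibition ratio (> 0) coupling the two activations in the reduced map.
    w_EE, w_EI, w_IE, w_II : float
        Synaptic weights of the full two-neuron system.  Defaults satisfy the
        reduction constraint exactly (w_EE = w_IE = 1, w_EI = w_II = k).
    """

    a: float
    b: float = DEFAULT_B
    k: float = DEFAULT_K_RATIO
    w_EE: float = 1.0
    w_EI: float | None = None
    w_IE: float = 1.0
    w_II: float | None = None

    def __post_init__(self) -> None:
        for name in ("a", "b", "k"):
            v = _require_finite(name, getattr(self, name))
            if v <= 0:
                raise InvalidParameterError(f"{name} must be > 0, got {v}")
            object.__setattr__(self, name, v)
        if self.w_EI is None:
            object.__setattr__(self, "w_EI", self.k * self.w_EE)
        if self.w_II is None:
            object.__setattr__(self, "w_II", self.k * self.w_IE)
        for name in ("w_EE", "w_EI", "w_IE", "w_II"):
            object.__setattr__(self, name, _require_finite(name, getattr(self, name)))
        # the 2-D -> 1-D reduction only holds on this weight manifold
        for num, den in ((self.w_EI, self.w_EE), (self.w_II, self.w_IE)):
            if den == 0 or abs(num / den - self.k) > _WEIGHT_RTOL * max(1.0, abs(self.k)):
                raise InvalidParameterError(
                    "weights must satisfy w_EI/w_EE = w_II/w_IE = k "
                    f"(got ratios {self.w_EI / self.w_EE if self.w_EE else float('nan')}, "
                    f"{self.w_II / self.w_IE if self.w_IE else float('nan')}; k={self.k})"
                )

    @property
    def z_bound(self) -> float:
        """Bound on |F(z)|: the map image lies in [-(1+k), 1+k]."""
        return 1.0 + self.k


@dataclass(frozen=True)
class FeedbackParams:
    """RRO feedback controller ``K * u(z)`` with Gaussian window.

    ``u(z) = -(z - z_d) exp(-(z - z_d)^2 / (2 sigma^2))`` pushes the orbit
    toward (K < 0) or away from (K > 0) the merging point ``z_d``.

    Parameters
    ----------
    K : float
        Feedback strength; negative values merge a separated attractor,
        positive values separate a merged one.
    z_d : float
        Merging point between the two chaotic sub-attractors (0 for the
        symmetric map).
    sigma : float
        Width of the feedback window (> 0); conventionally 1/a, the distance
        from the merging point to the local extremum of the map.
    """

    K: float = 0.0
    z_d: float = 0.0
    sigma: float = 0.1678

    def __post_init__(self) -> None:
        for name in ("K", "z_d", "sigma"):
            object.__setattr__(self, name, _require_finite(name, getattr(self, name)))
        if self.sigma <= 0:
            raise InvalidParameterError(f"sigma must be > 0, got {self.sigma}")

    @classmethod
    def for_map(cls, p: MapParams, K: float = 0.0, z_d: float = 0.0) -> "FeedbackParams":
        """Controller with the conventional width sigma = 1/a."""
        return cls(K=K, z_d=z_d, sigma=1.0 / p.a)


@dataclass(frozen=True)
class DriveParams:
    """External forcing: weak sinusoid S(t) = A sin(2 pi Omega t) plus noise.

    Parameters
    ----------
    A : float
        Signal amplitude (>= 0, state units).
    Omega : float
        Signal frequency in cycles per iteration; 0 <= Omega < 0.5 (Nyquist).
    D : float
        Strength of the additive zero-mean unit-variance Gaussian noise (>= 0).
    seed : int or None
        Seed for the noise realization; None draws from OS entropy.
    """

    A: float = 0.0
    Omega: float = 0.0
    D: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("A", "Omega", "D"):
            object.__setattr__(self, name, _require_finite(name, getattr(self, name)))
        if self.A < 0:
            raise InvalidParameterError(f"A must be >= 0, got {self.A}")
        if self.D < 0:
            raise InvalidParameterError(f"D must be >= 0, got {self.D}")
        if not 0.0 <= self.Omega < 0.5:
            raise InvalidParameterError(f"Omega must be in [0, 0.5), got {self.Omega}")
        if self.seed is not None:
            object.__setattr__(self, "seed", int(self.seed))
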