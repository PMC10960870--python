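"""Random variate generation for classical and interval-valued
Birnbaum-Saunders samples.

Variates come from the exact normal-transform construction
``X = (1/b) * (a*Z/2 + sqrt((a*Z/2)^2 + 1))^2`` with ``Z ~ N(0,1)``.

The (1+I) factor makes the neutrosophic density improper, so sampling is
defined from the *normalized* (classical) law at each interval endpoint;
the indeterminacy enters estimation only through the likelihood constant
``n log(1+I)``, mirroring the likelihood used for fitting.  Interval
samples couple the two endpoints through one shared normal draw per unit
by default ("shared-normal"), which keeps intervals coherent; independent
endpoint draws (then sorted per unit) are available for sensitivity
analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Union

import numpy as np

from .core import NBSParams, NeutroPair

__all__ = ["IntervalSample", "GenConfig", "rbs", "rnbs_interval"]


@dataclass(frozen=True)
class IntervalSample:
    """n interval observations [lower_i, upper_i], 0 < lower <= upper."""

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self):
        lo = np.atleast_1d(np.asarray(self.lower, dtype=float))
        up = np.atleast_1d(np.asarray(self.upper, dtype=float))
        if lo.shape != up.shape or lo.ndim != 1:
            raise ValueError("lower and upper must be 1-D arrays of equal length")
        if np.any(lo <= 0):
            raise ValueError("all observations must be strictly positive")
        if np.any(lo > up):
            raise ValueError("every observation must satisfy lower <= upper")
        object.__setattr__(self, "lower", lo)
        object.__setattr__(self, "upper", up)

    @classmethod
    def from_pairs(cls, pairs) -> "IntervalSample":
        arr = np.asarray([(p.lower, p.upper) if isinstance(p, NeutroPair) else tuple(p) for p in pairs], dtype=float)
        return cls(arr[:, 0], arr[:, 1])

    @classmethod
    def degenerate(cls, values) -> "IntervalSample":
        v = np.asarray(values, dtype=float)
        return cls(v, v.copy())

    @property
    def n(self) -> int:
        return self.lower.size

    @property
    def is_degenerate(self) -> bool:
        return bool(np.all(self.lower == self.upper))

    @property
    def observations(self) -> Iterator[NeutroPair]:
        return (NeutroPair(lo, up) for lo, up in zip(self.lower, self.upper))

    def endpoint_data(self):
        """The two endpoint vectors, in (lower, upper) order."""
        return self.lower, self.upper


@dataclass(frozen=True)
class GenConfig:
    """Configuration of the interval-sample generator."""

    n: int
    params: NBSParams
    seed: Union[int, np.random.Generator, None] = None
    endpoint_coupling: str = "shared-normal"

    def __post_init__(self):
        if self.n < 1:
            raise ValueError(f"sample size must be >= 1, got {self.n}")
        if self.endpoint_coupling not in ("shared-normal", "independent"):
            raise ValueError(
                f"endpoint_coupling must be 'shared-normal' or 'independent', "
                f"got {self.endpoint_coupling!r}"
            )


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _transform(z: np.ndarray, alpha: float, beta: float) -> np.ndarray:
    t = 0.5 * alpha * z
    return (t + np.sqrt(t * t + 1.0)) ** 2 / beta


def rbs(n: int, alpha: float, beta: float, seed=None) -> np.ndarray:
    """n classical Birnbaum-Saunders variates (rate parameterization).

    Deterministic given ``seed`` (an int or a ``numpy.random.Generator``).
    """
    if n < 1:
        raise ValueError(f"sample size must be >= 1, got {n}")
    if alpha <= 0 or beta <= 0:
        raise ValueError("alpha and beta must be strictly positive")
    z = _rng(seed).standard_normal(n)
    return _transform(z, alpha, beta)


def rnbs_interval(config: GenConfig) -> IntervalSample:
    """An interval-valued sample from the endpoint parameter sets.

    shared-normal: one Z per unit mapped through both endpoint parameter
    sets (then sorted per unit, guaranteeing lower <= upper); independent:
    endpoint draws are independent, then sorted per unit.
    """
    rng = _rng(config.seed)
    (al, bl, _), (au, bu, _) = config.params.endpoints()
    if config.endpoint_coupling == "shared-normal":
        z = rng.standard_normal(config.n)
        x_lo = _transform(z, al, bl)
        x_up = _transform(z, au, bu)
    else:
        x_lo = _transform(rng.standard_normal(config.n), al, bl)
        x_up = _transform(rng.standard_normal(config.n), au, bu)
    lower = np.minimum(x_lo, x_up)
    upper = np.maximum(x_lo, x_up)
    return IntervalSample(lower, upper)
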