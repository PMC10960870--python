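"""Neutrosophic Birnbaum-Saunders (NBS) distribution.

The classical Birnbaum-Saunders law describes a positive lifetime ``X``
built from a standard normal ``Z`` through

    (sqrt(b*x) - 1/sqrt(b*x)) / a  ~  N(0, 1),

with shape ``a > 0`` (dimensionless) and *rate* ``b > 0`` (1/time), so the
distribution is centred near ``1/b``.  The neutrosophic extension carries
an indeterminacy interval ``I = (I_L, I_U)`` with ``0 <= I_L <= I_U``:
the density and distribution function are inflated by ``(1 + I)``, so the
total probability mass is ``1 + I`` and the CDF ranges over ``(0, 1 + I)``.
Every neutrosophic quantity is evaluated endpoint-wise at ``(I_L, I_U)``
(and at each endpoint of ``a``/``b`` when those are interval-valued); the
result is reported as an ordered pair.  ``I = (0, 0)`` recovers the
classical distribution exactly.

All evaluation functions accept scalar or array ``x``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Union

import numpy as np
from scipy import optimize, special

__all__ = [
    "NeutroPair",
    "NBSParams",
    "EvaluationGrid",
    "npdf",
    "ncdf",
    "nreliability",
    "nhazard",
    "nmode",
    "nmedian",
    "nquantile",
]

_SQRT2PI = math.sqrt(2.0 * math.pi)


@dataclass(frozen=True)
class NeutroPair:
    """An ordered (lower, upper) pair carrying any neutrosophic quantity.

    The pair collapses to a scalar when ``lower == upper``.  Ordering is a
    *data* invariant for indeterminacy intervals and observations (enforced
    by :class:`NBSParams` / ``IntervalSample``); computed outputs keep the
    association "value at the lower endpoint, value at the upper endpoint",
    which for some quantities (e.g. reliability under ``I > 0``) reverses
    the numerical order.  Use :meth:`ordered` when the invariant applies.
    """

    lower: Union[float, np.ndarray]
    upper: Union[float, np.ndarray]

    @classmethod
    def of(cls, value) -> "NeutroPair":
        """Degenerate pair from a scalar, or pass-through for a pair."""
        if isinstance(value, NeutroPair):
            return value
        if np.ndim(value) == 1 and np.size(value) == 2:
            return cls(float(value[0]), float(value[1]))
        return cls(value, value)

    @classmethod
    def ordered(cls, lower, upper) -> "NeutroPair":
        if np.any(np.asarray(lower) > np.asarray(upper)):
            raise ValueError(
                f"NeutroPair requires lower <= upper, got ({lower}, {upper})"
            )
        return cls(lower, upper)

    @property
    def is_degenerate(self) -> bool:
        return bool(np.all(np.asarray(self.lower) == np.asarray(self.upper)))

    def map(self, fn) -> "NeutroPair":
        return NeutroPair(fn(self.lower), fn(self.upper))

    def __iter__(self):
        yield self.lower
        yield self.upper

    def __float__(self) -> float:
        if not self.is_degenerate:
            raise ValueError("cannot collapse a non-degenerate NeutroPair to a scalar")
        return float(self.lower)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"NeutroPair({self.lower!r}, {self.upper!r})"


def _positive_endpoints(name: str, value) -> NeutroPair:
    pair = NeutroPair.of(value)
    for v in pair:
        if not np.all(np.asarray(v) > 0):
            raise ValueError(f"{name} must be strictly positive, got {v}")
    return pair


@dataclass(frozen=True)
class NBSParams:
    """Parameters of the NBS distribution.

    ``alpha``/``beta`` may each be a scalar or a ``NeutroPair`` (evaluated
    per endpoint); ``indeterminacy`` is the pair ``(I_L, I_U)`` with
    ``0 <= I_L <= I_U``.
    """

    alpha: Union[float, NeutroPair]
    beta: Union[float, NeutroPair]
    indeterminacy: Union[float, NeutroPair] = field(default=0.0)

    def __post_init__(self):
        object.__setattr__(self, "alpha", _positive_endpoints("alpha", self.alpha))
        object.__setattr__(self, "beta", _positive_endpoints("beta", self.beta))
        ind = NeutroPair.of(self.indeterminacy)
        if ind.lower < 0:
            raise ValueError(f"indeterminacy must be >= 0, got {ind.lower}")
        ind = NeutroPair.ordered(ind.lower, ind.upper)
        object.__setattr__(self, "indeterminacy", ind)

    def endpoints(self):
        """The (alpha, beta, I) triple at the lower and upper endpoints."""
        a, b, i = self.alpha, self.beta, self.indeterminacy
        return (
            (float(a.lower), float(b.lower), float(i.lower)),
            (float(a.upper), float(b.upper), float(i.upper)),
        )

    @property
    def is_classical(self) -> bool:
        return self.indeterminacy.is_degenerate and float(self.indeterminacy.lower) == 0.0

    def _degenerate_triple(self):
        lo, up = self.endpoints()
        return lo if lo == up else None


@dataclass(frozen=True)
class EvaluationGrid:
    """A vector of positive evaluation points (time units)."""

    points: np.ndarray

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 1 or pts.size == 0:
            raise ValueError("EvaluationGrid requires a non-empty 1-D array")
        if np.any(pts <= 0):
            raise ValueError("all evaluation points must be positive")
        object.__setattr__(self, "points", pts)


def _as_positive_x(x):
    if isinstance(x, EvaluationGrid):
        return x.points
    arr = np.asarray(x, dtype=float)
    if np.any(arr <= 0):
        raise ValueError(f"x must be strictly positive, got {x}")
    return arr


def _erf_arg(x, a, b):
    """(b*x - 1) / (sqrt(2) * a * sqrt(b*x)) -- the Erf argument of the CDF."""
    bx = b * x
    return (bx - 1.0) / (math.sqrt(2.0) * a * np.sqrt(bx))


def _classical_logpdf(x, a, b):
    # log of (1+bx) * exp(-(bx-1)^2 / (2 a^2 bx)) / (2 a sqrt(2 pi b) x^{3/2});
    # the exponent is expanded to (bx - 2 + 1/(bx)) to stay finite in both tails
    bx = b * x
    return (
        -(bx - 2.0 + 1.0 / bx) / (2.0 * a * a)
        + np.log1p(bx)
        - math.log(2.0 * a)
        - 0.5 * math.log(2.0 * math.pi * b)
        - 1.5 * np.log(x)
    )


def _endpointwise(params: NBSParams, fn) -> NeutroPair:
    lo, up = params.endpoints()
    return NeutroPair(fn(*lo), fn(*up))


def npdf(x, params: NBSParams) -> NeutroPair:
    """Neutrosophic density (units 1/time); total mass is ``1 + I``."""
    xv = _as_positive_x(x)
    return _endpointwise(
        params, lambda a, b, i: (1.0 + i) * np.exp(_classical_logpdf(xv, a, b))
    )


def ncdf(x, params: NBSParams) -> NeutroPair:
    """Neutrosophic CDF; nondecreasing in ``x`` with limit ``1 + I``."""
    xv = _as_positive_x(x)
    return _endpointwise(
        params,
        lambda a, b, i: 0.5 * (1.0 + special.erf(_erf_arg(xv, a, b))) * (1.0 + i),
    )


def nreliability(x, params: NBSParams) -> NeutroPair:
    """``1 - ncdf(x)``, returned exactly as computed.

    For ``I > 0`` this becomes negative at large ``x`` (the CDF tends to
    ``1 + I``); the value is reported as defined, without clipping.
    """
    xv = _as_positive_x(x)
    return _endpointwise(
        params,
        lambda a, b, i: 1.0
        - 0.5 * (1.0 + special.erf(_erf_arg(xv, a, b))) * (1.0 + i),
    )


def nhazard(x, params: NBSParams) -> NeutroPair:
    """Neutrosophic hazard (units 1/time).

    Evaluated through the scaled complementary error function so that the
    0/0 ratio at large ``x`` never overflows: with ``w`` the Erf argument,
    ``h = (1+I) * (1+bx) / (a*sqrt(2*pi*b)*x^{3/2} * erfcx(w))``.
    At ``I = 0`` this equals ``npdf / (1 - ncdf)`` identically.
    """
    xv = _as_positive_x(x)

    def one(a, b, i):
        w = _erf_arg(xv, a, b)
        pref = (1.0 + b * xv) / (a * math.sqrt(2.0 * math.pi * b) * xv**1.5)
        return (1.0 + i) * pref / special.erfcx(w)

    return _endpointwise(params, one)


def _mode_root(a: float, b: float) -> float:
    # unique positive root of -1 + (3a^2-1)b x + (1+a^2)b^2 x^2 + b^3 x^3
    c1 = (3.0 * a * a - 1.0) * b
    c2 = (1.0 + a * a) * b * b
    c3 = b**3

    def poly(x):
        return -1.0 + x * (c1 + x * (c2 + x * c3))

    hi = 1.0 / b
    while poly(hi) <= 0.0:
        hi *= 2.0
    return float(optimize.brentq(poly, 0.0, hi, xtol=1e-14, rtol=8.9e-16))


def nmode(params: NBSParams):
    """Mode of the density: the unique positive root of the stationarity
    cubic ``-1 + (3a^2-1)b x + (1+a^2)b^2 x^2 + b^3 x^3 = 0``.

    The ``(1+I)`` factor rescales the density without moving its argmax,
    so the mode is independent of the indeterminacy.  Returns a float when
    ``alpha`` and ``beta`` are scalars, otherwise a per-endpoint pair.
    """
    (al, bl, _), (au, bu, _) = params.endpoints()
    lo = _mode_root(al, bl)
    if (al, bl) == (au, bu):
        return lo
    return NeutroPair(lo, _mode_root(au, bu))


def _median_roots(a: float, b: float, i: float):
    # 0.5*(1+Erf(z))*(1+I) = 0.5  =>  z = InverseErf(-I/(1+I)) <= 0
    z = special.erfinv(-i / (1.0 + i))
    k2 = z * z
    big = 1.0 + k2 * a * a
    disc = math.sqrt(big * big - 1.0)
    return (big - disc) / b, (big + disc) / b


def nmedian(params: NBSParams, strict: bool = False) -> NeutroPair:
    """Median of the NBS distribution.

    The defining equation ``F(m) = 0.5`` reduces to a quadratic in ``m``
    with roots ``m± = [(1 + k²a²) ± sqrt((1 + k²a²)² - 1)] / b`` where
    ``k² = InverseErf(-I/(1+I))²``.  By default *both* roots are returned
    as the ordered pair ``(m-, m+)`` (at ``I = 0`` they coincide at
    ``1/b``); only the smaller root actually satisfies ``F = 0.5`` when
    ``I > 0``.  With ``strict=True`` the ``F = 0.5`` root is returned,
    per endpoint when the parameters are interval-valued.
    """
    lo, up = params.endpoints()
    if strict:
        return NeutroPair(_median_roots(*lo)[0], _median_roots(*up)[0])
    if lo != up:
        raise ValueError(
            "the two-root median form is defined for endpoint-degenerate "
            "parameters; use strict=True for per-endpoint F=0.5 roots"
        )
    m_lo, m_hi = _median_roots(*lo)
    return NeutroPair(m_lo, m_hi)


def _quantile_one(p: float, a: float, b: float, i: float) -> float:
    if not 0.0 < p < 1.0 + i:
        raise ValueError(
            f"p={p} outside the attainable CDF range (0, {1.0 + i}) under "
            f"indeterminacy I={i}"
        )
    z = special.erfinv((2.0 * p - 1.0 - i) / (1.0 + i))
    if z == 0.0:
        return 1.0 / b
    big = 1.0 + z * z * a * a
    disc = math.sqrt(big * big - 1.0)
    return (big - disc) / b if z < 0.0 else (big + disc) / b


def nquantile(p, params: NBSParams):
    """Inverse of :func:`ncdf`: the ``x`` with ``F(x) = p``.

    The quadratic-root form erases the sign of ``InverseErf``; it is
    restored here so that exactly one root is returned -- the smaller for
    ``p`` below the half-mass point ``(1+I)/2``, the larger above it, and
    ``1/b`` at it.  ``p`` must lie in ``(0, 1 + I)`` per endpoint.
    """
    lo, up = params.endpoints()
    pv = np.asarray(p, dtype=float)
    if pv.ndim == 0:
        low = _quantile_one(float(pv), *lo)
        if lo == up:
            return low
        return NeutroPair(low, _quantile_one(float(pv), *up))
    low = np.array([_quantile_one(float(q), *lo) for q in pv])
    if lo == up:
        return low
    high = np.array([_quantile_one(float(q), *up) for q in pv])
    return NeutroPair(low, high)
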