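"""Optinalytic constructions and the Kabirian coefficient.

Optinalysis scores how well an ordered numeric structure mirrors itself
(automorphic use: symmetry) or how well two equal-length structures mirror
each other about an external centre (isomorphic use: similarity).  The two
structures are concatenated into a single odd-length *layout* around a
central value ``delta``, an arithmetic *optiscale* of ranks ``r_i = ±i*k``
is laid over it, and the Kabirian coefficient is

    Kc = r_median * sum(layout) / sum(r_i * layout_i)

Kc equals 1 exactly when the layout is palindromic (perfect symmetry or
element-wise identity).  The choice of the scale interval ``k`` and its
sign cancels in the quotient, so Kc depends only on the layout.

Arithmetic in this module deliberately stays in plain Python numbers: for
integer-valued inputs with an integer scale interval, the numerator and
denominator of Kc are exact integers and are exposed as such.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, replace
from typing import Sequence

__all__ = [
    "OptinalysisError",
    "InvalidParameterError",
    "PairingLengthError",
    "AutomorphicParityError",
    "DegenerateStructureError",
    "Sign",
    "PairingStyle",
    "Regime",
    "Optiscale",
    "OpticalDistanceScale",
    "OptinalyticConstruction",
    "build_optiscale",
    "construct_isoreflective",
    "construct_autoreflective",
    "numeration",
    "sum_of_scalements",
    "kc_of_construction",
    "kc_isomorphic",
    "kc_automorphic",
    "isomorphic_sums",
    "optical_moment",
    "classify_regime",
    "pericentral_rotation",
    "central_rotation",
]


class OptinalysisError(ValueError):
    """Base class for optinalysis domain errors."""


class InvalidParameterError(OptinalysisError):
    """A scale or construction parameter is out of its legal range."""


class PairingLengthError(OptinalysisError):
    """The two structures of an isoreflective pair differ in length."""


class AutomorphicParityError(OptinalysisError):
    """Automorphic input must have odd length (pad or re-specify upstream)."""


class DegenerateStructureError(OptinalysisError):
    """The rank-weighted sum vanishes, so the coefficient is undefined."""


class Sign(str, enum.Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"


class PairingStyle(str, enum.Enum):
    """Which ends of the two structures sit farthest from the centre.

    Head-to-head places the first elements maximally distant from the
    central connection point; tail-to-tail places them adjacent to it.
    """

    HEAD_TO_HEAD = "head_to_head"
    TAIL_TO_TAIL = "tail_to_tail"


class Regime(str, enum.Enum):
    """The printed range the coefficient falls in, decided by optical moments."""

    EQUAL = "equal"                        # g(A) = g(B)   -> Kc = 1
    NEGATED = "negated"                    # g(A) = -g(B)  -> Kc = 0
    LESS = "less"                          # g(A) < g(B)   -> 0 <= Kc <= 1
    GREATER_BOUNDED = "greater_bounded"    # g(A) > g(B)   -> 1 <= Kc <= n+1
    GREATER_UNBOUNDED = "greater_unbounded"  # g(A) > g(B) -> Kc >= n+1 or Kc < 0


def _validate_structure(values: Sequence[float], name: str = "structure") -> tuple:
    vals = tuple(values)
    if len(vals) < 1:
        raise InvalidParameterError(f"{name} must contain at least one element")
    for i, v in enumerate(vals):
        if isinstance(v, bool) or not isinstance(v, (int, float)):
            raise InvalidParameterError(
                f"{name}[{i}] = {v!r} is not a real number"
            )
        if not math.isfinite(v):
            raise InvalidParameterError(f"{name}[{i}] = {v!r} is not finite")
    return vals


@dataclass(frozen=True)
class Optiscale:
    """Uniform arithmetic rank scale r_i = ±i*k of odd length 2n+1."""

    interval: float
    sign: Sign
    length: int

    def __post_init__(self) -> None:
        if self.interval <= 0:
            raise InvalidParameterError(f"interval must be > 0, got {self.interval}")
        if self.length < 3 or self.length % 2 == 0:
            raise InvalidParameterError(
                f"optiscale length must be odd and >= 3, got {self.length}"
            )

    @property
    def n_dimensions(self) -> int:
        return (self.length - 1) // 2

    @property
    def ranks(self) -> tuple:
        s = 1 if self.sign is Sign.POSITIVE else -1
        return tuple(s * i * self.interval for i in range(1, self.length + 1))

    @property
    def median_rank(self):
        s = 1 if self.sign is Sign.POSITIVE else -1
        return s * ((self.length + 1) // 2) * self.interval


def build_optiscale(
    n_dimensions: int, interval: float = 1.0, sign: Sign | str = Sign.POSITIVE
) -> Optiscale:
    """Build the rank scale covering a construction with ``n_dimensions`` per side."""
    if not isinstance(n_dimensions, int) or n_dimensions < 1:
        raise InvalidParameterError(
            f"n_dimensions must be a positive integer, got {n_dimensions!r}"
        )
    return Optiscale(interval=interval, sign=Sign(sign), length=2 * n_dimensions + 1)


@dataclass(frozen=True)
class OpticalDistanceScale:
    """Strictly increasing distances d_j = j*k used for optical moments."""

    distances: tuple

    @classmethod
    def uniform(cls, n: int, interval: float = 1.0) -> "OpticalDistanceScale":
        if n < 1 or interval <= 0:
            raise InvalidParameterError("need n >= 1 and interval > 0")
        return cls(tuple(j * interval for j in range(1, n + 1)))


@dataclass(frozen=True)
class OptinalyticConstruction:
    """A concatenated mirror layout zipped with its optiscale.

    ``layout`` has odd length 2n+1 with ``delta`` at the centre.  For
    isomorphic constructions delta is external to both structures; for
    automorphic constructions it is the middle element of the input.
    """

    layout: tuple
    delta: float
    optiscale: Optiscale
    kind: str  # "isomorphic" | "automorphic"
    pairing: PairingStyle | None = None

    def __post_init__(self) -> None:
        if len(self.layout) != self.optiscale.length:
            raise InvalidParameterError(
                f"layout length {len(self.layout)} != optiscale length "
                f"{self.optiscale.length}"
            )
        if self.layout[self.n_dimensions] != self.delta:
            raise InvalidParameterError("central layout element must equal delta")

    @property
    def n_dimensions(self) -> int:
        return self.optiscale.n_dimensions

    @property
    def center_index(self) -> int:
        return self.n_dimensions  # 0-based; (L+1)/2 in 1-based terms

    @property
    def left(self) -> tuple:
        """The left structure in its original (outward-first) order."""
        return self.layout[: self.n_dimensions]

    @property
    def right(self) -> tuple:
        """The right structure read back into its original order."""
        return tuple(reversed(self.layout[self.n_dimensions + 1 :]))


def construct_isoreflective(
    x: Sequence[float],
    y: Sequence[float],
    pairing: PairingStyle | str = PairingStyle.HEAD_TO_HEAD,
    delta: float = 0,
    interval: float = 1.0,
    sign: Sign | str = Sign.POSITIVE,
) -> OptinalyticConstruction:
    """Concatenate two equal-length structures into a mirror layout about delta.

    Head-to-head: ``(x1..xn, delta, yn..y1)``; tail-to-tail:
    ``(xn..x1, delta, y1..yn)``.
    """
    xs = _validate_structure(x, "x")
    ys = _validate_structure(y, "y")
    if len(xs) != len(ys):
        raise PairingLengthError(
            f"isoreflective pairing needs equal lengths, got {len(xs)} and {len(ys)}"
        )
    pairing = PairingStyle(pairing)
    if pairing is PairingStyle.HEAD_TO_HEAD:
        layout = xs + (delta,) + tuple(reversed(ys))
    else:
        layout = tuple(reversed(xs)) + (delta,) + ys
    scale = build_optiscale(len(xs), interval=interval, sign=sign)
    return OptinalyticConstruction(
        layout=layout, delta=delta, optiscale=scale, kind="isomorphic", pairing=pairing
    )


def construct_autoreflective(
    a: Sequence[float],
    interval: float = 1.0,
    sign: Sign | str = Sign.POSITIVE,
) -> OptinalyticConstruction:
    """Read an odd-length structure as its own mirror pair about its middle element."""
    vals = _validate_structure(a, "a")
    if len(vals) % 2 == 0:
        raise AutomorphicParityError(
            f"automorphic optinalysis needs odd length, got {len(vals)}; "
            "pad or re-specify the structure upstream"
        )
    if len(vals) < 3:
        raise InvalidParameterError("automorphic structure must have length >= 3")
    n = (len(vals) - 1) // 2
    scale = build_optiscale(n, interval=interval, sign=sign)
    return OptinalyticConstruction(
        layout=vals, delta=vals[n], optiscale=scale, kind="automorphic"
    )


def numeration(c: OptinalyticConstruction):
    """Median optiscale rank times the sum of all layout elements."""
    return c.optiscale.median_rank * sum(c.layout)


def sum_of_scalements(c: OptinalyticConstruction):
    """Rank-weighted sum over the layout (the coefficient's denominator)."""
    return sum(r * v for r, v in zip(c.optiscale.ranks, c.layout))


def kc_of_construction(c: OptinalyticConstruction) -> float:
    den = sum_of_scalements(c)
    if den == 0:
        raise DegenerateStructureError(
            "sum of scalements is zero; Kabirian coefficient undefined"
        )
    return numeration(c) / den


def kc_isomorphic(
    x: Sequence[float],
    y: Sequence[float],
    pairing: PairingStyle | str = PairingStyle.HEAD_TO_HEAD,
    delta: float = 0,
    interval: float = 1.0,
    sign: Sign | str = Sign.POSITIVE,
) -> float:
    """Kabirian coefficient of similarity between two equal-length structures."""
    return kc_of_construction(
        construct_isoreflective(x, y, pairing, delta, interval, sign)
    )


def kc_automorphic(
    a: Sequence[float],
    interval: float = 1.0,
    sign: Sign | str = Sign.POSITIVE,
) -> float:
    """Kabirian coefficient of symmetry of a single odd-length structure."""
    return kc_of_construction(construct_autoreflective(a, interval, sign))


def isomorphic_sums(
    x: Sequence[float],
    y: Sequence[float],
    pairing: PairingStyle | str = PairingStyle.HEAD_TO_HEAD,
    delta: float = 0,
    interval: float = 1.0,
    sign: Sign | str = Sign.POSITIVE,
) -> tuple:
    """Exact (numeration, denomination) of the isomorphic coefficient.

    With integer inputs and an integer interval both sums stay exact
    integers, so worked examples can be asserted without rounding.
    """
    c = construct_isoreflective(x, y, pairing, delta, interval, sign)
    return numeration(c), sum_of_scalements(c)


def optical_moment(half: Sequence[float], distances: OpticalDistanceScale):
    """Distance-weighted sum of one half: the first element gets the largest distance."""
    vals = _validate_structure(half, "half")
    d = distances.distances
    if len(vals) != len(d):
        raise InvalidParameterError(
            f"half has {len(vals)} elements but distance scale has {len(d)}"
        )
    n = len(vals)
    return sum(d[n - 1 - j] * vals[j] for j in range(n))


def classify_regime(c: OptinalyticConstruction) -> Regime:
    """Decide which printed Kc range applies by comparing the halves' optical moments.

    The distance scale uses the same uniform spacing as the optiscale.  The
    two open-ended moment orderings are split on the value of Kc itself:
    coefficients inside [1, n+1] are the bounded regime, anything at or
    beyond n+1 or below 0 the unbounded one.
    """
    n = c.n_dimensions
    d = OpticalDistanceScale.uniform(n, c.optiscale.interval)
    g_a = optical_moment(c.left, d)
    g_b = optical_moment(c.right, d)
    if g_a == g_b:
        return Regime.EQUAL
    if g_a == -g_b:
        return Regime.NEGATED
    if g_a < g_b:
        return Regime.LESS
    kc = kc_of_construction(c)
    if 1 <= kc <= n + 1:
        return Regime.GREATER_BOUNDED
    return Regime.GREATER_UNBOUNDED


def pericentral_rotation(c: OptinalyticConstruction) -> OptinalyticConstruction:
    """Reverse each half in place (alternate reflection).

    Converts a head-to-head layout of a pair into the tail-to-tail layout of
    the same pair and vice versa.  An involution.
    """
    n = c.n_dimensions
    layout = (
        tuple(reversed(c.layout[:n])) + (c.layout[n],) + tuple(reversed(c.layout[n + 1 :]))
    )
    pairing = None
    if c.pairing is not None:
        pairing = (
            PairingStyle.TAIL_TO_TAIL
            if c.pairing is PairingStyle.HEAD_TO_HEAD
            else PairingStyle.HEAD_TO_HEAD
        )
    return replace(c, layout=layout, pairing=pairing)


def central_rotation(c: OptinalyticConstruction) -> OptinalyticConstruction:
    """Reverse the whole layout (inversion): the two structures exchange roles."""
    return replace(c, layout=tuple(reversed(c.layout)))
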