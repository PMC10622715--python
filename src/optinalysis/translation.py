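"""Coefficient-to-probability translation models.

A Kabirian coefficient is not itself a probability: its two branches
(below 1 and at-or-above 1) live on different scales.  The translation
models map a coefficient to a probability of symmetry/similarity/identity
``p`` in [-1, 1], map ``p`` to its complement, and map ``p`` back to the
two possible *bi-coefficients* — the coefficient obtained with the
structures in either role.  Exchanging the roles of the two structures
changes the coefficient but not the translated probability (the Y-rule),
which is what makes coefficients from different role orders comparable.

``r1``, the first optiscale rank, appears in the printed models and is
exposed, although it cancels algebraically.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

__all__ = [
    "TranslationSingularityError",
    "TranslationRangeWarning",
    "KabirianResult",
    "kc_to_p",
    "p_complement",
    "p_to_kc_alt1",
    "p_to_kc_alt2",
    "kc_alternate",
    "translate",
]


class TranslationSingularityError(ValueError):
    """A translation branch denominator vanished."""


class TranslationRangeWarning(UserWarning):
    """The translated probability fell outside [-1, 1]."""


def kc_to_p(kc: float, n: int, r1: float = 1.0) -> float:
    """Translate a Kabirian coefficient to the probability of similarity.

    Coefficients in [0, 1) use the lower-scale branch
    ``((n+1)r1 - kc(2n+1)r1) / (r1*kc - (n+1)r1)``; all others (including
    exactly 1, where both branches agree) use the upper-scale branch
    ``((n+1)r1 - r1*kc) / (kc(2n+1)r1 - (n+1)r1)``.

    ``n`` is the per-side dimension of the construction the coefficient
    came from.  Results outside [-1, 1] (possible for coefficients outside
    every printed validity range) are returned with a warning attached.
    """
    _check_nr1(n, r1)
    if not math.isfinite(kc):
        raise TranslationSingularityError(f"kc must be finite, got {kc!r}")
    if 0 <= kc < 1:
        den = r1 * kc - (n + 1) * r1
        if den == 0:
            raise TranslationSingularityError("lower-branch denominator is zero")
        p = ((n + 1) * r1 - kc * (2 * n + 1) * r1) / den
    else:
        den = kc * (2 * n + 1) * r1 - (n + 1) * r1
        if den == 0:
            raise TranslationSingularityError(
                f"upper-branch denominator is zero at kc = {kc}"
            )
        p = ((n + 1) * r1 - r1 * kc) / den
    if not -1 <= p <= 1:
        warnings.warn(
            f"translated probability {p} outside [-1, 1]; kc={kc} lies outside "
            "every validity range of the translation model",
            TranslationRangeWarning,
            stacklevel=2,
        )
    return p


def p_complement(p: float) -> float:
    """Probability of asymmetry/dissimilarity: 1-p for p >= 0, else -1-p."""
    if not -1 <= p <= 1:
        raise ValueError(f"probability must lie in [-1, 1], got {p}")
    return 1 - p if p >= 0 else -1 - p


def _check_nr1(n: int, r1: float) -> None:
    if not isinstance(n, int) or n < 1:
        raise ValueError(f"n must be a positive integer, got {n!r}")
    if r1 <= 0:
        raise ValueError(f"r1 must be > 0, got {r1}")


def p_to_kc_alt1(p: float, n: int, r1: float = 1.0) -> float:
    """Backward translation onto the lower coefficient scale ([0, 1] for p in [0, 1])."""
    _check_nr1(n, r1)
    if not -1 <= p <= 1:
        raise ValueError(f"probability must lie in [-1, 1], got {p}")
    return (n + 1) * r1 * (p + 1) / (r1 * p + (2 * n + 1) * r1)


def p_to_kc_alt2(p: float, n: int, r1: float = 1.0) -> float:
    """Backward translation onto the upper coefficient scale ([1, n+1] for p in [0, 1])."""
    _check_nr1(n, r1)
    if not -1 <= p <= 1:
        raise ValueError(f"probability must lie in [-1, 1], got {p}")
    den = r1 + p * (2 * n + 1) * r1
    if den == 0:
        raise TranslationSingularityError(
            f"upper backward translation is singular at p = {p}"
        )
    return (n + 1) * r1 * (1 + p) / den


def kc_alternate(kc: float, n: int, r1: float = 1.0) -> float:
    """The bi-coefficient on the other scale: the coefficient the same pair
    would give with the two structures' roles exchanged.

    Applying it twice returns the original coefficient.
    """
    p = kc_to_p(kc, n, r1)
    if 0 <= kc < 1:
        return p_to_kc_alt2(p, n, r1)
    return p_to_kc_alt1(p, n, r1)


@dataclass(frozen=True)
class KabirianResult:
    """A coefficient with its full set of translated estimates.

    ``p_sim``/``p_dsim`` are fractions in [-1, 1]; percentage presentation
    is left to reporting.  ``kc_alt`` is whichever of the two backward
    translations lies on the scale opposite ``kc``.
    """

    kc: float
    n_dimensions: int
    r1: float
    p_sim: float
    p_dsim: float
    kc_alt1: float
    kc_alt2: float
    kc_alt: float

    @property
    def pgsim(self) -> float:
        """Percentage similarity (p_sim * 100)."""
        return 100.0 * self.p_sim

    @property
    def pgdsim(self) -> float:
        """Percentage dissimilarity (p_dsim * 100)."""
        return 100.0 * self.p_dsim


def translate(kc: float, n: int, r1: float = 1.0) -> KabirianResult:
    """Run the full translation chain for one coefficient."""
    p = kc_to_p(kc, n, r1)
    alt1 = p_to_kc_alt1(p, n, r1)
    alt2 = p_to_kc_alt2(p, n, r1)
    alt = alt2 if 0 <= kc < 1 else alt1
    return KabirianResult(
        kc=kc,
        n_dimensions=n,
        r1=r1,
        p_sim=p,
        p_dsim=p_complement(p),
        kc_alt1=alt1,
        kc_alt2=alt2,
        kc_alt=alt,
    )
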