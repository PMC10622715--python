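"""Geometrical pairwise analysis of aligned biological sequences.

Pre-aligned, equal-length DNA/RNA/protein sequences (gaps as ``-``) are
encoded residue-by-residue as molecular masses in g/mol, paired head-to-head
into an isoreflective construction, and scored with the Kabirian
coefficient, which the translation models turn into a percentage
geometrical similarity (PGsim) and dissimilarity (PGdsim).  Because every
aligned position keeps its own rank on the optiscale, the score is
sensitive to *where* a mismatch or deletion sits, unlike the conventional
match-count percentage, which is also provided as a baseline.

Alignment itself is upstream (Needle, Stretcher, MAFFT, ...); this module
consumes its output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

from .core import PairingStyle, kc_isomorphic
from .translation import KabirianResult, translate

__all__ = [
    "EncodingError",
    "AlignmentRequiredError",
    "EncodingScheme",
    "DNA_SCHEME",
    "RNA_SCHEME",
    "PROTEIN_SCHEME",
    "get_scheme",
    "GAP_CHARS",
    "encode_sequence",
    "conventional_percent_similarity",
    "pairwise_analysis",
    "result_record",
]

logger = logging.getLogger(__name__)

#: accepted gap symbols; '.' and '*' are normalized to the canonical '-'
GAP_CHARS = frozenset("-.*")


class EncodingError(ValueError):
    """A residue outside the scheme's alphabet was met in strict mode."""


class AlignmentRequiredError(ValueError):
    """Unequal sequence lengths: align upstream (Needle/Stretcher/MAFFT...)."""


@dataclass(frozen=True)
class EncodingScheme:
    """Character -> molecular mass (g/mol) map with a gap rule.

    Lookups are case-insensitive; gap symbols map to ``gap_value``.
    Ambiguity codes (N, X, B, Z, ...) are *not* in the alphabet: zeroing
    them would conflate an unknown residue with a deletion, so strict mode
    rejects them and lenient mode zeroes them with a logged warning.
    """

    name: str
    mass_map: Mapping[str, float]
    gap_value: float = 0.0

    def mass(self, char: str, position: int, strict: bool = True) -> float:
        if char in GAP_CHARS:
            return self.gap_value
        try:
            return self.mass_map[char.upper()]
        except KeyError:
            if strict:
                raise EncodingError(
                    f"character {char!r} at position {position + 1} is not in "
                    f"the {self.name} alphabet"
                ) from None
            logger.warning(
                "character %r at position %d unknown to %s scheme; encoding as %s",
                char, position + 1, self.name, self.gap_value,
            )
            return self.gap_value


# Monomer molecular masses (g/mol) used for the geometric encoding.
DNA_SCHEME = EncodingScheme("DNA", {"C": 111, "T": 126, "A": 135, "G": 151})
RNA_SCHEME = EncodingScheme("RNA", {"C": 111, "U": 112, "A": 135, "G": 151})
PROTEIN_SCHEME = EncodingScheme(
    "protein",
    {
        "G": 75, "A": 89, "S": 105, "P": 115, "V": 117, "T": 119, "C": 121,
        "I": 131, "L": 131, "N": 132, "D": 133, "Q": 146, "K": 146, "E": 147,
        "M": 149, "H": 155, "F": 165, "R": 174, "Y": 181, "W": 204,
    },
)

_SCHEMES = {"dna": DNA_SCHEME, "rna": RNA_SCHEME, "protein": PROTEIN_SCHEME}


def get_scheme(name: "str | EncodingScheme") -> EncodingScheme:
    if isinstance(name, EncodingScheme):
        return name
    try:
        return _SCHEMES[name.lower()]
    except KeyError:
        raise ValueError(
            f"unknown encoding scheme {name!r}; choose from DNA, RNA, protein"
        ) from None


def encode_sequence(
    seq: str, scheme: "str | EncodingScheme" = DNA_SCHEME, strict: bool = True
) -> list:
    """Encode a gapped sequence as its per-residue molecular-mass list."""
    if not seq:
        raise ValueError("cannot encode an empty sequence")
    sch = get_scheme(scheme)
    return [sch.mass(c, i, strict=strict) for i, c in enumerate(seq)]


def _normalize_gaps(seq: str) -> str:
    return "".join("-" if c in GAP_CHARS else c.upper() for c in seq)


def conventional_percent_similarity(seq_x: str, seq_y: str) -> float:
    """Match-count percentage: identical columns over aligned length.

    For unequal lengths the longer length is the denominator.  A gap-gap
    column counts as a match; gap-versus-residue is a mismatch.
    """
    if not seq_x or not seq_y:
        raise ValueError("both sequences must be non-empty")
    x, y = _normalize_gaps(seq_x), _normalize_gaps(seq_y)
    matches = sum(a == b for a, b in zip(x, y))
    return 100.0 * matches / max(len(x), len(y))


@dataclass(frozen=True)
class AlignedPair:
    """Two pre-aligned equal-length gapped sequences under one scheme."""

    seq_x: str
    seq_y: str
    scheme: EncodingScheme = DNA_SCHEME

    def __post_init__(self) -> None:
        if len(self.seq_x) != len(self.seq_y):
            raise AlignmentRequiredError(
                f"sequences have lengths {len(self.seq_x)} and {len(self.seq_y)}; "
                "align them upstream (e.g. Needle, Stretcher, MAFFT)"
            )


def pairwise_analysis(
    seq_x: str,
    seq_y: str,
    scheme: "str | EncodingScheme" = DNA_SCHEME,
    pairing: "PairingStyle | str" = PairingStyle.HEAD_TO_HEAD,
    delta: float = 0,
    interval: float = 1.0,
    strict: bool = True,
) -> KabirianResult:
    """Full geometric pipeline for one aligned pair.

    Encodes both sequences, pairs them (head-to-head by default, matching
    the 5'->3' reading convention), computes the Kabirian coefficient of
    similarity with the aligned length as the per-side dimension, and
    returns it with all translated estimates (``.pgsim``/``.pgdsim`` give
    the percentage forms).
    """
    if not seq_x or not seq_y:
        raise ValueError("both sequences must be non-empty")
    if len(seq_x) != len(seq_y):
        raise AlignmentRequiredError(
            f"sequences have lengths {len(seq_x)} and {len(seq_y)}; "
            "align them upstream (e.g. Needle, Stretcher, MAFFT)"
        )
    sch = get_scheme(scheme)
    x = encode_sequence(seq_x, sch, strict=strict)
    y = encode_sequence(seq_y, sch, strict=strict)
    kc = kc_isomorphic(x, y, pairing=pairing, delta=delta, interval=interval)
    return translate(kc, n=len(x), r1=interval)


def result_record(
    result: KabirianResult,
    seq_x_id: str = "x",
    seq_y_id: str = "y",
    scheme: str = "DNA",
    pairing: str = PairingStyle.HEAD_TO_HEAD.value,
    cm_percent_similarity: "float | None" = None,
) -> dict:
    """Flatten a result into one serializable record (JSON object / TSV row)."""
    rec = {
        "seq_x_id": seq_x_id,
        "seq_y_id": seq_y_id,
        "scheme": scheme,
        "pairing": pairing,
        "kc": result.kc,
        "pgsim": result.pgsim,
        "pgdsim": result.pgdsim,
        "kc_alt1": result.kc_alt1,
        "kc_alt2": result.kc_alt2,
        "kc_alt": result.kc_alt,
    }
    if cm_percent_similarity is not None:
        rec["cm_percent_similarity"] = cm_percent_similarity
    return rec
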