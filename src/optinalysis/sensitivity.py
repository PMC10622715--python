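"""Entropy-based sensitivity evaluation of similarity estimators.

A similarity method is *sensitive* to a class of sequence variation when
distinct variants get distinct scores.  Given a reference sequence and a
panel of variants sharing one variation pattern (a substitution swept along
the positions, a deletion sweep, terminal-deletion series, ...), each
method scores every (variant, reference) pair, and the Shannon entropy of
the resulting score column measures how much the method discriminates:
log2(n) bits (100 % relative entropy) when all n scores differ, 0 when the
method is blind to the variation.

The panel generator reconstructs the benchmark panels used to validate the
geometric method and can build randomized analogues of each pattern.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import PairingStyle
from .seqgeom import (
    conventional_percent_similarity,
    get_scheme,
    pairwise_analysis,
)

__all__ = [
    "PanelParameterError",
    "VariantPanel",
    "SensitivityReport",
    "PanelEvaluation",
    "shannon_entropy",
    "relative_entropy_percent",
    "generate_panel",
    "preset_panel",
    "PANEL_PRESETS",
    "evaluate_panel",
    "panel_from_fasta",
    "report_to_tsv",
]


class PanelParameterError(ValueError):
    """Panel generation parameters are inconsistent with the panel kind."""


PANEL_KINDS = (
    "position_substitution",
    "character_substitution",
    "position_deletion",
    "terminal_deletion",
    "composition",
)


@dataclass(frozen=True)
class VariantPanel:
    """A reference sequence with an ordered set of aligned variants."""

    reference: str
    variants: tuple  # of (id, sequence) pairs
    panel_kind: str
    scheme_name: str = "DNA"

    def __post_init__(self) -> None:
        ids = [i for i, _ in self.variants]
        if len(set(ids)) != len(ids):
            raise PanelParameterError("variant ids must be unique")
        for vid, seq in self.variants:
            if len(seq) != len(self.reference):
                raise PanelParameterError(
                    f"variant {vid} has length {len(seq)}, reference has "
                    f"{len(self.reference)}; panels must be pre-aligned"
                )


@dataclass(frozen=True)
class SensitivityReport:
    """Entropy summary of one method's score column over a panel."""

    method_name: str
    values: tuple
    entropy_bits: float
    relative_entropy_percent: float
    rounding_decimals: int


def shannon_entropy(values: Sequence[float], rounding_decimals: int = 2) -> float:
    """Entropy (bits) of the empirical distribution of rounded values.

    Scores are binned at the stated rounding before counting, so two scores
    that agree to that precision count as the same outcome.
    """
    vals = list(values)
    if not vals:
        raise ValueError("cannot take the entropy of an empty list")
    counts = Counter(round(v, rounding_decimals) for v in vals)
    n = len(vals)
    # + 0.0 normalizes the -0.0 produced by a single-bin distribution
    return -sum((c / n) * math.log2(c / n) for c in counts.values()) + 0.0


def relative_entropy_percent(
    values: Sequence[float],
    rounding_decimals: int = 2,
    ratio_rounding: "int | None" = None,
) -> float:
    """Observed entropy as a percentage of the all-distinct maximum log2(n).

    ``ratio_rounding`` pre-rounds both entropies to that many decimals
    before dividing, reproducing reports that quote the ratio of
    two-decimal entropy figures; by default the unrounded ratio is
    returned.
    """
    vals = list(values)
    if len(vals) < 2:
        raise ValueError("relative entropy needs at least two values")
    h = shannon_entropy(vals, rounding_decimals)
    h_max = math.log2(len(vals))
    if ratio_rounding is not None:
        h, h_max = round(h, ratio_rounding), round(h_max, ratio_rounding)
    return 100.0 * h / h_max


def _substitute(seq: str, pos: int, char: str) -> str:
    return seq[:pos] + char + seq[pos + 1 :]


def _check_position(reference: str, pos: int) -> None:
    if not 1 <= pos <= len(reference):
        raise PanelParameterError(
            f"position {pos} out of range 1..{len(reference)}"
        )


def generate_panel(
    reference: str,
    panel_kind: str,
    positions: "Iterable[int] | None" = None,
    replacement_chars=None,
    deletion_lengths: "Iterable[int] | None" = None,
    n_variants: "int | None" = None,
    seed: "int | None" = None,
    alphabet: "str | None" = None,
    scheme_name: str = "DNA",
    variants: "Iterable[tuple] | None" = None,
    start_id: int = 1,
) -> VariantPanel:
    """Build a variant panel of one variation pattern.  Deterministic given seed.

    Kinds and their parameters (positions are 1-based):

    - ``position_substitution``: one substitution swept over ``positions``
      (default: every position).  ``replacement_chars`` may be a single
      character, a mapping from reference character to replacement, or a
      list parallel to ``positions``; if omitted, a seeded random non-self
      character from ``alphabet`` is drawn per position.
    - ``character_substitution``: every replacement in ``replacement_chars``
      (a list) tried at every position in ``positions``.
    - ``position_deletion``: one ``-`` swept over ``positions``.
    - ``terminal_deletion``: for each length L in ``deletion_lengths``,
      delete L terminal residues — from the right end for positive L, from
      the left end for negative L.
    - ``composition``: either explicit ``variants`` (id, sequence) pairs, or
      ``n_variants`` seeded random variants each carrying three
      substitutions and two deletions.
    """
    if not reference:
        raise PanelParameterError("reference must be non-empty")
    if panel_kind not in PANEL_KINDS:
        raise PanelParameterError(
            f"unknown panel kind {panel_kind!r}; choose from {PANEL_KINDS}"
        )
    rng = np.random.default_rng(seed)
    if alphabet is None:
        alphabet = "".join(sorted(set(reference) - {"-"}))
    out: list = []
    counter = start_id

    def add(seq: str) -> None:
        nonlocal counter
        out.append((f"S_{counter}", seq))
        counter += 1

    if panel_kind == "position_substitution":
        pos_list = list(positions) if positions is not None else list(
            range(1, len(reference) + 1)
        )
        for idx, pos in enumerate(pos_list):
            _check_position(reference, pos)
            ref_char = reference[pos - 1]
            if replacement_chars is None:
                choices = [c for c in alphabet if c != ref_char]
                repl = str(rng.choice(choices))
            elif isinstance(replacement_chars, Mapping):
                repl = replacement_chars[ref_char]
            elif isinstance(replacement_chars, str) and len(replacement_chars) == 1:
                repl = replacement_chars
            else:
                repl = replacement_chars[idx]
            if repl == ref_char:
                raise PanelParameterError(
                    f"replacement {repl!r} equals the reference character at "
                    f"position {pos}"
                )
            add(_substitute(reference, pos - 1, repl))

    elif panel_kind == "character_substitution":
        if positions is None or replacement_chars is None:
            raise PanelParameterError(
                "character_substitution needs positions and replacement_chars"
            )
        for pos in positions:
            _check_position(reference, pos)
            ref_char = reference[pos - 1]
            for repl in replacement_chars:
                if repl == ref_char:
                    raise PanelParameterError(
                        f"replacement {repl!r} equals the reference character "
                        f"at position {pos}"
                    )
                add(_substitute(reference, pos - 1, repl))

    elif panel_kind == "position_deletion":
        pos_list = list(positions) if positions is not None else list(
            range(1, len(reference) + 1)
        )
        for pos in pos_list:
            _check_position(reference, pos)
            add(_substitute(reference, pos - 1, "-"))

    elif panel_kind == "terminal_deletion":
        if deletion_lengths is None:
            raise PanelParameterError("terminal_deletion needs deletion_lengths")
        for length in deletion_lengths:
            m = abs(length)
            if not 1 <= m < len(reference):
                raise PanelParameterError(
                    f"terminal deletion length {length} out of range"
                )
            if length > 0:
                add(reference[: len(reference) - m] + "-" * m)
            else:
                add("-" * m + reference[m:])

    else:  # composition
        if variants is not None:
            out = [(str(vid), seq) for vid, seq in variants]
        else:
            if n_variants is None:
                raise PanelParameterError(
                    "composition needs explicit variants or n_variants"
                )
            for _ in range(n_variants):
                seq = reference
                picks = rng.choice(len(reference), size=5, replace=False)
                for pos in picks[:3]:
                    choices = [c for c in alphabet if c != seq[pos]]
                    seq = _substitute(seq, int(pos), str(rng.choice(choices)))
                for pos in picks[3:]:
                    seq = _substitute(seq, int(pos), "-")
                add(seq)

    return VariantPanel(
        reference=reference,
        variants=tuple(out),
        panel_kind=panel_kind,
        scheme_name=scheme_name,
    )


# ---------------------------------------------------------------------------
# Benchmark presets
# ---------------------------------------------------------------------------

_DNA_REF = "CTAGCTAGCTAG"
_PROT_REF = "GASPCLDQMFRY"

# Composition panels (three substitutions + two deletions in irregular
# patterns): shipped verbatim; each string was checked against its published
# geometric-similarity coefficient.
_TABLE10_DNA = (
    "GTA-CTGCCT-G", "C-GG-TAGATAT", "-TAGGTAACCA-", "C--GCTAAGTAA",
    "TCAGCGAGCT--", "CCAGCGC--TAG", "CCAGCCG--TAG", "CAAGCCG--TAG",
    "CGAGCCG--TAG", "C--ACTAGGGAG", "C--ACTAGCGAT", "C--TCTAGCATG",
    "C--CCTAGCAGT",
)
_TABLE10_PROTEIN = (
    "YAS-CLWSMF-Y", "G-WP-LDQGFRW", "-ASPWLDAMAR-", "G--PCLDPAFRS",
    "WASPCYDQMF--", "GYSPCDL--FRY", "GYSPCLD--FRY", "GRSPCLD--FRY",
    "GFSPCLD--FRY", "--WPCLDQPPRY", "--FPCLDQMYRF", "--RPCLDQMRFY",
    "--YPCLDQMRYF",
)


def _preset_table6b_dna() -> VariantPanel:
    # one substitution swept left->right; C<->G and T<->A exchanges
    return generate_panel(
        _DNA_REF, "position_substitution",
        replacement_chars={"C": "G", "T": "A", "A": "T", "G": "C"},
        scheme_name="DNA", start_id=1,
    )


def _preset_table6b_protein() -> VariantPanel:
    return generate_panel(
        _PROT_REF, "position_substitution", replacement_chars="W",
        scheme_name="protein", start_id=1,
    )


def _preset_table7_dna() -> VariantPanel:
    panels = []
    counter = 13
    for pos in (1, 6, 11):
        repls = [c for c in "GATC" if c != _DNA_REF[pos - 1]]
        p = generate_panel(
            _DNA_REF, "character_substitution", positions=[pos],
            replacement_chars=repls, scheme_name="DNA", start_id=counter,
        )
        panels.extend(p.variants)
        counter += len(repls)
    return VariantPanel(_DNA_REF, tuple(panels), "character_substitution", "DNA")


def _preset_table7_protein() -> VariantPanel:
    return generate_panel(
        _PROT_REF, "character_substitution", positions=[1, 6, 11],
        replacement_chars=["A", "S", "P"], scheme_name="protein", start_id=13,
    )


def _preset_table8(ref: str, scheme: str) -> VariantPanel:
    return generate_panel(ref, "position_deletion", scheme_name=scheme, start_id=22)


def _preset_table9(ref: str, scheme: str) -> VariantPanel:
    lengths = list(range(2, 9)) + [-m for m in range(8, 1, -1)]
    return generate_panel(
        ref, "terminal_deletion", deletion_lengths=lengths,
        scheme_name=scheme, start_id=34,
    )


def _preset_table10(ref: str, scheme: str, seqs: tuple) -> VariantPanel:
    ids = [f"S_{i}" for i in range(48, 48 + len(seqs))]
    return generate_panel(
        ref, "composition", variants=list(zip(ids, seqs)), scheme_name=scheme,
    )


PANEL_PRESETS = {
    "table6b_dna": _preset_table6b_dna,
    "table6b_protein": _preset_table6b_protein,
    "table7_dna": _preset_table7_dna,
    "table7_protein": _preset_table7_protein,
    "table8_dna": lambda: _preset_table8(_DNA_REF, "DNA"),
    "table8_protein": lambda: _preset_table8(_PROT_REF, "protein"),
    "table9_dna": lambda: _preset_table9(_DNA_REF, "DNA"),
    "table9_protein": lambda: _preset_table9(_PROT_REF, "protein"),
    "table10_dna": lambda: _preset_table10(_DNA_REF, "DNA", _TABLE10_DNA),
    "table10_protein": lambda: _preset_table10(_PROT_REF, "protein", _TABLE10_PROTEIN),
}


def preset_panel(name: str) -> VariantPanel:
    """One of the built-in benchmark panels (``table6b_dna`` ... ``table10_protein``)."""
    try:
        factory = PANEL_PRESETS[name.lower()]
    except KeyError:
        raise PanelParameterError(
            f"unknown preset {name!r}; available: {sorted(PANEL_PRESETS)}"
        ) from None
    return factory()


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PanelEvaluation:
    """Per-variant scores plus per-method entropy summaries."""

    panel: VariantPanel
    per_variant: pd.DataFrame
    reports: Mapping[str, SensitivityReport]


def evaluate_panel(
    panel: VariantPanel,
    scheme=None,
    methods: Sequence[str] = ("conventional", "geometrical"),
    pairing: "PairingStyle | str" = PairingStyle.HEAD_TO_HEAD,
    delta: float = 0,
    rounding_decimals: int = 2,
    ratio_rounding: "int | None" = None,
) -> PanelEvaluation:
    """Score every variant against the reference and summarize each method.

    The geometric method is scored with the variant as the left structure
    of the pair.  Entropy is taken over the similarity column of each
    method (conventional %, geometric PGsim).
    """
    sch = get_scheme(scheme if scheme is not None else panel.scheme_name)
    methods = tuple(methods)
    for m in methods:
        if m not in ("conventional", "geometrical"):
            raise ValueError(f"unknown method {m!r}")
    rows = []
    for vid, seq in panel.variants:
        row: dict = {"variant_id": vid, "sequence": seq}
        try:
            if "conventional" in methods:
                row["cm_percent_similarity"] = conventional_percent_similarity(
                    seq, panel.reference
                )
            if "geometrical" in methods:
                res = pairwise_analysis(
                    seq, panel.reference, scheme=sch, pairing=pairing, delta=delta
                )
                row.update(kc=res.kc, pgsim=res.pgsim, pgdsim=res.pgdsim)
        except ValueError as exc:
            raise type(exc)(f"variant {vid}: {exc}") from exc
        rows.append(row)
    table = pd.DataFrame(rows)

    reports = {}
    column = {"conventional": "cm_percent_similarity", "geometrical": "pgsim"}
    for m in methods:
        vals = tuple(table[column[m]])
        h = shannon_entropy(vals, rounding_decimals)
        rel = (
            relative_entropy_percent(vals, rounding_decimals, ratio_rounding)
            if len(vals) >= 2
            else 0.0
        )
        reports[m] = SensitivityReport(
            method_name=m,
            values=vals,
            entropy_bits=h,
            relative_entropy_percent=rel,
            rounding_decimals=rounding_decimals,
        )
    return PanelEvaluation(panel=panel, per_variant=table, reports=reports)


# ---------------------------------------------------------------------------
# Panel I/O
# ---------------------------------------------------------------------------


def panel_from_fasta(path, panel_kind: str = "composition", scheme_name: str = "DNA") -> VariantPanel:
    """Read an aligned multi-FASTA panel: first record is the reference."""
    from Bio import SeqIO

    records = [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]
    if len(records) < 2:
        raise ValueError(
            f"panel FASTA {path} needs a reference plus at least one variant, "
            f"found {len(records)} record(s)"
        )
    ref_id, ref_seq = records[0]
    return VariantPanel(
        reference=ref_seq,
        variants=tuple(records[1:]),
        panel_kind=panel_kind,
        scheme_name=scheme_name,
    )


def report_to_tsv(evaluation: PanelEvaluation, float_decimals: int = 6) -> str:
    """One TSV row per variant plus summary rows per method."""
    table = evaluation.per_variant.copy()
    lines = [table.to_csv(sep="\t", index=False, float_format=f"%.{float_decimals}f").rstrip("\n")]
    for name, rep in evaluation.reports.items():
        lines.append(f"entropy\t{name}\t{rep.entropy_bits:.{float_decimals}f}")
        lines.append(
            f"relative_entropy_percent\t{name}\t"
            f"{rep.relative_entropy_percent:.{float_decimals}f}"
        )
    return "\n".join(lines) + "\n"
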