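# Methods

## The optinalytic model

An *optinalytic construction* compares structures by reading them as a
mirror reflection about a centre. For two equal-length structures
`A = (a1..an)` and `B = (b1..bn)` and an external centre δ, the
head-to-head layout is `(a1..an, δ, bn..b1)`; tail-to-tail reverses which
ends face the centre. A single structure of odd length is its own
construction, its middle element serving as the centre (automorphic
form). A uniform rank scale (*optiscale*) `r_i = ±i·k`, `k > 0`, indexes
the layout, and the Kabirian coefficient is the median rank times the
layout sum, divided by the rank-weighted layout sum:

    Kc = r_{n+1} · Σ layout / Σ r_i · layout_i .

Pairing positions i and 2n+2−i of a palindromic layout shows each pair
contributes `2·r_{n+1}` per unit value, hence Kc = 1 exactly for
identical (or perfectly symmetric) inputs. Both k and the scale's sign
cancel in the quotient, as does a common multiplicative factor on the
data; these invariances are enforced by randomized tests at 1e−12.
Which side of 1 the coefficient falls on is governed by the *optical
moments* of the two halves (distance-weighted sums with the first element
farthest out); `classify_regime` reports the five cases (equal, negated,
below 1, in [1, n+1], outside). The printed condition table's last two
cases share one premise (g(A) > g(B)); they are disambiguated here by the
computed coefficient itself, and the distance scale reuses the optiscale
interval since nothing else is specified.

## Probability translation

The coefficient lives on two scales joined at 1: [0, 1) when the left
structure's moment is smaller, (1, n+1] and beyond when larger. Two
branch formulas map it to a probability of similarity `p ∈ [−1, 1]`
(`kc_to_p`; the branch split is taken at Kc = 1, where both branches
agree), a piecewise complement gives the dissimilarity, and two backward
maps return the *bi-coefficients* on each scale. The composition
`kc_alternate` returns the coefficient the same pair would produce with
the structures' roles exchanged — the Y-rule: `Kc(A,B)` and `Kc(B,A)`
differ, but both translate to the same `p`, verified over 1000 random
pairs at 1e−9 along with the round-trip identities.

Two analytic facts discovered while testing are worth recording. First,
both branches map their entire domains into [−1, 1] (the upper branch
tends to −1/(2n+1) as |Kc| grows), so the defensive out-of-range warning
in `kc_to_p` is unreachable for real inputs. Second, the piecewise
complement is involutive on (−1, 1] but not at exactly −1
(−1 → 0 → 1); callers relying on double-complement identities should
avoid the closed endpoint.

`r1`, the first rank, appears in the printed models and is exposed as a
parameter (default 1) although it cancels algebraically. `n` is the
per-side dimension of the construction the coefficient came from.

## Sequence pipeline

Pre-aligned, equal-length sequences (alignment is upstream — Needle,
Stretcher, MAFFT and kin; this package never aligns) are encoded
residue-by-residue as monomer molecular masses in g/mol: DNA/RNA bases
C 111, T 126, A 135, G 151, U 112; the twenty amino acids from Gly 75 to
Trp 204. Gap symbols (`-`, with `.` and `*` accepted as synonyms) encode
as 0. Ambiguity codes are rejected in strict mode rather than zeroed,
since a zero is indistinguishable from a deletion; lenient mode zeroes
them with a logged warning. Leu/Ile (131) and Gln/Lys (146) share masses,
so sequences differing only by those swaps are *isobaric*: they encode
identically and score PGsim = 100 — an inherent property of a pure
mass encoding, documented rather than corrected.

Pairing is head-to-head by default, matching the 5′→3′ reading
convention; δ = 0 unless the caller modulates the centre. The aligned
length is the construction dimension `n`, and `100·p` is reported as
PGsim (percentage geometrical similarity). The conventional baseline
(identical columns over aligned length, gap–gap counting as a match, the
longer length as denominator for unaligned input) is computed alongside.
Coefficients are reported at 6 decimals and percentages at 2, matching
the precision the statistic is typically quoted at.

When a variant panel is scored, the variant is placed as the left
structure of each pair. The two role orders give the two bi-coefficients
of the same pair; the variant-first order is the one under which the
published benchmark coefficients reproduce, and PGsim is role-symmetric
either way.

## Sensitivity evaluation and the panel generator

A method's sensitivity over a panel of n variants is the Shannon entropy
of its score column, with scores binned at 2 decimals (the precision the
scores are quoted at; configurable) before counting; relative entropy is
the percentage of the all-distinct maximum log2(n). The reported relative
entropy uses the unrounded ratio by default; a `ratio_rounding` option
pre-rounds both entropies (e.g. 2.81/3.81 → 73.75 %) to reproduce reports
quoting two-decimal entropy figures.

The generator builds the benchmark panel families deterministically:
single substitutions swept along the positions, fixed-position character
substitutions, a single-deletion sweep, terminal-deletion series (signed
lengths: positive from the right end, negative from the left), and
mixed-composition variants. Ten presets reconstruct the published
12-base DNA (`CTAGCTAGCTAG`) and 12-residue protein (`GASPCLDQMFRY`)
benchmark panels; the irregular composition panels are shipped as
verbatim strings, each validated against its published coefficient.
Randomized analogues (seeded, three substitutions plus two deletions per
variant) emulate the composition pattern but not other features of real
data — no transition/transversion bias, no indel clustering, no length
variation — so passing tests demonstrate the estimator's discriminating
power on controlled variation, not calibration on natural sequences.

Two fixture-level caveats. The published conventional-method column for
the composition panels is printed as a constant, but the panel's own
variant strings (validated via their coefficients) give non-constant
conventional scores for a few variants; the conventional method's total
blindness is therefore asserted only on the single-substitution,
character-substitution and single-deletion panels. Likewise, PGsim is
strictly monotone in mismatch position only when the substituted
character is constant (the protein panel, all-Trp); the DNA sweep changes
the character with position and is non-monotone, so the DNA panel is
tested for pairwise distinctness instead.

## Numerical choices

- Kernel arithmetic uses plain Python sums (n is at most a few dozen in
  practice): integer inputs with an integer interval yield exact integer
  numerator/denominator, asserted exactly for the worked example
  (8260/7790).
- A zero rank-weighted sum (e.g. all-zero structures with δ = 0) raises a
  degenerate-structure error rather than returning NaN.
- Even-length automorphic input is an error; padding policy belongs to
  the caller.
- Branch selection in `kc_to_p` at exactly 1 uses the upper branch; the
  half-open split [0, 1) vs the rest removes ambiguity.
- Probabilities are stored as fractions; ×100 happens only in reporting.

## Known limitations

- Only pairwise comparison is defined; no multi-structure generalisation.
- The probability translation is the framework's own algebraic construct,
  not a frequency or Bayesian probability.
- Scores depend on element order and require equal lengths; alignment
  quality is entirely upstream.
- The mass encoding conflates isobaric residues (see above) and weights
  mismatches by mass difference, which has no evolutionary-model
  interpretation (no substitution-matrix semantics).
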