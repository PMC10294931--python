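# Methods

## Model

The assessment model is a weighted three-layer criterion tree. Sixty
tertiary indices receive integer expert scores on a six-level scale
(0 negligible, 1 low, 2 slight, 3 medium, 4 high, 5 extremely high risk).
Scores propagate upward by *cumulative* aggregation — each parent is the
dot product of its children with their weights — through twelve secondary
indices (P1–P12) and four primary indices (R1 hazard of the species, R2
entry, R3 exposure, R4 consequence) to the total risk value R. Because
every sibling weight group sums to one and all weights are positive, each
aggregate is a convex combination: values stay in [0, 5], a constant sheet
maps to that constant at every level, and raising any single score strictly
raises all of its ancestors.

The model family also recognises multiplicative and substitution
relationships between indices, but only the cumulative case has a defined
aggregation rule; the package models that case only.

Aggregation uses full-precision values throughout; rounding (half-even,
four decimals) happens only in display output. The bundled coefficients are
themselves printed at four decimals, which sets two tolerances used
package-wide: sibling weight groups must sum to 1 within 1e-4, and
comparisons against the published results table use ±5e-4.

## AHP weight derivation

Weights for each sibling group come from a pairwise comparison matrix:
positive, unit diagonal, reciprocal (`a[j][i] = 1/a[i][j]`, enforced within
1e-9; a geometric-mean symmetrisation option exists for hand-entered
matrices but is off by default). Entries outside the Saaty 1–9 scale and
its reciprocals trigger a warning, not an error.

The weight vector is the principal right eigenvector, computed by power
iteration (L1-normalised iterates, convergence tolerance 1e-12 on the
vector, at most 10,000 iterations). Matrices here are at most 9×9, so power
iteration is fast and fully deterministic; the test suite cross-checks it
against a dense eigendecomposition to 1e-8. The dominant eigenvalue λmax is
the Rayleigh quotient at the converged vector and satisfies λmax ≥ n, with
equality exactly when the matrix is consistent.

Consistency diagnostics: CI = (λmax − n)/(n − 1), CR = CI/RI(n), accepted
when CR < 0.1. The RI (random index) table is Saaty's standard
RI(1..9) = (0, 0, 0.58, 0.90, 1.12, 1.24, 1.32, 1.41, 1.45), overridable in
configuration or on the command line; orders beyond the table raise an
error asking for a user-supplied RI. Degenerate orders are defined by
convention: a 1×1 matrix has CI = 0, and for n ≤ 2 (where RI = 0 and any
reciprocal matrix is consistent) CR is reported as 0 with a consistent
verdict iff CI ≈ 0. The source model's own comparison matrices were never
published, so the engine is validated by properties (round-trip recovery of
known weight vectors, agreement with a dense eigensolver, permutation
equivariance, scale invariance), not by reproducing specific matrices.

## Scoring rubric and validation

The rubric stores the published criterion text for every tertiary index.
Two entry kinds exist: *enumerated* indices print one sentence per level,
and *discussion* indices print a single scoring instruction and are graded
against shared discussion rules after expert deliberation. Seven enumerated
indices (p44, p61, p63, p64, p83, p121, p126) print levels 1–5 only, while
the global rule gives every index the same 0–5 assignment range. Both
readings are preserved: validation always accepts 0–5, and strict mode adds
advisory warnings when a score falls on a level the rubric does not print.
One rubric quirk is stored as printed: p44 repeats the same sentence for
levels 4 and 5.

Scores must be integers — the published case study assigns whole levels
throughout — and validation is total: any input yields a report listing
missing, unknown, non-integer and out-of-range entries, never an exception.

## Grading

R maps onto five lower-open/upper-closed intervals: negligible (0, 1], low
(1, 2], medium (2, 3], high (3, 4], extremely high (4, 5], each carrying
its policy recommendation. R = 0, attainable from an all-zero sheet, is
graded negligible by closure. Cross-subject ranking is by descending
unrounded R with lexicographic tie-break on the subject id (the source
material does not specify a tie rule).

## Case-study fixture and synthetic sheets

The embedded case study carries the five species' 300 tertiary scores and
the published aggregate values stored verbatim as printed strings, so tests
compare against the literal published figures. Four rows of the published
score table capitalise the index symbol (P113…P126); these are normalised
to the lowercase tertiary ids.

One published cell is internally inconsistent: R4 for *Pterygoplichthys
pardalis* is printed as 3.8843, but the same table's P11 = 3.7002 and
P12 = 4.6164 under R4 = 0.8·P11 + 0.2·P12 give 3.8834. The printed value
appears to be a digit transposition; it is kept verbatim, flagged in
`KNOWN_ERRATA`, and the strict reproduction test for that single cell
fails by design (84 of 85 values and all five grades reproduce within
±5e-4). The published total R for that species (3.6973) was evidently
computed from the transposed value but still agrees with unrounded
propagation (3.6971) within tolerance.

The synthetic generator draws uniform integer scores in [0, 5],
independently per index and subject, from a seeded PRNG. It emulates only
the *shape* of real score sheets — complete, integral, in range — not their
statistics: real expert scores are correlated within secondary groups and
far from uniform. Passing property tests therefore demonstrates algebraic
correctness of the aggregation (oracle equality, convexity, monotonicity,
linearity), not calibration of the model to real introductions.

## Problem sizes and determinism

Everything is small by construction: matrices are ≤ 9×9, the default
hierarchy has 77 nodes, and the full test suite (including 2,000 randomised
matrices in the bulk engine check and 100 oracle sheets) runs in seconds.
All randomness flows through explicit seeds; repeated runs are bit-identical.

## Known limitations

- Only three criterion layers and cumulative aggregation are supported.
- No uncertainty propagation over scores, no multi-expert reconciliation,
  no group aggregation of comparison matrices, and no fuzzy/interval AHP
  variants.
- The rubric's expert-discussion notes for the case-study scores were not
  published; the scores are taken as given.
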