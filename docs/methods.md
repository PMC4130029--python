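# Methods

## The shared-k-mer similarity

The score implemented throughout is

    F(X, Y) = Σ_τ min[n_X(τ), n_Y(τ)] / [min(L_X, L_Y) − k + 1]

where τ ranges over k-mers in class-representative space, n_X(τ) is the
occurrence count of τ in X, and L_X, L_Y are the raw sequence lengths.
The numerator Σ min counts shared k-mer occurrences with multiplicity;
the denominator is the window count of the shorter sequence, so
F ∈ [0, 1] and F(X, X) = 1 for any clean sequence of length ≥ k. The
score assumes nothing about alignability; it treats a sequence as its
bag of k-mer occurrences, which is what makes it O(n) per pair. It is
strand-naive (no reverse-complement matching) and has no significance
model attached — it is a similarity, not a p-value, and no distance
transform is applied.

Counting slides a width-k window over the translated sequence. Storage
is sparse (hash map from occurring k-mer to count): the conceptual
dense vector over all r^k tuples of an r-class alphabet is infeasible
for r = 20 and k ≥ 4, and is retained only as a brute-force oracle in
the test suite, where the sparse and dense routes are compared
element-wise for r ≤ 10, k ≤ 3.

## Compressed alphabets

A compressed alphabet is a partition of the 20 standard amino acids
into disjoint classes of biochemically exchangeable residues; every
class is written as its alphabetically first member, and sequences are
translated into that representative space before counting. The eleven
built-ins are the classic reduced alphabets (Dayhoff 6, Murphy 10, Li
A/B 10, Solis D/G 10, and the SE-B/SE-V series from 6 to 14 classes),
plus the identity partitions for protein and DNA. Construction
validates the partition property (disjoint classes exactly covering
the base set), so a typo in a user-supplied partition fails fast.

Coarsening the alphabet can only merge count bins, and a sum of
minima over merged bins dominates the sum over the original bins;
hence F under any compressed alphabet is ≥ F under the identity
alphabet for the same pair and k. This monotonicity is asserted as a
property test rather than assumed.

Which (alphabet, k) pair gives the best similarity estimate is a
statistical question outside this package's scope; the CLI defaults —
k = 3 with SE-V(10) for protein, k = 3 with the plain 4-letter
alphabet for DNA — follow the package's worked conservation example
and are overridable. Deriving new alphabets from substitution
statistics is a non-goal.

## Degenerate inputs and filtering

All residue filtering happens in exactly one place: k-mer counting.
Translation passes unknown symbols (ambiguity codes such as X/B/Z,
gaps) through unchanged; any window containing one is skipped and
tallied, never counted. The Eq.-style denominator keeps the *raw*
length even when windows were skipped, so filtering can only lower F —
a deliberately conservative choice that never inflates similarity. In
conservation counting, a column containing an unknown symbol is never
conserved. A pair whose shorter sequence is shorter than k has an
undefined denominator; `similarity` returns 0.0 with a logged warning
instead of raising, so one fragmentary record cannot abort a large
matrix run. Empty sequences and non-positive k are errors.

## Matrix build and the master–worker scheme

The sequential build is the plain strict-lower-triangle double loop:
entry (i, j), 1 ≤ j < i ≤ n, computed once, n(n−1)/2 entries, no
diagonal. The container validates the exact index set and the [0, 1]
range on construction.

The parallel scheme is static cyclic row scheduling: all n rows
(row 1 carrying zero pairs) are dealt round-robin, row i to worker
((i−1) mod p) + 1. Every worker receives the full sequence set once —
mirroring a broadcast — computes its rows in ascending order, and
returns a single flat vector: row i contributes its i−1 values in
column order. The master reassembles the triangle from the vectors and
the worker ids; a missing or mis-sized vector is an error naming the
worker. There is no work stealing: cyclic dealing of triangle rows is
already balanced to within one row's worth of pairs per worker (the
suite asserts max−min per-worker pair load ≤ n_rows), and the
one-message-per-worker contract keeps communication minimal.

Determinism is structural, not approximate: each F value is computed
as an integer numerator divided by an integer denominator in a single
floating-point operation, so sequential and parallel builds agree
bit-for-bit for every worker count, backend and arrival order. Two
backends share the contract: `serial-emulation` (workers run in a loop
inside the master process; the default, and what the tests exercise)
and `process` (a stdlib multiprocessing pool, one task per worker).
The worker-communication contract is transport-agnostic, so a
message-passing backend could be added behind the same three
operations (assign, compute rows, assemble) without touching them.

## Synthetic families

The generator emulates the minimal homologous family: one uniform
random ancestor of the configured length, and members that differ from
it by i.i.d. per-residue substitutions at a fixed rate, the substitute
drawn uniformly from the other residues. It is seeded and exactly
reproducible. It deliberately does **not** model indels, positional
rate heterogeneity, compositional bias, or tree-structured descent —
every member is an independent child of the ancestor. Passing tests on
these families therefore demonstrate correctness and determinism of
the counting and scheduling machinery, not biological calibration of
F on real homolog sets.

Default study conditions used by the deeper end-to-end tests: 50
sequences of length 200 at substitution rate 0.2 for the
parallel-vs-sequential identity check (worker counts 1, 2, 3, 4, 7);
200 random pairs of length 20–120 at rates 0.05–0.5 for the
coarsening-monotonicity property; 100 random sequences for the
sparse/dense oracle equivalence. Lengths and rates were fixed once as
a realistic mid-divergence regime.

## Numerical notes

- F values are exact binary ratios; tests compare them with equality
  or 1e-12 tolerance, and the TSV/PHYLIP writers round to 6 decimals
  (round-trip asserted at 1e-6).
- Frequency vectors sum to 1 within 1e-12 whenever at least one valid
  window exists; an empty count table has no frequency vector (error).
- Ties never arise: counting and assembly are pure integer bookkeeping.

## Known limitations

- No reverse-complement-aware DNA counting; inputs are compared as
  written.
- The `process` backend ships the whole sequence set to every worker;
  for very large inputs on one machine, shared memory would be cheaper.
- F is reported as a similarity only; guide-tree construction,
  alignment, and interop with aligner-specific matrix formats are out
  of scope.
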