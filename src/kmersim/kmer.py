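"""k-mer counting and the shared-k-mer similarity score.

The similarity between two sequences X and Y is the fraction of k-mer
occurrences they share, counted in class-representative space::

    F(X, Y) = sum_tau min(n_X(tau), n_Y(tau)) / (min(L_X, L_Y) - k + 1)

where tau ranges over k-mers, n_X(tau) is the occurrence count of tau in
X, and L_X, L_Y are the raw sequence lengths. F lies in [0, 1] and needs
no alignment; computing it is O(n) per pair.

Counting is sparse: only k-mers that actually occur are stored. The
conceptual dense vector over all r**k possible tuples (r = alphabet size)
is recoverable and is used as a brute-force oracle in the test suite.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

from .alphabets import Alphabet, translate

__all__ = [
    "KmerCountTable",
    "FrequencyTable",
    "count_kmers",
    "kmer_frequencies",
    "shared_kmer_count",
    "similarity",
    "conserved_window_count",
]

logger = logging.getLogger("kmersim")


@dataclass(frozen=True)
class KmerCountTable:
    """Sparse occurrence counts of k-mers in one sequence.

    Attributes
    ----------
    k
        Word length.
    counts
        Map k-mer (in representative space) -> occurrence count >= 1.
    effective_windows
        Number of windows actually counted; equals
        ``raw_length - k + 1 - skipped_windows``.
    skipped_windows
        Windows dropped because they contained an out-of-alphabet symbol.
    raw_length
        Untranslated sequence length (the L in the similarity denominator).
    """

    k: int
    counts: dict[str, int]
    effective_windows: int
    skipped_windows: int
    raw_length: int

    def __post_init__(self) -> None:
        if sum(self.counts.values()) != self.effective_windows:
            raise ValueError("count total does not match effective window count")

    def count(self, kmer: str) -> int:
        """Occurrences of ``kmer`` (0 if absent)."""
        return self.counts.get(kmer, 0)


@dataclass(frozen=True)
class FrequencyTable:
    """Relative k-mer frequencies; values sum to 1 over stored keys."""

    k: int
    frequencies: dict[str, float] = field(repr=False)

    def frequency(self, kmer: str) -> float:
        return self.frequencies.get(kmer, 0.0)


def count_kmers(sequence: str, k: int, alphabet: Alphabet) -> KmerCountTable:
    """Slide a window of width ``k`` over ``sequence`` and count each word.

    The sequence is uppercased and translated into class-representative
    space first, so counts are per compressed-alphabet tuple. Windows
    containing any symbol outside the alphabet contribute nothing and are
    tallied in ``skipped_windows``. A sequence shorter than ``k`` yields
    an empty table.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    raw_length = len(sequence)
    translated = translate(sequence, alphabet)
    counts: Counter[str] = Counter()
    skipped = 0
    valid = alphabet.representative_of
    # invalid[i] is True where the translated symbol is out-of-alphabet
    invalid = [ch not in valid for ch in translated]
    for start in range(raw_length - k + 1):
        if any(invalid[start : start + k]):
            skipped += 1
        else:
            counts[translated[start : start + k]] += 1
    return KmerCountTable(
        k=k,
        counts=dict(counts),
        effective_windows=sum(counts.values()),
        skipped_windows=skipped,
        raw_length=raw_length,
    )


def kmer_frequencies(table: KmerCountTable) -> FrequencyTable:
    """Normalise counts to relative frequencies (count / windows counted)."""
    if table.effective_windows < 1:
        raise ValueError("cannot compute frequencies of an empty count table")
    denom = table.effective_windows
    return FrequencyTable(
        k=table.k,
        frequencies={kmer: c / denom for kmer, c in table.counts.items()},
    )


def shared_kmer_count(x: KmerCountTable, y: KmerCountTable) -> int:
    """Sum over k-mers of min(n_X, n_Y): the shared-occurrence numerator."""
    if x.k != y.k:
        raise ValueError(f"mismatched k: {x.k} vs {y.k}")
    small, large = (x, y) if len(x.counts) <= len(y.counts) else (y, x)
    return sum(min(c, large.count(kmer)) for kmer, c in small.counts.items())


def similarity(seq_x: str, seq_y: str, k: int, alphabet: Alphabet) -> float:
    """Shared-k-mer similarity F(X, Y) in [0, 1].

    The denominator uses the raw (pre-filtering) lengths, so skipped
    windows only ever lower the score. If the shorter sequence has fewer
    than ``k`` residues the score is undefined; 0.0 is returned with a
    warning so that batch runs over many sequences never abort.
    """
    if not seq_x or not seq_y:
        raise ValueError("similarity is undefined for an empty sequence")
    shorter = min(len(seq_x), len(seq_y))
    if shorter < k:
        logger.warning(
            "sequence shorter than k (%d < %d); returning similarity 0.0",
            shorter,
            k,
        )
        return 0.0
    tx = count_kmers(seq_x, k, alphabet)
    ty = count_kmers(seq_y, k, alphabet)
    # integer / integer at the very last step: bit-identical everywhere
    return shared_kmer_count(tx, ty) / (shorter - k + 1)


def conserved_window_count(
    aligned_sequences: list[str], k: int, alphabet: Alphabet
) -> int:
    """Count fully conserved k-wide windows across pre-aligned sequences.

    A column is conserved when every sequence carries the same class
    representative there; a window of ``k`` consecutive conserved columns
    is a fully conserved k-mer. For ``k=1`` this is the classic
    conserved-column count. Columns where any sequence has an
    out-of-alphabet symbol are never conserved.
    """
    if len(aligned_sequences) < 2:
        raise ValueError("need at least two sequences")
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    lengths = {len(s) for s in aligned_sequences}
    if len(lengths) != 1:
        raise ValueError(f"sequences must have equal length, got lengths {sorted(lengths)}")
    length = lengths.pop()
    rows = [translate(s, alphabet) for s in aligned_sequences]
    valid = alphabet.representative_of
    conserved = [
        all(r[i] == rows[0][i] for r in rows) and rows[0][i] in valid
        for i in range(length)
    ]
    return sum(
        1 for i in range(length - k + 1) if all(conserved[i : i + k])
    )
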