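"""Brute-force dense-vector oracles, independent of the package internals.

Everything here works on the conceptual dense count vector over all r**k
possible tuples (r = alphabet size), built by direct enumeration. Only
feasible for small r and k; used to cross-check the sparse implementation.
"""

from __future__ import annotations

import itertools

from kmersim.alphabets import Alphabet


def dense_tuple_space(alphabet: Alphabet, k: int) -> list[str]:
    """All r**k tuples over the class representatives, lexicographic."""
    reps = sorted(alphabet.representatives)
    return ["".join(t) for t in itertools.product(reps, repeat=k)]


def dense_counts(sequence: str, k: int, alphabet: Alphabet) -> dict[str, int]:
    """Dense occurrence vector: compare every window against every tuple."""
    rep = alphabet.representative_of
    translated = "".join(rep.get(ch, ch) for ch in sequence.upper())
    vector = {tup: 0 for tup in dense_tuple_space(alphabet, k)}
    for start in range(len(translated) - k + 1):
        window = translated[start : start + k]
        if window in vector:
            vector[window] += 1
    return vector


def dense_similarity(x: str, y: str, k: int, alphabet: Alphabet) -> float:
    """F(X, Y) from the dense vectors; denominator from raw lengths."""
    if min(len(x), len(y)) < k:
        return 0.0
    cx = dense_counts(x, k, alphabet)
    cy = dense_counts(y, k, alphabet)
    numerator = sum(min(cx[t], cy[t]) for t in cx)
    return numerator / (min(len(x), len(y)) - k + 1)
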