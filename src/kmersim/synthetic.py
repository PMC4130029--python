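"""Synthetic sequence families for tests and demos.

Real benchmark sets for all-pairs similarity are families of homologous
sequences of varying divergence. The generator emulates the simplest such
family: a random ancestor and descendants produced by i.i.d. point
substitutions at a fixed per-residue rate. It makes no attempt to model
indels, rate heterogeneity across sites, or phylogenetic structure
(every member is an independent draw from the same ancestor).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alphabets import Alphabet, get_alphabet
from .io import SequenceRecord

__all__ = ["SyntheticFamilyConfig", "generate_family"]


@dataclass(frozen=True)
class SyntheticFamilyConfig:
    """Parameters of a simulated sequence family.

    ``substitution_rate`` is the per-residue probability that a member
    differs from the ancestor at that position; the substituted residue
    is drawn uniformly from the other base residues. The same seed always
    reproduces the same family.
    """

    n_sequences: int
    length: int
    substitution_rate: float
    alphabet: Alphabet = field(default_factory=lambda: get_alphabet("identity-protein"))
    seed: int = 0
    id_prefix: str = "synth"

    def __post_init__(self) -> None:
        if self.n_sequences < 1:
            raise ValueError("n_sequences must be >= 1")
        if self.length < 1:
            raise ValueError("length must be >= 1")
        if not 0.0 <= self.substitution_rate <= 1.0:
            raise ValueError("substitution_rate must lie in [0, 1]")


def generate_family(config: SyntheticFamilyConfig) -> list[SequenceRecord]:
    """Draw one ancestor and ``n_sequences`` mutated copies of it.

    Residues are drawn uniformly from the base residue set of
    ``config.alphabet`` (its full residue set, not the compressed
    classes). At rate 0 all members equal the ancestor, so every pairwise
    similarity is exactly 1.
    """
    rng = np.random.default_rng(config.seed)
    residues = np.array(sorted(config.alphabet.residues))
    n_res = len(residues)
    ancestor = rng.integers(0, n_res, size=config.length)
    records: list[SequenceRecord] = []
    for m in range(config.n_sequences):
        member = ancestor.copy()
        hit = rng.random(config.length) < config.substitution_rate
        # substitute with a uniform draw over the OTHER residues
        offsets = rng.integers(1, n_res, size=int(hit.sum()))
        member[hit] = (member[hit] + offsets) % n_res
        records.append(
            SequenceRecord(
                id=f"{config.id_prefix}{m + 1}",
                sequence="".join(residues[member]),
            )
        )
    return records
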