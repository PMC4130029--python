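"""Residue alphabets and compressed (reduced) amino-acid alphabets.

A compressed alphabet partitions the 20 standard amino acids into disjoint
classes of biochemically similar residues; every member of a class is
treated as identical for k-mer counting. Each class is named by its
canonical representative, the alphabetically first residue in the class.
Translating a sequence into representative space before counting raises
the shared-k-mer similarity of related sequences (class-internal
substitutions no longer break a match).

The built-in compressed alphabets are the classic reduced alphabets of
Dayhoff, Murphy, Li, Solis and the SE-B/SE-V families; ``identity-protein``
and ``identity-dna`` are the trivial one-residue-per-class partitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "Alphabet",
    "AMINO_ACIDS",
    "DNA_BASES",
    "available_alphabets",
    "get_alphabet",
    "alphabet_from_classes",
    "load_alphabet_config",
    "translate",
]

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")
DNA_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class Alphabet:
    """A named partition of a residue set into disjoint classes.

    Parameters
    ----------
    name
        Short identifier, e.g. ``"se-v10"``.
    classes
        Ordered tuple of residue classes, each a string of member residues
        sorted alphabetically.
    """

    name: str
    classes: tuple[str, ...]
    representative_of: dict[str, str] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        rep: dict[str, str] = {}
        for cls in self.classes:
            if not cls:
                raise ValueError(f"alphabet {self.name!r}: empty class")
            members = sorted(cls)
            canonical = members[0]
            for residue in members:
                if residue in seen:
                    raise ValueError(
                        f"alphabet {self.name!r}: residue {residue!r} in two classes"
                    )
                seen.add(residue)
                rep[residue] = canonical
        object.__setattr__(self, "representative_of", rep)

    @property
    def size(self) -> int:
        """Number of classes (the r in the k-mer space size r**k)."""
        return len(self.classes)

    @property
    def residues(self) -> frozenset[str]:
        """All residues covered by the partition."""
        return frozenset(self.representative_of)

    @property
    def representatives(self) -> tuple[str, ...]:
        """Sorted canonical symbols, one per class."""
        return tuple(sorted({min(cls) for cls in self.classes}))

    def __contains__(self, residue: str) -> bool:
        return residue in self.representative_of


def _partition(name: str, spec: str, base: frozenset[str]) -> Alphabet:
    classes = tuple("".join(sorted(cls)) for cls in spec.split(","))
    alpha = Alphabet(name, classes)
    if alpha.residues != base:
        missing = "".join(sorted(base - alpha.residues))
        extra = "".join(sorted(alpha.residues - base))
        raise ValueError(
            f"alphabet {name!r} is not a partition of the base set "
            f"(missing={missing!r}, extra={extra!r})"
        )
    return alpha


_PROTEIN_TABLES: dict[str, str] = {
    "se-b14": "A,C,D,EQ,FY,G,H,IV,KR,LM,N,P,ST,W",
    "se-b10": "AST,C,DN,EQ,FY,G,HW,ILMV,KR,P",
    "se-v10": "AST,C,DEN,FY,G,H,ILMV,KQR,P,W",
    "li-a10": "AC,DE,FWY,G,HN,IV,KQR,LM,P,ST",
    "li-b10": "AST,C,DEQ,FWY,G,HN,IV,KR,LM,P",
    "solis-d10": "AM,C,DNS,EKQR,F,GP,HT,IV,LY,W",
    "solis-g10": "AEFIKLMQRVW,C,D,G,H,N,P,S,T,Y",
    "murphy10": "A,C,DENQ,FWY,G,H,ILMV,KR,P,ST",
    "se-b8": "AST,C,DHN,EKQR,FWY,G,ILMV,P",
    "se-b6": "AST,CP,DEHKNQR,FWY,G,ILMV",
    "dayhoff6": "AGPST,C,DENQ,FWY,HKR,ILMV",
}

_REGISTRY: dict[str, Alphabet] = {
    name: _partition(name, spec, AMINO_ACIDS) for name, spec in _PROTEIN_TABLES.items()
}
_REGISTRY["identity-protein"] = Alphabet(
    "identity-protein", tuple(sorted(AMINO_ACIDS))
)
_REGISTRY["identity-dna"] = Alphabet("identity-dna", tuple(sorted(DNA_BASES)))


def available_alphabets() -> list[str]:
    """Names accepted by :func:`get_alphabet`, sorted."""
    return sorted(_REGISTRY)


def get_alphabet(name: str) -> Alphabet:
    """Look up a built-in alphabet by name (case-insensitive).

    Raises
    ------
    KeyError
        If the name is unknown; the message lists the valid names.
    """
    key = name.strip().lower()
    try:
        return _REGISTRY[key]
    except KeyError:
        valid = ", ".join(available_alphabets())
        raise KeyError(f"unknown alphabet {name!r}; valid names: {valid}") from None


def alphabet_from_classes(name: str, classes: list[str]) -> Alphabet:
    """Build a user-defined alphabet from explicit residue classes.

    The classes must be disjoint; unlike the built-ins no base-set
    completeness is enforced, so partial partitions (e.g. RNA with U)
    are allowed.
    """
    return Alphabet(name, tuple("".join(sorted(c.upper())) for c in classes))


def load_alphabet_config(text: str) -> dict[str, Alphabet]:
    """Parse user alphabet definitions, one per line: ``NAME: CLASS,CLASS,...``.

    Blank lines and ``#`` comments are ignored.
    """
    result: dict[str, Alphabet] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if ":" not in line:
            raise ValueError(f"line {lineno}: expected 'NAME: CLASS,CLASS,...'")
        name, _, spec = line.partition(":")
        name = name.strip().lower()
        classes = [c.strip() for c in spec.split(",") if c.strip()]
        if not name or not classes:
            raise ValueError(f"line {lineno}: empty name or class list")
        result[name] = alphabet_from_classes(name, classes)
    return result


def translate(sequence: str, alphabet: Alphabet) -> str:
    """Map each residue of ``sequence`` to its class representative.

    Input is uppercased first. Residues outside the alphabet's base set
    (ambiguity codes, gaps, ...) are passed through unchanged; they are
    excluded later, at k-mer counting, which is the single point of
    filtering. Output length always equals input length.
    """
    rep = alphabet.representative_of
    return "".join(rep.get(ch, ch) for ch in sequence.upper())
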