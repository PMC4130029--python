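"""FASTA input and similarity-matrix output (TSV and lower-triangular PHYLIP)."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO

from .alphabets import DNA_BASES
from .matrix import SimilarityMatrix

__all__ = [
    "SequenceRecord",
    "read_fasta",
    "write_matrix",
    "read_matrix_tsv",
    "guess_molecule",
]


@dataclass(frozen=True)
class SequenceRecord:
    """One FASTA record: id (first header token) and uppercased sequence."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record with empty id")
        if not self.sequence:
            raise ValueError(f"record {self.id!r} has an empty sequence")


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a multi-FASTA file into records, preserving file order.

    Sequences are uppercased; duplicate ids are an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such FASTA file: {path}")
    records = [
        SequenceRecord(id=rec.id, sequence=str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
    return records


def guess_molecule(records: list[SequenceRecord]) -> str:
    """Classify input as 'dna' or 'protein' from residue content.

    A dataset whose residues (ignoring N and gaps) are all in {A, C, G, T}
    is treated as DNA; anything else as protein.
    """
    residues = set("".join(r.sequence for r in records)) - set("N-.*")
    return "dna" if residues <= DNA_BASES else "protein"


def write_matrix(
    matrix: SimilarityMatrix, path: str | Path, format: str = "tsv"
) -> None:
    """Write the lower-triangular similarity matrix to ``path``.

    ``tsv``: a header row of sequence ids, then one line per row i with
    the id and its j < i values at 6 decimal places (row 1 is the bare
    id). ``phylip-lower``: the sequence count on the first line, then one
    line per sequence with the id padded to 10 characters followed by its
    lower-triangle values.
    """
    path = Path(path)
    ids = matrix.sequence_ids
    lines: list[str] = []
    if format == "tsv":
        lines.append("\t".join(("id", *ids[: matrix.n_sequences - 1])))
        for i in range(1, matrix.n_sequences + 1):
            cells = [f"{v:.6f}" for v in matrix.row(i)]
            lines.append("\t".join((ids[i - 1], *cells)))
    elif format == "phylip-lower":
        lines.append(str(matrix.n_sequences))
        for i in range(1, matrix.n_sequences + 1):
            cells = [f"{v:.6f}" for v in matrix.row(i)]
            lines.append(" ".join((f"{ids[i - 1]:<10s}", *cells)).rstrip())
    else:
        raise ValueError(f"unknown format {format!r}; use 'tsv' or 'phylip-lower'")
    path.write_text("\n".join(lines) + "\n")


def read_matrix_tsv(path: str | Path) -> SimilarityMatrix:
    """Read back a TSV matrix written by :func:`write_matrix` (roundtrip)."""
    lines = Path(path).read_text().splitlines()
    if len(lines) < 3:
        raise ValueError(f"not a similarity-matrix TSV: {path}")
    ids: list[str] = []
    entries: dict[tuple[int, int], float] = {}
    for i, line in enumerate(lines[1:], start=1):
        fields = line.split("\t")
        ids.append(fields[0])
        values = [float(v) for v in fields[1:]]
        if len(values) != i - 1:
            raise ValueError(f"row {i} has {len(values)} values, expected {i - 1}")
        for j, v in enumerate(values, start=1):
            entries[(i, j)] = v
    return SimilarityMatrix(sequence_ids=tuple(ids), entries=entries)
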