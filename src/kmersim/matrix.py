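"""All-pairs similarity matrix: sequential and master-worker parallel builds.

F(X, Y) is symmetric, so only the strict lower triangle is computed and
stored: entry (i, j) for 1 <= j < i <= n, n(n-1)/2 values in total.

The parallel scheme is a static master-worker design. Matrix rows
1..n are dealt cyclically to p workers (row i goes to worker
((i-1) mod p) + 1), every worker sees the whole sequence set (the
master broadcasts it once), computes its rows, and returns all its F
values concatenated into one flat vector — a single message per worker.
The master reassembles the triangle from those vectors. Because every
entry is an integer ratio evaluated in one floating-point division, the
assembled matrix is bit-identical to the sequential one for any worker
count and any arrival order.
"""

from __future__ import annotations

import multiprocessing
from dataclasses import dataclass

import numpy as np

from .alphabets import Alphabet
from .kmer import similarity

__all__ = [
    "SimilarityMatrix",
    "RowAssignment",
    "WorkerResultVector",
    "compute_matrix_sequential",
    "assign_rows",
    "compute_worker_rows",
    "assemble_matrix",
    "compute_matrix_parallel",
]


@dataclass(frozen=True)
class SimilarityMatrix:
    """Strictly-lower-triangular matrix of pairwise similarities.

    ``entries`` maps the 1-based ordered pair (i, j), j < i, to F(i, j).
    """

    sequence_ids: tuple[str, ...]
    entries: dict[tuple[int, int], float]

    def __post_init__(self) -> None:
        n = self.n_sequences
        expected = {(i, j) for i in range(1, n + 1) for j in range(1, i)}
        if set(self.entries) != expected:
            raise ValueError(
                f"expected exactly the {n * (n - 1) // 2} strict lower-triangle "
                f"pairs for n={n}"
            )
        for pair, value in self.entries.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"similarity {value} at {pair} outside [0, 1]")

    @property
    def n_sequences(self) -> int:
        return len(self.sequence_ids)

    def value(self, i: int, j: int) -> float:
        """F between sequences i and j (1-based, order-free); 1.0 on the diagonal."""
        if i == j:
            return 1.0
        if i < j:
            i, j = j, i
        return self.entries[(i, j)]

    def row(self, i: int) -> list[float]:
        """The stored row i: values for j = 1..i-1 (empty for row 1)."""
        return [self.entries[(i, j)] for j in range(1, i)]

    def to_square_array(self) -> np.ndarray:
        """Dense symmetric numpy array with unit diagonal (for downstream use)."""
        n = self.n_sequences
        out = np.eye(n)
        for (i, j), v in self.entries.items():
            out[i - 1, j - 1] = out[j - 1, i - 1] = v
        return out


@dataclass(frozen=True)
class RowAssignment:
    """Cyclic (round-robin) distribution of matrix rows to workers.

    Worker w (1-based) owns exactly the rows i with (i-1) mod p == w - 1,
    p being the worker count. The per-worker row lists are ascending and
    together partition {1..n_rows}; workers beyond n_rows get nothing.
    """

    n_rows: int
    n_workers: int

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_workers < 1:
            raise ValueError("n_rows and n_workers must be positive")

    def rows_of(self, worker_id: int) -> list[int]:
        self._check_worker(worker_id)
        return list(range(worker_id, self.n_rows + 1, self.n_workers))

    def worker_of(self, row: int) -> int:
        if not 1 <= row <= self.n_rows:
            raise ValueError(f"row {row} outside 1..{self.n_rows}")
        return (row - 1) % self.n_workers + 1

    def _check_worker(self, worker_id: int) -> None:
        if not 1 <= worker_id <= self.n_workers:
            raise ValueError(
                f"worker id {worker_id} outside 1..{self.n_workers}"
            )


def assign_rows(n_rows: int, n_workers: int) -> RowAssignment:
    """Deal rows 1..n_rows cyclically to workers 1..n_workers.

    With 7 rows and 3 workers: worker 1 gets rows 1, 4, 7; worker 2 gets
    2 and 5; worker 3 gets 3 and 6.
    """
    return RowAssignment(n_rows=n_rows, n_workers=n_workers)


@dataclass(frozen=True)
class WorkerResultVector:
    """One worker's entire result, flattened into a single vector.

    Rows are concatenated in ascending order; row i contributes its i-1
    values in column order j = 1..i-1. Row 1, if assigned, contributes
    nothing (the triangle is strict).
    """

    worker_id: int
    values: tuple[float, ...]

    @staticmethod
    def expected_length(assignment: RowAssignment, worker_id: int) -> int:
        return sum(i - 1 for i in assignment.rows_of(worker_id))


def compute_matrix_sequential(
    sequences: list[str], k: int, alphabet: Alphabet,
    sequence_ids: list[str] | None = None,
) -> SimilarityMatrix:
    """Double loop over the strict lower triangle; each pair computed once."""
    ids = _resolve_ids(sequences, sequence_ids)
    entries = {
        (i, j): similarity(sequences[i - 1], sequences[j - 1], k, alphabet)
        for i in range(1, len(sequences) + 1)
        for j in range(1, i)
    }
    return SimilarityMatrix(sequence_ids=ids, entries=entries)


def compute_worker_rows(
    sequences: list[str],
    assignment: RowAssignment,
    worker_id: int,
    k: int,
    alphabet: Alphabet,
) -> WorkerResultVector:
    """Compute one worker's assigned rows into a flat result vector."""
    if assignment.n_rows != len(sequences):
        raise ValueError(
            f"assignment covers {assignment.n_rows} rows but there are "
            f"{len(sequences)} sequences"
        )
    values: list[float] = []
    for i in assignment.rows_of(worker_id):
        for j in range(1, i):
            values.append(similarity(sequences[i - 1], sequences[j - 1], k, alphabet))
    return WorkerResultVector(worker_id=worker_id, values=tuple(values))


def assemble_matrix(
    result_vectors: list[WorkerResultVector],
    assignment: RowAssignment,
    sequence_ids: list[str] | None = None,
) -> SimilarityMatrix:
    """Rebuild the triangle from one result vector per worker.

    Arrival order of the vectors is irrelevant; each carries its worker
    id. A missing worker or a vector of the wrong length is an error
    naming the worker.
    """
    by_worker = {v.worker_id: v for v in result_vectors}
    if len(by_worker) != len(result_vectors):
        raise ValueError("duplicate worker id among result vectors")
    entries: dict[tuple[int, int], float] = {}
    for w in range(1, assignment.n_workers + 1):
        if w not in by_worker:
            raise ValueError(f"missing result vector for worker {w}")
        vec = by_worker[w]
        expected = WorkerResultVector.expected_length(assignment, w)
        if len(vec.values) != expected:
            raise ValueError(
                f"worker {w} returned {len(vec.values)} values, expected {expected}"
            )
        cursor = 0
        for i in assignment.rows_of(w):
            for j in range(1, i):
                entries[(i, j)] = vec.values[cursor]
                cursor += 1
    if sequence_ids is None:
        sequence_ids = [f"seq{i}" for i in range(1, assignment.n_rows + 1)]
    return SimilarityMatrix(sequence_ids=tuple(sequence_ids), entries=entries)


def _worker_task(args: tuple) -> WorkerResultVector:
    sequences, assignment, worker_id, k, alphabet = args
    return compute_worker_rows(sequences, assignment, worker_id, k, alphabet)


def compute_matrix_parallel(
    sequences: list[str],
    k: int,
    alphabet: Alphabet,
    n_workers: int,
    backend: str = "serial-emulation",
    sequence_ids: list[str] | None = None,
) -> SimilarityMatrix:
    """Master-worker build of the similarity matrix.

    ``backend="serial-emulation"`` runs the workers one after another in
    the master process (the default; exercises the full distribute/pack/
    assemble path without process overhead). ``backend="process"`` runs
    each worker in its own process; the full sequence set is shipped to
    every worker and each returns its single flat result vector.

    The result is identical to :func:`compute_matrix_sequential` for any
    backend and worker count.
    """
    ids = _resolve_ids(sequences, sequence_ids)
    if n_workers < 1:
        raise ValueError("n_workers must be >= 1")
    assignment = assign_rows(len(sequences), n_workers)
    tasks = [
        (sequences, assignment, w, k, alphabet)
        for w in range(1, n_workers + 1)
    ]
    if backend == "serial-emulation":
        vectors = [_worker_task(t) for t in tasks]
    elif backend == "process":
        with multiprocessing.Pool(processes=n_workers) as pool:
            vectors = pool.map(_worker_task, tasks)
    else:
        raise ValueError(
            f"unknown backend {backend!r}; use 'serial-emulation' or 'process'"
        )
    return assemble_matrix(vectors, assignment, sequence_ids=list(ids))


def _resolve_ids(
    sequences: list[str], sequence_ids: list[str] | None
) -> tuple[str, ...]:
    if len(sequences) < 2:
        raise ValueError("need at least two sequences")
    if sequence_ids is None:
        return tuple(f"seq{i}" for i in range(1, len(sequences) + 1))
    if len(sequence_ids) != len(sequences):
        raise ValueError("sequence_ids length must match sequences")
    return tuple(sequence_ids)
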