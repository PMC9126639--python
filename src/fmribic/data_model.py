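"""Core containers for Region x Time matrices and biclusters.

A *bicluster* is a submatrix of a data matrix ``A`` (``n`` region rows by
``p`` time-point columns) selected by a row index set ``I`` and a column
index set ``J``.  Search algorithms typically operate on a discretized or
otherwise transformed copy of ``A``; before any quality index is computed,
every bicluster is *materialized* back onto the original real values, so
that indices always refer to ``A`` and the stored submatrix equals
``A[I, J]`` exactly.

The post-processing protocol applied to every algorithm's raw output is:

1. materialize on the original matrix (:func:`materialize_bicluster`),
2. drop biclusters with fewer than two rows or two columns
   (:func:`filter_min_size`),
3. collapse exact duplicates from repeated stochastic runs (:func:`dedupe`),
4. pool per-scan results into one collection-level set
   (:func:`union_collection`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "Provenance",
    "DataMatrix",
    "Bicluster",
    "BiclusterSet",
    "materialize_bicluster",
    "filter_min_size",
    "dedupe",
    "union_collection",
]


@dataclass(frozen=True)
class Provenance:
    """Where a bicluster came from: algorithm name, run index and scan id."""

    algorithm: str = ""
    run: int = 0
    scan: str = ""


@dataclass(frozen=True)
class DataMatrix:
    """A real-valued Region x Time matrix with row/column labels.

    Rows are brain regions (or genes, for transcriptomics matrices), columns
    are time points.  Values must be finite; both dimensions must be at
    least 2.
    """

    values: np.ndarray
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    matrix_id: str = "scan"

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 2:
            raise ValueError(f"matrix must be 2-D, got ndim={vals.ndim}")
        n, p = vals.shape
        if n < 2 or p < 2:
            raise ValueError(f"matrix must be at least 2x2, got {n}x{p}")
        if not np.all(np.isfinite(vals)):
            raise ValueError("matrix contains non-finite values")
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "row_labels", tuple(str(r) for r in self.row_labels))
        object.__setattr__(self, "col_labels", tuple(str(c) for c in self.col_labels))
        if len(self.row_labels) != n:
            raise ValueError(
                f"{len(self.row_labels)} row labels for {n} rows"
            )
        if len(self.col_labels) != p:
            raise ValueError(
                f"{len(self.col_labels)} column labels for {p} columns"
            )
        if len(set(self.row_labels)) != n:
            raise ValueError("row labels are not unique")
        if len(set(self.col_labels)) != p:
            raise ValueError("column labels are not unique")

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    @property
    def n_time(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class Bicluster:
    """A materialized bicluster: sorted index sets plus the original values.

    ``values`` is always the submatrix of the source matrix at
    ``rows x cols`` — never discretized or normalized data.
    """

    rows: tuple[int, ...]
    cols: tuple[int, ...]
    values: np.ndarray
    matrix_id: str = ""
    provenance: Provenance = field(default_factory=Provenance)

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.cols)

    @property
    def area(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def key(self) -> tuple[str, tuple[int, ...], tuple[int, ...]]:
        """Identity key (scan, I, J) used for deduplication."""
        scan = self.provenance.scan or self.matrix_id
        return (scan, self.rows, self.cols)


def materialize_bicluster(
    matrix: DataMatrix,
    rows: Iterable[int],
    cols: Iterable[int],
    provenance: Provenance | None = None,
) -> Bicluster:
    """Build a bicluster from index sets, copying the original values.

    Indices are canonicalized (sorted ascending, duplicates removed) and
    checked against the matrix bounds.  Raises ``IndexError`` naming the
    offending index, or ``ValueError`` for an empty index set.
    """
    r = sorted(set(int(i) for i in rows))
    c = sorted(set(int(j) for j in cols))
    if not r or not c:
        raise ValueError("bicluster row and column sets must be non-empty")
    n, p = matrix.shape
    for i in r:
        if i < 0 or i >= n:
            raise IndexError(f"row index {i} out of range for {n} rows")
    for j in c:
        if j < 0 or j >= p:
            raise IndexError(f"column index {j} out of range for {p} columns")
    prov = provenance or Provenance(scan=matrix.matrix_id)
    if not prov.scan:
        prov = replace(prov, scan=matrix.matrix_id)
    return Bicluster(
        rows=tuple(r),
        cols=tuple(c),
        values=matrix.values[np.ix_(r, c)].copy(),
        matrix_id=matrix.matrix_id,
        provenance=prov,
    )


@dataclass
class BiclusterSet:
    """An ordered collection of biclusters, typically one per (scan, algorithm)
    or the pooled union over a whole data collection."""

    biclusters: list[Bicluster] = field(default_factory=list)
    collection_id: str = ""

    def __len__(self) -> int:
        return len(self.biclusters)

    def __iter__(self) -> Iterator[Bicluster]:
        return iter(self.biclusters)

    def __getitem__(self, idx: int) -> Bicluster:
        return self.biclusters[idx]


def filter_min_size(
    bset: BiclusterSet, min_rows: int = 2, min_cols: int = 2
) -> BiclusterSet:
    """Drop biclusters with fewer than ``min_rows`` rows or ``min_cols`` columns.

    Biclusters spanning a single row or column carry no row-coherence
    information and are treated as uninteresting.  Order is preserved.
    """
    kept = [
        b
        for b in bset
        if b.n_rows >= min_rows and b.n_cols >= min_cols
    ]
    return BiclusterSet(kept, collection_id=bset.collection_id)


def dedupe(bset: BiclusterSet) -> BiclusterSet:
    """Collapse exact (scan, I, J) duplicates, keeping the first occurrence.

    Repeated stochastic runs of greedy algorithms frequently rediscover the
    same bicluster; statistics over the pooled set should count it once.
    Idempotent and order-stable.
    """
    seen: set[tuple] = set()
    kept: list[Bicluster] = []
    for b in bset:
        if b.key not in seen:
            seen.add(b.key)
            kept.append(b)
    return BiclusterSet(kept, collection_id=bset.collection_id)


def union_collection(
    per_scan_sets: Sequence[BiclusterSet], collection_id: str = ""
) -> BiclusterSet:
    """Pool per-scan bicluster sets into one collection-level set.

    Concatenates in the given order, then dedupes.  All inputs must carry
    the same (possibly empty) collection id; mixing collections is an error.
    """
    ids = {s.collection_id for s in per_scan_sets if s.collection_id}
    if len(ids) > 1:
        raise ValueError(f"mixed collection ids: {sorted(ids)}")
    if not collection_id and ids:
        collection_id = next(iter(ids))
    merged = BiclusterSet(
        [b for s in per_scan_sets for b in s], collection_id=collection_id
    )
    return dedupe(merged)
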