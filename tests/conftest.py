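"""Shared fixtures and independent brute-force oracles."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from fmribic import DataMatrix, materialize_bicluster


def make_matrix(values, matrix_id: str = "m") -> DataMatrix:
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    return DataMatrix(
        values=values,
        row_labels=tuple(f"r{i}" for i in range(n)),
        col_labels=tuple(f"c{j}" for j in range(p)),
        matrix_id=matrix_id,
    )


def full_bicluster(values):
    """Materialize the whole of a small matrix as one bicluster."""
    m = make_matrix(values)
    return materialize_bicluster(m, range(m.n_regions), range(m.n_time))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


# ---------------------------------------------------------------------------
# Brute-force oracles (deliberately naive; independent of the implementations)
# ---------------------------------------------------------------------------

def brute_force_ccc(symbols: np.ndarray) -> set[tuple[tuple[int, ...], tuple[int, ...]]]:
    """All containment-maximal (rows, contiguous column interval) pairs where
    every row carries the same symbol string, with >=2 rows and columns."""
    n, p = symbols.shape
    candidates = []
    for j1 in range(p):
        for j2 in range(j1 + 1, p):
            for size in range(2, n + 1):
                for rows in itertools.combinations(range(n), size):
                    sub = symbols[list(rows), j1 : j2 + 1]
                    if np.all(sub == sub[0]):
                        candidates.append((frozenset(rows), j1, j2))
    maximal = set()
    for rows, j1, j2 in candidates:
        contained = any(
            (rows, j1, j2) != (r2, a2, b2) and rows <= r2 and a2 <= j1 and j2 <= b2
            for r2, a2, b2 in candidates
        )
        if not contained:
            maximal.add((tuple(sorted(rows)), tuple(range(j1, j2 + 1))))
    return maximal


def brute_force_bimax(binary: np.ndarray) -> set[tuple[tuple[int, ...], tuple[int, ...]]]:
    """All inclusion-maximal all-ones submatrices with >=2 rows and columns,
    via closure of every row subset."""
    n, p = binary.shape
    out = set()
    for size in range(2, n + 1):
        for rows in itertools.combinations(range(n), size):
            cols = tuple(j for j in range(p) if all(binary[i, j] for i in rows))
            if len(cols) < 2:
                continue
            closed_rows = tuple(
                i for i in range(n) if all(binary[i, j] for j in cols)
            )
            if closed_rows == rows:
                out.add((rows, cols))
    return out
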