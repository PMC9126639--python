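"""Internal quality indices for biclusters.

Four indices, each tuned to one family of coherent patterns:

* ``variance`` (VAR) — mean squared deviation from the bicluster mean;
  zero only for *constant* biclusters ``b_ij = pi``.
* ``msr`` — Cheng–Church mean squared residue; zero for *shifting*
  (additive) biclusters ``b_ij = pi_i + beta_j``.
* ``smsr`` — scaling mean squared residue; zero for *scaling*
  (multiplicative) biclusters ``b_ij = pi_i * beta_j`` with nonzero
  row/column means, undefined (NaN) when any row or column mean is zero.
* ``virtual_error`` (VE) — mean absolute deviation of the row-standardized
  bicluster from its *virtual pattern* (the column-wise mean of the
  standardized rows, i.e. the average temporal behaviour).  VE is zero for
  every bicluster whose rows are positive affine transforms of one another,
  which covers both shifting and positive-scaling patterns, and it grows
  roughly linearly with induced noise — making it the most pattern-agnostic
  of the four.

Standardization uses the population standard deviation (divide by the cell
count): it is a descriptive normalizer, not an inferential estimate.
Constant rows (sd = 0) are mapped to all-zero rows and recorded as
degenerate, so a perfectly constant bicluster scores VE = 0 rather than
raising a division error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import Bicluster, BiclusterSet

__all__ = [
    "BiclusterMoments",
    "StandardizedBicluster",
    "VirtualPattern",
    "MetricsRecord",
    "moments",
    "variance",
    "msr",
    "smsr",
    "standardize_rows",
    "virtual_pattern",
    "virtual_error",
    "compute_all",
    "records_to_frame",
]


@dataclass(frozen=True)
class BiclusterMoments:
    """Row means ``b_iJ``, column means ``b_Ij`` and overall mean ``b_IJ``."""

    row_means: np.ndarray
    col_means: np.ndarray
    overall_mean: float


@dataclass(frozen=True)
class StandardizedBicluster:
    """Row-standardized values plus the per-row moments that produced them.

    Rows with zero standard deviation are set to all-zero and listed in
    ``degenerate_rows`` (positions within the bicluster, not matrix indices).
    """

    values: np.ndarray
    row_means_used: np.ndarray
    row_sds_used: np.ndarray
    degenerate_rows: tuple[int, ...]


@dataclass(frozen=True)
class VirtualPattern:
    """The average standardized temporal behaviour, one value per column."""

    values: np.ndarray


@dataclass(frozen=True)
class MetricsRecord:
    """All four quality indices plus size descriptors for one bicluster."""

    bicluster: Bicluster
    var: float
    msr: float
    smsr: float  # NaN when undefined (zero row/column mean)
    ve: float
    n_rows: int
    n_cols: int
    area: int

    @property
    def algorithm(self) -> str:
        return self.bicluster.provenance.algorithm

    @property
    def run(self) -> int:
        return self.bicluster.provenance.run

    @property
    def scan(self) -> str:
        return self.bicluster.provenance.scan or self.bicluster.matrix_id


def moments(b: Bicluster) -> BiclusterMoments:
    """Arithmetic means over the bicluster's rows, columns and all cells."""
    v = b.values
    return BiclusterMoments(
        row_means=v.mean(axis=1),
        col_means=v.mean(axis=0),
        overall_mean=float(v.mean()),
    )


def variance(b: Bicluster, grand_mean: float | None = None) -> float:
    """Mean squared deviation of the cells from their mean.

    By default deviations are taken from the bicluster's own mean, which
    makes VAR zero exactly for constant biclusters.  Passing ``grand_mean``
    centers on an externally supplied constant instead (e.g. the full data
    matrix mean, an alternative reading under which VAR measures departure
    from the global background level).
    """
    v = b.values
    center = float(v.mean()) if grand_mean is None else float(grand_mean)
    return float(np.mean((v - center) ** 2))


def msr(b: Bicluster) -> float:
    """Mean squared residue: mean of ``(b_ij - b_iJ - b_Ij + b_IJ)^2``.

    Zero for every additive (shifting) bicluster; insensitive to adding
    per-row and per-column constants.
    """
    v = b.values
    resid = v - v.mean(axis=1, keepdims=True) - v.mean(axis=0, keepdims=True) + v.mean()
    return float(np.mean(resid**2))


def smsr(b: Bicluster) -> float:
    """Scaling mean squared residue.

    Mean of ``(b_iJ * b_Ij - b_ij * b_IJ)^2 / (b_iJ^2 * b_Ij^2)``; zero for
    every multiplicative (scaling) bicluster with nonzero means.  Returns
    NaN when any row or column mean is zero — the index is undefined there,
    and padding the denominator would only manufacture arbitrary magnitudes.
    """
    v = b.values
    row_m = v.mean(axis=1)
    col_m = v.mean(axis=0)
    if np.any(row_m == 0.0) or np.any(col_m == 0.0):
        return math.nan
    overall = v.mean()
    num = (row_m[:, None] * col_m[None, :] - v * overall) ** 2
    den = row_m[:, None] ** 2 * col_m[None, :] ** 2
    return float(np.mean(num / den))


def standardize_rows(b: Bicluster) -> StandardizedBicluster:
    """Z-score each row over the bicluster's columns (population sd).

    Rows with zero spread are mapped to all-zero and flagged degenerate.
    """
    v = b.values
    mu = v.mean(axis=1)
    sd = v.std(axis=1)  # population convention (ddof=0)
    # a row of identical values can still have sd ~1e-16 when its mean
    # rounds inexactly; range == 0 identifies exact constancy regardless
    flat = v.max(axis=1) == v.min(axis=1)
    degenerate = np.flatnonzero(flat | (sd == 0.0))
    safe_sd = np.where(sd == 0.0, 1.0, sd)
    z = (v - mu[:, None]) / safe_sd[:, None]
    z[degenerate, :] = 0.0
    return StandardizedBicluster(
        values=z,
        row_means_used=mu,
        row_sds_used=sd,
        degenerate_rows=tuple(int(i) for i in degenerate),
    )


def virtual_pattern(s: StandardizedBicluster) -> VirtualPattern:
    """Column-wise mean of the standardized rows."""
    return VirtualPattern(values=s.values.mean(axis=0))


def virtual_error(b: Bicluster) -> float:
    """Mean absolute deviation of standardized rows from the virtual pattern.

    Degenerate (constant) rows participate as all-zero rows: a fully
    constant bicluster therefore scores 0, consistent with constant being a
    degenerate shifting pattern.
    """
    s = standardize_rows(b)
    rho = virtual_pattern(s)
    return float(np.mean(np.abs(s.values - rho.values[None, :])))


def compute_all(bset: BiclusterSet) -> list[MetricsRecord]:
    """One :class:`MetricsRecord` per bicluster, input order preserved."""
    out: list[MetricsRecord] = []
    for b in bset:
        out.append(
            MetricsRecord(
                bicluster=b,
                var=variance(b),
                msr=msr(b),
                smsr=smsr(b),
                ve=virtual_error(b),
                n_rows=b.n_rows,
                n_cols=b.n_cols,
                area=b.area,
            )
        )
    return out


def records_to_frame(records: list[MetricsRecord]) -> pd.DataFrame:
    """Tabulate records as a DataFrame (undefined SMSR becomes NaN)."""
    return pd.DataFrame(
        {
            "scan": [r.scan for r in records],
            "algorithm": [r.algorithm for r in records],
            "run": [r.run for r in records],
            "n_rows": [r.n_rows for r in records],
            "n_cols": [r.n_cols for r in records],
            "area": [r.area for r in records],
            "var": [r.var for r in records],
            "msr": [r.msr for r in records],
            "smsr": [r.smsr for r in records],
            "ve": [r.ve for r in records],
        }
    )
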