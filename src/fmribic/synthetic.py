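"""Synthetic fMRI-like scans with planted coherent biclusters.

Each scan is a Region x Time matrix built from three ingredients:

1. a per-region smooth baseline (Gaussian-filtered white noise, rescaled to
   a target amplitude) — a transparent stand-in for slow spontaneous
   fluctuations of parcellated BOLD signals;
2. planted coherent blocks — constant (``pi``), shifting (``pi_i + beta_j``)
   or scaling (``pi_i * beta_j``) submatrices that by default *overwrite*
   the baseline on their cells, so that at zero noise the type-matching
   quality index of each block is exactly zero;
3. i.i.d. Gaussian observation noise over the whole matrix.

Shifting-block time profiles alternate in sign with magnitudes bounded away
from zero (event-like on/off responses): consecutive time-point changes are
then large relative to realistic noise levels, and the block's symbolic
transition signature is jagged enough that smooth background rows virtually
never match it by chance.  Constant blocks sit well above the baseline
range (elevated plateaus), and scaling blocks use strictly positive
log-uniform effects spanning a 9-fold dynamic range, so their virtual
error is exactly zero while their multiplicative structure is genuinely
distinct from an additive one.

Default collection geometry is 20 scans of 30 regions x 150 time points
(the artificial-scale setting); a real-scale preset of 463 regions x 94
time points is available for scalability checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .data_model import Bicluster, BiclusterSet, DataMatrix

__all__ = [
    "PlantedBicluster",
    "BlockSpec",
    "ScanSpec",
    "REAL_SCALE",
    "generate_scan",
    "generate_collection",
    "recovery_score",
    "best_recovery",
]


@dataclass(frozen=True)
class PlantedBicluster:
    """Ground truth for one planted block.

    ``pattern_values()`` reconstructs the noise-free cell values:
    constant -> ``base_level``; shifting -> ``pi_i + beta_j``;
    scaling -> ``pi_i * beta_j``.
    """

    rows: tuple[int, ...]
    cols: tuple[int, ...]
    pattern_type: str  # "constant" | "shifting" | "scaling"
    row_effects: tuple[float, ...] = ()
    col_effects: tuple[float, ...] = ()
    base_level: float = 0.0
    matrix_id: str = ""

    def pattern_values(self) -> np.ndarray:
        if self.pattern_type == "constant":
            return np.full((len(self.rows), len(self.cols)), self.base_level)
        pi = np.asarray(self.row_effects)[:, None]
        beta = np.asarray(self.col_effects)[None, :]
        if self.pattern_type == "shifting":
            return pi + beta
        if self.pattern_type == "scaling":
            return pi * beta
        raise ValueError(f"unknown pattern type {self.pattern_type!r}")

    @property
    def area(self) -> int:
        return len(self.rows) * len(self.cols)


@dataclass(frozen=True)
class BlockSpec:
    """How to draw one planted block.

    ``amplitude`` scales all drawn effects.  With ``rows``/``cols`` unset,
    placement is random: rows sampled without replacement (disjoint from
    previously planted blocks), columns a random contiguous interval
    (``contiguous=False`` samples a general column set instead).
    ``negative_scaling`` allows sign-flipped scaling effects, an adversarial
    setting under which the virtual error of a perfect block is no longer
    zero.
    """

    n_rows: int = 10
    n_cols: int = 25
    pattern_type: str = "shifting"
    amplitude: float = 1.0
    rows: tuple[int, ...] | None = None
    cols: tuple[int, ...] | None = None
    contiguous: bool = True
    negative_scaling: bool = False


@dataclass(frozen=True)
class ScanSpec:
    """Full recipe for one synthetic scan.

    Baseline smoothness is the Gaussian kernel sd in time points; amplitude
    is the per-row baseline standard deviation and ``baseline_mean`` the
    overall signal level (signal units; raw BOLD-like data is positive, so
    multiplicative-pattern studies should use a mean well above zero —
    scaling structure, like the SMSR index itself, is only meaningful for
    signals bounded away from zero).  With
    ``superpose=True`` planted patterns are added on top of the baseline
    instead of overwriting it (zero-noise metric identities then no longer
    hold exactly).
    """

    n_regions: int = 30
    n_time: int = 150
    noise_sd: float = 0.1
    baseline_smoothness: float = 3.0
    baseline_amplitude: float = 1.0
    baseline_mean: float = 0.0
    blocks: tuple[BlockSpec, ...] = ()
    seed: int = 0
    superpose: bool = False


#: Shape preset mirroring the real-data scale (for scalability testing).
REAL_SCALE = dict(n_regions=463, n_time=94)


def _smooth_baseline(
    rng: np.random.Generator, n: int, p: int, smoothness: float, amplitude: float
) -> np.ndarray:
    """Per-row Gaussian-filtered white noise with mean 0 and sd = amplitude."""
    if amplitude == 0.0:
        return np.zeros((n, p))
    half = max(1, int(round(4 * smoothness)))
    t = np.arange(-half, half + 1)
    kernel = np.exp(-0.5 * (t / max(smoothness, 1e-9)) ** 2)
    kernel /= kernel.sum()
    raw = rng.standard_normal((n, p + 2 * half))
    base = np.empty((n, p))
    for i in range(n):
        base[i] = np.convolve(raw[i], kernel, mode="valid")[:p]
    base -= base.mean(axis=1, keepdims=True)
    sd = base.std(axis=1, keepdims=True)
    sd[sd == 0.0] = 1.0
    return base / sd * amplitude


def _draw_block(
    rng: np.random.Generator,
    spec: BlockSpec,
    n: int,
    p: int,
    used_rows: set[int],
    matrix_id: str,
) -> PlantedBicluster:
    if spec.rows is not None:
        rows = tuple(sorted(int(i) for i in spec.rows))
    else:
        free = sorted(set(range(n)) - used_rows)
        if len(free) < spec.n_rows:
            raise ValueError(
                f"cannot place {spec.n_rows}-row block: only {len(free)} free rows"
            )
        rows = tuple(sorted(rng.choice(free, size=spec.n_rows, replace=False).tolist()))
    if spec.cols is not None:
        cols = tuple(sorted(int(j) for j in spec.cols))
    elif spec.contiguous:
        if spec.n_cols > p:
            raise ValueError(f"block of {spec.n_cols} columns exceeds {p} time points")
        start = int(rng.integers(0, p - spec.n_cols + 1))
        cols = tuple(range(start, start + spec.n_cols))
    else:
        cols = tuple(sorted(rng.choice(p, size=spec.n_cols, replace=False).tolist()))
    if not rows or not cols:
        raise ValueError("planted block must have at least one row and column")
    if rows[0] < 0 or rows[-1] >= n or cols[0] < 0 or cols[-1] >= p:
        raise ValueError(
            f"planted block {rows[0]}..{rows[-1]} x {cols[0]}..{cols[-1]} "
            f"exceeds matrix bounds {n}x{p}"
        )

    amp = spec.amplitude
    kind = spec.pattern_type
    nr, nc = len(rows), len(cols)
    if kind == "constant":
        level = float(rng.choice([-1.0, 1.0]) * rng.uniform(2.5, 3.5) * amp)
        return PlantedBicluster(rows, cols, "constant", (), (), level, matrix_id)
    if kind == "shifting":
        pi = rng.normal(0.0, amp, size=nr)
        signs = np.where(np.arange(nc) % 2 == 0, 1.0, -1.0)
        if rng.integers(0, 2) == 1:
            signs = -signs
        beta = signs * rng.uniform(0.5, 1.5, size=nc) * amp
        return PlantedBicluster(
            rows, cols, "shifting", tuple(pi.tolist()), tuple(beta.tolist()), 0.0, matrix_id
        )
    if kind == "scaling":
        # log-uniform factors over a 9-fold dynamic range: a multiplicative
        # pattern with near-unit gains would be indistinguishable from an
        # additive one, so scaling blocks get genuinely wide row/column gains
        pi = np.exp(rng.uniform(np.log(1 / 3), np.log(3), size=nr))
        beta = np.exp(rng.uniform(np.log(1 / 3), np.log(3), size=nc)) * amp
        if spec.negative_scaling:
            beta *= rng.choice([-1.0, 1.0], size=nc)
        return PlantedBicluster(
            rows, cols, "scaling", tuple(pi.tolist()), tuple(beta.tolist()), 0.0, matrix_id
        )
    raise ValueError(f"unknown pattern type {kind!r}")


def generate_scan(
    spec: ScanSpec, matrix_id: str = "scan"
) -> tuple[DataMatrix, list[PlantedBicluster]]:
    """Generate one scan and its ground truth; deterministic for a fixed seed."""
    if spec.noise_sd < 0:
        raise ValueError(f"noise_sd must be non-negative, got {spec.noise_sd}")
    n, p = spec.n_regions, spec.n_time
    rng = np.random.default_rng(spec.seed)
    values = spec.baseline_mean + _smooth_baseline(
        rng, n, p, spec.baseline_smoothness, spec.baseline_amplitude
    )

    truth: list[PlantedBicluster] = []
    used_rows: set[int] = set()
    for bs in spec.blocks:
        planted = _draw_block(rng, bs, n, p, used_rows, matrix_id)
        used_rows.update(planted.rows)
        block = planted.pattern_values()
        idx = np.ix_(planted.rows, planted.cols)
        if spec.superpose:
            values[idx] += block
        else:
            values[idx] = block
        truth.append(planted)

    if spec.noise_sd > 0:
        values = values + rng.normal(0.0, spec.noise_sd, size=(n, p))

    matrix = DataMatrix(
        values=values,
        row_labels=tuple(f"R{i:03d}" for i in range(n)),
        col_labels=tuple(f"T{j:03d}" for j in range(p)),
        matrix_id=matrix_id,
    )
    return matrix, truth


def generate_collection(
    template: ScanSpec,
    n_scans: int = 20,
    seed: int = 0,
    collection_id: str = "collection",
) -> list[tuple[DataMatrix, list[PlantedBicluster]]]:
    """Generate a collection of scans with per-scan seeds derived from ``seed``."""
    if n_scans < 1:
        raise ValueError("n_scans must be >= 1")
    master = np.random.default_rng(seed)
    scan_seeds = master.integers(0, 2**31 - 1, size=n_scans)
    out = []
    for i in range(n_scans):
        scan_spec = replace(template, seed=int(scan_seeds[i]))
        mid = f"{collection_id}-scan{i:02d}"
        out.append(generate_scan(scan_spec, matrix_id=mid))
    return out


def recovery_score(found: Bicluster, truth: PlantedBicluster) -> float:
    """Jaccard index of the two cell sets (I x J viewed as sets of cells)."""
    ri = len(set(found.rows) & set(truth.rows))
    ci = len(set(found.cols) & set(truth.cols))
    inter = ri * ci
    union = found.area + truth.area - inter
    return inter / union if union else 0.0


def best_recovery(found: BiclusterSet, truth: PlantedBicluster) -> float:
    """Best Jaccard recovery of ``truth`` over a set of found biclusters."""
    if len(found) == 0:
        return 0.0
    return max(recovery_score(b, truth) for b in found)
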