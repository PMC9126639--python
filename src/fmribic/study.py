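"""Pre-configured study protocols built from the library primitives.

These are the standard experiments the package runs on its own synthetic
collections:

* :func:`ccc_recovery` — plant shifting blocks, run CCC on transition
  symbols, score each planted block by its best Jaccard recovery.
* :func:`planted_block_population` — a bicluster population emulating
  imperfect algorithm output: every planted block plus variants diluted
  with extra background rows and columns.  Used for pattern-type
  inference studies (the dilution gradient makes the quality indices vary
  jointly with the virtual error).
* :func:`run_algorithm_suite` / :func:`benchmark_collection` — the full
  biclustering-vs-clustering comparison on one scan / one collection.

Problem sizes default to a handful of scans so a full benchmark stays in
the tens of seconds; the artificial-collection geometry itself (30
regions x 150 time points, 20 scans) is in :class:`~fmribic.synthetic.ScanSpec`.
"""

from __future__ import annotations

import numpy as np

from .algorithms import (
    bimax_like,
    binarize,
    ccc,
    cluster_regions,
    cluster_times,
    discretize_rowwise,
    discretize_transitions,
    run_repeated,
    xmotifs_greedy,
)
from .data_model import BiclusterSet, filter_min_size, materialize_bicluster, union_collection
from .metrics import MetricsRecord, compute_all
from .synthetic import BlockSpec, ScanSpec, best_recovery, generate_collection

__all__ = [
    "ALGORITHM_GROUPS",
    "ccc_recovery",
    "planted_block_population",
    "run_algorithm_suite",
    "benchmark_collection",
]

#: Super-group membership for pooled biclustering-vs-clustering comparisons.
ALGORITHM_GROUPS = {
    "ccc": "biclustering",
    "bimax": "biclustering",
    "xmotifs": "biclustering",
    "kmeans-regions": "region_clustering",
    "ward-regions": "region_clustering",
    "kmeans-times": "temporal_clustering",
    "ward-times": "temporal_clustering",
}


def ccc_recovery(
    noise_sd: float,
    n_scans: int = 20,
    seed: int = 0,
    n_symbols: int = 3,
    blocks_per_scan: int = 2,
) -> np.ndarray:
    """Best Jaccard recovery of each planted shifting block by CCC.

    Generates a collection of 30x150 scans with ``blocks_per_scan`` planted
    shifting blocks, runs CCC on the transition discretization, and returns
    one best-recovery score per planted block.
    """
    template = ScanSpec(
        blocks=tuple(BlockSpec() for _ in range(blocks_per_scan)), noise_sd=noise_sd
    )
    scores = []
    for matrix, truth in generate_collection(template, n_scans=n_scans, seed=seed):
        found = ccc(matrix, discretize_transitions(matrix, n_symbols=n_symbols))
        for t in truth:
            scores.append(best_recovery(found, t))
    return np.asarray(scores)


def planted_block_population(
    pattern_type: str,
    n_scans: int = 6,
    amplitudes: tuple[float, ...] = (0.5, 1.0, 2.0),
    noise_sd: float = 0.1,
    baseline_mean: float = 0.0,
    dilutions: tuple[int, ...] = (2, 4, 6),
    seed: int = 0,
) -> list[MetricsRecord]:
    """Metrics for planted blocks of one family plus diluted variants.

    Each scan plants one block per amplitude; for every block the pure
    materialization and one variant per dilution level (that many extra
    background rows *and* columns) enter the population.  Scaling-family
    studies should pass a positive ``baseline_mean``: multiplicative
    structure — like the SMSR index itself — is only meaningful on signals
    bounded away from zero.
    """
    rng = np.random.default_rng(seed + 1)
    template = ScanSpec(
        blocks=tuple(BlockSpec(pattern_type=pattern_type, amplitude=a) for a in amplitudes),
        noise_sd=noise_sd,
        baseline_mean=baseline_mean,
    )
    population = []
    for matrix, truth in generate_collection(template, n_scans=n_scans, seed=seed):
        n, p = matrix.shape
        for t in truth:
            population.append(materialize_bicluster(matrix, t.rows, t.cols))
            for d in dilutions:
                extra_r = rng.choice(sorted(set(range(n)) - set(t.rows)), d, replace=False)
                extra_c = rng.choice(sorted(set(range(p)) - set(t.cols)), d, replace=False)
                population.append(
                    materialize_bicluster(
                        matrix,
                        list(t.rows) + list(extra_r),
                        list(t.cols) + list(extra_c),
                    )
                )
    return compute_all(BiclusterSet(population))


def run_algorithm_suite(
    matrix,
    seed: int = 0,
    bimax_max: int = 500,
    bimax_cap: int = 2500,
    xmotifs_runs: int = 10,
    kmeans_runs: int = 3,
) -> BiclusterSet:
    """Run every algorithm and baseline on one scan; pooled, filtered, deduped."""
    disc5 = discretize_rowwise(matrix, k=5)
    outputs = [
        ccc(matrix, discretize_transitions(matrix, n_symbols=3)),
        bimax_like(matrix, binarize(matrix), max_biclusters=bimax_max, explore_cap=bimax_cap),
        run_repeated(
            lambda s: xmotifs_greedy(matrix, disc5, seed=s), n_runs=xmotifs_runs, seed=seed
        ),
        run_repeated(
            lambda s: cluster_regions(matrix, "kmeans", seed=s), n_runs=kmeans_runs, seed=seed
        ),
        cluster_regions(matrix, "ward"),
        run_repeated(
            lambda s: cluster_times(matrix, "kmeans", seed=s), n_runs=kmeans_runs, seed=seed
        ),
        cluster_times(matrix, "ward"),
    ]
    return union_collection([filter_min_size(o) for o in outputs])


def benchmark_collection(
    n_scans: int = 6,
    seed: int = 0,
    noise_sd: float = 0.1,
    amplitude: float = 1.5,
    blocks_per_scan: int = 2,
) -> list[MetricsRecord]:
    """Full comparison study on one synthetic collection with strong local
    shifting patterns; returns pooled per-bicluster metrics."""
    template = ScanSpec(
        blocks=tuple(BlockSpec(amplitude=amplitude) for _ in range(blocks_per_scan)),
        noise_sd=noise_sd,
    )
    per_scan = [
        run_algorithm_suite(matrix, seed=seed)
        for matrix, _ in generate_collection(template, n_scans=n_scans, seed=seed)
    ]
    return compute_all(union_collection(per_scan))
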