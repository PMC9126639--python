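"""Discretization rules, algorithm/oracle equivalence, baselines, repetition."""

import numpy as np
import pytest

from fmribic import (
    BiclusterSet,
    BlockSpec,
    ScanSpec,
    best_recovery,
    generate_scan,
)
from fmribic.algorithms import (
    DiscretizedMatrix,
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

from conftest import brute_force_bimax, brute_force_ccc, make_matrix


def symbolic(symbols, alphabet_size, **kw):
    """Wrap a symbol matrix as (dummy matrix, DiscretizedMatrix)."""
    symbols = np.asarray(symbols)
    m = make_matrix(symbols.astype(float))
    return m, DiscretizedMatrix(symbols, alphabet_size=alphabet_size, scheme="rowwise_bins", **kw)


def as_index_sets(bset):
    return {(b.rows, b.cols) for b in bset}


class TestDiscretizeRowwise:
    def test_bin_edges(self):
        m = make_matrix([[0.0, 0.5, 1.0], [0.0, 0.5, 1.0]])
        d = discretize_rowwise(m, k=2)
        np.testing.assert_array_equal(d.symbols[0], [0, 1, 1])

    def test_constant_row_maps_to_zero(self):
        m = make_matrix([[3.0, 3.0, 3.0], [0.0, 1.0, 2.0]])
        d = discretize_rowwise(m, k=5)
        np.testing.assert_array_equal(d.symbols[0], [0, 0, 0])

    def test_monotone_equally_spaced_row_uses_all_symbols(self):
        m = make_matrix([[0.0, 1.0, 2.0, 3.0, 4.0], [4.0, 3.0, 2.0, 1.0, 0.0]])
        d = discretize_rowwise(m, k=5)
        np.testing.assert_array_equal(d.symbols[0], [0, 1, 2, 3, 4])
        np.testing.assert_array_equal(d.symbols[1], [4, 3, 2, 1, 0])

    def test_rejects_tiny_alphabet(self):
        with pytest.raises(ValueError):
            discretize_rowwise(make_matrix([[1.0, 2.0], [3.0, 4.0]]), k=1)


class TestDiscretizeTransitions:
    def test_two_symbol_signs(self):
        m = make_matrix([[1.0, 2.0, 1.0], [1.0, 2.0, 1.0]])
        d = discretize_transitions(m, n_symbols=2)
        np.testing.assert_array_equal(d.symbols[0], [1, 0])  # Up, Down
        assert d.transition_offset and d.symbols.shape[1] == 2

    def test_three_symbol_threshold(self):
        m = make_matrix([[0.0, 0.01, 5.0], [0.0, 0.01, 5.0]])
        d = discretize_transitions(m, n_symbols=3, t=0.2)
        np.testing.assert_array_equal(d.symbols[0], [1, 2])  # NoChange, Up

    def test_constant_row_all_nochange(self):
        m = make_matrix([[2.0, 2.0, 2.0], [0.0, 1.0, 0.0]])
        d = discretize_transitions(m, n_symbols=3)
        np.testing.assert_array_equal(d.symbols[0], [1, 1])


class TestBinarize:
    def test_above_row_median_is_strict(self):
        m = make_matrix([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        d = binarize(m)
        np.testing.assert_array_equal(d.symbols[0], [0, 0, 1])

    def test_constant_row_all_zero(self):
        m = make_matrix([[2.0, 2.0, 2.0], [1.0, 2.0, 3.0]])
        np.testing.assert_array_equal(binarize(m).symbols[0], [0, 0, 0])

    def test_ones_at_most_half_under_strict_rule(self, rng):
        m = make_matrix(rng.normal(size=(10, 9)))
        d = binarize(m)
        assert (d.symbols.sum(axis=1) <= 9 / 2).all()


class TestCCC:
    def test_worked_symbolic_example(self):
        # rows: AABB / AABC / CABB  (A=0, B=1, C=2)
        m, d = symbolic([[0, 0, 1, 1], [0, 0, 1, 2], [2, 0, 1, 1]], 3)
        expected = {
            ((0, 1, 2), (1, 2)),
            ((0, 2), (1, 2, 3)),
            ((0, 1), (0, 1, 2)),
        }
        assert as_index_sets(ccc(m, d)) == expected
        assert as_index_sets(ccc(m, d)) == brute_force_ccc(d.symbols)

    def test_identical_rows_give_single_full_bicluster(self):
        m, d = symbolic([[0, 1, 2, 1]] * 4, 3)
        out = ccc(m, d)
        assert as_index_sets(out) == {((0, 1, 2, 3), (0, 1, 2, 3))}

    def test_matches_brute_force_on_random_matrices(self, rng):
        for _ in range(200):
            n = int(rng.integers(2, 7))
            p = int(rng.integers(2, 9))
            k = int(rng.integers(2, 4))
            m, d = symbolic(rng.integers(0, k, size=(n, p)), k)
            assert as_index_sets(ccc(m, d)) == brute_force_ccc(d.symbols)

    def test_transition_interval_maps_back_to_time_points(self):
        # two rows with identical transition signature over all 4 time points
        m = make_matrix([[0.0, 1.0, 0.0, 1.0], [2.0, 3.0, 2.0, 3.0], [0.0, 0.0, 0.0, 0.0]])
        d = discretize_transitions(m, n_symbols=2)
        out = ccc(m, d)
        assert ((0, 1), (0, 1, 2, 3)) in as_index_sets(out)

    def test_zero_noise_planted_constant_block_recovered_exactly(self):
        spec = ScanSpec(
            noise_sd=0.0, blocks=(BlockSpec(pattern_type="constant"),), seed=21
        )
        m, truth = generate_scan(spec)
        out = ccc(m, discretize_rowwise(m, k=5))
        assert best_recovery(out, truth[0]) == 1.0

    def test_materialized_and_contiguous(self, rng):
        m, d = symbolic(rng.integers(0, 3, size=(6, 8)), 3)
        for b in ccc(m, d):
            assert b.n_rows >= 2 and b.n_cols >= 2
            assert b.cols == tuple(range(b.cols[0], b.cols[-1] + 1))
            np.testing.assert_array_equal(
                b.values, m.values[np.ix_(b.rows, b.cols)]
            )


class TestBimax:
    def test_worked_binary_example(self):
        m = make_matrix([[1.0, 1.0, 0.0], [1.0, 1.0, 1.0], [0.0, 1.0, 1.0]])
        d = DiscretizedMatrix(m.values.astype(int), 2, scheme="binary")
        assert as_index_sets(bimax_like(m, d)) == {
            ((0, 1), (0, 1)),
            ((1, 2), (1, 2)),
        }

    def test_all_ones_and_all_zeros(self):
        ones = make_matrix(np.ones((3, 4)))
        d1 = DiscretizedMatrix(np.ones((3, 4), dtype=int), 2, scheme="binary")
        assert as_index_sets(bimax_like(ones, d1)) == {((0, 1, 2), (0, 1, 2, 3))}
        zeros = make_matrix(np.zeros((3, 4)))
        d0 = DiscretizedMatrix(np.zeros((3, 4), dtype=int), 2, scheme="binary")
        assert len(bimax_like(zeros, d0)) == 0

    def test_matches_brute_force_on_random_binary_matrices(self, rng):
        for _ in range(200):
            n = int(rng.integers(2, 9))
            p = int(rng.integers(2, 9))
            sym = rng.integers(0, 2, size=(n, p))
            m = make_matrix(sym.astype(float))
            d = DiscretizedMatrix(sym, 2, scheme="binary")
            assert as_index_sets(bimax_like(m, d)) == brute_force_bimax(sym)

    def test_truncation_keeps_largest_area_first(self, rng):
        sym = rng.integers(0, 2, size=(8, 10))
        m = make_matrix(sym.astype(float))
        d = DiscretizedMatrix(sym, 2, scheme="binary")
        full = bimax_like(m, d, max_biclusters=10000)
        top2 = bimax_like(m, d, max_biclusters=2)
        areas = sorted((b.area for b in full), reverse=True)
        assert [b.area for b in top2] == areas[:2]

    def test_rejects_non_binary_scheme(self):
        m = make_matrix([[1.0, 2.0], [3.0, 4.0]])
        with pytest.raises(ValueError, match="binary"):
            bimax_like(m, discretize_rowwise(m, k=5))


class TestXMotifs:
    def test_two_conserved_groups_found(self):
        rows_a = [0, 1, 2, 0, 2]
        rows_b = [4, 0, 3, 1, 1]
        sym = np.array([rows_a, rows_a, rows_a, rows_b, rows_b, rows_b])
        m = make_matrix(sym.astype(float))
        d = DiscretizedMatrix(sym, 5, scheme="rowwise_bins")
        out = xmotifs_greedy(m, d, sd_size=3, seed=0)
        assert ((0, 1, 2), (0, 1, 2, 3, 4)) in as_index_sets(out)
        assert ((3, 4, 5), (0, 1, 2, 3, 4)) in as_index_sets(out)

    def test_deterministic_per_seed(self):
        m, _ = generate_scan(ScanSpec(blocks=(BlockSpec(),), seed=3))
        d = discretize_rowwise(m, k=5)
        a = xmotifs_greedy(m, d, seed=5)
        b = xmotifs_greedy(m, d, seed=5)
        assert as_index_sets(a) == as_index_sets(b)

    def test_planted_conserved_block_recovered_across_seeds(self):
        hits = 0
        for seed in range(5):
            spec = ScanSpec(
                noise_sd=0.0,
                blocks=(BlockSpec(pattern_type="constant", n_cols=100),),
                seed=40 + seed,
            )
            m, truth = generate_scan(spec)
            d = discretize_rowwise(m, k=5)
            out = run_repeated(
                lambda s: xmotifs_greedy(m, d, seed=s), n_runs=10, seed=seed
            )
            # conserved-state recovery: all planted cells found (the greedy
            # column extension may legitimately add coincidental columns)
            best = max(
                (
                    len(set(b.rows) & set(truth[0].rows))
                    * len(set(b.cols) & set(truth[0].cols))
                    / truth[0].area
                    for b in out
                ),
                default=0.0,
            )
            if best >= 0.9:
                hits += 1
        assert hits >= 4

    def test_rejects_oversized_discriminating_set(self):
        m = make_matrix(np.zeros((3, 4)))
        d = discretize_rowwise(make_matrix(np.arange(12.0).reshape(3, 4)), k=2)
        with pytest.raises(ValueError):
            xmotifs_greedy(m, d, sd_size=4)


class TestClusteringBaselines:
    def test_region_partition_contract(self):
        m, _ = generate_scan(ScanSpec(seed=1))
        for method in ("kmeans", "ward"):
            out = cluster_regions(m, method=method, n_clusters=4, seed=0)
            rows = sorted(r for b in out for r in b.rows)
            assert rows == list(range(m.n_regions))  # disjoint cover
            assert all(b.cols == tuple(range(m.n_time)) for b in out)

    def test_time_partition_contract(self):
        m, _ = generate_scan(ScanSpec(seed=1))
        out = cluster_times(m, method="ward", n_clusters=5)
        cols = sorted(c for b in out for c in b.cols)
        assert cols == list(range(m.n_time))
        assert all(b.rows == tuple(range(m.n_regions)) for b in out)

    def test_single_cluster_requires_explicit_flag(self):
        m, _ = generate_scan(ScanSpec(seed=1))
        with pytest.raises(ValueError):
            cluster_regions(m, n_clusters=1)
        out = cluster_regions(m, n_clusters=1, allow_single=True)
        assert len(out) == 1 and out[0].area == m.n_regions * m.n_time

    def test_separated_row_groups_recovered(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0.0, 0.1, size=(5, 20))
        b = rng.normal(10.0, 0.1, size=(5, 20))
        m = make_matrix(np.vstack([a, b]))
        for method in ("kmeans", "ward"):
            out = cluster_regions(m, method=method, n_clusters=2, seed=0)
            groups = {b_.rows for b_ in out}
            assert groups == {tuple(range(5)), tuple(range(5, 10))}

    def test_two_phase_time_course_recovered(self):
        rng = np.random.default_rng(1)
        phase1 = rng.normal(0.0, 0.1, size=(8, 10))
        phase2 = rng.normal(5.0, 0.1, size=(8, 10))
        m = make_matrix(np.hstack([phase1, phase2]))
        out = cluster_times(m, method="kmeans", n_clusters=2, seed=0)
        groups = {b.cols for b in out}
        assert groups == {tuple(range(10)), tuple(range(10, 20))}


class TestRunRepeated:
    def test_deterministic_algorithm_collapses_to_single_run(self):
        m, _ = generate_scan(ScanSpec(blocks=(BlockSpec(),), seed=2))
        d = discretize_transitions(m, n_symbols=3)
        single = ccc(m, d)
        repeated = run_repeated(lambda s: ccc(m, d), n_runs=5, seed=0)
        assert as_index_sets(repeated) == as_index_sets(single)

    def test_output_size_matches_brute_force_distinct_count(self):
        m, _ = generate_scan(ScanSpec(blocks=(BlockSpec(),), seed=3))
        d = discretize_rowwise(m, k=5)
        runs = {}
        seeds = np.random.default_rng(17).integers(0, 2**31 - 1, size=6)
        all_keys = set()
        for s in seeds:
            for b in xmotifs_greedy(m, d, seed=int(s)):
                all_keys.add((b.rows, b.cols))
        out = run_repeated(lambda s: xmotifs_greedy(m, d, seed=s), n_runs=6, seed=17)
        assert len(out) == len(all_keys)

    def test_single_run(self):
        m, _ = generate_scan(ScanSpec(blocks=(BlockSpec(),), seed=4))
        d = discretize_rowwise(m, k=5)
        out = run_repeated(lambda s: xmotifs_greedy(m, d, seed=s), n_runs=1, seed=3)
        assert all(b.provenance.run == 0 for b in out)
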