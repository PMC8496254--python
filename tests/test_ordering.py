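"""Obligate crossovers, seriation, ripple search, multipoint map EM."""

import itertools

import numpy as np
import pytest

from capmap import (GenotypeMatrix, OrderingParams, count_obligate_xo,
                    estimate_map, initial_order, map_gaps, order_likelihood,
                    order_markers, ripple_window)
from capmap.core import chars_to_codes
from capmap.errors import ConfigError
from capmap.ordering import LinkageGroupMap
from capmap.twopoint import haldane_cM, twopoint_all


def _seq_matrix(*sequences):
    """Matrix from call strings ('A','H','B','-'), one individual per string."""
    rows = [list(s) for s in sequences]
    m = len(rows[0])
    return GenotypeMatrix(
        chars_to_codes(np.array(rows, dtype=object)),
        np.array([f"i{k}" for k in range(len(rows))], dtype=object),
        np.array([f"m{k}" for k in range(m)], dtype=object),
    )


def enumeration_min_xo(seq):
    """Oracle: exhaustive minimum over per-site gamete assignments."""
    typed = [g for g in seq if g >= 0]
    if len(typed) < 2:
        return 0
    options = [[(0, 0)] if g == 0 else ([(1, 1)] if g == 2 else [(0, 1), (1, 0)])
               for g in typed]
    best = None
    for path in itertools.product(*options):
        cost = sum(abs(a1 - b1) + abs(a2 - b2)
                   for (a1, a2), (b1, b2) in zip(path, path[1:]))
        best = cost if best is None else min(best, cost)
    return best


class TestObligateCrossovers:
    @pytest.mark.parametrize("calls,expected", [
        ("AAHB", 2),   # A->H (1) plus H->B (1)
        ("AAAA", 0),
        ("HHHH", 0),
        ("AB", 2),     # both gametes must recombine
        ("A-B", 2),    # missing call skipped
        ("A-H", 1),
        ("AHA", 2),
        ("--", 0),
    ])
    def test_known_sequences(self, calls, expected):
        m = _seq_matrix(calls)
        per, total = count_obligate_xo(list(m.marker_ids), m)
        assert total == expected

    def test_matches_enumeration_oracle_on_short_sequences(self):
        for length in (3, 4, 5):
            for seq in itertools.product([-1, 0, 1, 2], repeat=length):
                chars = "".join({-1: "-", 0: "A", 1: "H", 2: "B"}[g] for g in seq)
                m = _seq_matrix(chars)
                _, total = count_obligate_xo(list(m.marker_ids), m)
                assert total == enumeration_min_xo(seq), seq

    def test_sums_over_individuals(self):
        m = _seq_matrix("AAHB", "AAAA", "AB-B")
        per, total = count_obligate_xo(list(m.marker_ids), m)
        assert list(per) == [2, 0, 2]
        assert total == 4


class TestInitialOrder:
    def test_three_markers_all_starts(self, clean_chromosome):
        truth, matrix = clean_chromosome
        trio = list(matrix.marker_ids[:3])
        sub = matrix.select_markers(trio)
        tp = twopoint_all(sub, min_informative=1)
        for perm in itertools.permutations(trio):
            got = initial_order(list(perm), tp)
            assert got == trio or got == trio[::-1]

    def test_two_markers_trivial(self, clean_chromosome):
        _, matrix = clean_chromosome
        duo = list(matrix.marker_ids[:2])
        tp = twopoint_all(matrix.select_markers(duo), min_informative=1)
        assert sorted(initial_order(duo, tp)) == sorted(duo)


class TestRipple:
    def test_optimal_order_untouched(self, clean_chromosome):
        _, matrix = clean_chromosome
        order = list(matrix.marker_ids)
        _, before = count_obligate_xo(order, matrix)
        out = ripple_window(order, matrix, window=4, rng=np.random.default_rng(0))
        _, after = count_obligate_xo(out, matrix)
        assert after <= before

    def test_adjacent_swap_repaired(self, clean_chromosome):
        _, matrix = clean_chromosome
        order = list(matrix.marker_ids)
        broken = order.copy()
        broken[10], broken[11] = broken[11], broken[10]
        fixed = ripple_window(broken, matrix, window=2, rng=np.random.default_rng(1))
        _, c_fixed = count_obligate_xo(fixed, matrix)
        _, c_true = count_obligate_xo(order, matrix)
        assert c_fixed <= c_true

    def test_window_larger_than_cap_rejected(self, clean_chromosome):
        _, matrix = clean_chromosome
        with pytest.raises(ConfigError):
            ripple_window(list(matrix.marker_ids), matrix, window=9)


class TestOrderLikelihood:
    def test_reversal_has_identical_likelihood(self, clean_chromosome):
        _, matrix = clean_chromosome
        order = list(matrix.marker_ids[:20])
        a = order_likelihood(order, matrix)
        b = order_likelihood(order[::-1], matrix)
        assert a == pytest.approx(b, abs=1e-6)

    def test_true_order_beats_random_permutations(self, clean_chromosome):
        _, matrix = clean_chromosome
        order = list(matrix.marker_ids[:30])
        sub = matrix.select_markers(order)
        ll_true = order_likelihood(order, sub)
        rng = np.random.default_rng(2)
        for _ in range(100):
            perm = list(rng.permutation(order))
            if perm == order or perm == order[::-1]:
                continue
            assert order_likelihood(perm, sub) <= ll_true + 1e-6

    def test_two_marker_group_equals_twopoint_likelihood(self, clean_chromosome):
        from capmap.twopoint import _log10_lik, estimate_rf_em

        _, matrix = clean_chromosome
        duo = list(matrix.marker_ids[:2])
        sub = matrix.select_markers(duo)
        counts = np.zeros((3, 3))
        for g1 in range(3):
            for g2 in range(3):
                counts[g1, g2] = ((sub.calls[:, 0] == g1) & (sub.calls[:, 1] == g2)).sum()
        r_hat, _ = estimate_rf_em(counts)
        ll_pair = _log10_lik(counts, r_hat)
        assert order_likelihood(duo, sub, error_prob=0.0) == pytest.approx(ll_pair, abs=1e-6)


class TestEstimateMap:
    def test_two_marker_map_equals_haldane_of_twopoint(self, clean_chromosome):
        _, matrix = clean_chromosome
        duo = list(matrix.marker_ids[:2])
        sub = matrix.select_markers(duo)
        tp = twopoint_all(sub, min_informative=1)
        lg = estimate_map(duo, sub, error_prob=0.0)
        assert lg.length_cM == pytest.approx(haldane_cM(tp.rf[0, 1]), abs=1e-6)

    def test_zero_recombinant_pair_has_zero_length(self):
        m = _seq_matrix(*(["AA"] * 10 + ["HH"] * 20 + ["BB"] * 10))
        lg = estimate_map(list(m.marker_ids), m, error_prob=0.0)
        assert lg.length_cM == pytest.approx(0.0, abs=1e-9)

    def test_interval_rfs_within_bounds_and_loglik_monotone(self, clean_chromosome):
        _, matrix = clean_chromosome
        lg = estimate_map(list(matrix.marker_ids), matrix)
        assert np.all(lg.interval_rf >= 0.0)
        assert np.all(lg.interval_rf < 0.5)
        traj = np.array(lg.loglik_trajectory)
        assert np.all(np.diff(traj) >= -1e-8)

    def test_length_invariant_under_reversal(self, clean_chromosome):
        _, matrix = clean_chromosome
        order = list(matrix.marker_ids)
        a = estimate_map(order, matrix)
        b = estimate_map(order[::-1], matrix)
        assert a.length_cM == pytest.approx(b.length_cM, abs=1e-6)
        assert a.loglik == pytest.approx(b.loglik, abs=1e-6)

    def test_recovers_simulated_length(self, clean_chromosome):
        truth, matrix = clean_chromosome
        lg = estimate_map(list(matrix.marker_ids), matrix, error_prob=1e-4)
        assert lg.length_cM == pytest.approx(100.0, rel=0.10)


class TestOrderMarkers:
    def test_recovers_true_order_on_clean_data(self, clean_chromosome):
        _, matrix = clean_chromosome
        params = OrderingParams(n_runs=2, seed=11)
        best = order_markers(list(matrix.marker_ids), matrix, params)
        true_order = list(matrix.marker_ids)
        assert best == true_order or best == true_order[::-1]

    def test_deterministic_for_seed(self, clean_chromosome):
        _, matrix = clean_chromosome
        group = list(matrix.marker_ids[:15])
        params = OrderingParams(n_runs=2, seed=5)
        assert (order_markers(group, matrix, params)
                == order_markers(group, matrix, params))

    def test_single_marker_group_trivial(self, clean_chromosome):
        _, matrix = clean_chromosome
        assert order_markers([matrix.marker_ids[0]], matrix) == [matrix.marker_ids[0]]

    def test_orientation_follows_physical_metadata(self, clean_chromosome):
        truth, matrix = clean_chromosome
        params = OrderingParams(n_runs=1, seed=3)
        best = order_markers(list(matrix.marker_ids), matrix, params,
                             metadata=truth.metadata)
        meta = truth.metadata.set_index("marker_id")
        bp = meta.loc[best, "pos_bp"].to_numpy()
        assert bp[0] < bp[-1]


class TestMapGaps:
    def test_arithmetic(self):
        lg = LinkageGroupMap("LG01", ["a", "b", "c"], np.array([0.0, 5.0, 31.0]),
                             np.array([0.05, 0.2]), loglik=0.0)
        largest, n = map_gaps(lg, 10.0)
        assert largest == pytest.approx(26.0)
        assert n == 1

    def test_uniform_spacing_has_no_gaps(self):
        pos = np.arange(0.0, 20.0, 1.0)
        lg = LinkageGroupMap("LG01", [f"m{i}" for i in range(len(pos))], pos,
                             np.full(len(pos) - 1, 0.01), loglik=0.0)
        assert map_gaps(lg, 10.0) == (1.0, 0)

    def test_planted_gap_recovered(self):
        cfg_positions = np.array([0.0, 1.0, 2.0, 27.0, 28.0])
        lg = LinkageGroupMap("LG01", [f"m{i}" for i in range(5)], cfg_positions,
                             np.full(4, 0.01), loglik=0.0)
        largest, n = map_gaps(lg, 10.0)
        assert largest == pytest.approx(25.0)
        assert n == 1
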