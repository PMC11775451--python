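"""Jaccard-index synchrony: examples, properties and independent oracles."""
from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import maximum_bipartite_matching
from scipy.stats import bootstrap as scipy_bootstrap

from zgsync.datatypes import SpikeTrain
from zgsync.synchrony import (bootstrap_ci, classify_coupled, jaccard_index,
                              pairwise_ji, shift_null, summarize_coupled_ji,
                              SynchronyResult)


def train(frames, n=100, cid="a", dt=0.1):
    return SpikeTrain(cid, np.asarray(sorted(frames), dtype=np.int64), n, dt)


def brute_force_ji(fa, fb):
    """Independent oracle: JI on plain Python frame sets."""
    A, B = set(map(int, fa)), set(map(int, fb))
    if not A and not B:
        return float("nan")
    return len(A & B) / len(A | B)


def max_matching_ji(fa, fb, tol):
    """Independent oracle: maximum bipartite matching within +-tol frames."""
    na, nb = len(fa), len(fb)
    if na == 0 and nb == 0:
        return float("nan")
    rows, cols = [], []
    for i, x in enumerate(fa):
        for j, y in enumerate(fb):
            if abs(int(x) - int(y)) <= tol:
                rows.append(i)
                cols.append(j)
    if not rows:
        return 0.0
    graph = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(na, nb))
    m = int((maximum_bipartite_matching(graph, perm_type="column") >= 0).sum())
    return m / (na + nb - m)


frame_sets = st.sets(st.integers(min_value=0, max_value=99), max_size=25)


class TestJaccardIndex:
    @pytest.mark.parametrize("fa, fb, tol, expected", [
        ([1, 5, 9], [1, 5, 9], 0, 1.0),          # identical
        ([1, 5, 9], [2, 6, 10], 0, 0.0),         # disjoint
        ([1, 5, 9], [1, 5, 12], 0, 0.5),         # 2 shared of 4 distinct
        ([1, 5, 9], [2, 5, 12], 1, 0.5),         # matches 1<->2 and 5<->5
        ([], [3, 4], 0, 0.0),                    # one silent cell
    ])
    def test_examples(self, fa, fb, tol, expected):
        assert jaccard_index(train(fa), train(fb, cid="b"), tol) == pytest.approx(expected)

    def test_both_empty_is_undefined(self):
        assert np.isnan(jaccard_index(train([]), train([], cid="b")))

    def test_mismatched_grids_rejected(self):
        with pytest.raises(ValueError):
            jaccard_index(train([1], n=100), train([1], n=200, cid="b"))

    @settings(max_examples=200, deadline=None)
    @given(fa=frame_sets, fb=frame_sets)
    def test_matches_brute_force_and_is_symmetric(self, fa, fb):
        a, b = train(fa), train(fb, cid="b")
        ji = jaccard_index(a, b)
        oracle = brute_force_ji(np.array(sorted(fa)), np.array(sorted(fb)))
        if np.isnan(oracle):
            assert np.isnan(ji)
        else:
            assert ji == pytest.approx(oracle)
            assert 0.0 <= ji <= 1.0
            assert jaccard_index(b, a) == pytest.approx(ji)

    @settings(max_examples=150, deadline=None)
    @given(fa=frame_sets, fb=frame_sets, tol=st.integers(min_value=1, max_value=4))
    def test_tolerant_matching_equals_maximum_matching(self, fa, fb, tol):
        ji = jaccard_index(train(fa), train(fb, cid="b"), tol)
        oracle = max_matching_ji(sorted(fa), sorted(fb), tol)
        if np.isnan(oracle):
            assert np.isnan(ji)
        else:
            assert ji == pytest.approx(oracle)

    @settings(max_examples=150, deadline=None)
    @given(fa=frame_sets, fb=frame_sets)
    def test_monotone_in_tolerance(self, fa, fb):
        a, b = train(fa), train(fb, cid="b")
        if not fa and not fb:
            return
        values = [jaccard_index(a, b, t) for t in range(4)]
        assert all(x <= y + 1e-12 for x, y in zip(values, values[1:]))

    def test_identity_iff_equal_at_zero_tolerance(self):
        a = train([2, 30, 77])
        assert jaccard_index(a, train([2, 30, 77], cid="b")) == 1.0
        assert jaccard_index(a, train([2, 30, 78], cid="b")) < 1.0


class TestPairwise:
    def test_two_identical_cells(self):
        trains = {"a": train([1, 5]), "b": train([1, 5], cid="b")}
        res = pairwise_ji(trains)
        assert res.ji_matrix[0, 1] == 1.0

    def test_pair_count_combinatorics(self):
        trains = {f"c{i}": train([i, 2 * i + 1], cid=f"c{i}") for i in range(7)}
        res = pairwise_ji(trains)
        iu = np.triu_indices(7, 1)
        assert np.isfinite(res.ji_matrix[iu]).sum() == 7 * 6 // 2

    def test_cross_slice_pairs_never_formed(self):
        trains = {"a": train([1]), "b": train([1], cid="b")}
        res = pairwise_ji(trains, slice_of={"a": "s0", "b": "s1"})
        assert np.isnan(res.ji_matrix[0, 1])
        assert res.pairs_table().empty

    def test_matrix_symmetry(self):
        rng = np.random.default_rng(0)
        trains = {f"c{i}": train(rng.choice(100, size=10, replace=False), cid=f"c{i}")
                  for i in range(5)}
        res = pairwise_ji(trains)
        m = res.ji_matrix
        assert np.allclose(m, m.T, equal_nan=True)


class TestClassifyCoupled:
    def test_all_zero_matrix(self):
        trains = {"a": train([1]), "b": train([2], cid="b"), "c": train([3], cid="c")}
        res = pairwise_ji(trains)
        pairs, cells = classify_coupled(res)
        assert pairs == [] and cells == set()

    def test_single_coupled_pair(self):
        mat = np.full((3, 3), 0.0)
        mat[0, 1] = mat[1, 0] = 0.5
        np.fill_diagonal(mat, np.nan)
        res = SynchronyResult(["c1", "c2", "c3"], mat,
                              {c: "s0" for c in ("c1", "c2", "c3")})
        pairs, cells = classify_coupled(res)
        assert pairs == [("c1", "c2")]
        assert cells == {"c1", "c2"}

    def test_threshold_is_strict(self):
        mat = np.array([[np.nan, 0.1], [0.1, np.nan]])
        res = SynchronyResult(["a", "b"], mat, {"a": "s0", "b": "s0"}, threshold=0.1)
        assert classify_coupled(res)[0] == []


class TestShiftNull:
    def test_identical_trains_decorrelate_at_shift_one(self):
        frames = [3, 17, 31, 52, 70, 88]  # aperiodic, sparse
        trains = {"a": train(frames), "b": train(frames, cid="b")}
        res = shift_null(trains, max_shift=3)
        assert res.mean_ji[0] == 1.0
        assert res.mean_ji[1] < 1.0

    def test_periodic_train_invariant_under_period_shift(self):
        frames = list(range(0, 100, 10))
        trains = {"a": train(frames), "b": train(frames, cid="b")}
        res = shift_null(trains, max_shift=10)
        assert res.mean_ji[10] == pytest.approx(res.mean_ji[0])

    def test_shift_zero_reproduces_pairwise(self):
        rng = np.random.default_rng(1)
        trains = {f"c{i}": train(rng.choice(200, size=15, replace=False), n=200,
                                 cid=f"c{i}") for i in range(4)}
        res = shift_null(trains, max_shift=2)
        direct = pairwise_ji(trains)
        assert np.allclose(res.matrices[0], direct.ji_matrix, equal_nan=True)

    def test_excessive_shift_rejected(self):
        trains = {"a": train([1]), "b": train([2], cid="b")}
        with pytest.raises(ValueError):
            shift_null(trains, max_shift=100)


class TestBootstrap:
    def test_constant_input_degenerate_ci(self):
        ci = bootstrap_ci(np.full(20, 3.3), seed=0)
        assert ci.lower == ci.upper == pytest.approx(3.3)

    def test_ci_contains_sample_mean(self):
        rng = np.random.default_rng(2)
        vals = rng.exponential(size=50)
        ci = bootstrap_ci(vals, seed=0)
        assert ci.lower <= vals.mean() <= ci.upper

    def test_seed_determinism(self):
        vals = np.random.default_rng(3).normal(size=40)
        a = bootstrap_ci(vals, seed=7)
        b = bootstrap_ci(vals, seed=7)
        assert (a.lower, a.upper) == (b.lower, b.upper)

    def test_agrees_with_scipy_percentile_bootstrap(self):
        """Same method in scipy gives the same interval (independent route)."""
        vals = np.random.default_rng(4).normal(loc=1.0, size=80)
        ours = bootstrap_ci(vals, n_resamples=20_000, seed=0)
        ref = scipy_bootstrap((vals,), np.mean, n_resamples=20_000,
                              confidence_level=0.95, method="percentile",
                              random_state=np.random.default_rng(0))
        assert ours.lower == pytest.approx(ref.confidence_interval.low, abs=0.02)
        assert ours.upper == pytest.approx(ref.confidence_interval.high, abs=0.02)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_ci([])


class TestSummarizeCoupled:
    def _result(self, ji_values):
        n = len(ji_values) + 1
        mat = np.full((n, n), 0.0)
        for k, v in enumerate(ji_values):
            mat[0, k + 1] = mat[k + 1, 0] = v
        np.fill_diagonal(mat, np.nan)
        ids = [f"c{i}" for i in range(n)]
        return SynchronyResult(ids, mat, {c: "s0" for c in ids})

    def test_single_connection(self):
        mean, ci = summarize_coupled_ji(self._result([0.5]), seed=0)
        assert mean == 0.5 and ci.lower == ci.upper == 0.5

    def test_mean_of_connections(self):
        mean, _ = summarize_coupled_ji(self._result([0.2, 0.4]), seed=0)
        assert mean == pytest.approx(0.3)

    def test_no_coupled_connections_flagged(self):
        assert summarize_coupled_ji(self._result([0.05]), seed=0) is None
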