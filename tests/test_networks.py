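"""Sliding-window segmentation and FC network construction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hyfcnet import (
    SubjectTimeSeries,
    WindowSpec,
    associated_high_order_network,
    build_dynamic_networks,
    build_static_networks,
    high_order_network,
    low_order_network,
    segment_sliding_windows,
    standardize_columns,
)
from hyfcnet.errors import (
    DegenerateProfileError,
    DegenerateSignalError,
    InvalidWindowError,
    ShapeError,
)
from hyfcnet.networks import ConnectivityMatrix
from hyfcnet.synthetic import generate_fixture_matrices

from conftest import pearson_loop, pearson_matrix_loop, random_time_series


def _ts(data, tr=3.0):
    data = np.asarray(data, dtype=float)
    return SubjectTimeSeries(data, [f"R{i}" for i in range(data.shape[1])], tr_seconds=tr)


def brute_force_window_starts(p, length, step):
    """All window placements by direct enumeration."""
    return [s for s in range(0, p - length + 1) if s % step == 0]


class TestSegmentation:
    def test_reference_window_count(self, rng):
        ts = _ts(rng.standard_normal((130, 4)))
        windows = segment_sliding_windows(ts, WindowSpec(70, 1))
        assert len(windows) == 61

    def test_full_length_window_is_the_series(self, rng):
        ts = _ts(rng.standard_normal((25, 3)))
        windows = segment_sliding_windows(ts, WindowSpec(25, 1))
        assert len(windows) == 1
        np.testing.assert_array_equal(windows[0], ts.data)

    def test_strided_windows_match_enumeration(self):
        fixtures = generate_fixture_matrices()
        ts = _ts(fixtures["windowing"])  # 10 x 3
        windows = segment_sliding_windows(ts, WindowSpec(4, 3))
        starts = brute_force_window_starts(10, 4, 3)
        assert starts == [0, 3, 6]
        assert len(windows) == len(starts)
        for w, s in zip(windows, starts):
            np.testing.assert_array_equal(w, ts.data[s : s + 4])

    @settings(deadline=None, max_examples=60)
    @given(
        p=st.integers(4, 60),
        length=st.integers(2, 60),
        step=st.integers(1, 7),
    )
    def test_window_count_identity(self, p, length, step):
        ts = _ts(np.arange(p * 2, dtype=float).reshape(p, 2) ** 1.5)
        if length > p:
            with pytest.raises(InvalidWindowError):
                segment_sliding_windows(ts, WindowSpec(length, step))
            return
        windows = segment_sliding_windows(ts, WindowSpec(length, step))
        assert len(windows) == (p - length) // step + 1
        for k, w in enumerate(windows):
            np.testing.assert_array_equal(w, ts.data[k * step : k * step + length])

    def test_invalid_window_errors_name_values(self, rng):
        ts = _ts(rng.standard_normal((10, 3)))
        with pytest.raises(InvalidWindowError, match="L=20"):
            segment_sliding_windows(ts, WindowSpec(20, 1))
        with pytest.raises(InvalidWindowError, match="S=0"):
            WindowSpec(10, 0)


class TestStandardize:
    def test_three_point_column(self):
        out = standardize_columns(np.array([[1.0], [2.0], [3.0]]))
        np.testing.assert_allclose(
            out.ravel(), [-1 / np.sqrt(2), 0.0, 1 / np.sqrt(2)], atol=1e-15
        )

    def test_idempotent(self, rng):
        m = rng.standard_normal((20, 5))
        once = standardize_columns(m)
        np.testing.assert_allclose(standardize_columns(once), once, atol=1e-14)

    def test_product_is_pearson(self, rng):
        m = rng.standard_normal((20, 5))
        s = standardize_columns(m)
        np.testing.assert_allclose(s.T @ s, pearson_matrix_loop(m), atol=1e-12)

    def test_constant_column_names_roi(self):
        m = np.ones((8, 2))
        m[:, 0] = np.arange(8)
        with pytest.raises(DegenerateSignalError, match="Hippocampus"):
            standardize_columns(m, labels=["Precuneus", "Hippocampus"])


class TestLowOrder:
    def test_identical_and_negated_columns(self, rng):
        x = rng.standard_normal(30)
        m = np.column_stack([x, x + 0.0, -x, rng.standard_normal(30)])
        c = low_order_network(m).values
        assert c[0, 1] == pytest.approx(1.0, abs=1e-12)
        assert c[0, 2] == pytest.approx(-1.0, abs=1e-12)

    def test_matches_loop_pearson(self, rng):
        m = rng.standard_normal((30, 6))
        c = low_order_network(m).values
        np.testing.assert_allclose(c, pearson_matrix_loop(m), atol=1e-12)

    def test_structure(self, rng):
        c = low_order_network(rng.standard_normal((40, 8))).values
        np.testing.assert_array_equal(c, c.T)
        np.testing.assert_allclose(np.diag(c), 1.0)
        assert np.all(np.abs(c) <= 1.0)


class TestHighOrder:
    def test_identical_profiles_correlate_to_one(self, rng):
        # two ROIs with identical connectivity to everything else
        base = rng.standard_normal(50)
        m = np.column_stack(
            [base + 0.01 * rng.standard_normal(50),
             base + 0.01 * rng.standard_normal(50),
             rng.standard_normal((50, 3))]
        )
        c = low_order_network(m)
        h = high_order_network(c).values
        assert h[0, 1] > 0.99

    def test_matches_loop_pearson_of_profiles(self, rng):
        c = low_order_network(rng.standard_normal((40, 8)))
        h = high_order_network(c).values
        np.testing.assert_allclose(h, pearson_matrix_loop(c.values), atol=1e-12)

    def test_structure(self, rng):
        c = low_order_network(rng.standard_normal((40, 8)))
        h = high_order_network(c).values
        np.testing.assert_array_equal(h, h.T)
        np.testing.assert_allclose(np.diag(h), 1.0)
        assert np.all(np.abs(h) <= 1.0)

    def test_degenerate_profile_error(self):
        c = ConnectivityMatrix(np.eye(3), "low", 1)
        # identity columns all have identical variance pattern; make one constant
        vals = np.full((3, 3), 0.5)
        np.fill_diagonal(vals, 1.0)
        vals[:, 0] = 0.7  # constant profile
        with pytest.raises(DegenerateProfileError):
            high_order_network(ConnectivityMatrix(vals, "low", 1))
        del c


class TestAssociated:
    def test_substituting_h_equal_c_gives_symmetric_raw(self, rng):
        c = low_order_network(rng.standard_normal((40, 8)))
        fake_h = ConnectivityMatrix(c.values.copy(), "high", c.window_index)
        raw = associated_high_order_network(c, fake_h, symmetrize=False).values
        np.testing.assert_allclose(raw, raw.T, atol=1e-12)
        sym = associated_high_order_network(c, fake_h, symmetrize=True).values
        np.testing.assert_allclose(sym, raw, atol=1e-12)

    def test_matches_loop_pearson_low_vs_high_profiles(self, rng):
        c = low_order_network(rng.standard_normal((40, 8)))
        h = high_order_network(c)
        raw = associated_high_order_network(c, h, symmetrize=False).values
        r = c.n_rois
        expected = np.empty((r, r))
        for i in range(r):
            for j in range(r):
                expected[i, j] = pearson_loop(c.values[:, i], h.values[:, j])
        np.testing.assert_allclose(raw, expected, atol=1e-12)
        assert np.all(np.abs(raw) <= 1.0 + 1e-12)

    def test_symmetrization(self, rng):
        c = low_order_network(rng.standard_normal((40, 8)))
        h = high_order_network(c)
        a = associated_high_order_network(c, h).values
        np.testing.assert_array_equal(a, a.T)

    def test_dimension_mismatch(self, rng):
        c = low_order_network(rng.standard_normal((40, 8)))
        h = high_order_network(low_order_network(rng.standard_normal((40, 5))))
        with pytest.raises(ShapeError):
            associated_high_order_network(c, h)


class TestBuildDynamic:
    def test_window_counts_per_type(self, rng):
        ts = random_time_series(rng, p=130, r=5)
        sets = build_dynamic_networks(ts, WindowSpec(70, 1), types={"low"})
        assert sets["low"].n_windows == 61

    def test_static_limit_matches_static_builder(self, rng):
        ts = random_time_series(rng, p=30, r=6)
        dyn = build_dynamic_networks(ts, WindowSpec(30, 1))
        stat = build_static_networks(ts)
        for t in ("low", "high", "associated"):
            assert dyn[t].n_windows == 1
            np.testing.assert_array_equal(dyn[t].matrices[0].values, stat[t].values)

    def test_composition_matches_manual_per_window(self, rng):
        ts = random_time_series(rng, p=24, r=5)
        spec = WindowSpec(10, 7)
        sets = build_dynamic_networks(ts, spec)
        windows = segment_sliding_windows(ts, spec)
        for k, w in enumerate(windows):
            c = low_order_network(w, window_index=k + 1)
            h = high_order_network(c)
            a = associated_high_order_network(c, h)
            np.testing.assert_array_equal(sets["low"].matrices[k].values, c.values)
            np.testing.assert_array_equal(sets["high"].matrices[k].values, h.values)
            np.testing.assert_array_equal(sets["associated"].matrices[k].values, a.values)

    def test_permutation_equivariance(self, rng):
        ts = random_time_series(rng, p=40, r=6)
        perm = rng.permutation(6)
        ts_p = SubjectTimeSeries(
            ts.data[:, perm], [ts.roi_labels[i] for i in perm], tr_seconds=3.0
        )
        orig = build_static_networks(ts)
        permuted = build_static_networks(ts_p)
        for t in ("low", "high", "associated"):
            np.testing.assert_allclose(
                permuted[t].values, orig[t].values[np.ix_(perm, perm)], atol=1e-12
            )
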