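"""Edge indexing, Pearson connectivity and temporal cleaning."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from connstab import (
    ConfoundSet,
    EdgeTable,
    ROITimeSeries,
    clean_timeseries,
    correlation_matrix,
    edge_index_to_pair,
    edge_pair_to_index,
    extract_roi_series,
    n_edges,
    unvectorize_edges,
    vectorize_edges,
)


class TestEdgeIndexing:
    @pytest.mark.parametrize(
        "k,n,pair",
        [(0, 90, (0, 1)), (4004, 90, (88, 89)), (0, 2, (0, 1)), (5, 4, (2, 3))],
    )
    def test_known_positions(self, k, n, pair):
        assert edge_index_to_pair(k, n) == pair
        assert edge_pair_to_index(*pair, n) == k

    def test_roundtrip_matches_enumeration(self):
        """Closed-form inverse agrees with brute-force upper-triangle listing."""
        for n in range(2, 21):
            pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
            assert len(pairs) == n_edges(n)
            for k, pair in enumerate(pairs):
                assert edge_index_to_pair(k, n) == pair
                assert edge_pair_to_index(*pair, n) == k

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            edge_index_to_pair(4005, 90)
        with pytest.raises(ValueError):
            edge_pair_to_index(3, 3, 90)


class TestVectorize:
    def test_lengths(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=(90, 90))
        m = np.clip((a + a.T) / 2, -0.99, 0.99) / 10
        np.fill_diagonal(m, 1.0)
        vec, edge_map = vectorize_edges(m)
        assert vec.shape == (4005,)
        assert edge_map[0] == (0, 1) and edge_map[-1] == (88, 89)

    def test_two_rois_single_edge(self):
        m = np.array([[1.0, 0.3], [0.3, 1.0]])
        vec, _ = vectorize_edges(m)
        assert vec.tolist() == [0.3]

    def test_canonical_order_n4(self):
        m = np.eye(4)
        m[0, 1] = m[1, 0] = 0.5
        m[2, 3] = m[3, 2] = -0.25
        vec, _ = vectorize_edges(m)
        assert vec[0] == 0.5 and vec[5] == -0.25

    def test_asymmetry_rejected(self):
        m = np.eye(3)
        m[0, 1] = 0.5
        with pytest.raises(ValueError, match="asymmetric"):
            vectorize_edges(m)

    def test_unvectorize_inverts(self):
        for n in range(2, 21):
            rng = np.random.default_rng(n)
            vec = rng.uniform(-1, 1, n_edges(n))
            back, _ = vectorize_edges(unvectorize_edges(vec, n))
            np.testing.assert_array_equal(back, vec)


class TestCorrelation:
    def _ts(self, cols):
        arr = np.column_stack(cols).astype(float)
        return ROITimeSeries(arr, tr=2.0, roi_names=[f"r{i}" for i in range(arr.shape[1])])

    @pytest.mark.parametrize(
        "a,b,r",
        [((1, 2, 3), (1, 2, 3), 1.0), ((1, 2, 3), (3, 2, 1), -1.0), ((1, 2, 3), (1, 3, 2), 0.5)],
    )
    def test_known_pairs(self, a, b, r):
        m = correlation_matrix(self._ts([a, b]))
        assert m.values[0, 1] == pytest.approx(r)
        assert m.values[0, 0] == 1.0 and m.values[1, 1] == 1.0

    def test_zero_variance_names_roi(self):
        with pytest.raises(ValueError, match="r1"):
            correlation_matrix(self._ts([(1, 2, 3), (5, 5, 5)]))

    @given(scale=st.floats(0.1, 50), shift=st.floats(-100, 100))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_affine_invariance(self, scale, shift):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(40, 4))
        base = correlation_matrix(
            ROITimeSeries(x, tr=2.0, roi_names=list("abcd"))
        ).values
        x2 = x.copy()
        x2[:, 1] = x2[:, 1] * scale + shift
        rescaled = correlation_matrix(
            ROITimeSeries(x2, tr=2.0, roi_names=list("abcd"))
        ).values
        np.testing.assert_allclose(rescaled, base, atol=1e-10)


class TestExtractROISeries:
    def test_one_unit_per_roi_is_identity(self):
        x = np.arange(12.0).reshape(4, 3)
        ts = extract_roi_series(x, ["a", "b", "c"], tr=2.0)
        np.testing.assert_array_equal(ts.values, x)

    def test_duplicate_units_average_to_member(self):
        col = np.array([1.0, 2.0, 3.0])
        ts = extract_roi_series(np.column_stack([col, col]), ["a", "a"], tr=2.0)
        np.testing.assert_array_equal(ts.values[:, 0], col)

    def test_arithmetic_mean(self):
        units = np.array([[1.0, 3.0], [2.0, 4.0], [3.0, 5.0]])
        ts = extract_roi_series(units, ["a", "a"], tr=2.0)
        np.testing.assert_array_equal(ts.values[:, 0], [2.0, 3.0, 4.0])

    def test_empty_roi_rejected(self):
        with pytest.raises(ValueError, match="'b'"):
            extract_roi_series(np.ones((3, 1)), ["a"], tr=2.0, roi_order=["a", "b"])


class TestCleanTimeseries:
    def _noise_ts(self, t=400, r=3, seed=0):
        rng = np.random.default_rng(seed)
        return ROITimeSeries(
            rng.normal(size=(t, r)), tr=2.0, roi_names=[f"r{i}" for i in range(r)]
        )

    def test_confound_identical_to_roi_removes_it(self):
        ts = self._noise_ts()
        conf = ConfoundSet(ts.values[:, :1].copy(), roles=["csf"])
        out = clean_timeseries(ts, conf)
        # that ROI's residual is ~0 before filtering, hence ~0 after
        assert np.max(np.abs(out.values[:, 0])) < 1e-8

    def test_passband_sinusoid_retained(self):
        t = np.arange(600) * 2.0
        x = np.sin(2 * np.pi * 0.05 * t)[:, None]
        out = clean_timeseries(ROITimeSeries(x, tr=2.0, roi_names=["a"]))
        mid = slice(60, 540)
        ratio = np.sqrt(np.mean(out.values[mid, 0] ** 2) / np.mean(x[mid, 0] ** 2))
        assert ratio > 0.9

    def test_stopband_sinusoid_attenuated(self):
        t = np.arange(600) * 2.0
        x = np.sin(2 * np.pi * 0.2 * t)[:, None]
        out = clean_timeseries(ROITimeSeries(x, tr=2.0, roi_names=["a"]))
        mid = slice(60, 540)
        ratio = np.sqrt(np.mean(out.values[mid, 0] ** 2) / np.mean(x[mid, 0] ** 2))
        assert ratio < 0.1

    def test_band_outside_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            clean_timeseries(self._noise_ts(), band=(0.01, 0.3))

    def test_idempotent_on_passband_content(self):
        """Re-cleaning already-cleaned in-band signal changes little away from edges."""
        t = np.arange(800) * 2.0
        x = (np.sin(2 * np.pi * 0.05 * t) + 0.5 * np.sin(2 * np.pi * 0.04 * t))[:, None]
        once = clean_timeseries(ROITimeSeries(x, tr=2.0, roi_names=["a"]))
        twice = clean_timeseries(once)
        mid = slice(80, 720)
        rel = np.max(np.abs(twice.values[mid, 0] - once.values[mid, 0])) / np.std(
            once.values[mid, 0]
        )
        assert rel < 0.05

    def test_rank_deficient_confounds_warn_not_fail(self, caplog):
        ts = self._noise_ts()
        col = np.random.default_rng(1).normal(size=(ts.n_timepoints, 1))
        conf = ConfoundSet(np.hstack([col, col]), roles=["csf", "wm"])
        with caplog.at_level("WARNING"):
            out = clean_timeseries(ts, conf)
        assert out.values.shape == ts.values.shape
        assert any("rank deficient" in r.message for r in caplog.records)


class TestEdgeTableIO:
    def test_csv_roundtrip(self, tmp_path, tiny_table):
        path = tmp_path / "edges.csv"
        tiny_table.to_csv(path)
        back = EdgeTable.from_csv(path)
        np.testing.assert_allclose(back.values, tiny_table.values)
        np.testing.assert_array_equal(back.labels, tiny_table.labels)
        assert back.n_roi == tiny_table.n_roi

    def test_from_timeseries_shape_and_values(self):
        rng = np.random.default_rng(5)
        series = [
            ROITimeSeries(rng.normal(size=(50, 4)), tr=2.0, roi_names=list("abcd"))
            for _ in range(4)
        ]
        table = EdgeTable.from_timeseries(series, labels=[0, 0, 1, 1])
        assert table.values.shape == (4, 6)
        expected, _ = vectorize_edges(correlation_matrix(series[0]))
        np.testing.assert_allclose(table.values[0], expected)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            EdgeTable(np.zeros((3, 3)), labels=[1, 1, 1], n_roi=3)
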