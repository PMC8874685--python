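import numpy as np
import pytest
from scipy.spatial.distance import cdist

from oracles import hog1d_reference
from sdatw.descriptors import (
    BASIC_KINDS,
    DescriptorConfig,
    describe,
    describe_window,
    descriptor_distance,
    distance_matrix,
    extract_subsequence,
)
from sdatw.errors import ParameterError

OFFSET_INVARIANT = ("slope", "derivative", "hog1d")


class TestExtractSubsequence:
    def test_interior_is_exact_slice(self):
        x = np.arange(20.0)
        np.testing.assert_array_equal(extract_subsequence(x, 10, 5), x[8:13])

    def test_edge_replication(self):
        np.testing.assert_array_equal(
            extract_subsequence(np.array([7.0, 8.0, 9.0]), 0, 3), [7.0, 7.0, 8.0]
        )

    def test_window_centers_reassemble_series(self):
        x = np.random.default_rng(0).normal(size=40)
        seq = describe(x, DescriptorConfig(kind="raw", l=7))
        np.testing.assert_array_equal(seq.vectors[:, 3], x)


class TestDescribeUnitTruths:
    def test_paa_interval_means(self):
        cfg = DescriptorConfig(kind="paa", l=9, intervals=5)
        got = describe_window(np.arange(1.0, 11.0), cfg)
        np.testing.assert_allclose(got, [1.5, 3.5, 5.5, 7.5, 9.5])

    @pytest.mark.parametrize("kind", ["slope", "derivative"])
    def test_ramp_maps_to_constant_slope(self, kind):
        slope = 0.7
        cfg = DescriptorConfig(kind=kind, l=11, intervals=3)
        got = describe_window(slope * np.arange(33.0), cfg)
        np.testing.assert_allclose(got, np.full_like(got, slope), atol=1e-12)

    @pytest.mark.parametrize("kind", ["slope", "derivative"])
    def test_constant_series_gives_zero_descriptors(self, kind):
        cfg = DescriptorConfig(kind=kind, l=9)
        seq = describe(np.full(30, 4.2), cfg)
        np.testing.assert_allclose(seq.vectors, 0.0, atol=1e-12)

    def test_dwt_details_of_constant_are_zero(self):
        cfg = DescriptorConfig(kind="dwt", l=15, dwt_levels=3)
        vec = describe_window(np.full(16, 3.0), cfg)
        # first block is the level-3 approximation; all detail blocks vanish
        n_approx = 16 // 2**3
        np.testing.assert_allclose(vec[n_approx:], 0.0, atol=1e-12)

    def test_hog1d_matches_reference_histograms(self):
        rng = np.random.default_rng(1)
        cfg = DescriptorConfig(kind="hog1d", l=31)
        for _ in range(5):
            w = rng.normal(size=31)
            got = describe_window(w, cfg)
            want = hog1d_reference(w, cfg.hog_bins, cfg.hog_intervals, cfg.hog_scale)
            np.testing.assert_allclose(got, want, atol=1e-12)

    @pytest.mark.parametrize("kind", OFFSET_INVARIANT)
    def test_fluctuation_descriptors_offset_invariant(self, kind):
        rng = np.random.default_rng(2)
        x = rng.normal(size=60)
        cfg = DescriptorConfig(kind=kind, l=11)
        a = describe(x, cfg).vectors
        b = describe(x + 123.456, cfg).vectors
        np.testing.assert_allclose(a, b, atol=1e-9)

    @pytest.mark.parametrize("kind", BASIC_KINDS)
    def test_descriptor_dimension_constant_and_finite(self, kind):
        x = np.random.default_rng(3).normal(size=50)
        seq = describe(x, DescriptorConfig(kind=kind, l=9, intervals=3, dwt_levels=2))
        assert seq.vectors.shape[0] == 50
        assert np.all(np.isfinite(seq.vectors))


class TestDistances:
    def test_identical_vectors_distance_zero(self):
        v = np.array([1.0, 2.0, 3.0])
        assert descriptor_distance(v, v) == 0.0

    def test_three_four_five(self):
        assert descriptor_distance([0.0, 0.0], [3.0, 4.0]) == pytest.approx(5.0)

    def test_symmetry(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            a, b = rng.normal(size=(2, 8))
            assert descriptor_distance(a, b) == pytest.approx(descriptor_distance(b, a))

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ParameterError):
            descriptor_distance([1.0], [1.0, 2.0])

    def test_query_equals_template_zero_diagonal(self):
        x = np.random.default_rng(5).normal(size=30)
        cfg = DescriptorConfig(kind="paa", l=7, intervals=3)
        dm = distance_matrix(describe(x, cfg), describe(x, cfg))
        np.testing.assert_allclose(np.diag(dm), 0.0, atol=1e-12)

    def test_minimal_case_single_distance(self):
        cfg = DescriptorConfig(kind="raw", l=1)
        q = describe(np.array([1.0, 5.0]), cfg)
        t = describe(np.array([2.0, 2.0]), cfg)
        dm = distance_matrix(q, t)
        assert dm[0, 0] == pytest.approx(
            descriptor_distance(q.vectors[0], t.vectors[0])
        )

    def test_raw_l1_reduces_to_pointwise_cost(self):
        rng = np.random.default_rng(6)
        q, t = rng.normal(size=25), rng.normal(size=10)
        cfg = DescriptorConfig(kind="raw", l=1)
        dm = distance_matrix(describe(q, cfg), describe(t, cfg))
        np.testing.assert_allclose(dm, np.abs(q[:, None] - t[None, :]), atol=1e-12)

    def test_multi_channel_distances_sum(self):
        rng = np.random.default_rng(7)
        cfg = DescriptorConfig(kind="paa", l=7, intervals=3)
        q1, q2 = rng.normal(size=(2, 20))
        t1, t2 = rng.normal(size=(2, 12))
        dm = distance_matrix(
            [describe(q1, cfg), describe(q2, cfg)],
            [describe(t1, cfg), describe(t2, cfg)],
        )
        expected = distance_matrix(describe(q1, cfg), describe(t1, cfg)) + \
            distance_matrix(describe(q2, cfg), describe(t2, cfg))
        np.testing.assert_allclose(dm, expected, atol=1e-12)

    def test_periodic_query_shows_four_alignment_valleys(self):
        # a query of 4 concatenated templates produces 4 near-zero
        # top-to-bottom alignment paths in the distance matrix
        rng = np.random.default_rng(8)
        t = np.cumsum(rng.normal(size=40))
        q = np.tile(t, 4)
        cfg = DescriptorConfig(kind="raw", l=5)
        dm = distance_matrix(describe(q, cfg), describe(t, cfg, pad="wrap"))
        diag_means = [
            np.mean([dm[k * 40 + j, j] for j in range(40)]) for k in range(4)
        ]
        assert all(d < 0.05 * dm.mean() for d in diag_means)


class TestCompound:
    def test_concatenation_distance_combines_blocks(self):
        rng = np.random.default_rng(9)
        x, y = rng.normal(size=(2, 40))
        cfg = DescriptorConfig.from_name("hog1d+raw", l=9)
        a_cfg, b_cfg = cfg.components
        full_q, full_t = describe(x, cfg).vectors, describe(y, cfg).vectors
        d_full = cdist(full_q, full_t)

        def normalized(series, c):
            block = describe(series, c).vectors
            norms = np.linalg.norm(block, axis=1, keepdims=True)
            return block / np.where(norms == 0, 1, norms)

        d_a = cdist(normalized(x, a_cfg), normalized(y, a_cfg))
        d_b = cdist(normalized(x, b_cfg), normalized(y, b_cfg))
        wa, wb = cfg.weights
        np.testing.assert_allclose(
            d_full, np.sqrt(wa**2 * d_a**2 + wb**2 * d_b**2), atol=1e-10
        )

    def test_json_round_trip(self):
        cfg = DescriptorConfig.from_name("hog1d+paa", l=15)
        assert DescriptorConfig.from_json(cfg.to_json()) == cfg

    def test_from_name_rejects_unknown(self):
        with pytest.raises(ParameterError):
            DescriptorConfig.from_name("fourier")
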