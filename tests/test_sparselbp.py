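import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mammocad as mc
from mammocad.sparselbp import _RING, NONUNIFORM

from conftest import naive_sparse_lbp


class TestCodebook:
    def test_exactly_58_uniform_patterns(self):
        cb = mc.uniform_codebook(8)
        assert len(cb) == 58
        assert sorted(cb.values()) == list(range(58))

    def test_transition_rule(self):
        cb = mc.uniform_codebook(8)
        assert 0b11111111 in cb and 0b00000000 in cb
        assert 0b00001111 in cb          # one block: 2 transitions
        assert 0b01010101 not in cb      # alternating: 8 transitions


class TestUlbpCode:
    def test_all_neighbors_equal_center(self):
        win = np.full((3, 3), 0.5)
        # ties set the bit -> pattern 11111111, uniform
        assert mc.ulbp_code(win) == mc.uniform_codebook(8)[0xFF]

    def test_all_neighbors_below_center(self):
        win = np.full((3, 3), 0.2)
        win[1, 1] = 0.9
        assert mc.ulbp_code(win) == mc.uniform_codebook(8)[0x00]

    @settings(derandomize=True, max_examples=200)
    @given(st.lists(st.floats(-1, 1, allow_nan=False, allow_infinity=False),
                    min_size=9, max_size=9))
    def test_code_matches_definition_on_arbitrary_windows(self, vals):
        # bit p set iff ring neighbor >= center; uniform iff <= 2 circular
        # transitions; bin taken from the ascending-pattern codebook
        win = np.array(vals).reshape(3, 3)
        bits = [1 if win[1 + dr, 1 + dc] >= win[1, 1] else 0
                for dr, dc in _RING]
        transitions = sum(bits[i] != bits[(i + 1) % 8] for i in range(8))
        code = sum(b << p for p, b in enumerate(bits))
        expected = (mc.uniform_codebook(8)[code] if transitions <= 2
                    else NONUNIFORM)
        assert mc.ulbp_code(win) == expected

    def test_alternating_ring_nonuniform(self):
        win = np.full((3, 3), 0.5)
        # set alternate ring positions above center: 8 transitions
        for dr, dc in [(0, 1), (-1, 0), (0, -1), (1, 0)]:
            win[1 + dr, 1 + dc] = 0.9
        for dr, dc in [(-1, 1), (-1, -1), (1, -1), (1, 1)]:
            win[1 + dr, 1 + dc] = 0.1
        assert mc.ulbp_code(win) == NONUNIFORM


class TestBuildLookup:
    def test_all_zero_band(self):
        lut = mc.build_lookup(np.zeros((6, 6)))
        assert not lut.foreground.any()
        assert len(lut) == 16

    def test_all_nonzero_band(self, rng):
        lut = mc.build_lookup(rng.random((6, 6)) + 0.5)
        assert lut.foreground.all()

    def test_diagonal_hand_count(self):
        # 5x5 band with 3 nonzeros on the diagonal: every interior window
        # covers all 3 of them except the corners of the 3x3 window grid
        band = np.zeros((5, 5))
        band[1, 1] = band[2, 2] = band[3, 3] = 1.0
        lut = mc.build_lookup(band)
        fg = dict(zip(map(tuple, lut.centers), lut.foreground))
        expected = {(r, c): len({1, 2, 3} & {d for d in (1, 2, 3)
                                 if abs(d - r) <= 1 and abs(d - c) <= 1}) >= 3
                    for r in (1, 2, 3) for c in (1, 2, 3)}
        assert fg == expected

    def test_count_two_is_background(self):
        band = np.zeros((3, 3))
        band[0, 0] = band[2, 2] = 1.0
        lut = mc.build_lookup(band)
        assert not lut.foreground[0]

    def test_too_small(self):
        with pytest.raises(ValueError):
            mc.build_lookup(np.zeros((2, 5)))


class TestSparseLbpHist:
    def test_58_bins(self, rng):
        h = mc.sparse_lbp_hist(rng.random((10, 10)))
        assert h.bins.shape == (58,)

    def test_all_zero_band(self):
        h = mc.sparse_lbp_hist(np.zeros((8, 8)))
        assert h.n_foreground == 0
        assert np.all(h.bins == 0)

    def test_dense_band_equals_plain_ulbp(self, rng):
        band = rng.random((20, 20)) + 0.1  # no zeros anywhere
        mine = mc.sparse_lbp_hist(band)
        ref, n_fg = naive_sparse_lbp(band, 0.0)
        assert n_fg == 18 * 18
        assert np.allclose(mine.bins, ref)

    def test_normalized_or_zero(self, rng):
        band = rng.normal(size=(15, 15)) * (rng.random((15, 15)) < 0.3)
        h = mc.sparse_lbp_hist(band)
        if h.bins.sum() > 0:
            assert h.bins.sum() == pytest.approx(1.0)

    def test_oracle_equivalence_random_sparse_bands(self, rng):
        # lookup-table path must agree bin-for-bin with the per-pixel
        # reference on sparse bands
        for _ in range(100):
            h = int(rng.integers(4, 33))
            w = int(rng.integers(4, 33))
            band = rng.normal(size=(h, w)) * (rng.random((h, w)) < 0.4)
            tol = float(rng.choice([0.0, 1e-9, 0.05]))
            mine = mc.sparse_lbp_hist(band, tol)
            ref, n_fg = naive_sparse_lbp(band, tol)
            assert mine.n_foreground == n_fg
            assert np.allclose(mine.bins, ref)

    def test_translation_invariance(self, rng):
        core = rng.normal(size=(8, 8)) * (rng.random((8, 8)) < 0.6)
        a = np.zeros((20, 20))
        b = np.zeros((20, 20))
        a[3:11, 3:11] = core
        b[7:15, 9:17] = core
        ha = mc.sparse_lbp_hist(a)
        hb = mc.sparse_lbp_hist(b)
        assert np.allclose(ha.bins, hb.bins)
        assert ha.n_foreground == hb.n_foreground


class TestDescribeRoi:
    def test_length_986(self):
        roi = mc.make_sparse_roi((30, 26), 0.3, 0.4, seed=1)
        vec = mc.describe_roi(roi)
        assert vec.shape == (986,)

    def test_zero_roi(self):
        roi = mc.SparseROI(pixels=np.zeros((30, 30)))
        assert np.all(mc.describe_roi(roi) == 0)

    def test_minimum_size_enforced(self):
        with pytest.raises(ValueError):
            mc.describe_roi(mc.SparseROI(pixels=np.zeros((20, 20))))

    def test_deterministic(self):
        roi = mc.make_sparse_roi((28, 24), 0.4, 0.4, seed=9)
        assert np.array_equal(mc.describe_roi(roi), mc.describe_roi(roi))

    def test_foreground_reduction_on_sparse_roi(self):
        # the sparse rule must reject some windows on every subband of a
        # genuinely sparse ROI, and the count must match a direct
        # re-computation of the > 2 nonzero rule
        roi = mc.make_sparse_roi((32, 28), 0.3, 0.4, seed=2)
        for band in mc.sparse_subbands(roi):
            tol = 1e-6 * np.abs(band).max()
            lut = mc.build_lookup(band, tol)
            n_fg_direct = sum(
                1
                for r in range(1, band.shape[0] - 1)
                for c in range(1, band.shape[1] - 1)
                if (np.abs(band[r - 1:r + 2, c - 1:c + 2]) > tol).sum() > 2)
            assert lut.foreground.sum() == n_fg_direct
            assert lut.foreground.sum() < len(lut)

    def test_subband_support_masked(self):
        # coefficients off the mass support are exactly zero in every band
        roi = mc.make_sparse_roi((30, 26), 0.4, 0.4, seed=3)
        for band in mc.sparse_subbands(roi):
            assert np.all(band[~roi.mask] == 0.0)
        stats = mc.roi_reduction_stats(roi)
        assert 0 < stats["window_reduction_pct"] < 100
        assert 0 < stats["coefficient_reduction_pct"] < 100


class TestSpatialSparseLbp:
    def test_58_bins(self):
        roi = mc.make_sparse_roi((28, 24), 0.3, 0.4, seed=0)
        assert mc.spatial_sparse_lbp(roi).bins.shape == (58,)

    def test_all_positive_equals_plain_ulbp(self, rng):
        roi = mc.SparseROI(pixels=rng.random((20, 20)) * 0.5 + 0.25)
        mine = mc.spatial_sparse_lbp(roi)
        ref, _ = naive_sparse_lbp(roi.pixels, 0.0)
        assert np.allclose(mine.bins, ref)

    def test_sparse_support_zero_histogram(self):
        pixels = np.zeros((30, 30))
        pixels[::5, ::5] = 0.5  # never 3 nonzeros in any 3x3 window
        h = mc.spatial_sparse_lbp(mc.SparseROI(pixels=pixels))
        assert h.n_foreground == 0
        assert np.all(h.bins == 0)


def test_reduction_stats(rng):
    band = rng.normal(size=(20, 20)) * (rng.random((20, 20)) < 0.3)
    stats = mc.reduction_stats(band)
    assert 0 <= stats["window_reduction_pct"] <= 100
    assert stats["coefficient_reduction_pct"] == pytest.approx(
        100.0 * (band == 0).mean())
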