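"""Outline projection, slide/flip algebra and the form dissimilarity."""

import numpy as np
import pytest

from ippkit import outline, plots
from ippkit.errors import InvalidInputError, InvalidShiftError
from ippkit.outline import OutlineVector, hflip, outline_dissimilarity, slide


def brute_force_dissimilarity(a, b, max_slide):
    """Exhaustive minimum over every slide and flip, both directions.

    Written directly from the slide/flip definitions, independent of the
    library's vectorised transform stack.
    """

    def slid(v, n):
        v = list(v)
        if n > 0:
            return v[n:] + [0.0] * n
        if n < 0:
            return [0.0] * (-n) + v[:n]
        return v

    def directed(x, y):
        best = np.inf
        for n in range(-max_slide, max_slide + 1):
            for flip in (False, True):
                yy = list(y[::-1]) if flip else list(y)
                d = np.sqrt(sum((xi - yi) ** 2 for xi, yi in zip(x, slid(yy, n))))
                best = min(best, d)
        return best

    return min(directed(list(a), list(b)), directed(list(b), list(a)))


class TestSlideFlip:
    @pytest.mark.parametrize(
        "n,expected",
        [(0, [1, 2, 3, 4]), (-1, [0, 1, 2, 3]), (1, [2, 3, 4, 0]), (2, [3, 4, 0, 0]), (-3, [0, 0, 0, 1])],
    )
    def test_slide_definition(self, n, expected):
        np.testing.assert_array_equal(slide(np.array([1.0, 2, 3, 4]), n), expected)

    def test_slide_magnitude_bounded(self):
        with pytest.raises(InvalidShiftError):
            slide(np.arange(4.0), 4)

    def test_slide_preserves_metadata(self):
        v = OutlineVector(np.arange(5.0), 0.01, plot_id="p1")
        out = slide(v, 2)
        assert isinstance(out, OutlineVector) and out.plot_id == "p1" and out.bin_width == 0.01

    def test_hflip_reverses_and_is_involution(self, rng):
        np.testing.assert_array_equal(hflip(np.array([1.0, 2, 3])), [3, 2, 1])
        v = rng.uniform(size=20)
        np.testing.assert_array_equal(hflip(hflip(v)), v)
        np.testing.assert_array_equal(hflip(np.zeros(5)), np.zeros(5))


def _tile_from_heights(dsm, gsd=0.004, ridge=(1.0, 0.0)):
    h, w = dsm.shape
    return plots.PlotTile(
        plot_id="t",
        rgb=np.zeros((h, w, 3), np.uint8),
        dsm=np.asarray(dsm, float),
        ground=np.zeros((h, w)),
        inside=np.ones((h, w), bool),
        transform=plots.GeoTransform(0.0, h * gsd, gsd, gsd),
        ridge_axis=ridge,
    )


class TestProjectOutline:
    def test_single_pixel_plant(self):
        dsm = np.zeros((20, 20))
        dsm[10, 10] = 0.7
        mask = dsm > 0
        v = outline.project_outline(_tile_from_heights(dsm), mask, bin_width=0.004, length=33)
        nz = np.nonzero(v.values)[0]
        assert len(nz) == 1 and v.values[nz[0]] == pytest.approx(0.7)

    def test_uniform_strip_fills_consecutive_bins(self):
        dsm = np.zeros((10, 40))
        dsm[4:6, 10:30] = 0.5  # 20 columns at 4 mm -> 80 mm along the ridge
        mask = dsm > 0
        v = outline.project_outline(_tile_from_heights(dsm), mask, bin_width=0.004, length=61)
        filled = np.nonzero(v.values)[0]
        assert np.array_equal(filled, np.arange(filled[0], filled[0] + 20))
        assert np.allclose(v.values[filled], 0.5)

    def test_dome_matches_direct_binning_oracle(self, rng):
        n = 60
        xs = (np.arange(n) + 0.5) * 0.004
        dome = np.clip(0.6 * (1 - ((xs[None, :] - 0.12) ** 2 + (xs[:, None] - 0.12) ** 2) / 0.01), 0, None)
        mask = dome > 0
        tile = _tile_from_heights(dome)
        L, bw = 81, 0.004
        v = outline.project_outline(tile, mask, bin_width=bw, length=L)

        # oracle: re-bin by explicit loop over mask pixels
        rr, cc = np.nonzero(mask)
        x_world = (cc + 0.5) * 0.004
        s = x_world - x_world.mean()  # ridge = +x; centroid-centred
        expected = np.zeros(L)
        bins = np.floor(s / bw).astype(int) + L // 2
        for b in np.unique(bins):
            expected[b] = np.percentile(dome[rr[bins == b], cc[bins == b]], 99)
        np.testing.assert_allclose(v.values, expected, atol=1e-12)

    def test_empty_mask_warns_and_returns_zeros(self):
        tile = _tile_from_heights(np.zeros((5, 5)))
        with pytest.warns(UserWarning):
            v = outline.project_outline(tile, np.zeros((5, 5), bool), length=11)
        assert not v.values.any()


class TestDissimilarity:
    def test_self_distance_zero(self, rng):
        v = rng.uniform(size=50)
        assert outline_dissimilarity(v, v, max_slide=10) == 0.0

    def test_flip_distance_zero(self, rng):
        v = rng.uniform(size=50)
        assert outline_dissimilarity(v, v[::-1].copy(), max_slide=0) == 0.0

    def test_slide_within_margin_distance_zero(self, rng):
        v = np.zeros(60)
        v[25:35] = rng.uniform(1, 2, 10)
        for k in (1, 5, 10):
            assert outline_dissimilarity(v, slide(v, k), max_slide=10) == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_on_random_pairs(self, rng):
        for _ in range(25):
            a, b = rng.uniform(size=50), rng.uniform(size=50)
            got = outline_dissimilarity(a, b, max_slide=10)
            assert got == pytest.approx(brute_force_dissimilarity(a, b, 10), abs=1e-12)

    def test_monotone_in_max_slide(self, rng):
        a, b = rng.uniform(size=40), rng.uniform(size=40)
        ds = [outline_dissimilarity(a, b, max_slide=k) for k in (0, 2, 5, 10, 20)]
        assert all(d1 >= d2 - 1e-12 for d1, d2 in zip(ds, ds[1:]))

    def test_positive_scaling_scales_distance(self, rng):
        a, b = rng.uniform(size=40), rng.uniform(size=40)
        d1 = outline_dissimilarity(a, b, max_slide=5)
        d3 = outline_dissimilarity(3 * a, 3 * b, max_slide=5)
        assert d3 == pytest.approx(3 * d1, rel=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(InvalidInputError):
            outline_dissimilarity(np.zeros(10), np.zeros(11))

    def test_l1_metric_option(self, rng):
        a, b = rng.uniform(size=30), rng.uniform(size=30)
        d_l1 = outline_dissimilarity(a, b, max_slide=0, metric="l1")
        assert d_l1 >= outline_dissimilarity(a, b, max_slide=0)  # L1 >= L2 elementwise sums


class TestDissimilarityMatrix:
    def test_single_outline_gives_zero_matrix(self):
        dm = outline.dissimilarity_matrix([OutlineVector(np.arange(5.0), 0.01, "a")])
        assert dm.matrix.shape == (1, 1) and dm.matrix[0, 0] == 0.0

    def test_duplicate_outline_off_diagonal_zero(self, rng):
        v = rng.uniform(size=30)
        dm = outline.dissimilarity_matrix(
            [OutlineVector(v, 0.01, "a"), OutlineVector(v.copy(), 0.01, "b")], max_slide=3
        )
        assert dm.matrix[0, 1] == 0.0

    def test_matrix_matches_pairwise_operation(self, rng):
        vecs = [OutlineVector(rng.uniform(size=30), 0.01, f"p{i}") for i in range(5)]
        dm = outline.dissimilarity_matrix(vecs, max_slide=4)
        assert np.allclose(dm.matrix, dm.matrix.T) and np.allclose(np.diag(dm.matrix), 0)
        for i in range(5):
            for j in range(i + 1, 5):
                assert dm.matrix[i, j] == pytest.approx(
                    outline_dissimilarity(vecs[i], vecs[j], max_slide=4), abs=1e-12
                )


class TestAlgebraProperties:
    """Hypothesis checks of the slide/flip algebra on arbitrary vectors."""

    from hypothesis import given, settings, strategies as st
    from hypothesis.extra.numpy import arrays

    vectors = arrays(
        np.float64,
        st.integers(4, 40),
        elements=st.floats(0, 10, allow_nan=False, width=32),
    )

    @given(v=vectors, n=st.integers(-3, 3))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_slide_preserves_length_and_mass_bound(self, v, n):
        out = slide(v, n)
        assert out.size == v.size
        assert out.sum() <= v.sum() + 1e-9  # sliding only discards mass

    @given(v=vectors)
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_flip_is_involution_and_distance_invariant(self, v):
        np.testing.assert_array_equal(hflip(hflip(v)), v)
        assert outline_dissimilarity(v, hflip(v), max_slide=0) == pytest.approx(0.0, abs=1e-9)

    @given(v=vectors, n=st.integers(1, 3))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_opposite_slides_cancel_on_padded_vectors(self, v, n):
        padded = np.concatenate([np.zeros(3), v, np.zeros(3)])
        np.testing.assert_array_equal(slide(slide(padded, n), -n)[n:-n or None], padded[n:-n or None])
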