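"""Windowing, CLAHE and Wiener filter contracts."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from skimage.exposure import equalize_hist

from nodulepipe.image_io import SliceImage
from nodulepipe.preprocess import (ClaheParams, LUNG_WINDOW, SOFT_TISSUE_WINDOW,
                                   WienerParams, WindowSpec, apply_window, clahe,
                                   preprocess_slice, wiener_filter)


def unit_slice(arr):
    return SliceImage(np.asarray(arr, dtype=float), unit_normalized=True)


def hu_slice(arr):
    return SliceImage(np.asarray(arr, dtype=float), unit_normalized=False)


class TestApplyWindow:
    @pytest.mark.parametrize("hu,expected", [(-1350.0, 0.0), (-600.0, 0.5),
                                             (150.0, 1.0), (-2000.0, 0.0),
                                             (500.0, 1.0)])
    def test_lung_window_endpoints_and_midpoint(self, hu, expected):
        out = apply_window(hu_slice(np.full((4, 4), hu)), LUNG_WINDOW)
        assert np.allclose(out.pixels, expected)
        assert out.unit_normalized

    def test_soft_tissue_window_clips_low(self):
        out = apply_window(hu_slice(np.full((4, 4), -1000.0)), SOFT_TISSUE_WINDOW)
        assert np.all(out.pixels == 0.0)

    def test_monotone_on_full_hu_sweep(self):
        sweep = np.linspace(-1400, 400, 1801).reshape(1, -1)
        out = apply_window(hu_slice(sweep), LUNG_WINDOW).pixels[0]
        assert np.all(np.diff(out) >= 0)

    def test_linear_in_window_interior(self):
        hu = np.array([[-975.0, -225.0]])
        out = apply_window(hu_slice(hu), LUNG_WINDOW).pixels
        assert np.allclose(out, [[0.25, 0.75]])

    def test_rejects_unit_normalized_input(self):
        with pytest.raises(ValueError):
            apply_window(unit_slice(np.zeros((4, 4))), LUNG_WINDOW)

    def test_invalid_width(self):
        with pytest.raises(ValueError):
            WindowSpec(center=0, width=0)


class TestClahe:
    def test_constant_image_unchanged_contrast(self):
        # no contrast to equalize: output must stay constant
        out = clahe(unit_slice(np.full((16, 16), 0.4)),
                    ClaheParams(tile_grid=(2, 2)))
        assert np.ptp(out.pixels) < 1e-12

    def test_output_in_unit_interval_and_same_shape(self, rng):
        img = unit_slice(rng.random((32, 24)))
        out = clahe(img, ClaheParams(tile_grid=(4, 3)))
        assert out.shape == (32, 24)
        assert out.pixels.min() >= 0 and out.pixels.max() <= 1

    def test_bimodal_contrast_non_decreasing(self):
        # 50/50 two-level image with a generous clip limit: equalization
        # pushes the levels apart (or keeps them), never closer
        img = np.zeros((16, 16))
        img[:, 8:] = 0.6
        img += 0.2
        before = 0.6
        out = clahe(unit_slice(img), ClaheParams(clip_limit=1.0, tile_grid=(1, 1)))
        after = float(out.pixels[:, 8:].mean() - out.pixels[:, :8].mean())
        assert after >= before - 1e-9

    def test_unclipped_single_tile_matches_global_equalization(self, rng):
        # clip -> infinity with one tile reduces to plain histogram
        # equalization; reference: skimage equalize_hist on the fixture
        img = rng.random((8, 8))
        ours = clahe(unit_slice(img), ClaheParams(clip_limit=1e9, tile_grid=(1, 1),
                                                  n_bins=4096)).pixels
        ref = equalize_hist(img, nbins=4096)
        # both are CDF maps; anchoring of the lowest bin differs slightly
        assert np.allclose(ours, ref, atol=0.05)

    def test_unclipped_limit_matches_ahe_oracle(self, rng):
        """clip->inf equals plain tile-wise adaptive equalization.

        The oracle re-derives per-tile CDF maps and bilinear blending
        with independent per-pixel loops.
        """
        img = rng.random((8, 8))
        p = ClaheParams(clip_limit=1e12, tile_grid=(2, 2), n_bins=64)
        ours = clahe(unit_slice(img), p).pixels

        # --- independent AHE oracle -----------------------------------
        n_bins = p.n_bins
        edges_r, edges_c = [0, 4, 8], [0, 4, 8]
        luts = {}
        for ti in range(2):
            for tj in range(2):
                tile = img[edges_r[ti]:edges_r[ti + 1], edges_c[tj]:edges_c[tj + 1]]
                hist = np.zeros(n_bins)
                for v in tile.ravel():
                    hist[min(int(v * n_bins), n_bins - 1)] += 1
                cdf = np.cumsum(hist)
                cdf_min = cdf[np.nonzero(hist)[0][0]]
                # bins below a tile's observed minimum map to 0
                luts[ti, tj] = np.clip((cdf - cdf_min) / (cdf[-1] - cdf_min), 0, 1)
        centers_r = centers_c = [2.0, 6.0]
        oracle = np.zeros_like(img)
        for r in range(8):
            for c in range(8):
                fi = min(max((r - centers_r[0]) / 4.0, 0.0), 1.0)
                fj = min(max((c - centers_c[0]) / 4.0, 0.0), 1.0)
                b = min(int(img[r, c] * n_bins), n_bins - 1)
                oracle[r, c] = (
                    (1 - fi) * (1 - fj) * luts[0, 0][b]
                    + (1 - fi) * fj * luts[0, 1][b]
                    + fi * (1 - fj) * luts[1, 0][b]
                    + fi * fj * luts[1, 1][b]
                )
        assert np.allclose(ours, np.clip(oracle, 0, 1), atol=1e-9)

    def test_tile_grid_larger_than_image_errors(self):
        with pytest.raises(ValueError, match="tile grid"):
            clahe(unit_slice(np.zeros((4, 4))), ClaheParams(tile_grid=(8, 8)))

    def test_requires_unit_input(self):
        with pytest.raises(ValueError):
            clahe(hu_slice(np.zeros((8, 8))))


class TestWienerFilter:
    def test_constant_image_is_identity(self):
        img = unit_slice(np.full((16, 16), 0.7))
        out = wiener_filter(img, WienerParams(kernel=(5, 5)))
        assert np.allclose(out.pixels, 0.7)

    def test_reduces_variance_on_pure_noise(self):
        rng = np.random.default_rng(77)
        noise = np.clip(0.5 + rng.normal(0, 0.1, (64, 64)), 0, 1)
        out = wiener_filter(unit_slice(noise), WienerParams(kernel=(5, 5)))
        assert out.pixels.var() < noise.var()

    def test_matches_scipy_wiener_in_interior(self, rng):
        # independent cross-check away from boundary-handling differences
        from scipy.signal import wiener as scipy_wiener
        img = np.clip(0.5 + rng.normal(0, 0.05, (32, 32)), 0, 1)
        sigma2 = 0.05 ** 2
        ours = wiener_filter(unit_slice(img),
                             WienerParams(kernel=(3, 3), noise_power=sigma2)).pixels
        ref = scipy_wiener(img, (3, 3), noise=sigma2)
        assert np.allclose(ours[4:-4, 4:-4], ref[4:-4, 4:-4], atol=1e-10)

    def test_step_edge_location_preserved(self):
        rng = np.random.default_rng(5)
        img = np.zeros((32, 32))
        img[:, 16:] = 1.0
        noisy = np.clip(img + rng.normal(0, 0.01, img.shape), 0, 1)
        out = wiener_filter(unit_slice(noisy), WienerParams(kernel=(3, 3))).pixels
        for row in (4, 16, 28):
            assert np.argmax(np.diff(out[row])) == np.argmax(np.diff(img[row]))

    def test_even_kernel_errors(self):
        with pytest.raises(ValueError, match="odd"):
            WienerParams(kernel=(4, 4))


class TestPreprocessSlice:
    def test_constant_window_floor_slice_full_chain(self):
        # at the lung-window floor (-1350 HU) the whole chain emits zeros
        sl = hu_slice(np.full((512, 512), -1350.0))
        out = preprocess_slice(sl, target_size=(256, 256))
        assert out.shape == (256, 256)
        assert np.allclose(out.pixels, 0.0)

    def test_constant_air_slice_stays_constant(self):
        # air (-1000 HU) sits inside the lung window at (low+350)/1500
        sl = hu_slice(np.full((512, 512), -1000.0))
        out = preprocess_slice(sl, target_size=(256, 256))
        assert np.ptp(out.pixels) < 1e-12

    def test_phantom_slice_contract(self, phantom_cases):
        cases, _ = phantom_cases
        sl = cases[0].image.slice(0)
        out = preprocess_slice(sl, c=ClaheParams(tile_grid=(4, 4)),
                               target_size=(32, 32))
        assert out.shape == (32, 32)
        assert out.pixels.min() >= 0 and out.pixels.max() <= 1

    def test_disabled_stages_equal_window_resize(self, rng):
        sl = hu_slice(rng.normal(-600, 400, (64, 64)))
        from nodulepipe.image_io import resize_slice
        chain = preprocess_slice(sl, c=None, n=None, target_size=(32, 32))
        manual = resize_slice(apply_window(sl, LUNG_WINDOW), (32, 32))
        assert np.array_equal(chain.pixels, manual.pixels)

    def test_pure_function_bit_identical(self, rng):
        sl = hu_slice(rng.normal(-600, 400, (64, 64)))
        a = preprocess_slice(sl, c=ClaheParams(tile_grid=(4, 4)), target_size=(32, 32))
        b = preprocess_slice(sl, c=ClaheParams(tile_grid=(4, 4)), target_size=(32, 32))
        assert np.array_equal(a.pixels, b.pixels)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10 ** 6))
def test_window_idempotent_on_clipped_and_monotone(seed):
    """Windowing of random HU data is monotone and clips into [0,1]."""
    rng = np.random.default_rng(seed)
    hu = rng.uniform(-1400, 500, (6, 6))
    out = apply_window(hu_slice(hu), LUNG_WINDOW).pixels
    assert out.min() >= 0 and out.max() <= 1
    order = np.argsort(hu.ravel())
    assert np.all(np.diff(out.ravel()[order]) >= -1e-12)
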