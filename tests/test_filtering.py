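import numpy as np
import pytest

import glogseed as gs
from glogseed.exceptions import DimensionError, ParameterError
from glogseed.filtering import ConvolutionConfig, convolve2d, to_uint8
from glogseed.kernels import Kernel2D, quantize_kernel


def identity_kernel():
    return Kernel2D(np.array([[1.0]]), (0, 0))


class TestConvolve2d:
    def test_identity_kernel(self, rng):
        img = rng.integers(0, 256, (9, 13)).astype(np.uint8)
        out = convolve2d(img, identity_kernel())
        assert np.array_equal(out, img.astype(float))

    def test_constant_image_with_normalized_kernel(self):
        img = np.full((16, 16), 77, dtype=np.uint8)
        out = convolve2d(img, gs.make_gaussian_kernel(7, 1.3))
        assert np.allclose(out, 77.0)

    def test_center_of_averaging_kernel_zero_border(self, rng):
        img = rng.integers(0, 256, (3, 3)).astype(np.uint8)
        k = Kernel2D(np.full((3, 3), 1.0 / 9.0), (1, 1))
        out = convolve2d(img, k, ConvolutionConfig(border_mode="zero"))
        assert out[1, 1] == pytest.approx(img.mean())

    def test_transpose_consistency(self, rng):
        img = rng.integers(0, 256, (12, 17)).astype(np.uint8)
        k = gs.glog_kernel(8.0, 6.0, 0.4, 7)
        a = convolve2d(img, k).T
        kt = Kernel2D(k.weights.T, k.center)
        b = convolve2d(img.T, kt)
        assert np.allclose(a, b)

    def test_linearity_float_mode(self, rng):
        i1 = rng.integers(0, 100, (10, 10)).astype(np.uint8)
        i2 = rng.integers(0, 100, (10, 10)).astype(np.uint8)
        k = gs.make_gaussian_kernel(5, 1.0)
        cfg = ConvolutionConfig(border_mode="zero")
        lhs = convolve2d(2 * i1.astype(float) + 3 * i2.astype(float), k, cfg)
        rhs = 2 * convolve2d(i1, k, cfg) + 3 * convolve2d(i2, k, cfg)
        assert np.allclose(lhs, rhs)

    def test_reflect_kernel_too_large(self):
        img = np.zeros((3, 3), dtype=np.uint8)
        k = gs.make_gaussian_kernel(9, 1.0)
        with pytest.raises(DimensionError):
            convolve2d(img, k, ConvolutionConfig(border_mode="reflect"))

    def test_invalid_config(self):
        with pytest.raises(ParameterError):
            ConvolutionConfig(border_mode="wrap")
        with pytest.raises(ParameterError):
            ConvolutionConfig(arithmetic="double")


class TestToUint8:
    def test_truncation_toward_zero(self):
        assert to_uint8(np.array([[254.7]]))[0, 0] == 254

    def test_constant_map_smoothing_path_unchanged(self):
        img = np.full((4, 4), 123.0)
        assert (to_uint8(img) == 123).all()

    def test_rescale_endpoints(self):
        m = np.array([[-3.2, 12.8], [4.0, -3.2]])
        out = to_uint8(m, rescale=True)
        assert out[0, 0] == 0 and out[1, 1] == 0
        assert out[0, 1] == 255

    def test_rescale_constant_map_is_zero(self):
        assert (to_uint8(np.full((3, 3), 9.9), rescale=True) == 0).all()


class TestGaussianSmooth:
    def test_constant_image_unchanged(self):
        img = np.full((20, 20), 140, dtype=np.uint8)
        assert np.array_equal(gs.gaussian_smooth(img, 7, 1.0), img)

    def test_single_bright_pixel_symmetric_peak(self):
        img = np.zeros((21, 21), dtype=np.uint8)
        img[10, 10] = 255
        H = gs.gaussian_smooth(img, 7, 1.0)
        assert np.unravel_index(np.argmax(H), H.shape) == (10, 10)
        assert np.array_equal(H, H.T)
        assert np.array_equal(H, np.rot90(H, 2))

    def test_impulse_response_equals_quantized_kernel(self):
        # fixed mode: impulse of amplitude 128 reproduces the quantized taps
        img = np.zeros((15, 15), dtype=np.uint8)
        img[7, 7] = 128
        k = gs.make_gaussian_kernel(7, 1.0)
        qk = quantize_kernel(k)
        resp = convolve2d(img, k, ConvolutionConfig(arithmetic="fixed", border_mode="zero"))
        expected = np.zeros((15, 15))
        # out(p) = sum_t k(t) img(p - t + center): the tap at offset d from the
        # center lands at pixel (7,7) + d, so the weights appear unflipped
        expected[4:11, 4:11] = qk.weights * 128
        assert np.allclose(resp, expected)

    def test_float_vs_fixed_within_one_level(self, rng):
        for _ in range(25):
            img = rng.integers(0, 256, (64, 64)).astype(np.uint8)
            a = gs.gaussian_smooth(img, 7, 1.0, ConvolutionConfig(arithmetic="float"))
            b = gs.gaussian_smooth(img, 7, 1.0, ConvolutionConfig(arithmetic="fixed"))
            assert np.abs(a.astype(int) - b.astype(int)).max() <= 1


class TestResponseMaps:
    def test_ten_maps_in_order(self, default_bank):
        H = np.random.default_rng(3).integers(0, 256, (40, 40)).astype(np.uint8)
        maps = gs.glog_response_maps(H, default_bank)
        assert len(maps) == 10
        assert all(m.shape == H.shape and m.dtype == np.uint8 for m in maps)

    def test_constant_image_gives_constant_maps(self, default_bank):
        H = np.full((40, 40), 90, dtype=np.uint8)
        for m in gs.glog_response_maps(H, default_bank):
            assert (m == m.flat[0]).all()

    @pytest.mark.parametrize("bright", [False, True])
    def test_blob_peak_at_center(self, default_bank, bright):
        # a radius-8 blob: the RS response map must peak within 2 px of center
        size = 80
        rows, cols = np.mgrid[0:size, 0:size].astype(float)
        prof = np.exp(-(((rows - 40) ** 2 + (cols - 40) ** 2) / (2 * 4.0 ** 2)))
        base = 60 + 140 * prof if bright else 200 - 140 * prof
        H = np.rint(base).astype(np.uint8)
        rs_map = gs.glog_response_maps(H, default_bank, negate=bright)[-1]
        peak = np.unravel_index(np.argmax(rs_map), rs_map.shape)
        assert np.hypot(peak[0] - 40, peak[1] - 40) <= 2.0
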