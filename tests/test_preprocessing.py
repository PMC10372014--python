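import numpy as np
import pytest

from serialign.color import srgb_to_jch
from serialign.preprocessing import (ProcessedImage, denoise,
                                     normalize_image_set,
                                     process_fluorescence,
                                     standardize_chroma,
                                     to_inverted_grayscale)
from serialign.slide_io import SlideImage


class TestStandardizeChroma:
    def test_output_has_target_chroma_and_hue(self):
        rng = np.random.default_rng(0)
        rgb = rng.random((32, 32, 3))
        out = standardize_chroma(rgb, chroma=0.2, hue=0.0)
        jch = srgb_to_jch(out)
        inside = (out > 1e-3).all(axis=-1) & (out < 1 - 1e-3).all(axis=-1)
        assert inside.mean() > 0.5
        assert np.abs(jch[inside, 1] - 0.2).max() < 1e-3
        hue = (jch[inside, 2] + 180) % 360 - 180
        assert np.abs(hue).max() < 1.0

    def test_black_lightness_preserved(self):
        black = np.zeros((4, 4, 3))
        out = standardize_chroma(black)
        assert srgb_to_jch(out)[..., 0].max() < 1e-6

    def test_idempotent_in_gamut(self):
        # pixels whose standardized colour needed gamut clipping cannot be
        # reproduced exactly; idempotence holds for the in-gamut remainder
        rng = np.random.default_rng(1)
        rgb = rng.random((16, 16, 3))
        once = standardize_chroma(rgb)
        twice = standardize_chroma(once)
        in_gamut = ((once > 1e-6) & (once < 1 - 1e-6)).all(axis=-1)
        assert in_gamut.mean() > 0.5
        assert np.abs(once - twice)[in_gamut].max() < 1e-3

    def test_uint8_range_preserved(self):
        rng = np.random.default_rng(2)
        rgb = rng.integers(0, 255, size=(8, 8, 3), dtype=np.uint8)
        out = standardize_chroma(rgb)
        assert out.dtype == np.uint8

    def test_rejects_non_rgb(self):
        with pytest.raises(ValueError):
            standardize_chroma(np.zeros((8, 8)))


class TestInvertedGrayscale:
    def test_white_to_zero_black_to_max(self):
        white = np.ones((8, 8, 3))
        assert to_inverted_grayscale(white).pixels.max() == 0
        black = np.zeros((8, 8, 3))
        mixed = black.copy()
        mixed[0, 0] = 1.0  # max defines the inversion anchor
        out = to_inverted_grayscale(mixed)
        assert out.pixels[4, 4] == pytest.approx(out.pixels.max())

    def test_checkerboard_histogram_mirrored(self):
        board = np.indices((8, 8)).sum(axis=0) % 2
        rgb = np.repeat(board[..., None], 3, axis=-1).astype(float)
        out = to_inverted_grayscale(rgb)
        np.testing.assert_allclose(out.pixels, 1.0 - board, atol=1e-12)


class TestFluorescence:
    def _slide(self):
        rng = np.random.default_rng(3)
        arr = rng.integers(0, 1000, size=(32, 32, 3), dtype=np.uint16)
        return SlideImage(name="f", levels=[arr], is_rgb=False,
                          channel_names=["CD3", "DAPI", "CD8"])

    def test_named_channel_selected_and_scaled(self):
        slide = self._slide()
        out = process_fluorescence(slide, channel="DAPI")
        chan = slide.levels[0][..., 1].astype(float)
        np.testing.assert_allclose(out.pixels, chan / chan.max())

    def test_default_prefers_dapi_alias(self):
        out = process_fluorescence(self._slide())
        chan = self._slide().levels[0][..., 1].astype(float)
        np.testing.assert_allclose(out.pixels, chan / chan.max())

    def test_index_equals_slice(self):
        arr = np.random.default_rng(4).random((16, 16, 4))
        out = process_fluorescence(arr, channel=1)
        np.testing.assert_allclose(out.pixels, arr[..., 1] / arr[..., 1].max())

    def test_constant_zero_channel(self):
        arr = np.zeros((8, 8, 2))
        out = process_fluorescence(arr, channel=0)
        assert (out.pixels == 0).all()

    def test_missing_channel_lists_available(self):
        with pytest.raises(KeyError, match="CD3"):
            process_fluorescence(self._slide(), channel="FOXP3")


class TestNormalizeImageSet:
    def test_identical_images_are_fixed_point(self):
        rng = np.random.default_rng(5)
        a = ProcessedImage(pixels=rng.random((64, 64)))
        out = normalize_image_set([a, ProcessedImage(pixels=a.pixels.copy())])
        for o in out:
            assert np.abs(o.pixels - a.pixels).max() < 1e-6

    def test_scaled_copy_realigned(self):
        rng = np.random.default_rng(6)
        base = rng.random((128, 128))
        out = normalize_image_set([ProcessedImage(pixels=base),
                                   ProcessedImage(pixels=base * 0.5)])
        p = [np.percentile(o.pixels, [5, 95]) for o in out]
        assert np.abs(p[0] - p[1]).max() < 0.02  # within 1 unit on [0,1]*255

    def test_single_image_unchanged(self):
        rng = np.random.default_rng(7)
        a = ProcessedImage(pixels=rng.random((64, 64)))
        out = normalize_image_set([a])
        assert np.abs(out[0].pixels - a.pixels).max() < 1e-6

    def test_pooled_knots_match_targets(self):
        rng = np.random.default_rng(8)
        imgs = [ProcessedImage(pixels=rng.random((64, 64)) * s)
                for s in (1.0, 0.6, 1.4)]
        knots = np.array([[np.percentile(i.pixels, 5),
                           np.percentile(i.pixels, 95)] for i in imgs])
        target = knots.mean(axis=0)
        out = normalize_image_set(imgs)
        pooled = np.concatenate([o.pixels.ravel() for o in out])
        got = [np.percentile(pooled, 5), np.percentile(pooled, 95)]
        assert np.abs(np.array(got) - target).max() < 0.02

    def test_constant_image_warns_and_passes_through(self):
        const = ProcessedImage(pixels=np.full((16, 16), 0.5))
        other = ProcessedImage(pixels=np.random.default_rng(9).random((16, 16)))
        with pytest.warns(UserWarning, match="degenerate"):
            out = normalize_image_set([const, other])
        np.testing.assert_array_equal(out[0].pixels, const.pixels)


class TestDenoise:
    def test_zero_weight_is_identity(self):
        img = ProcessedImage(pixels=np.random.default_rng(10).random((32, 32)))
        assert denoise(img, 0) is img

    def test_constant_unchanged(self):
        img = ProcessedImage(pixels=np.full((32, 32), 0.3))
        np.testing.assert_allclose(denoise(img, 0.05).pixels, 0.3, atol=1e-6)

    def test_reduces_total_variation_keeps_edge(self):
        rng = np.random.default_rng(11)
        step = np.zeros((64, 64))
        step[:, 32:] = 1.0
        noisy = step + rng.normal(0, 0.08, step.shape)

        def tv(a):
            return (np.abs(np.diff(a, axis=0)).sum()
                    + np.abs(np.diff(a, axis=1)).sum())

        out = denoise(ProcessedImage(pixels=noisy), 0.05).pixels
        assert tv(out) < tv(noisy)
        grad_col = np.abs(np.diff(out, axis=1)).sum(axis=0)
        assert abs(int(grad_col.argmax()) - 31) <= 1
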