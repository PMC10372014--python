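import numpy as np
import pytest

from serialign.nonrigid import DisplacementField
from serialign.rigid import RigidTransform
from serialign.slide_io import SlideImage
from serialign.warping import (TransformChain, merge_channels, scale_chain,
                               warp_image, warp_points)


def _bump_chain(n=200, amp=4.0, sigma=30.0, angle_deg=8.0, tx=6.0, ty=-4.0):
    yy, xx = np.mgrid[0:n, 0:n].astype(float)
    g = np.exp(-((xx - n / 2) ** 2 + (yy - n / 2) ** 2) / (2 * sigma**2))
    field = DisplacementField(X=amp * g, Y=-0.6 * amp * g)
    a = np.radians(angle_deg)
    m = np.array([[np.cos(a), -np.sin(a), tx],
                  [np.sin(a), np.cos(a), ty],
                  [0, 0, 1.0]])
    return TransformChain(rigid=RigidTransform(matrix=m), nonrigid=field,
                          registration_scale=1.0, full_shape=(n, n),
                          canvas_offset=(0.0, 0.0), canvas_shape=(n, n))


def _identity_chain(n=64):
    return TransformChain(rigid=RigidTransform.identity(),
                          registration_scale=1.0, full_shape=(n, n),
                          canvas_offset=(0.0, 0.0), canvas_shape=(n, n))


class TestScaleChain:
    def test_same_scale_unchanged(self):
        chain = _bump_chain()
        assert scale_chain(chain, 1.0) is chain

    def test_translation_scales_linearly(self):
        chain = TransformChain(
            rigid=RigidTransform(matrix=np.array([[1, 0, 7.0], [0, 1, -3.0],
                                                  [0, 0, 1]])),
            registration_scale=0.5, full_shape=(100, 100),
            canvas_shape=(100, 100))
        scaled = scale_chain(chain, 1.0)
        np.testing.assert_allclose(scaled.rigid.translation, [14.0, -6.0])

    def test_rotation_invariant_under_scaling(self):
        chain = _bump_chain(angle_deg=12.0)
        chain.registration_scale = 0.25
        scaled = scale_chain(chain, 0.75)
        assert scaled.rigid.rotation_deg == pytest.approx(12.0, abs=1e-9)
        assert scaled.rigid.scale_factor == pytest.approx(1.0, abs=1e-9)

    def test_field_vectors_rescaled(self):
        chain = _bump_chain(amp=4.0)
        chain.registration_scale = 0.5
        scaled = scale_chain(chain, 1.0)
        assert scaled.nonrigid.X.max() == pytest.approx(
            2 * chain.nonrigid.X.max(), rel=0.05)


class TestWarpImage:
    def test_identity_chain_is_exact_copy(self):
        rng = np.random.default_rng(0)
        img = rng.integers(0, 255, size=(64, 64), dtype=np.uint8)
        out = warp_image(img, _identity_chain())
        np.testing.assert_array_equal(out, img)

    def test_tiled_equals_untiled(self):
        rng = np.random.default_rng(1)
        img = rng.integers(0, 255, size=(200, 200), dtype=np.uint8)
        chain = _bump_chain()
        full = warp_image(img, chain, tile_size=4096)
        tiled = warp_image(img, chain, tile_size=64)
        np.testing.assert_array_equal(full, tiled)

    def test_multiscale_consistency(self):
        # warping at double resolution then downsampling matches the
        # preview warp away from interpolation-heavy edges
        from scipy.ndimage import gaussian_filter
        from skimage.transform import resize

        rng = np.random.default_rng(2)
        base = gaussian_filter(rng.random((200, 200)), 3)
        base = (base - base.min()) / np.ptp(base)
        chain = _bump_chain(n=100, amp=2.0, angle_deg=5.0, tx=3.0, ty=2.0)
        preview_src = resize(base, (100, 100), anti_aliasing=True)
        preview = warp_image(preview_src, chain, source_scale=1.0,
                             target_scale=1.0)
        full = warp_image(base, chain, source_scale=2.0, target_scale=2.0)
        down = resize(full, preview.shape, anti_aliasing=True)
        inner = np.s_[20:-20, 20:-20]
        assert np.median(np.abs(down - preview)[inner]) < 2 / 255


class TestWarpPoints:
    def test_identity_chain_points_unchanged(self):
        xy = np.array([[10.0, 20.0], [30.0, 5.0]])
        np.testing.assert_allclose(warp_points(xy, _identity_chain()), xy)

    def test_forward_inverse_round_trip(self):
        chain = _bump_chain()
        rng = np.random.default_rng(3)
        xy = rng.random((200, 2)) * 150 + 25
        fwd = warp_points(xy, chain)
        back = warp_points(fwd, chain, inverse=True)
        err = np.linalg.norm(back - xy, axis=1)
        assert np.median(err) < 0.5

    def test_point_image_consistency(self):
        # a marked pixel's warped coordinate lands on the mark in the
        # warped image
        chain = _bump_chain(amp=3.0)
        img = np.zeros((200, 200))
        marks = [(60.0, 80.0), (120.0, 90.0), (100.0, 140.0)]
        for x, y in marks:
            img[int(y), int(x)] = 1.0
        warped = warp_image(img, chain)
        pts = warp_points(np.array(marks), chain)
        for (px, py) in pts:
            yy, xx = np.unravel_index(np.argmax(
                warped[max(int(py) - 3, 0):int(py) + 4,
                       max(int(px) - 3, 0):int(px) + 4]), (7, 7))
            peak = (max(int(px) - 3, 0) + xx, max(int(py) - 3, 0) + yy)
            assert np.hypot(peak[0] - px, peak[1] - py) <= 1.5

    def test_outside_field_flagged_and_rigid_extrapolated(self):
        chain = _bump_chain()
        far = np.array([[-500.0, -500.0]])
        warped, flags = warp_points(far, chain, return_flags=True)
        assert flags[0]
        rigid_only = chain.rigid.apply(far)
        np.testing.assert_allclose(warped, rigid_only, atol=1e-6)


class TestMergeChannels:
    def _slide(self, name, channels, seed):
        rng = np.random.default_rng(seed)
        arr = rng.integers(0, 255, size=(32, 32, len(channels)),
                           dtype=np.uint8)
        return SlideImage(name=name, levels=[arr], is_rgb=False,
                          channel_names=channels, pixel_size_um=0.5)

    def test_two_three_channel_slides_give_six(self):
        a = self._slide("r1", ["DAPI", "CD3", "CD8"], 0)
        b = self._slide("r2", ["DAPI", "FOXP3", "PD1"], 1)
        merged = merge_channels([a, b])
        assert merged.n_channels == 6
        assert merged.channel_names == [
            "r1_DAPI", "r1_CD3", "r1_CD8", "r2_DAPI", "r2_FOXP3", "r2_PD1"]
        np.testing.assert_array_equal(merged.levels[0][..., 4],
                                      b.levels[0][..., 1])
        assert merged.pixel_size_um == 0.5

    def test_duplicate_dapi_dropped_on_request(self):
        a = self._slide("r1", ["DAPI", "CD3"], 2)
        b = self._slide("r2", ["DAPI", "CD8"], 3)
        merged = merge_channels([a, b], keep_duplicate_names=False)
        assert merged.channel_names == ["r1_DAPI", "r1_CD3", "r2_CD8"]

    def test_shape_mismatch_rejected(self):
        a = self._slide("r1", ["DAPI"], 4)
        b = SlideImage(name="r2", levels=[np.zeros((16, 16), np.uint8)],
                       is_rgb=False)
        with pytest.raises(ValueError):
            merge_channels([a, b])
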