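import numpy as np
import pytest

from serialign.features import MatchSet, match_all_pairs
from serialign.ordering import (build_similarity, choose_reference,
                                order_by_similarity)
from serialign.rigid import (EstimationError, RigidTransform,
                             estimate_similarity, mi_refine, neighbor_filter,
                             serial_rigid_register, warp_rigid)


def _matchset(idx_i, idx_j, n=None):
    k = len(idx_i)
    xy = np.arange(2 * k, dtype=float).reshape(k, 2)
    return MatchSet(i=1, j=0, xy_i=xy, xy_j=xy + 1,
                    idx_i=np.asarray(idx_i), idx_j=np.asarray(idx_j),
                    n_raw=k, n_after_ransac=k, n_after_tukey=k)


class TestNeighborFilter:
    def test_shared_keypoints_survive(self):
        inner = _matchset(idx_i=np.arange(40), idx_j=np.arange(40))
        outer = _matchset(idx_i=np.arange(30), idx_j=np.arange(30))
        outer.j = 2
        out = neighbor_filter(inner, outer)
        assert len(out) == 30
        np.testing.assert_array_equal(out.idx_i, np.arange(30))

    def test_exclusive_matches_removed(self):
        # 30 keypoints shared with both neighbors + 10 only matched inner
        inner = _matchset(idx_i=np.arange(40), idx_j=np.arange(40))
        outer = _matchset(idx_i=np.arange(30), idx_j=np.arange(30))
        outer.j = 2
        out = neighbor_filter(inner, outer)
        assert set(out.idx_i) == set(range(30))

    def test_fallback_when_too_few_shared(self):
        inner = _matchset(idx_i=np.arange(10), idx_j=np.arange(10))
        outer = _matchset(idx_i=np.arange(100, 103), idx_j=np.arange(3))
        outer.j = 2
        with pytest.warns(UserWarning, match="falling back"):
            out = neighbor_filter(inner, outer)
        assert len(out) == 10


class TestEstimateSimilarity:
    def test_identity_on_identical_points(self):
        rng = np.random.default_rng(0)
        xy = rng.random((20, 2)) * 100
        t = estimate_similarity(xy, xy)
        assert np.abs(t.matrix - np.eye(3)).max() < 1e-9

    def test_exact_rotation_translation_recovery(self):
        rng = np.random.default_rng(1)
        xy = rng.random((30, 2)) * 200
        ang = np.radians(30)
        R = np.array([[np.cos(ang), -np.sin(ang)],
                      [np.sin(ang), np.cos(ang)]])
        center = xy.mean(axis=0)
        dst = (xy - center) @ R.T + center + [5, -3]
        t = estimate_similarity(xy, dst)
        assert abs(t.rotation_deg - 30) < 1e-6
        np.testing.assert_allclose(t.apply(xy), dst, atol=1e-9)
        assert t.residual_rms < 1e-9

    def test_noisy_recovery_within_statistical_bound(self):
        rng = np.random.default_rng(2)
        n, sigma = 50, 1.0
        angles = []
        for _ in range(20):
            xy = rng.random((n, 2)) * 400
            ang = np.radians(10)
            R = np.array([[np.cos(ang), -np.sin(ang)],
                          [np.sin(ang), np.cos(ang)]])
            dst = xy @ R.T + [7, 2] + rng.normal(0, sigma, xy.shape)
            t = estimate_similarity(xy, dst)
            angles.append(t.rotation_deg)
        # angle error scales like sigma / (rms radius * sqrt(n))
        assert abs(np.mean(angles) - 10) < 3 * sigma / np.sqrt(n)

    def test_degenerate_raises(self):
        xy = np.zeros((5, 2))
        with pytest.raises(EstimationError):
            estimate_similarity(xy, xy + 1)


class TestSerialRigid:
    def _register(self, series):
        from serialign.masking import make_tissue_mask
        from serialign.preprocessing import process_brightfield
        from serialign.features import detect_and_describe

        masks = [make_tissue_mask(im) for im in series.images]
        feats = [detect_and_describe(process_brightfield(im).pixels, m.mask)
                 for im, m in zip(series.images, masks)]
        matches = match_all_pairs(feats, seed=0)
        so = choose_reference(order_by_similarity(
            build_similarity(matches, n=len(series.images))))
        shapes = [im.shape[:2] for im in series.images]
        return so, serial_rigid_register(matches, so, image_shapes=shapes)

    def test_reference_is_identity_and_angles_recovered(self, small_series):
        so, rr = self._register(small_series)
        ref = so.reference_image
        assert np.abs(rr.transforms[ref].matrix - np.eye(3)).max() == 0
        # recovered absolute rotations vs ground truth (towards image ref)
        for k in range(len(small_series.images)):
            true_k = np.degrees(np.arctan2(small_series.true_rigid[k][1, 0],
                                           small_series.true_rigid[k][0, 0]))
            true_ref = np.degrees(np.arctan2(
                small_series.true_rigid[ref][1, 0],
                small_series.true_rigid[ref][0, 0]))
            got = rr.transforms[k].rotation_deg
            assert abs(got - (true_ref - true_k)) < 1.0

    def test_registered_landmark_error_small(self, small_series):
        so, rr = self._register(small_series)
        ref = so.reference_image
        errs = []
        for k in range(len(small_series.images)):
            if k == ref:
                continue
            warped = rr.transforms[k].apply(small_series.landmarks[k])
            ref_lm = rr.transforms[ref].apply(small_series.landmarks[ref])
            errs.append(np.linalg.norm(warped - ref_lm, axis=1))
        med = np.median(np.concatenate(errs))
        assert med < 2.0  # deformation-limited at registration scale

    def test_single_image_identity(self):
        from serialign.ordering import SeriesOrdering

        so = SeriesOrdering(S=np.ones((1, 1)), order=[0], reference_index=0)
        rr = serial_rigid_register({}, so, image_shapes=[(64, 64)])
        assert np.abs(rr.transforms[0].matrix - np.eye(3)).max() == 0

    def test_rigid_not_worse_than_unregistered(self, small_series):
        so, rr = self._register(small_series)
        for a, b in zip(so.order, so.order[1:]):
            unreg = np.median(np.linalg.norm(
                small_series.landmarks[a] - small_series.landmarks[b],
                axis=1))
            reg = np.median(np.linalg.norm(
                rr.transforms[a].apply(small_series.landmarks[a])
                - rr.transforms[b].apply(small_series.landmarks[b]), axis=1))
            assert reg <= unreg


class TestMiRefine:
    def test_identity_retained_for_identical_images(self, small_processed):
        img = small_processed[0][0].pixels
        t = RigidTransform.identity()
        out = mi_refine(img, img, t)
        assert np.abs(out.matrix - np.eye(3)).max() < 1e-6

    def test_planted_offset_reduced(self, small_processed):
        img = small_processed[0][0].pixels
        h, w = img.shape
        off = RigidTransform(matrix=np.array([[1, 0, 2.0], [0, 1, 0],
                                              [0, 0, 1]]))
        out = mi_refine(img, img, off)
        # translation error shrinks by at least half
        assert np.abs(out.translation).max() <= 1.0


def test_warp_rigid_translation():
    img = np.zeros((32, 32))
    img[10, 10] = 1.0
    t = RigidTransform(matrix=np.array([[1, 0, 5.0], [0, 1, 3.0],
                                        [0, 0, 1]]))
    out = warp_rigid(img, t, canvas_shape=(32, 32))
    assert out[13, 15] == pytest.approx(1.0)
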