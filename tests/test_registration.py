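"""Deformable registration, landmarks, piecewise-affine warping."""

import numpy as np
import pytest

from sliceloc.atlas import slice_oblique, simplify_atlas_slice
from sliceloc.frames import PlaneParams
from sliceloc.localization import normalize_image
from sliceloc.registration import (
    DisplacementField,
    LandmarkSet,
    PiecewiseAffineTransform,
    RegistrationError,
    RegistrationResult,
    apply_transform,
    auto_register,
    build_piecewise_affine,
    contour_landmarks,
    foreground_mask,
    mutual_information,
    register_hybrid,
)
from sliceloc.synthetic import DeformSpec, random_smooth_field, simulate_section


def disk_mask(shape=(128, 128), center=(64, 64), radius=50):
    rr, cc = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


class TestForegroundMask:
    def test_white_disk(self):
        img = disk_mask().astype(float)
        assert np.array_equal(foreground_mask(img), disk_mask())

    def test_speck_removed(self):
        img = disk_mask().astype(float)
        img[5, 5] = 1.0
        mask = foreground_mask(img)
        assert not mask[5, 5]
        assert mask[64, 64]

    def test_hole_filled(self):
        img = disk_mask().astype(float)
        img[60:68, 60:68] = 0.0
        assert foreground_mask(img)[63, 63]

    def test_empty_rejected(self):
        with pytest.raises(RegistrationError, match="empty"):
            foreground_mask(np.zeros((8, 8)))


class TestMutualInformation:
    def test_self_information_equals_entropy(self):
        # two-level image with p = (0.25, 0.75): H = 0.8113 bits
        img = np.zeros((20, 20))
        img[:10, :10] = 1.0  # 100 of 400 pixels
        assert mutual_information(img, img, bins=2) == pytest.approx(0.8113, abs=1e-4)

    def test_constant_image_zero(self):
        rng = np.random.default_rng(0)
        img = rng.uniform(size=(32, 32))
        assert mutual_information(img, np.ones_like(img)) == pytest.approx(0.0, abs=1e-12)

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(42)
        a = rng.uniform(size=(256, 256))
        b = rng.uniform(size=(256, 256))
        assert mutual_information(a, b, bins=8) < 0.05

    def test_symmetry(self):
        rng = np.random.default_rng(3)
        a = rng.uniform(size=(64, 64))
        b = np.roll(a, 5, axis=0)
        assert mutual_information(a, b) == pytest.approx(mutual_information(b, a),
                                                         abs=1e-12)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            mutual_information(np.zeros((4, 4)), np.zeros((5, 5)))


class TestAutoRegister:
    def test_identical_images_near_identity(self, phantom):
        vol, graph = phantom
        anchor = vol.frame.center_um()[:2]
        sec = simulate_section(vol, graph, PlaneParams(1, 1, 5000.0, anchor),
                               artifact_level=1, seed=21)
        field, hist = auto_register(sec.image, sec.image)
        assert np.sqrt((field.field**2).sum(-1)).mean() < 0.5

    def test_translation_recovered(self, phantom):
        vol, graph = phantom
        anchor = vol.frame.center_um()[:2]
        simplified = simplify_atlas_slice(
            slice_oblique(vol, PlaneParams(0, 0, 5200.0, anchor)), graph)
        src = normalize_image(simplified)
        tgt = np.roll(np.roll(src, 10, axis=0), -7, axis=1)
        field, hist = auto_register(src, tgt)
        fg = tgt > 0
        mean_dr = field.field[..., 0][fg].mean()
        mean_dc = field.field[..., 1][fg].mean()
        assert mean_dr == pytest.approx(-10.0, abs=1.0)
        assert mean_dc == pytest.approx(7.0, abs=1.0)

    def test_intensity_rescaling_invariance(self, phantom):
        # MI-driven stages are unaffected by global intensity rescaling
        vol, graph = phantom
        anchor = vol.frame.center_um()[:2]
        sec = simulate_section(vol, graph, PlaneParams(2, -2, 5600.0, anchor),
                               artifact_level=1, seed=22)
        simplified = simplify_atlas_slice(
            slice_oblique(vol, PlaneParams(2, -2, 5600.0, anchor)), graph)
        f1, _ = auto_register(simplified, sec.image)
        f2, _ = auto_register(simplified, sec.image * 0.5)
        assert np.allclose(f1.field, f2.field, atol=1e-9)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(RegistrationError, match="shapes"):
            auto_register(np.ones((8, 8)), np.ones((9, 9)))


class TestContourLandmarks:
    def test_exactly_n_points(self):
        lm = contour_landmarks(disk_mask(), n=20)
        assert len(lm) == 20
        assert all(o == "automatic_contour" for o in lm.origin)

    def test_circle_equal_arc_gaps(self):
        lm = contour_landmarks(disk_mask(radius=50), n=20)
        pts = np.vstack([lm.points, lm.points[:1]])
        gaps = np.sqrt((np.diff(pts, axis=0) ** 2).sum(1))
        assert gaps.max() - gaps.min() < 1.0

    def test_deterministic(self):
        a = contour_landmarks(disk_mask(), n=20)
        b = contour_landmarks(disk_mask(), n=20)
        assert np.array_equal(a.points, b.points)

    def test_starts_topmost_leftmost(self):
        lm = contour_landmarks(disk_mask(center=(64, 64), radius=40), n=8)
        assert lm.points[0][0] == pytest.approx(24, abs=1.0)  # topmost row

    def test_too_short_contour(self):
        mask = np.zeros((8, 8), bool)
        mask[3, 3] = True
        with pytest.raises(RegistrationError, match="shorter|component"):
            contour_landmarks(mask, n=20)

    def test_multi_component_rejected(self):
        mask = np.zeros((20, 20), bool)
        mask[2:5, 2:5] = True
        mask[12:16, 12:16] = True
        with pytest.raises(RegistrationError, match="component"):
            contour_landmarks(mask)


class TestPiecewiseAffine:
    def grid_points(self):
        pts = [(r, c) for r in (0.0, 30.0, 60.0) for c in (0.0, 40.0, 80.0)]
        return np.array(pts)

    def test_identity(self):
        pts = self.grid_points()
        t = build_piecewise_affine(pts, pts, (61, 81))
        rng = np.random.default_rng(0)
        sample = rng.uniform((0, 0), (60, 80), size=(30, 2))
        assert np.allclose(t.transform_points(sample), sample, atol=1e-9)
        img = rng.uniform(size=(61, 81))
        assert np.allclose(t.warp(img), img, atol=1e-7)

    def test_global_affine_recovered_per_triangle(self):
        src = self.grid_points()
        A = np.array([[1.1, 0.08], [-0.05, 0.95]])
        t_vec = np.array([3.0, -2.0])
        dst = src @ A.T + t_vec
        t = build_piecewise_affine(src, dst, (61, 81))
        expected = np.hstack([A, t_vec[:, None]])
        for k in range(len(t.tri.simplices)):
            if t.valid[k]:
                assert np.allclose(t.forward[k], expected, atol=1e-9)
        interior = np.array([[12.3, 17.9], [40.0, 55.5]])
        assert np.allclose(t.transform_points(interior),
                           interior @ A.T + t_vec, atol=1e-9)

    def test_barycentric_interpolation(self):
        # a point inside a triangle maps by barycentric mixing of the
        # vertex correspondences
        src = np.array([[0.0, 0.0], [0.0, 10.0], [10.0, 0.0], [10.0, 10.0]])
        dst = src + np.array([[1, 1], [2, -1], [-1, 2], [0, 0]])
        t = build_piecewise_affine(src, dst, (11, 11))
        p = np.array([[2.0, 3.0]])
        q = t.transform_points(p)[0]
        # oracle: locate containing src triangle, mix vertices by weights
        for simplex in t.tri.simplices:
            s3, d3 = src[simplex], dst[simplex]
            T = np.vstack([(s3[1] - s3[0]), (s3[2] - s3[0])]).T
            try:
                bary = np.linalg.solve(T, p[0] - s3[0])
            except np.linalg.LinAlgError:
                continue
            w = np.array([1 - bary.sum(), *bary])
            if (w >= -1e-12).all():
                assert np.allclose(q, w @ d3, atol=1e-9)
                break
        else:
            pytest.fail("point not inside any source triangle")

    def test_shared_edge_continuity(self):
        rng = np.random.default_rng(8)
        src = rng.uniform(0, 100, size=(12, 2))
        dst = src + rng.uniform(-5, 5, size=(12, 2))
        t = build_piecewise_affine(src, dst, (101, 101))
        tri = t.tri
        # collect shared edges between simplex pairs
        for k, neighbors in enumerate(tri.neighbors):
            for m in neighbors:
                if m < 0 or not (t.valid[k] and t.valid[m]):
                    continue
                shared = np.intersect1d(tri.simplices[k], tri.simplices[m])
                if len(shared) != 2:
                    continue
                p0, p1 = t.dst[shared[0]], t.dst[shared[1]]
                for frac in (0.0, 0.25, 0.5, 0.75, 1.0):
                    p = p0 + frac * (p1 - p0)
                    homo = np.array([p[0], p[1], 1.0])
                    assert np.allclose(t.backward[k] @ homo,
                                       t.backward[m] @ homo, atol=1e-9)

    def test_out_of_hull_identity(self):
        pts = self.grid_points()
        t = build_piecewise_affine(pts, pts + 2.0, (61, 81))
        outside = np.array([[200.0, 200.0]])
        assert np.allclose(t.transform_points(outside), outside)

    def test_collinear_landmarks_rejected(self):
        src = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0], [3.0, 3.0]])
        with pytest.raises(RegistrationError, match="degenerate|collinear"):
            build_piecewise_affine(src, src, (10, 10))

    def test_count_mismatch(self):
        with pytest.raises(ValueError, match="counts"):
            build_piecewise_affine(np.zeros((4, 2)), np.zeros((5, 2)), (10, 10))


class TestApplyTransform:
    def test_identity_bit_exact(self):
        rng = np.random.default_rng(1)
        labels = rng.integers(0, 7, size=(32, 32)).astype(np.int32)
        res = RegistrationResult(m_ard=DisplacementField.identity((32, 32)))
        out = apply_transform(labels, res, "nearest")
        assert np.array_equal(out, labels)

    def test_pure_translation_preserves_id_set(self):
        labels = np.zeros((32, 32), dtype=np.int32)
        labels[8:20, 8:20] = 5
        labels[10:14, 10:14] = 9
        field = np.zeros((32, 32, 2))
        field[..., 0] = 4.0  # sample 4 rows down -> content moves up 4
        res = RegistrationResult(m_ard=DisplacementField(field))
        out = apply_transform(labels, res, "nearest")
        assert np.array_equal(out[4:16, 8:20], labels[8:20, 8:20])
        assert set(np.unique(out)) <= set(np.unique(labels))

    def test_linear_on_labels_rejected(self):
        labels = np.ones((8, 8), dtype=np.int32)
        res = RegistrationResult(m_ard=DisplacementField.identity((8, 8)))
        with pytest.raises(ValueError, match="label"):
            apply_transform(labels, res, "linear")

    def test_composition_equals_sequential(self):
        rng = np.random.default_rng(9)
        ard = random_smooth_field((40, 40), 3.0, 5, rng)
        src_pts = np.array([(r, c) for r in (5.0, 20.0, 35.0) for c in (5.0, 20.0, 35.0)])
        dst_pts = src_pts + rng.uniform(-2, 2, size=src_pts.shape)
        m_lm = build_piecewise_affine(src_pts, dst_pts, (40, 40))
        res = RegistrationResult(m_ard=DisplacementField(ard), m_lm=m_lm)
        total = res.total_coords((40, 40))
        # oracle: sequential pull-back at integer pixels, with the landmark
        # stage evaluated through the exact per-triangle backward affine
        pts = rng.integers(6, 34, size=(10, 2))
        for r, c in pts:
            p = np.array([float(r), float(c)])
            simplex = int(m_lm.tri.find_simplex(p[None, :])[0])
            if simplex < 0:
                q = p
            else:
                q = m_lm.backward[simplex] @ np.array([p[0], p[1], 1.0])
            expected = DisplacementField(ard).sample_at(q.reshape(2, 1)).ravel()
            assert np.allclose(total[:, r, c], expected, atol=1e-9)


class TestRegisterHybrid:
    def test_no_landmarks_reduces_to_auto(self, phantom):
        vol, graph = phantom
        anchor = vol.frame.center_um()[:2]
        plane = PlaneParams(1, -1, 5400.0, anchor)
        sec = simulate_section(vol, graph, plane,
                               deform_spec=DeformSpec(max_displacement_px=4.0),
                               artifact_level=1, seed=30)
        slc = slice_oblique(vol, plane)
        res = register_hybrid(slc, sec.image, graph)
        assert res.m_lm is None
        assert res.warped_labels is not None
        assert set(np.unique(res.warped_labels)) <= slc.id_set() | {0}

    def test_identity_landmarks_leave_refinement_neutral(self, phantom):
        vol, graph = phantom
        anchor = vol.frame.center_um()[:2]
        plane = PlaneParams(0, 0, 5000.0, anchor)
        sec = simulate_section(vol, graph, plane,
                               deform_spec=DeformSpec(max_displacement_px=3.0),
                               artifact_level=1, seed=31)
        slc = slice_oblique(vol, plane)
        auto_res = register_hybrid(slc, sec.image, graph)
        # manual landmarks equal on both sides: interior refinement anchored
        # to identity stays close to the auto result
        pts = np.array([(r, c) for r in (40.0, 64.0, 90.0) for c in (50.0, 80.0, 110.0)])
        lm = LandmarkSet(points=pts)
        hyb = register_hybrid(slc, sec.image, graph,
                              manual_landmarks=(lm, LandmarkSet(points=pts.copy())))
        assert hyb.m_lm is not None
        inner = hyb.m_lm.transform_points(pts)
        assert np.allclose(inner, pts, atol=1e-9)
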