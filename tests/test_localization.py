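"""Quadrant splitting, Q-label prediction, plane solving, group routing."""

import math

import numpy as np
import pytest

from sliceloc.frames import (
    GroupLabel,
    PlaneParams,
    ap_to_ara_section,
    ara_section_to_ap,
    plane_geometry,
)
from sliceloc.localization import (
    ConstantPredictor,
    LocalizationError,
    PlaneOraclePredictor,
    QLabels,
    QuadrantCrop,
    SearchGrid,
    brute_force_localize,
    detect_group_c_components,
    localize,
    predict_qlabels,
    segment_group_a,
    solve_plane_from_qlabels,
    split_quadrants,
    OracleGroupASegmenter,
    NearestAtlasSegmenter,
)
from sliceloc.synthetic import DeformSpec, simulate_section


QUAD_CENTERS = {1: (-2000.0, -1500.0), 2: (2000.0, -1500.0),
                3: (-2000.0, 1500.0), 4: (2000.0, 1500.0)}


def crops_at(centers):
    return [QuadrantCrop(image=np.zeros((2, 2)), center_um=c, index=i)
            for i, c in centers.items()]


class TestSplitQuadrants:
    def test_symmetric_section_centers(self):
        img = np.zeros((40, 60))
        img[10:30, 10:50] = 1.0  # foreground box rows 10..29, cols 10..49
        crops = split_quadrants(img, GroupLabel.B, pixel_size_um=10.0,
                                center_xy_um=(0.0, 0.0))
        assert [c.index for c in crops] == [1, 2, 3, 4]
        # bounding-box arithmetic oracle: box rows [10,30), cols [10,50),
        # canvas center (19.5, 29.5); quadrant boxes split at (20, 30)
        def phys(r, c):
            return ((c - 29.5) * 10.0, (r - 19.5) * 10.0)
        assert crops[0].center_um == pytest.approx(phys((10 + 19) / 2, (10 + 29) / 2))
        assert crops[1].center_um == pytest.approx(phys((10 + 19) / 2, (30 + 49) / 2))
        assert crops[2].center_um == pytest.approx(phys((20 + 29) / 2, (10 + 29) / 2))
        assert crops[3].center_um == pytest.approx(phys((20 + 29) / 2, (30 + 49) / 2))

    def test_group_a_unsupported(self):
        with pytest.raises(LocalizationError, match="group A"):
            split_quadrants(np.ones((4, 4)), GroupLabel.A)

    def test_group_c_missing_cerebrum_flags(self, phantom):
        vol, graph = phantom
        anchor = vol.frame.center_um()[:2]
        plane = PlaneParams(0, 1.0, ara_section_to_ap(92), anchor)
        sec = simulate_section(vol, graph, plane,
                               deform_spec=DeformSpec(max_displacement_px=2.0,
                                                      delete_cerebrum="left"),
                               artifact_level=3, seed=3)
        report = detect_group_c_components(sec.image)
        crops = split_quadrants(sec.image, GroupLabel.C, components=report,
                                pixel_size_um=sec.pixel_size_um, center_xy_um=anchor)
        indices = {c.index for c in crops}
        assert indices == {2, 4, 5}  # Q1/Q3 missing with the left cerebrum

    def test_group_c_requires_brainstem(self):
        from sliceloc.localization import ComponentReport

        with pytest.raises(LocalizationError, match="brain stem"):
            split_quadrants(np.ones((8, 8)), GroupLabel.C,
                            components=ComponentReport(brainstem=None))


class TestPredictQLabels:
    def test_oracle_matches_plane_evaluation(self):
        plane = PlaneParams(4.0, -2.5, 5200.0, (0.0, 0.0))
        crops = crops_at(QUAD_CENTERS)
        q = predict_qlabels(crops, PlaneOraclePredictor(plane), GroupLabel.B)
        zf = plane_geometry(plane)
        for i, c in QUAD_CENTERS.items():
            expected = ap_to_ara_section(float(zf(*c)))
            assert q.values[i - 1] == pytest.approx(expected, abs=1e-6)

    def test_group_b_q5_invalid_and_zero(self):
        q = predict_qlabels(crops_at(QUAD_CENTERS), ConstantPredictor(42),
                            GroupLabel.B)
        assert q.values[4] == 0.0 and not q.valid[4]

    def test_constant_predictor(self):
        q = predict_qlabels(crops_at(QUAD_CENTERS), ConstantPredictor(17.5),
                            GroupLabel.BPRIME)
        assert np.allclose(q.values[:4], 17.5)

    def test_out_of_range_output_rejected(self):
        with pytest.raises(LocalizationError, match="outside"):
            predict_qlabels(crops_at(QUAD_CENTERS), ConstantPredictor(140),
                            GroupLabel.B)


class TestSolvePlane:
    def test_constant_labels_give_flat_plane(self):
        q = QLabels(values=[50, 50, 50, 50, 0], valid=[1, 1, 1, 1, 0])
        plane, res = solve_plane_from_qlabels(q, crops_at(QUAD_CENTERS))
        assert plane.alpha_deg == pytest.approx(0.0, abs=1e-9)
        assert plane.beta_deg == pytest.approx(0.0, abs=1e-9)
        assert plane.d_um == pytest.approx(4900.0, abs=1e-9)
        assert res == pytest.approx(0.0, abs=1e-9)

    def test_hand_least_squares_example(self):
        # left quadrants plate 50, right plate 52, dorsal = ventral:
        # alpha = atan(200 um / 4000 um), beta = 0, d = 5000 um
        q = QLabels(values=[50, 52, 50, 52, 0], valid=[1, 1, 1, 1, 0])
        plane, res = solve_plane_from_qlabels(q, crops_at(QUAD_CENTERS))
        assert plane.alpha_deg == pytest.approx(math.degrees(math.atan(200 / 4000)),
                                                abs=1e-9)
        assert plane.beta_deg == pytest.approx(0.0, abs=1e-9)
        assert plane.d_um == pytest.approx(5000.0, abs=1e-9)

    def test_exact_recovery_from_noiseless_labels(self):
        rng = np.random.default_rng(11)
        crops = crops_at(QUAD_CENTERS)
        for _ in range(50):
            a, b = rng.uniform(-20, 20, size=2)
            d = rng.uniform(1000, 12000)
            truth = PlaneParams(float(a), float(b), float(d), (0.0, 0.0))
            zf = plane_geometry(truth)
            vals = [float(ap_to_ara_section(float(zf(*QUAD_CENTERS[i]))))
                    for i in range(1, 5)]
            q = QLabels(values=vals + [0], valid=[1, 1, 1, 1, 0])
            plane, res = solve_plane_from_qlabels(q, crops)
            assert plane.alpha_deg == pytest.approx(a, abs=1e-6)
            assert plane.beta_deg == pytest.approx(b, abs=1e-6)
            assert plane.d_um == pytest.approx(d, abs=1e-3)

    def test_two_quadrants_fit_beta_and_d_only(self):
        q = QLabels(values=[50, 0, 54, 0, 0], valid=[1, 0, 1, 0, 0])
        plane, _ = solve_plane_from_qlabels(q, crops_at(QUAD_CENTERS))
        assert plane.alpha_deg == 0.0
        # z at y=-1500 is 4900, at +1500 is 5300: slope 400/3000
        assert plane.beta_deg == pytest.approx(
            math.degrees(math.atan(400 / 3000)), abs=1e-9)
        assert plane.d_um == pytest.approx(5100.0, abs=1e-9)

    def test_single_quadrant_d_only(self):
        q = QLabels(values=[0, 61, 0, 0, 0], valid=[0, 1, 0, 0, 0])
        plane, _ = solve_plane_from_qlabels(q, crops_at(QUAD_CENTERS))
        assert plane.d_um == pytest.approx(6000.0)
        assert plane.alpha_deg == 0.0 and plane.beta_deg == 0.0

    def test_no_valid_quadrants(self):
        q = QLabels(values=np.zeros(5), valid=np.zeros(5, bool))
        with pytest.raises(LocalizationError, match="no valid"):
            solve_plane_from_qlabels(q, crops_at(QUAD_CENTERS))

    def test_noise_robustness(self):
        # Gaussian label noise of one plate (100 um) at the quadrant centers:
        # the fitted plane stays well inside the stated error budget
        rng = np.random.default_rng(99)
        crops = crops_at(QUAD_CENTERS)
        errs_d, errs_a, errs_b = [], [], []
        for _ in range(200):
            a, b = rng.uniform(-10, 10, size=2)
            d = rng.uniform(3000, 9000)
            zf = plane_geometry(PlaneParams(float(a), float(b), float(d)))
            vals = []
            for i in range(1, 5):
                z = float(zf(*QUAD_CENTERS[i])) + float(rng.normal(0, 100.0))
                vals.append(float(np.clip(ap_to_ara_section(
                    float(np.clip(z, 0, 13100))), 1, 132)))
            q = QLabels(values=vals + [0], valid=[1, 1, 1, 1, 0])
            plane, _ = solve_plane_from_qlabels(q, crops)
            errs_d.append(abs(plane.d_um - d))
            errs_a.append(abs(plane.alpha_deg - a))
            errs_b.append(abs(plane.beta_deg - b))
        assert np.mean(errs_d) <= 100.0
        assert np.mean(errs_a) <= 3.0
        assert np.mean(errs_b) <= 3.0


class TestComponentDetection:
    def test_three_component_posterior_section(self, phantom):
        vol, graph = phantom
        anchor = vol.frame.center_um()[:2]
        sec = simulate_section(vol, graph,
                               PlaneParams(0, 1.0, ara_section_to_ap(92), anchor),
                               deform_spec=DeformSpec(max_displacement_px=2.0),
                               artifact_level=1, seed=4)
        rep = detect_group_c_components(sec.image)
        assert rep.missing() == []
        assert rep.detached
        # sides are geometrically sane
        assert rep.left_cerebrum.bbox[2] < rep.right_cerebrum.bbox[2]

    def test_deleted_cerebrum_flagged(self, phantom):
        vol, graph = phantom
        anchor = vol.frame.center_um()[:2]
        for side in ("left", "right"):
            sec = simulate_section(vol, graph,
                                   PlaneParams(0, 0, ara_section_to_ap(95), anchor),
                                   deform_spec=DeformSpec(max_displacement_px=2.0,
                                                          delete_cerebrum=side),
                                   artifact_level=3, seed=9)
            rep = detect_group_c_components(sec.image)
            assert rep.missing() == [f"{side}_cerebrum"]

    def test_single_blob_classified_no_detachment(self, phantom):
        vol, graph = phantom
        anchor = vol.frame.center_um()[:2]
        sec = simulate_section(vol, graph,
                               PlaneParams(0, 0, 5000.0, anchor),
                               deform_spec=DeformSpec(max_displacement_px=1.0),
                               artifact_level=1, seed=2)
        rep = detect_group_c_components(sec.image)
        assert not rep.detached
        assert rep.brainstem is None

    def test_empty_section_rejected(self):
        with pytest.raises(LocalizationError, match="empty"):
            detect_group_c_components(np.zeros((16, 16)))


class TestGroupASegmentation:
    def test_oracle_perfect_dice(self, phantom):
        from sliceloc.evaluation import dice
        from sliceloc.localization import classify_group_a_id

        vol, graph = phantom
        anchor = vol.frame.center_um()[:2]
        sec = simulate_section(vol, graph, PlaneParams(0, 0, 1000.0, anchor),
                               deform_spec=DeformSpec(max_displacement_px=0.0),
                               artifact_level=1, seed=1)
        seg = segment_group_a(sec.image, OracleGroupASegmenter(sec.truth_labels, graph))
        truth = np.zeros_like(seg)
        for i in np.unique(sec.truth_labels.labels):
            if i:
                truth[sec.truth_labels.labels == i] = classify_group_a_id(int(i), graph)
        for cls in np.unique(truth):
            if cls:
                assert dice(seg == cls, truth == cls) == 1.0

    def test_all_background_image(self, phantom):
        vol, graph = phantom
        seg = segment_group_a(
            np.zeros((32, 32)),
            NearestAtlasSegmenter(vol, graph, PlaneParams(
                0, 0, 1000.0, vol.frame.center_um()[:2])),
        )
        # no foreground pixels ever get a class
        assert not seg.any()

    def test_baseline_dice_on_mildly_deformed_section(self, phantom):
        from sliceloc.evaluation import dice
        from sliceloc.localization import classify_group_a_id

        vol, graph = phantom
        anchor = vol.frame.center_um()[:2]
        plane = PlaneParams(0, 0, 1100.0, anchor)
        sec = simulate_section(vol, graph, plane,
                               deform_spec=DeformSpec(max_displacement_px=1.5),
                               artifact_level=1, seed=6)
        seg = segment_group_a(sec.image, NearestAtlasSegmenter(vol, graph, plane))
        truth = np.zeros_like(seg)
        for i in np.unique(sec.truth_labels.labels):
            if i:
                truth[sec.truth_labels.labels == i] = classify_group_a_id(int(i), graph)
        scores = [dice(seg == c, truth == c) for c in np.unique(truth) if c]
        assert np.mean(scores) >= 0.8

    def test_unknown_class_rejected(self):
        class Bad:
            def segment(self, image):
                return np.full(image.shape, 77, dtype=np.int32)

        with pytest.raises(LocalizationError, match="unknown"):
            segment_group_a(np.ones((4, 4)), Bad())


class TestBruteForce:
    def test_deterministic(self, phantom):
        vol, graph = phantom
        anchor = vol.frame.center_um()[:2]
        sec = simulate_section(vol, graph, PlaneParams(2, -1, 5200.0, anchor),
                               artifact_level=1, seed=8)
        grid = SearchGrid(alpha_max_deg=4, beta_max_deg=4,
                          d_range_um=(4500.0, 6000.0))
        p1, s1 = brute_force_localize(sec.image, vol, graph, grid)
        p2, s2 = brute_force_localize(sec.image, vol, graph, grid)
        assert (p1.alpha_deg, p1.beta_deg, p1.d_um) == (p2.alpha_deg, p2.beta_deg, p2.d_um)
        assert s1 == s2

    def test_self_rendered_truth_scores_best(self, phantom):
        # noiseless self-rendered input: the true grid plane beats the
        # other grid points
        from sliceloc.localization import normalized_mutual_information, render_scalar_atlas

        vol, graph = phantom
        anchor = vol.frame.center_um()[:2]
        truth = PlaneParams(2.0, -3.0, 5200.0, anchor)
        img = render_scalar_atlas(vol, graph, truth, 160)
        s_true = normalized_mutual_information(
            img, render_scalar_atlas(vol, graph, truth, 160), bins=24)
        rng = np.random.default_rng(0)
        for _ in range(15):
            other = PlaneParams(float(rng.uniform(-8, 8)), float(rng.uniform(-8, 8)),
                                float(rng.uniform(3000, 8000)), anchor)
            if (other.alpha_deg, other.beta_deg, other.d_um) == (2.0, -3.0, 5200.0):
                continue
            s_other = normalized_mutual_information(
                img, render_scalar_atlas(vol, graph, other, 160), bins=24)
            assert s_true >= s_other

    def test_all_background_rejected(self, phantom):
        vol, graph = phantom
        with pytest.raises(LocalizationError, match="background"):
            brute_force_localize(np.zeros((32, 32)), vol, graph)


class TestLocalize:
    def test_group_b_oracle_recovers_plane(self, phantom):
        vol, graph = phantom
        anchor = vol.frame.center_um()[:2]
        truth = PlaneParams(3.0, -2.0, 5500.0, anchor)
        sec = simulate_section(vol, graph, truth,
                               deform_spec=DeformSpec(max_displacement_px=0.0),
                               artifact_level=1, seed=12)
        sl = ConstantPredictor(float(ap_to_ara_section(5500.0)))
        res = localize(sec.image, vol, graph, sl_predictor=sl,
                       ql_predictor=PlaneOraclePredictor(truth))
        assert res.group == GroupLabel.B
        assert res.plane.alpha_deg == pytest.approx(3.0, abs=0.01)
        assert res.plane.beta_deg == pytest.approx(-2.0, abs=0.01)
        assert res.plane.d_um == pytest.approx(5500.0, abs=1.0)

    def test_group_c_per_component_planes(self, phantom):
        vol, graph = phantom
        anchor = vol.frame.center_um()[:2]
        d = float(ara_section_to_ap(92))
        truth = PlaneParams(0.0, 2.0, d, anchor)
        sec = simulate_section(vol, graph, truth,
                               deform_spec=DeformSpec(max_displacement_px=2.0,
                                                      brainstem_offset_um=300.0),
                               artifact_level=3, seed=13)
        res = localize(sec.image, vol, graph,
                       sl_predictor=ConstantPredictor(92),
                       ql_predictor=PlaneOraclePredictor(sec.truth_plane))
        assert res.group == GroupLabel.C
        assert abs(res.plane["left_cerebrum"].d_um - d) <= 100.0
        assert abs(res.plane["right_cerebrum"].d_um - d) <= 100.0
        assert abs(res.plane["brainstem"].d_um - (d + 300.0)) <= 100.0
        assert res.plane["left_cerebrum"].alpha_deg == 0.0

    def test_group_a_routes_to_segmentation(self, phantom):
        vol, graph = phantom
        anchor = vol.frame.center_um()[:2]
        sec = simulate_section(vol, graph, PlaneParams(0, 0, 1000.0, anchor),
                               deform_spec=DeformSpec(max_displacement_px=1.0),
                               artifact_level=1, seed=14)
        res = localize(sec.image, vol, graph, sl_predictor=ConstantPredictor(11))
        assert res.group == GroupLabel.A
        assert res.group_a_mask is not None
        assert res.plane is None

    def test_group_routing_follows_sl_only(self, phantom):
        from sliceloc.frames import group_of_section

        # routing is a pure function of the SL prediction
        for s in range(1, 133):
            assert group_of_section(s).value in {"A", "B", "Bprime", "C"}
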