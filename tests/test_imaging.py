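import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import ndimage

from fpdscore.errors import (
    DegenerateFootpad,
    FootpadNotFound,
    InvalidThresholds,
    NoFootDetected,
)
from fpdscore.imaging import (
    ColorConfig,
    FootpadRegion,
    FootRecord,
    PipelineConfig,
    RgbImage,
    ScoreThresholds,
    circle_mask,
    classify_score,
    compute_area_ratio,
    detect_lesions,
    locate_footpad,
    score_image,
    segment_foot,
    select_foot,
)
from fpdscore.synthetic import SyntheticFootSpec, generate_foot

from oracles import brute_connected_components, brute_inscribed_circle

BLUE = (40, 80, 180)
SKIN = (205, 170, 150)


def image_from_mask(mask, fg=SKIN, bg=BLUE):
    px = np.zeros(mask.shape + (3,), np.uint8)
    px[:] = bg
    px[mask] = fg
    return RgbImage(pixels=px)


class TestRgbImage:
    def test_rejects_small_images(self):
        with pytest.raises(ValueError):
            RgbImage(pixels=np.zeros((32, 128, 3), np.uint8))

    def test_alpha_ignored_with_warning(self):
        px = np.zeros((64, 64, 4), np.uint8)
        with pytest.warns(UserWarning, match="alpha"):
            img = RgbImage(pixels=px)
        assert img.pixels.shape == (64, 64, 3)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            RgbImage(pixels=np.full((64, 64, 3), 300, np.int32))


class TestSegmentFoot:
    def test_uniform_blue_raises(self, blue_image):
        with pytest.raises(NoFootDetected):
            segment_foot(RgbImage(pixels=blue_image))

    def test_largest_component_only_vs_brute_force(self):
        # one large and one small blob on a hand-built raster
        mask = np.zeros((64, 64), bool)
        mask[10:40, 10:40] = True  # 900 px
        mask[50:56, 50:56] = True  # 36 px
        got = segment_foot(image_from_mask(mask))
        comps = brute_connected_components(mask)
        largest = max(comps, key=len)
        expected = np.zeros_like(mask)
        for y, x in largest:
            expected[y, x] = True
        assert np.array_equal(got, expected)

    def test_tiny_blob_below_one_percent_raises(self):
        mask = np.zeros((128, 128), bool)
        mask[5:12, 5:12] = True  # 49 px < 1% of 16384
        with pytest.raises(NoFootDetected):
            segment_foot(image_from_mask(mask))

    def test_holes_are_filled(self):
        mask = np.zeros((64, 64), bool)
        mask[8:56, 8:56] = True
        hollow = mask.copy()
        hollow[24:32, 24:32] = False
        got = segment_foot(image_from_mask(hollow))
        assert np.array_equal(got, mask)

    def test_synthetic_foot_high_jaccard(self, straight_foot):
        img, truth = straight_foot
        got = segment_foot(img)
        inter = (got & truth.foot_mask).sum()
        union = (got | truth.foot_mask).sum()
        assert inter / union >= 0.95

    def test_wrapping_hue_window(self, blue_image):
        # a window through 0 degrees classifies red as background
        px = blue_image.copy()
        px[:] = (200, 30, 40)
        cfg = ColorConfig(background_hue_window=(320.0, 40.0))
        with pytest.raises(NoFootDetected):
            segment_foot(RgbImage(pixels=px), cfg)


class TestLocateFootpad:
    def test_solid_disc(self):
        yy, xx = np.mgrid[0:128, 0:128]
        mask = (yy - 64) ** 2 + (xx - 60) ** 2 <= 40**2
        fp = locate_footpad(mask)
        assert abs(fp.center[0] - 64) <= 1 and abs(fp.center[1] - 60) <= 1
        assert abs(fp.radius - 40) <= 1

    @pytest.mark.parametrize("w,h", [(30, 50), (51, 31), (40, 40)])
    def test_rectangle(self, w, h):
        mask = np.zeros((80, 80), bool)
        mask[10 : 10 + h, 10 : 10 + w] = True
        fp = locate_footpad(mask)
        assert abs(fp.radius - min(w, h) // 2) <= 1

    def test_empty_mask_raises(self):
        with pytest.raises(FootpadNotFound):
            locate_footpad(np.zeros((64, 64), bool))

    def test_thin_mask_vanishes_under_opening(self):
        mask = np.zeros((64, 200), bool)
        mask[30:32, 10:190] = True  # 2-px ribbon, opening radius 4
        with pytest.raises(FootpadNotFound):
            locate_footpad(mask)

    def test_synthetic_foot_pad_found_toes_avoided(self, straight_foot):
        img, truth = straight_foot
        fp = locate_footpad(truth.foot_mask)
        assert truth.footpad_mask[fp.center]
        toes = np.logical_or.reduce(truth.toe_segment_masks)
        assert (fp.mask & toes).sum() <= 0.05 * fp.mask.sum()

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_on_small_masks(self, seed):
        from conftest import random_blob_mask

        rng = np.random.default_rng(seed)
        mask = random_blob_mask(rng, size=64)
        # no opening: compare the raw inscribed-circle construction
        dist = ndimage.distance_transform_edt(mask)
        center = np.unravel_index(int(np.argmax(dist)), dist.shape)
        radius = float(dist[center])
        oc, orad = brute_inscribed_circle(mask)
        assert oc == (int(center[0]), int(center[1]))
        assert radius == pytest.approx(orad, abs=1e-9)

    def test_mask_subset_of_foot(self, straight_foot):
        img, truth = straight_foot
        fp = locate_footpad(truth.foot_mask)
        assert not (fp.mask & ~truth.foot_mask).any()


class TestDetectLesions:
    def test_uniform_footpad_empty(self):
        yy, xx = np.mgrid[0:128, 0:128]
        pad = (yy - 64) ** 2 + (xx - 64) ** 2 <= 40**2
        img = image_from_mask(pad)
        fp = locate_footpad(pad)
        for alg in ("AUT1", "AUT2"):
            seg = detect_lesions(img, fp, algorithm=alg)
            assert seg.total_area_px == 0
            assert not seg.mask.any()

    @pytest.mark.parametrize("alg", ["AUT1", "AUT2"])
    def test_thirty_percent_lesion_recovered(self, alg, straight_foot):
        img, truth = straight_foot
        foot = segment_foot(img)
        fp = locate_footpad(foot)
        seg = detect_lesions(img, fp, algorithm=alg)
        assert seg.total_area_px / fp.area_px == pytest.approx(0.30, abs=0.05)

    def test_boundary_arc_kept_by_aut1_rejected_by_aut2(self):
        img, truth = generate_foot(
            SyntheticFootSpec(target_ratio=0.0, boundary_artifact=True, seed=3)
        )
        foot = segment_foot(img)
        fp = locate_footpad(foot)
        aut1 = detect_lesions(img, fp, algorithm="AUT1")
        aut2 = detect_lesions(img, fp, algorithm="AUT2")
        assert aut1.total_area_px > 0
        assert aut2.total_area_px == 0

    def test_lesion_mask_subset_of_footpad(self, straight_foot):
        img, _ = straight_foot
        foot = segment_foot(img)
        fp = locate_footpad(foot)
        for alg in ("AUT1", "AUT2"):
            seg = detect_lesions(img, fp, algorithm=alg)
            assert not (seg.mask & ~fp.mask).any()
            assert seg.total_area_px == sum(c.area_px for c in seg.components)

    def test_strata_labels(self, straight_foot):
        img, _ = straight_foot
        fp = locate_footpad(segment_foot(img))
        aut1 = detect_lesions(img, fp, algorithm="AUT1")
        assert all(c.stratum == "dark" for c in aut1.components)
        aut2 = detect_lesions(img, fp, algorithm="AUT2")
        assert all(c.stratum in ("dark", "intermediate") for c in aut2.components)


class TestAreaRatioAndScore:
    def test_direct_division(self):
        fp = FootpadRegion((0, 0), 1.0, np.ones((64, 64), bool), 1000)
        from fpdscore.imaging import LesionSegmentation

        lesions = LesionSegmentation(np.zeros((64, 64), bool), (), 50)
        assert compute_area_ratio(lesions, fp) == pytest.approx(0.05)
        assert compute_area_ratio(LesionSegmentation(np.zeros((64, 64), bool), (), 0), fp) == 0.0
        assert compute_area_ratio(LesionSegmentation(np.ones((64, 64), bool), (), 1000), fp) == 1.0

    def test_degenerate_footpad(self):
        from fpdscore.imaging import LesionSegmentation

        fp = FootpadRegion((0, 0), 1.0, np.zeros((64, 64), bool), 0)
        with pytest.raises(DegenerateFootpad):
            compute_area_ratio(LesionSegmentation(np.zeros((64, 64), bool), (), 0), fp)

    def test_intact_foot_level_zero(self):
        assert classify_score(0.0, has_lesion=False).level == 0

    @pytest.mark.parametrize(
        "ratio,expected", [(0.05, 1), (0.32, 3), (0.60, 4)]
    )
    def test_class_definitions(self, ratio, expected):
        assert classify_score(ratio, has_lesion=True).level == expected

    @pytest.mark.parametrize(
        "ratio,expected", [(0.10, 2), (0.25, 3), (0.50, 4)]
    )
    def test_half_open_boundaries(self, ratio, expected):
        # "<10%" is strict: exactly 10% falls in the next class
        assert classify_score(ratio, has_lesion=True).level == expected

    def test_invalid_thresholds(self):
        with pytest.raises(InvalidThresholds):
            classify_score(0.2, True, ScoreThresholds(t1=0.4, t2=0.3, t3=0.5))

    @given(st.floats(0, 1), st.floats(0, 1))
    def test_monotone_in_ratio(self, r1, r2):
        lo, hi = sorted((r1, r2))
        assert (
            classify_score(lo, True).level <= classify_score(hi, True).level
        )

    @given(st.floats(0, 1), st.booleans())
    def test_total_function(self, ratio, has_lesion):
        level = classify_score(ratio, has_lesion).level
        assert level in (0, 1, 2, 3, 4)
        if not has_lesion:
            assert level == 0


class TestScoreImage:
    def test_recovers_true_level(self, straight_foot):
        img, truth = straight_foot
        rec = score_image(img)
        assert rec.scorable
        assert rec.level == truth.true_level == 3

    def test_blue_frame_unscorable(self, blue_image):
        rec = score_image(RgbImage(pixels=blue_image, id="empty"))
        assert not rec.scorable
        assert rec.qc_flag == "NoFootDetected"
        assert rec.level is None

    def test_deterministic_record(self, straight_foot):
        img, _ = straight_foot
        r1 = score_image(img)
        r2 = score_image(img)
        assert r1 == r2
        assert np.array_equal(r1.footpad.mask, r2.footpad.mask)

    def test_mirror_invariance(self, straight_foot):
        img, _ = straight_foot
        mirrored = RgbImage(
            pixels=np.ascontiguousarray(img.pixels[:, ::-1]),
            id=img.id,
            laterality="right",
        )
        a, b = score_image(img), score_image(mirrored)
        assert a.level == b.level
        assert a.ratio == pytest.approx(b.ratio, abs=0.01)

    def test_mask_nesting_invariant(self, straight_foot):
        img, _ = straight_foot
        rec = score_image(img)
        foot = segment_foot(img)
        assert not (rec.footpad.mask & ~foot).any()
        assert not (rec.lesions.mask & ~rec.footpad.mask).any()


class TestSelectFoot:
    def _rec(self, flag="OK"):
        return FootRecord("f", "left", "AUT1", 1, 0.05, 100, 5, qc_flag=flag)

    def test_left_preferred(self):
        left, right = self._rec(), self._rec()
        assert select_foot((left, right)) is left

    def test_switches_to_right(self):
        left = self._rec("NoFootDetected")
        right = self._rec()
        assert select_foot((left, right)) is right

    def test_unscorable_pair(self):
        left = self._rec("NoFootDetected")
        right = self._rec("FootpadNotFound")
        chosen = select_foot((left, right))
        assert not chosen.scorable

    def test_both_policy(self):
        left, right = self._rec(), self._rec()
        assert select_foot((left, right), policy="both") == (left, right)

    def test_requires_one_record(self):
        with pytest.raises(ValueError):
            select_foot((None, None))


def test_circle_mask_convention():
    m = circle_mask((7, 7), (3, 3), 2.0)
    assert m[3, 3] and m[3, 5] and not m[3, 6]
    assert m.sum() == 13
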