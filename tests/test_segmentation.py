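import numpy as np
import pytest

from fluoroseg.color_features import make_feature_vector
from fluoroseg.labels import (BACKGROUND, BACKGROUND3, BROWN3, OPAQUE3, WHITE,
                              WHITE_YELLOW)
from fluoroseg.prototypes import PrototypeSet
from fluoroseg.segmentation import (SegmentationConfig, compute_ratios,
                                    morphological_cleanup, predict_class_map,
                                    reclassify_enclosed_background,
                                    remove_small_regions, segment_image)
from fluoroseg.synthetic import DEFAULT_MEANS


def class_mean_prototypes() -> PrototypeSet:
    """One prototype per class, sitting exactly at the class color means."""
    rgb = np.array([DEFAULT_MEANS[c] for c in
                    ("white", "yellow", "opaque", "brown", "background")])
    return PrototypeSet(make_feature_vector(rgb), np.arange(5))


def paint(img, rgb_name):
    img[...] = (np.array(DEFAULT_MEANS[rgb_name]) * 255).round().astype(np.uint8)


class TestPredictClassMap:
    def test_pure_class_colors_map_perfectly(self):
        protos = class_mean_prototypes()
        img = np.zeros((10, 15, 3), dtype=np.uint8)
        paint(img[:, :5], "white")
        paint(img[:, 5:10], "brown")
        paint(img[:, 10:], "background")
        cm = predict_class_map(img, protos)
        assert cm.shape == (10, 15)
        assert (cm[:, :5] == 0).all() and (cm[:, 5:10] == 3).all() and (cm[:, 10:] == 4).all()

    def test_constant_image_gives_constant_map(self):
        img = np.zeros((6, 6, 3), dtype=np.uint8)
        paint(img, "yellow")
        assert (predict_class_map(img, class_mean_prototypes()) == 1).all()


class TestMorphology:
    def test_isolated_speck_removed(self):
        mask = np.zeros((30, 30), dtype=bool)
        mask[15, 15] = True
        assert not morphological_cleanup(mask, opening_radius=2,
                                         dilation_radius=0).any()

    def test_large_rectangle_roughly_preserved(self):
        mask = np.zeros((40, 40), dtype=bool)
        mask[5:35, 5:35] = True
        out = morphological_cleanup(mask, opening_radius=2, dilation_radius=1)
        # interior survives; boundary moves by at most the radii involved
        assert out[8:32, 8:32].all()
        assert not out[:2].any()

    def test_opening_is_idempotent(self):
        rng = np.random.default_rng(0)
        mask = rng.random((50, 50)) > 0.4
        once = morphological_cleanup(mask, opening_radius=2, dilation_radius=0)
        twice = morphological_cleanup(once, opening_radius=2, dilation_radius=0)
        assert np.array_equal(once, twice)


class TestEnclosedBackground:
    def _ring_scene(self):
        img = np.zeros((21, 21, 3), dtype=np.uint8)
        paint(img, "background")
        mask = np.zeros((21, 21), dtype=bool)
        mask[3:18, 3:18] = True
        mask[8:13, 8:13] = False          # enclosed hole
        cm = np.full((21, 21), BACKGROUND)
        cm[mask] = WHITE
        paint(img[3:18, 3:18], "white")
        paint(img[8:13, 8:13], "white")   # hole is enamel-colored
        return img, mask, cm

    def test_enamel_colored_hole_relabeled_to_tooth_class(self):
        img, mask, cm = self._ring_scene()
        protos = class_mean_prototypes()
        new_cm, new_mask = reclassify_enclosed_background(img, mask, cm, protos)
        assert (new_cm[8:13, 8:13] == WHITE).all()
        assert new_mask[8:13, 8:13].all()

    def test_pixels_outside_holes_untouched(self):
        img, mask, cm = self._ring_scene()
        new_cm, _ = reclassify_enclosed_background(img, mask, cm,
                                                   class_mean_prototypes())
        hole = np.zeros_like(mask)
        hole[8:13, 8:13] = True
        assert np.array_equal(new_cm[~hole], cm[~hole])

    def test_no_holes_is_a_no_op(self):
        img = np.zeros((10, 10, 3), dtype=np.uint8)
        mask = np.zeros((10, 10), dtype=bool)
        mask[2:8, 2:8] = True
        cm = np.full((10, 10), BACKGROUND)
        cm[mask] = WHITE
        new_cm, new_mask = reclassify_enclosed_background(
            img, mask, cm, class_mean_prototypes())
        assert np.array_equal(new_cm, cm) and np.array_equal(new_mask, mask)


class TestSmallRegionRemoval:
    def _tooth(self, n=10_000):
        side = 100
        cm3 = np.full((side, side), WHITE_YELLOW)
        mask = np.ones((side, side), dtype=bool)
        return cm3, mask

    def test_opaque_below_threshold_removed(self):
        cm3, mask = self._tooth()
        cm3[:5, :10] = OPAQUE3            # 50 px = 0.50% < 0.55%
        out = remove_small_regions(cm3, mask)
        assert (out == WHITE_YELLOW).all()

    def test_opaque_above_threshold_kept(self):
        cm3, mask = self._tooth()
        cm3[:7, :8] = OPAQUE3             # 56 px = 0.56% >= 0.55%
        out = remove_small_regions(cm3, mask)
        assert (out[:7, :8] == OPAQUE3).all()

    def test_brown_above_its_smaller_threshold_kept(self):
        cm3, mask = self._tooth()
        cm3[0, :6] = BROWN3               # 6 px = 0.06% >= 0.05%
        out = remove_small_regions(cm3, mask)
        assert (out[0, :6] == BROWN3).all()

    def test_never_touches_background_or_grows_lesions(self):
        rng = np.random.default_rng(1)
        cm3 = rng.integers(0, 4, size=(60, 60))
        mask = cm3 != BACKGROUND3
        out = remove_small_regions(cm3, mask)
        assert (out == BACKGROUND3).sum() == (cm3 == BACKGROUND3).sum()
        assert (out == OPAQUE3).sum() <= (cm3 == OPAQUE3).sum()
        assert (out == BROWN3).sum() <= (cm3 == BROWN3).sum()

    def test_zero_tooth_area_rejected(self):
        cm3 = np.full((5, 5), BACKGROUND3)
        with pytest.raises(ValueError):
            remove_small_regions(cm3, np.zeros((5, 5), dtype=bool))


class TestRatios:
    def test_published_worked_example(self):
        # 200,431 white-yellow + 117,650 opaque + 5,397 brown tooth pixels
        counts = {WHITE_YELLOW: 200_431, OPAQUE3: 117_650, BROWN3: 5_397}
        flat = np.concatenate([np.full(n, code) for code, n in counts.items()])
        side = 600
        cm3 = np.full(side * side, BACKGROUND3)
        cm3[:flat.size] = flat
        cm3 = cm3.reshape(side, side)
        mask = np.zeros(side * side, dtype=bool)
        mask[:flat.size] = True
        r_opaque, r_brown = compute_ratios(cm3, mask.reshape(side, side))
        assert round(100 * r_brown, 2) == 1.67
        assert round(100 * r_opaque, 2) == 36.37

    def test_all_white_yellow_gives_zero_ratios(self):
        cm3 = np.full((10, 10), WHITE_YELLOW)
        assert compute_ratios(cm3, np.ones((10, 10), bool)) == (0.0, 0.0)

    def test_zero_tooth_area_rejected(self):
        cm3 = np.full((4, 4), BACKGROUND3)
        with pytest.raises(ValueError):
            compute_ratios(cm3, np.ones((4, 4), bool))


class TestSegmentImage:
    def test_deterministic_and_ratio_bounds(self, fixture_suite):
        images, _ = fixture_suite
        protos = class_mean_prototypes()
        a = segment_image(images[5].image, protos)
        b = segment_image(images[5].image, protos)
        assert np.array_equal(a.class_map3, b.class_map3)
        assert 0 <= a.r_opaque <= 1 and 0 <= a.r_brown <= 1
        assert a.r_opaque + a.r_brown <= 1

    def test_recovers_ground_truth_ratios_with_ideal_prototypes(self, fixture_suite):
        images, _ = fixture_suite
        protos = class_mean_prototypes()
        for mouth in (images[0], images[4], images[11]):
            seg = segment_image(mouth.image, protos)
            assert abs(seg.r_opaque - mouth.r_opaque) < 0.005
            assert abs(seg.r_brown - mouth.r_brown) < 0.005

    def test_cleanup_leaves_no_tiny_foreground_components(self, fixture_suite):
        from skimage import measure

        images, _ = fixture_suite
        seg = segment_image(images[3].image, class_mean_prototypes(),
                            SegmentationConfig(opening_radius=2))
        labeled = measure.label(seg.intermediates["raw_mask"] &
                                seg.mask, connectivity=2)
        if labeled.max():
            areas = np.bincount(labeled.ravel())[1:]
            assert areas.min() >= 4
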