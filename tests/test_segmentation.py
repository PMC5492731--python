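import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

import oracle
from henmon.frame_io import BinaryMask, TemperatureCalibration
from henmon.segmentation import (
    binarize,
    compute_bct,
    compute_histogram,
    count_colored_pixels,
    estimate_floor,
    filter_small_particles,
    label_particles,
)
from henmon.simulate import SceneConfig, render_frame
from henmon.templates import make_ellipse_template

pixel_grids = hnp.arrays(
    np.uint8, hnp.array_shapes(min_dims=2, max_dims=2, min_side=1, max_side=32)
)


class TestHistogram:
    def test_constant_frame(self, make_frame):
        hist = compute_histogram(make_frame(np.full((2, 2), 7)))
        assert hist.counts[7] == 4 and hist.total == 4
        assert hist.counts.sum() == 4

    def test_two_level_frame(self, make_frame):
        hist = compute_histogram(make_frame([[0, 255], [0, 255]]))
        assert hist.counts[0] == 2 and hist.counts[255] == 2

    def test_matches_per_pixel_tally_on_random_frame(self, make_frame):
        rng = np.random.default_rng(5)
        pixels = rng.integers(0, 256, size=(240, 320))
        hist = compute_histogram(make_frame(pixels))
        assert np.array_equal(hist.counts, oracle.histogram_tally(pixels))

    @settings(max_examples=30, derandomize=True)
    @given(pixels=pixel_grids)
    def test_conservation(self, pixels):
        from henmon.frame_io import ThermalFrame

        hist = compute_histogram(ThermalFrame(pixels=pixels))
        assert hist.total == pixels.size


class TestFloorEstimate:
    @pytest.mark.parametrize("method", ["mode", "trimmed-mean"])
    def test_constant_background_recovered(self, cal, make_frame, method):
        level = cal.intensity_of(8.0).level
        frame = make_frame(np.full((20, 20), level))
        bg = estimate_floor(frame, method=method)
        assert bg.floor_temperature == pytest.approx(8.0)
        assert bg.floor_intensity == level

    @pytest.mark.parametrize("floor_c", [5.0, 7.0, 8.0, 11.0, 13.0])
    def test_ambient_sweep_constant_floors(self, cal, make_frame, floor_c):
        frame = make_frame(np.full((30, 40), cal.intensity_of(floor_c).level))
        assert estimate_floor(frame).floor_temperature == pytest.approx(floor_c)

    def test_mode_robust_to_hot_blob(self):
        # noisy floor at 8 degC plus one hot elliptical blob on ~5% of pixels
        errors = []
        for seed in range(100):
            scene = SceneConfig(
                occupancy_schedule=(1,),
                hen_axes=(60.0, 30.0),
                footprint_rate=0, egg_rate=0, hot_patch_rate=0,
                seed=seed,
            )
            frame, _ = render_frame(scene, 0)
            errors.append(abs(estimate_floor(frame).floor_temperature - 8.0))
        assert max(errors) <= 0.2

    def test_unknown_method_rejected(self, make_frame):
        with pytest.raises(ValueError):
            estimate_floor(make_frame([[1]]), method="median")


class TestBct:
    @pytest.mark.parametrize("shift, expected", [(1.0, 90), (3.0, 110)])
    def test_linear_shift(self, cal, make_frame, shift, expected):
        bg = estimate_floor(make_frame(np.full((4, 4), 80)))
        bct = compute_bct(bg, shift, cal)
        assert bct.level == expected and not bct.saturated

    def test_zero_shift_rejected(self, cal, make_frame):
        bg = estimate_floor(make_frame([[80]]))
        with pytest.raises(ValueError):
            compute_bct(bg, 0.0, cal)

    def test_saturation_flagged(self, cal, make_frame):
        bg = estimate_floor(make_frame(np.full((4, 4), 250)))
        bct = compute_bct(bg, 3.0, cal)
        assert bct.level == 255 and bct.saturated


class TestBinarize:
    def test_strict_inequality(self, make_frame):
        mask = binarize(make_frame([[89, 90], [91, 120]]), 90)
        assert mask.pixels.tolist() == [[0, 0], [1, 1]]

    def test_extreme_thresholds(self, make_frame):
        frame = make_frame([[10, 20], [30, 255]])
        assert binarize(frame, 255).area() == 0
        assert binarize(frame, 0).area() == 4

    @settings(max_examples=30, derandomize=True)
    @given(pixels=pixel_grids, bct=st.integers(0, 255))
    def test_equivalence_with_double_loop(self, pixels, bct):
        from henmon.frame_io import ThermalFrame

        mask = binarize(ThermalFrame(pixels=pixels), bct)
        expected = [
            [1 if int(pixels[r, c]) > bct else 0 for c in range(pixels.shape[1])]
            for r in range(pixels.shape[0])
        ]
        assert mask.pixels.tolist() == expected

    @settings(max_examples=20, derandomize=True)
    @given(pixels=pixel_grids, lo=st.integers(0, 254))
    def test_cp_monotone_in_threshold(self, pixels, lo):
        from henmon.frame_io import ThermalFrame

        frame = ThermalFrame(pixels=pixels)
        cp_lo = count_colored_pixels(binarize(frame, lo))
        cp_hi = count_colored_pixels(binarize(frame, lo + 1))
        assert cp_hi <= cp_lo


class TestParticleFilter:
    def test_small_blob_removed(self):
        mask = np.zeros((20, 20), dtype=np.uint8)
        mask[5, 5:8] = 1
        out = filter_small_particles(BinaryMask(mask), min_area=30, opening_radius=0)
        assert out.area() == 0

    def test_selective_removal(self):
        mask = np.zeros((80, 80), dtype=np.uint8)
        mask[2, 2:12] = 1  # 10-pixel blob
        mask[20:60, 20:70] = 1  # 2000-pixel blob
        out = filter_small_particles(BinaryMask(mask), min_area=30, opening_radius=0)
        assert oracle.flood_fill_areas(out.pixels) == [2000]

    def test_opening_matches_bruteforce_on_rectangle(self):
        mask = np.zeros((60, 40), dtype=np.uint8)
        mask[5:55, 5:35] = 1  # solid 50 x 30 rectangle
        out = filter_small_particles(BinaryMask(mask), min_area=30, opening_radius=1)
        expected = oracle.opening_bruteforce(mask, 1)
        assert np.array_equal(out.pixels.astype(bool), expected)
        assert out.area() >= 48 * 28

    @settings(max_examples=15, derandomize=True)
    @given(
        pixels=hnp.arrays(
            np.uint8,
            hnp.array_shapes(min_dims=2, max_dims=2, min_side=8, max_side=24),
            elements=st.integers(0, 1),
        )
    )
    def test_idempotent_and_non_increasing(self, pixels):
        once = filter_small_particles(BinaryMask(pixels), 10, 1)
        twice = filter_small_particles(once, 10, 1)
        assert np.array_equal(once.pixels, twice.pixels)
        assert once.area() <= int(pixels.sum())


class TestColoredPixels:
    def test_empty_mask(self):
        assert count_colored_pixels(BinaryMask(np.zeros((4, 4), dtype=np.uint8))) == 0

    def test_filled_ellipse_exact_tally(self):
        tpl = make_ellipse_template(135, 63)
        assert count_colored_pixels(tpl.mask) == int(
            oracle.histogram_tally(tpl.mask.pixels)[1]
        )

    def test_full_hen_exceeds_cpt_at_shift_one(self, cal):
        scene = SceneConfig(
            occupancy_schedule=(1,), footprint_rate=0, egg_rate=0,
            hot_patch_rate=0, seed=9,
        )
        frame, _ = render_frame(scene, 0)
        bct = compute_bct(estimate_floor(frame), 1.0, cal)
        mask = filter_small_particles(binarize(frame, bct.level))
        assert count_colored_pixels(mask) > 1736


class TestLabelParticles:
    def test_axis_aligned_rectangle_extents(self):
        mask = np.zeros((120, 60), dtype=np.uint8)
        mask[10:110, 10:50] = 1  # 100 x 40
        (p,) = label_particles(BinaryMask(mask))
        assert p.rect_long == pytest.approx(100, abs=1)
        assert p.rect_short == pytest.approx(40, abs=1)
        assert p.pixel_count == 4000

    def test_equivalent_ellipse_axes_recovered(self):
        tpl = make_ellipse_template(135, 63)
        (p,) = label_particles(tpl.mask)
        assert abs(p.ellipse_major - 135) <= 3
        assert abs(p.ellipse_minor - 63) <= 2
        assert p.ellipse_major >= p.ellipse_minor > 0

    @pytest.mark.parametrize("angle", [0.0, 25.0, 60.0, 115.0])
    @pytest.mark.parametrize("axes", [(10, 10), (40, 18), (150, 70)])
    def test_rotated_ellipse_axes_within_5_percent(self, angle, axes):
        from henmon.simulate import _paint_ellipse

        temps = np.zeros((260, 260))
        _paint_ellipse(temps, (130, 130), axes, angle, 1.0)
        (p,) = label_particles(BinaryMask((temps > 0.5).astype(np.uint8)))
        assert p.ellipse_major == pytest.approx(axes[0], rel=0.05, abs=1.5)
        assert p.ellipse_minor == pytest.approx(axes[1], rel=0.05, abs=1.5)

    def test_two_blobs_match_flood_fill(self):
        rng = np.random.default_rng(3)
        mask = np.zeros((40, 40), dtype=np.uint8)
        mask[5:15, 5:15] = 1
        mask[25:38, 20:39] = (rng.random((13, 19)) < 0.9).astype(np.uint8)
        particles = label_particles(BinaryMask(mask))
        assert sorted(p.pixel_count for p in particles) == sorted(
            oracle.flood_fill_areas(mask)
        )
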