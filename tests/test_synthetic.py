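"""Generator contracts: determinism, mass linearity, ground-truth bookkeeping."""

from dataclasses import replace

import numpy as np
import pytest

from ringprofiler import (
    DynamicsSpec,
    GeometryError,
    NoiseSpec,
    SyntheticRingSpec,
    generate_random_network_image,
    generate_replicate_set,
    generate_ring_image,
    generate_timecourse,
    ground_truth_table,
    regression_dynamics,
)

NO_NOISE = NoiseSpec.NONE


class TestRingImage:
    def test_same_seed_bit_identical(self, small_spec):
        f1, t1 = generate_ring_image(small_spec, NoiseSpec(seed=3))
        f2, t2 = generate_ring_image(small_spec, NoiseSpec(seed=3))
        assert np.array_equal(f1.pixels, f2.pixels)
        assert t1 == t2

    def test_zero_amplitudes_give_blank_image(self, small_spec):
        spec = replace(small_spec, ring_amplitude=0.0, background_amplitude=0.0)
        frame, truth = generate_ring_image(spec, NO_NOISE)
        assert not frame.pixels.any()
        assert truth.foreground_area_um2 == 0.0

    def test_arc_fraction_halves_total_intensity(self, small_spec):
        """Total rendered ring intensity is proportional to the arc present."""
        spec = replace(small_spec, n_branches=0)
        full, _ = generate_ring_image(spec, NO_NOISE)
        half, _ = generate_ring_image(replace(spec, arc_fraction=0.5), NO_NOISE)
        ratio = half.pixels.sum() / full.pixels.sum()
        assert ratio == pytest.approx(0.5, rel=0.01)

    def test_total_intensity_linear_in_amplitude(self, small_spec):
        spec = replace(small_spec, n_branches=0)
        one, _ = generate_ring_image(spec, NO_NOISE)
        two, _ = generate_ring_image(replace(spec, ring_amplitude=2 * spec.ring_amplitude), NO_NOISE)
        assert two.pixels.sum() / one.pixels.sum() == pytest.approx(2.0, rel=0.01)

    def test_ring_peak_sits_at_half_diameter(self, small_spec):
        """The ideal annulus crest lies at radius = diameter / 2."""
        frame, truth = generate_ring_image(replace(small_spec, n_branches=0), NO_NOISE)
        h, w = frame.pixels.shape
        y, x = np.mgrid[0:h, 0:w]
        cx, cy = truth.center_px
        r_um = np.hypot(x - cx, y - cy) * frame.microns_per_pixel
        crest = r_um[frame.pixels == frame.pixels.max()]
        assert np.allclose(crest, truth.radius_um, atol=frame.microns_per_pixel)

    def test_oversized_ring_rejected(self, small_spec):
        with pytest.raises(GeometryError):
            generate_ring_image(replace(small_spec, ring_diameter_um=2100.0), NO_NOISE)

    def test_halfmax_area_matches_annulus_geometry(self, small_spec):
        """Bookkeeping: branch-free truth area ~ pi * diameter * thickness."""
        _, truth = generate_ring_image(replace(small_spec, n_branches=0), NO_NOISE)
        expected = np.pi * small_spec.ring_diameter_um * small_spec.ring_thickness_um
        assert truth.foreground_area_um2 == pytest.approx(expected, rel=0.02)

    def test_resolution_invariant_truth_area(self, small_spec):
        """Rendering at 2x resolution changes the true area by < 2%."""
        coarse = replace(small_spec, n_branches=0)
        fine = replace(coarse, image_size_px=(512, 512), microns_per_pixel=4.0)
        _, t_coarse = generate_ring_image(coarse, NO_NOISE)
        _, t_fine = generate_ring_image(fine, NO_NOISE)
        assert t_fine.foreground_area_um2 == pytest.approx(
            t_coarse.foreground_area_um2, rel=0.02
        )


class TestRandomNetwork:
    def test_empty_spec_gives_blank_image(self, small_spec):
        spec = replace(small_spec, n_branches=0, background_amplitude=0.0)
        frame, truth = generate_random_network_image(spec, NO_NOISE)
        assert not frame.pixels.any()
        assert truth.radius_um is None

    def test_determinism(self, small_spec):
        f1, _ = generate_random_network_image(small_spec, NoiseSpec(seed=9))
        f2, _ = generate_random_network_image(small_spec, NoiseSpec(seed=9))
        assert np.array_equal(f1.pixels, f2.pixels)

    def test_doubling_branches_roughly_doubles_foreground(self, small_spec):
        spec25 = replace(small_spec, n_branches=25)
        spec50 = replace(small_spec, n_branches=50)
        _, t25 = generate_random_network_image(spec25, NO_NOISE)
        _, t50 = generate_random_network_image(spec50, NO_NOISE)
        ratio = t50.foreground_area_um2 / t25.foreground_area_um2
        # sublinear only through overlap and field clipping
        assert 1.6 <= ratio <= 2.1


class TestTimecourse:
    def test_unit_multipliers_keep_area_constant(self, small_spec):
        dyn = DynamicsSpec(
            days=(-1, 0, 1),
            area_multiplier_per_day={-1: 1.0, 0: 1.0, 1: 1.0},
            thickness_multiplier_per_day={-1: 1.0, 0: 1.0, 1: 1.0},
            continuity_per_day={-1: 1.0, 0: 1.0, 1: 1.0},
        )
        _, truths = generate_timecourse(small_spec, NO_NOISE, dyn)
        areas = [t.foreground_area_um2 for t in truths]
        assert areas[1] == pytest.approx(areas[0], rel=0.011)
        assert areas[2] == pytest.approx(areas[0], rel=0.011)

    def test_programmed_growth_tracked_by_truth(self, small_spec):
        """A day-2 multiplier of 1.45 lands in the 1.43-1.47 band."""
        dyn = DynamicsSpec()
        _, truths = generate_timecourse(small_spec, NO_NOISE, dyn)
        by_day = {t.day: t.foreground_area_um2 for t in truths}
        assert 1.43 <= by_day[2] / by_day[-1] <= 1.47

    def test_regression_returns_to_baseline(self, small_spec):
        _, truths = generate_timecourse(small_spec, NO_NOISE, regression_dynamics())
        by_day = {t.day: t.foreground_area_um2 for t in truths}
        assert by_day[4] / by_day[-1] == pytest.approx(1.0, abs=0.02)

    def test_thickness_and_continuity_follow_their_maps(self, small_spec):
        dyn = DynamicsSpec(
            days=(-1, 0),
            area_multiplier_per_day={-1: 1.0, 0: 1.1},
            thickness_multiplier_per_day={-1: 1.0, 0: 1.2},
            continuity_per_day={-1: 1.0, 0: 0.7},
        )
        _, truths = generate_timecourse(small_spec, NO_NOISE, dyn)
        assert truths[1].thickness_um == pytest.approx(1.2 * small_spec.ring_thickness_um)
        assert truths[1].arc_fraction == pytest.approx(0.7)

    def test_baseline_multiplier_must_be_one(self):
        with pytest.raises(ValueError):
            DynamicsSpec(
                days=(-1, 0),
                area_multiplier_per_day={-1: 1.3, 0: 1.0},
                thickness_multiplier_per_day={-1: 1.0, 0: 1.0},
                continuity_per_day={-1: 1.0, 0: 1.0},
            ).validate()

    def test_unreachable_multiplier_raises(self, small_spec):
        dyn = DynamicsSpec(
            days=(-1, 0),
            area_multiplier_per_day={-1: 1.0, 0: 40.0},
            thickness_multiplier_per_day={-1: 1.0, 0: 1.0},
            continuity_per_day={-1: 1.0, 0: 1.0},
        )
        with pytest.raises(GeometryError):
            generate_timecourse(small_spec, NO_NOISE, dyn)


class TestReplicates:
    def test_zero_sds_reproduce_identical_geometry(self, small_spec):
        reps = generate_replicate_set(3, small_spec, {"ring_diameter_um": 0.0}, NO_NOISE)
        diams = {t.diameter_um for _, t in reps}
        assert diams == {small_spec.ring_diameter_um}

    def test_same_seed_identical_pair(self, small_spec):
        a = generate_replicate_set(2, small_spec, noise=NO_NOISE)
        b = generate_replicate_set(2, small_spec, noise=NO_NOISE)
        for (fa, ta), (fb, tb) in zip(a, b):
            assert np.array_equal(fa.pixels, fb.pixels)
            assert ta == tb

    def test_sample_mean_recovers_generating_mean(self, coarse_study_spec):
        """Drawn diameters average to the generating mean within 3 SE."""
        sds = {"ring_diameter_um": 142.0, "ring_thickness_um": 124.0}
        reps = generate_replicate_set(60, coarse_study_spec, sds, NO_NOISE)
        diams = np.array([t.diameter_um for _, t in reps])
        se = 142.0 / np.sqrt(len(diams))
        assert abs(diams.mean() - 1781.0) < 3 * se

    def test_n_below_two_rejected(self, small_spec):
        with pytest.raises(ValueError):
            generate_replicate_set(1, small_spec, noise=NO_NOISE)

    def test_degenerate_truncation_raises(self, small_spec):
        bad = replace(small_spec, ring_diameter_um=5000.0)
        with pytest.raises(GeometryError):
            generate_replicate_set(2, bad, {"ring_diameter_um": 1.0}, NO_NOISE)


def test_ground_truth_table_columns(small_spec):
    _, truth = generate_ring_image(small_spec, NO_NOISE)
    df = ground_truth_table([truth])
    assert list(df.columns) == [
        "day", "center_x_px", "center_y_px", "radius_um",
        "thickness_um", "arc_fraction", "area_um2", "seed",
    ]
    assert df.loc[0, "area_um2"] == truth.foreground_area_um2
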