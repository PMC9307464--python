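"""Radial-profile statistic: binning contract, peak, FWHM, AUC, centers."""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ringprofiler import (
    CenterEstimate,
    NoiseSpec,
    compute_radial_profile,
    estimate_center,
    generate_ring_image,
    profile_auc,
    profile_fwhm,
    profile_peak,
)
from ringprofiler.radialprofile import RadialProfile
from tests.conftest import frame_of

FWHM_PER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))


def naive_profile(pixels, cx, cy, mpp, r_max_um, bw_um, agg):
    """Independent double-loop accumulation oracle."""
    h, w = pixels.shape
    n_bins = int(math.ceil(r_max_um / bw_um))
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.intp)
    for i in range(h):
        for j in range(w):
            d = math.sqrt((j - cx) ** 2 + (i - cy) ** 2) * mpp
            if d < r_max_um:
                b = int(d // bw_um)
                sums[b] += float(pixels[i, j])
                counts[b] += 1
    if agg == "sum":
        values = sums.copy()
    else:
        values = np.where(counts > 0, sums / counts, 0.0)
    return values, counts


class TestBinningContract:
    @pytest.mark.parametrize("aggregation", ["sum", "mean"])
    def test_bit_exact_against_double_loop(self, rng, aggregation):
        pixels = rng.integers(0, 60000, size=(64, 64)).astype(np.uint16)
        frame = frame_of(pixels, mpp=2.0)
        center = CenterEstimate(31.3, 30.7)
        prof = compute_radial_profile(
            frame, center, r_max_um=80.0, bin_width_um=3.0, aggregation=aggregation
        )
        values, counts = naive_profile(pixels, 31.3, 30.7, 2.0, 80.0, 3.0, aggregation)
        assert np.array_equal(prof.n_pixels_per_bin, counts)
        assert np.array_equal(prof.values, values)

    @given(
        cx=st.floats(10, 90), cy=st.floats(10, 110),
        r_max=st.floats(10, 140), bw=st.floats(1.5, 12),
    )
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_pixel_conservation(self, cx, cy, r_max, bw):
        """Every pixel closer than r_max lands in exactly one bin."""
        h, w = 120, 100
        frame = frame_of(np.ones((h, w)), mpp=1.5)
        prof = compute_radial_profile(
            frame, CenterEstimate(cx, cy), r_max_um=r_max, bin_width_um=bw
        )
        y, x = np.mgrid[0:h, 0:w]
        d = np.hypot(x - cx, y - cy) * 1.5
        assert prof.n_pixels_per_bin.sum() == int((d < r_max).sum())

    def test_sum_mean_consistency(self, noisy_ring):
        frame, _ = noisy_ring
        prof = compute_radial_profile(frame, CenterEstimate(127.5, 127.5))
        prof_sum = prof.as_aggregation("sum")
        nz = prof.n_pixels_per_bin > 0
        assert np.allclose(
            prof_sum.values[nz], prof.values[nz] * prof.n_pixels_per_bin[nz]
        )

    def test_uniform_image_mean_profile_is_flat(self):
        frame = frame_of(np.ones((101, 101)))
        prof = compute_radial_profile(frame, CenterEstimate(50, 50), aggregation="mean")
        assert np.allclose(prof.values[prof.n_pixels_per_bin > 0], 1.0)

    def test_uniform_image_sum_profile_counts_annulus_pixels(self):
        frame = frame_of(np.ones((101, 101)))
        prof = compute_radial_profile(frame, CenterEstimate(50, 50), aggregation="sum")
        assert np.array_equal(prof.values, prof.n_pixels_per_bin.astype(float))

    def test_center_outside_image_rejected(self):
        frame = frame_of(np.ones((10, 10)))
        with pytest.raises(ValueError):
            compute_radial_profile(frame, CenterEstimate(50, 5))

    def test_bin_width_below_pixel_rejected(self):
        frame = frame_of(np.ones((10, 10)), mpp=4.0)
        with pytest.raises(ValueError):
            compute_radial_profile(frame, CenterEstimate(5, 5), bin_width_um=2.0)


def _profile_from(values, bw=1.0):
    values = np.asarray(values, dtype=float)
    radii = (np.arange(len(values)) + 0.5) * bw
    counts = np.full(len(values), 100, dtype=np.intp)
    return RadialProfile(
        radii_um=radii, values=values, bin_width_um=bw, aggregation="mean",
        center=CenterEstimate(0, 0), n_pixels_per_bin=counts,
        sums=values * 100,
    )


class TestPeak:
    def test_monotone_decreasing_peaks_at_first_bin(self):
        prof = _profile_from([9, 7, 5, 3, 1])
        peak = profile_peak(prof)
        assert peak.index == 0 and not peak.tie

    def test_tie_broken_toward_smaller_radius_and_flagged(self):
        prof = _profile_from([1, 5, 3, 5, 2])
        peak = profile_peak(prof)
        assert peak.index == 1
        assert peak.tie

    def test_all_zero_profile_signals_no_peak(self):
        assert profile_peak(_profile_from([0, 0, 0])) is None

    def test_parabolic_refinement_recovers_gaussian_mean(self):
        """Sub-bin refinement lands within 0.1 bin of the analytic mean."""
        mu, sigma, bw = 20.37, 4.0, 1.0
        radii = (np.arange(50) + 0.5) * bw
        vals = np.exp(-((radii - mu) ** 2) / (2 * sigma**2))
        prof = _profile_from(vals, bw)
        peak = profile_peak(prof, refine=True)
        assert peak.refined
        assert abs(peak.radius_um - mu) < 0.1 * bw


class TestFWHM:
    def test_gaussian_closed_form(self):
        """FWHM of a Gaussian peak is 2 sqrt(2 ln 2) sigma."""
        sigma, bw = 9.0, 1.0
        radii = (np.arange(120) + 0.5) * bw
        vals = 100.0 * np.exp(-((radii - 60.0) ** 2) / (2 * sigma**2))
        prof = _profile_from(vals, bw)
        peak = profile_peak(prof)
        fw = profile_fwhm(prof, peak, baseline=0.0)
        assert fw.width_um == pytest.approx(FWHM_PER_SIGMA * sigma, rel=0.02)
        assert not fw.one_sided

    def test_rectangular_peak_width_within_one_bin(self):
        vals = np.zeros(60)
        vals[20:35] = 7.0  # 15 bins wide
        prof = _profile_from(vals)
        fw = profile_fwhm(prof, profile_peak(prof), baseline=0.0)
        assert 14.0 <= fw.width_um <= 16.0

    def test_truncated_peak_reports_one_sided_width(self):
        """Half level never crossed on the left: double the right half-width."""
        sigma = 6.0
        radii = (np.arange(40) + 0.5)
        vals = 50.0 * np.exp(-((radii - 2.0) ** 2) / (2 * sigma**2))
        prof = _profile_from(vals)
        peak = profile_peak(prof)
        fw = profile_fwhm(prof, peak, baseline=0.0)
        assert fw.one_sided
        assert fw.left_um is None
        assert fw.width_um == pytest.approx(2 * (fw.right_um - peak.radius_um))

    def test_pedestal_shifts_half_level(self):
        """With an elevated baseline the width matches the peak-above-pedestal."""
        sigma = 9.0
        radii = (np.arange(120) + 0.5)
        vals = 30.0 + 100.0 * np.exp(-((radii - 60.0) ** 2) / (2 * sigma**2))
        prof = _profile_from(vals)
        fw = profile_fwhm(prof, profile_peak(prof), baseline=30.0)
        assert fw.width_um == pytest.approx(FWHM_PER_SIGMA * sigma, rel=0.02)


class TestAUC:
    def test_zero_profile_integrates_to_zero(self):
        prof = _profile_from(np.zeros(30))
        assert profile_auc(prof) == 0.0

    def test_constant_profile_rectangle_rule(self):
        prof = _profile_from(np.full(41, 3.0))
        # trapezoid over the bin-center span
        assert profile_auc(prof) == pytest.approx(3.0 * 40.0)

    def test_empty_range_rejected(self):
        prof = _profile_from(np.ones(30))
        with pytest.raises(ValueError):
            profile_auc(prof, r_range=(10.0, 10.0))

    def test_auc_linear_in_amplitude(self, small_spec):
        spec = replace(small_spec, n_branches=0)
        f1, t1 = generate_ring_image(spec, NoiseSpec.NONE)
        f2, _ = generate_ring_image(replace(spec, ring_amplitude=2 * spec.ring_amplitude), NoiseSpec.NONE)
        c = CenterEstimate(*t1.center_px)
        a1 = profile_auc(compute_radial_profile(f1, c, aggregation="sum"))
        a2 = profile_auc(compute_radial_profile(f2, c, aggregation="sum"))
        assert a2 / a1 == pytest.approx(2.0, rel=0.01)


class TestCenterEstimation:
    def test_centered_ring_centroid_hits_image_center(self, clean_ring):
        frame, truth = clean_ring
        c = estimate_center(frame)
        assert abs(c.x_px - truth.center_px[0]) < 1.0
        assert abs(c.y_px - truth.center_px[1]) < 1.0

    def test_offset_ring_centroid_within_two_px(self, small_spec):
        spec = replace(small_spec, n_branches=0, center_offset_um=(200.0, -120.0))
        frame, truth = generate_ring_image(spec, NoiseSpec.NONE)
        c = estimate_center(frame)
        assert np.hypot(c.x_px - truth.center_px[0], c.y_px - truth.center_px[1]) < 2.0

    def test_half_ring_refinement_beats_biased_centroid(self, small_spec):
        """Centroid drifts toward the arc; grid refinement recovers the center."""
        spec = replace(small_spec, arc_fraction=0.5)
        frame, truth = generate_ring_image(spec, NoiseSpec.NONE)
        centroid = estimate_center(frame)
        refined = estimate_center(frame, "grid_refined")
        err_centroid = np.hypot(
            centroid.x_px - truth.center_px[0], centroid.y_px - truth.center_px[1]
        )
        err_refined = np.hypot(
            refined.x_px - truth.center_px[0], refined.y_px - truth.center_px[1]
        )
        assert err_centroid > 10.0
        assert err_refined < 5.0

    def test_all_zero_frame_rejected(self):
        with pytest.raises(ValueError):
            estimate_center(frame_of(np.zeros((16, 16))))


def test_rotation_invariance(small_spec):
    """A 90-degree rotation moves the peak < 1 bin and the AUC < 1%."""
    from ringprofiler import ImageFrame, measure_ring

    frame, _ = generate_ring_image(small_spec, NoiseSpec.NONE)
    rotated = ImageFrame(np.rot90(frame.pixels).copy(), frame.microns_per_pixel)
    m1 = measure_ring(frame)
    m2 = measure_ring(rotated)
    assert abs(m1.diameter_um - m2.diameter_um) <= 2 * frame.microns_per_pixel
    assert m2.auc_AU_um == pytest.approx(m1.auc_AU_um, rel=0.01)
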