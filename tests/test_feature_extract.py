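"""Waveform-geometry and coverage-trend features."""

import math

import numpy as np
import pytest

from cfocr.feature_extract import (
    FEATURE_NAMES,
    X_SCALE,
    assemble_features,
    coverage_trends,
    peak_geometry,
    window_2000,
)
from cfocr.io_fragments import GenomeTile
from cfocr.peak_trough import Peak, Trough
from cfocr.wps_signal import CoverageTrack, WpsTrack
from oracles import ols_normal_equations


def make_track(values, start=0, contig="chrT", contig_length=None):
    values = np.asarray(values, dtype=float)
    tile = GenomeTile(
        contig, start, start + len(values), pad=0,
        contig_length=contig_length or (start + len(values)),
    )
    track = WpsTrack(tile=tile, raw=np.zeros(len(values), dtype=np.int64))
    track.normalized = values
    track.smoothed = values
    return track


def triangle(n, apex, left, right, amplitude=1.0):
    y = np.zeros(n)
    up = np.arange(left, apex + 1)
    y[up] = amplitude * (up - left) / (apex - left)
    down = np.arange(apex, right + 1)
    y[down] = amplitude * (right - down) / (right - apex)
    return y


class TestWindow2000:
    def test_centered(self):
        assert window_2000(5000) == (4000, 6000, False)

    def test_clamped_at_contig_start(self):
        lo, hi, clamped = window_2000(500)
        assert (lo, clamped) == (0, True)

    def test_clamped_at_contig_end(self):
        lo, hi, clamped = window_2000(9500, contig_length=10_000)
        assert (hi, clamped) == (10_000, True)


class TestPeakGeometry:
    def test_symmetric_triangle_closed_form(self):
        y = triangle(400, apex=150, left=100, right=200)
        track = make_track(y)
        peak = Peak(apex=150, height=1.0, width=50.0)
        area, angle, height, width = peak_geometry(peak, 100, 200, track)
        assert width == 100
        assert height == pytest.approx(1.0)
        assert area == pytest.approx(50.0)  # 1/2 * base 100 * height 1
        # apex vectors: (+-50 bp * 0.1, -1.0) => angle = 2*atan(5/1)
        assert angle == pytest.approx(math.degrees(2 * math.atan(5.0)), abs=1e-9)

    def test_x_scaling_changes_angle_as_closed_form(self):
        y = triangle(400, apex=150, left=100, right=200)
        track = make_track(y)
        peak = Peak(apex=150, height=1.0, width=50.0)
        _, angle, _, _ = peak_geometry(peak, 100, 200, track, x_scale=0.01)
        assert angle == pytest.approx(math.degrees(2 * math.atan(0.5)), abs=1e-9)

    def test_flat_segment_zero_area_and_height(self):
        track = make_track(np.zeros(400))
        peak = Peak(apex=150, height=0.0, width=50.0)
        area, angle, height, width = peak_geometry(peak, 100, 200, track)
        assert area == 0.0
        assert height == 0.0

    def test_troughs_must_flank(self):
        track = make_track(np.zeros(400))
        peak = Peak(apex=150, height=0.0, width=50.0)
        with pytest.raises(ValueError):
            peak_geometry(peak, 200, 100, track)


class TestCoverageTrends:
    def test_linear_coverage_recovered_on_all_subintervals(self):
        x = np.arange(2000, dtype=float)
        y = 2.0 * x + 1.0
        result = coverage_trends(y)
        assert result == pytest.approx((2.0, 1.0) * 3)

    def test_constant_coverage_zero_slopes(self):
        result = coverage_trends(np.full(2000, 0.8))
        assert result[0::2] == pytest.approx((0.0, 0.0, 0.0), abs=1e-12)
        assert result[1::2] == pytest.approx((0.8, 0.8, 0.8))

    def test_noisy_input_matches_normal_equations_oracle(self, rng):
        y = rng.normal(1.0, 0.3, 2000)
        slope_full, icpt_full, slope_l, icpt_l, slope_r, icpt_r = coverage_trends(y)
        for (lo, hi), got in [
            ((0, 2000), (slope_full, icpt_full)),
            ((0, 1200), (slope_l, icpt_l)),
            ((800, 2000), (slope_r, icpt_r)),
        ]:
            want = ols_normal_equations(np.arange(lo, hi), y[lo:hi])
            assert got == pytest.approx(want, abs=1e-9)


def two_peak_fixture(start=0):
    """Two triangular peaks with flanking troughs and a linear coverage dip.

    All geometry is closed-form so every feature can be hand-computed.
    """
    n = 2400
    y = (
        triangle(n, apex=1000 - start * 0, left=900, right=1100, amplitude=1.0)
        + triangle(n, apex=1200, left=1100, right=1300, amplitude=0.5)
    )
    track = make_track(y, start=start)
    peaks = [
        Peak(apex=start + 1000, height=1.0, width=100.0),
        Peak(apex=start + 1200, height=0.5, width=100.0),
    ]
    troughs = [
        Trough(position=start + 900, depth=0.0, width_from_peak=0.0),
        Trough(position=start + 1100, depth=0.0, width_from_peak=0.0),
        Trough(position=start + 1300, depth=0.0, width_from_peak=0.0),
    ]
    cov_vals = 1.0 + 0.0005 * np.arange(n)  # linear trend, slope known
    tile = track.tile
    cov = CoverageTrack(tile, cov_vals.copy())
    cov.normalized = cov_vals
    return track, peaks, troughs, cov


class TestAssembleFeatures:
    def test_two_peak_fixture_hand_computed(self):
        track, peaks, troughs, cov = two_peak_fixture()
        fv = assemble_features(1100, peaks, troughs, track, cov)
        # geometry, by hand: widths 200/200; heights 1.0/0.5 (trough values 0)
        assert fv.peak_width_mean == pytest.approx(200.0)
        assert fv.peak_width_var == pytest.approx(0.0)
        assert fv.peak_height_mean == pytest.approx(0.75)
        assert fv.peak_height_var == pytest.approx(0.0625)
        # areas: 1/2 * 200 * amplitude => 100 and 50
        assert fv.peak_area_mean == pytest.approx(75.0)
        assert fv.peak_area_var == pytest.approx(625.0)
        # spacing: single gap of 200
        assert fv.peak_spacing_mean == pytest.approx(200.0)
        assert fv.peak_spacing_var == pytest.approx(0.0)
        # angles: apex vectors (+-10, -amp) in scaled units
        a1 = math.degrees(2 * math.atan(10 / 1.0))
        a2 = math.degrees(2 * math.atan(10 / 0.5))
        assert fv.peak_angle_mean == pytest.approx((a1 + a2) / 2)
        assert fv.peak_angle_var == pytest.approx(((a1 - a2) / 2) ** 2)
        # coverage: linear 1 + 0.0005*x over window [100, 2100)
        assert fv.slope_full == pytest.approx(0.0005, abs=1e-12)
        assert fv.broad_interval_coverage == pytest.approx(
            np.mean(1.0 + 0.0005 * np.arange(100, 2100))
        )
        assert fv.geometry_missing == 0.0
        # central peak = nearest apex to centre 1100 -> the 1000 apex (tie to left)
        assert fv.bisector_dy < 0  # bisector points downward for a peak

    def test_translation_invariance(self):
        track0, peaks0, troughs0, cov0 = two_peak_fixture()
        fv0 = assemble_features(1100, peaks0, troughs0, track0, cov0)
        shift = 10_000
        track1, _, _, _ = two_peak_fixture()
        track1.tile = GenomeTile(
            "chrT", shift, shift + 2400, pad=0, contig_length=shift + 2400
        )
        peaks1 = [Peak(p.apex + shift, p.height, p.width) for p in peaks0]
        troughs1 = [
            Trough(t.position + shift, t.depth, t.width_from_peak) for t in troughs0
        ]
        cov1 = CoverageTrack(track1.tile, cov0.depth.copy())
        cov1.normalized = cov0.normalized
        fv1 = assemble_features(1100 + shift, peaks1, troughs1, track1, cov1)
        np.testing.assert_allclose(fv0.to_array(), fv1.to_array(), atol=1e-9)

    def test_single_peak_variances_zero(self):
        track, peaks, troughs, cov = two_peak_fixture()
        fv = assemble_features(1000, peaks[:1], troughs[:2], track, cov)
        for name in FEATURE_NAMES:
            if name.endswith("_var"):
                assert getattr(fv, name) == 0.0

    def test_no_complete_peak_sets_missing_flag(self):
        track, _, _, cov = two_peak_fixture()
        fv = assemble_features(1100, [], [], track, cov)
        assert fv.geometry_missing == 1.0
        assert fv.peak_height_mean == 0.0

    def test_uniform_coverage_narrow_equals_broad_equals_one(self):
        track, peaks, troughs, cov = two_peak_fixture()
        cov.normalized = np.ones_like(cov.normalized)
        fv = assemble_features(1100, peaks, troughs, track, cov)
        assert fv.narrow_interval_coverage == pytest.approx(1.0)
        assert fv.broad_interval_coverage == pytest.approx(1.0)

    def test_variance_zero_iff_values_equal(self):
        track, peaks, troughs, cov = two_peak_fixture()
        fv = assemble_features(1100, peaks, troughs, track, cov)
        assert fv.peak_height_var > 0  # heights differ (1.0 vs 0.5)
        assert fv.peak_width_var == 0.0  # widths equal (200, 200)
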