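"""Peak location, three-window trough scan, credibility predicate, calibration."""

import numpy as np
import pytest

from cfocr.io_fragments import GenomeTile
from cfocr.peak_trough import (
    Peak,
    PeakParams,
    Trough,
    calibrate_from_samples,
    find_troughs,
    find_wps_peaks,
    is_credible_trough,
    reconcile_troughs,
)
from cfocr.wps_signal import WpsTrack
from oracles import trough_predicate


def make_track(values, start=0, contig="chrT"):
    values = np.asarray(values, dtype=float)
    tile = GenomeTile(contig, start, start + len(values), pad=0,
                      contig_length=start + len(values))
    track = WpsTrack(tile=tile, raw=np.zeros(len(values), dtype=np.int64))
    track.normalized = values
    track.smoothed = values
    return track


def triangle_bump(n, apex, half_width, amplitude=1.0):
    """A triangular bump on a zero baseline; half-prominence width is known."""
    y = np.zeros(n)
    xs = np.arange(n)
    inside = np.abs(xs - apex) <= half_width
    y[inside] = amplitude * (1 - np.abs(xs[inside] - apex) / half_width)
    return y


class TestFindWpsPeaks:
    def test_flat_signal_no_peaks(self):
        track = make_track(np.zeros(2000))
        assert find_wps_peaks(track, PeakParams()) == []

    def test_single_bump_width_measured_at_half_prominence(self):
        # triangle: amplitude 1.0, value 0.5 reached half_width/2 from apex,
        # so the half-prominence width is exactly half_width
        y = triangle_bump(2000, apex=1000, half_width=140)
        track = make_track(y)
        params = PeakParams(min_height=0.28, min_distance=25, width_range=(100, 200))
        peaks = find_wps_peaks(track, params)
        assert len(peaks) == 1
        assert peaks[0].apex == 1000
        assert peaks[0].height == pytest.approx(1.0)
        assert peaks[0].width == pytest.approx(140, abs=1.5)

    def test_width_filter_rejects_out_of_range_bump(self):
        y = triangle_bump(2000, apex=1000, half_width=60)
        params = PeakParams(min_height=0.28, min_distance=25, width_range=(100, 200))
        assert find_wps_peaks(make_track(y), params) == []

    def test_min_distance_keeps_higher_of_close_pair(self):
        y = triangle_bump(2000, 990, 140, 0.9) + triangle_bump(2000, 1010, 140, 1.0)
        params = PeakParams(min_height=0.28, min_distance=25, width_range=(50, 400))
        peaks = find_wps_peaks(make_track(y), params)
        assert len(peaks) == 1

    def test_height_threshold(self):
        y = triangle_bump(2000, 1000, 140, amplitude=0.2)
        params = PeakParams(min_height=0.28, min_distance=25, width_range=(50, 400))
        assert find_wps_peaks(make_track(y), params) == []


class TestFindTroughs:
    def test_monotone_signal_no_proposals(self):
        track = make_track(np.linspace(0, 1, 1000))
        assert find_troughs(track, 0, 1000, w=5) == []

    def test_v_dip_proposed_within_w(self):
        y = np.abs(np.arange(1000) - 500) / 500.0
        track = make_track(y)
        proposals = find_troughs(track, 0, 1000, w=5)
        assert len(proposals) == 1
        assert abs(proposals[0] - 500) <= 5

    def test_sinusoid_minima_all_found(self):
        period = 180
        n = 2000
        x = np.arange(n)
        y = np.sin(2 * np.pi * x / period)
        track = make_track(y)
        proposals = find_troughs(track, 0, n, w=5)
        # analytic minima at x = 3*period/4 + k*period
        minima = [3 * period / 4 + k * period for k in range(11)
                  if 3 * period / 4 + k * period < n - 5]
        assert len(proposals) == len(minima)
        for p, m in zip(proposals, minima):
            assert abs(p - m) <= 5

    def test_too_short_span_rejected(self):
        track = make_track(np.zeros(100))
        with pytest.raises(ValueError):
            find_troughs(track, 0, 10, w=5)

    def test_shape_only_dependence(self):
        rng = np.random.default_rng(3)
        y = rng.normal(size=1500)
        assert (find_troughs(make_track(y), 0, 1500)
                == find_troughs(make_track(y + 42.0), 0, 1500))


class TestCredibilityPredicate:
    def _setup(self, height, width, peak_width):
        """Build a track realizing the given (height, width, peakWidth)."""
        n = 2000
        y = np.zeros(n)
        pending = 1000
        apex = pending - int(width)
        prev_trough_pos = pending - int(peak_width)
        y[apex] = 0.9
        y[pending] = 0.9 - height
        track = make_track(y)
        peak = Peak(apex=apex, height=0.9, width=150.0)
        prev = Trough(position=prev_trough_pos, depth=0.1, width_from_peak=10.0)
        return track, peak, prev, pending

    def test_large_drop_rejected(self):
        track, peak, prev, pending = self._setup(0.9, 60, 150)
        assert not is_credible_trough(track, peak, prev, pending)

    def test_printed_conjunction_accepts(self):
        track, peak, prev, pending = self._setup(0.3, 60, 150)
        assert is_credible_trough(track, peak, prev, pending)

    def test_no_previous_peak_rejected(self):
        track, _, prev, pending = self._setup(0.3, 60, 150)
        assert not is_credible_trough(track, None, prev, pending)

    def test_inverted_switch_flips_height_comparison(self):
        track, peak, prev, pending = self._setup(0.9, 60, 150)
        assert is_credible_trough(track, peak, prev, pending, inverted=True)

    def test_sweep_matches_predicate_oracle(self):
        rng = np.random.default_rng(99)
        for _ in range(1000):
            height = float(rng.uniform(-0.2, 1.2))
            width = int(rng.integers(5, 140))
            peak_width = int(rng.integers(width + 1, 300))
            track, peak, prev, pending = self._setup(height, width, peak_width)
            assert is_credible_trough(track, peak, prev, pending) == trough_predicate(
                height, width, peak_width
            )


class TestReconcile:
    def test_peaks_and_troughs_alternate(self):
        # shallow oscillation: the peak-to-trough drop (0.4) stays under the
        # credibility predicate's 0.58 bound, so troughs are accepted
        period = 180
        x = np.arange(4000)
        y = 0.5 + 0.2 * np.cos(2 * np.pi * x / period)
        track = make_track(y)
        params = PeakParams(min_height=0.6, min_distance=25, width_range=(50, 150))
        peaks = find_wps_peaks(track, params)
        assert len(peaks) > 10
        proposals = find_troughs(track, 0, 4000, w=5)
        troughs = reconcile_troughs(track, peaks, proposals)
        assert troughs, "regular sinusoid should yield credible troughs"
        landmarks = sorted(
            [(p.apex, "P") for p in peaks] + [(t.position, "T") for t in troughs]
        )
        kinds = [k for _, k in landmarks]
        for a, b in zip(kinds[:-1], kinds[1:]):
            assert (a, b) != ("T", "T"), "two troughs without a peak between"

    def test_min_distance_invariant(self):
        rng = np.random.default_rng(5)
        y = np.convolve(rng.normal(size=4000), np.ones(31) / 31, mode="same")
        track = make_track(y / np.max(np.abs(y)))
        params = PeakParams(min_height=0.05, min_distance=40, width_range=(5, 800))
        peaks = find_wps_peaks(track, params)
        apexes = np.array([p.apex for p in peaks])
        assert np.all(np.diff(apexes) >= 40)


class TestCalibration:
    def test_normal_heights_recover_mu_minus_three_sigma(self):
        rng = np.random.default_rng(2000)
        heights = rng.normal(0.7, 0.14, 2000)
        params, report = calibrate_from_samples(heights)
        assert params.min_height == pytest.approx(0.28, abs=0.02)
        assert report.normality_p > 1e-3  # drawn from a normal: not rejected hard

    def test_degenerate_constant_heights(self):
        with pytest.warns(UserWarning, match="degenerate"):
            params, _ = calibrate_from_samples(np.full(100, 0.5))
        assert params.min_height == pytest.approx(0.5)

    def test_stability_across_seeds(self):
        values = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            params, _ = calibrate_from_samples(rng.normal(0.7, 0.14, 2000))
            values.append(params.min_height)
        values = np.array(values)
        assert np.all(np.abs(values - values.mean()) / values.mean() < 0.05)

    def test_width_band_uses_central_quantiles(self):
        rng = np.random.default_rng(8)
        heights = rng.normal(0.7, 0.1, 500)
        widths = rng.lognormal(np.log(140), 0.1, 5000)  # skewed, like real widths
        params, _ = calibrate_from_samples(heights, widths=widths)
        from scipy.stats import norm

        q = np.quantile(widths, [norm.cdf(-3), norm.cdf(3)])
        assert params.width_range == pytest.approx(tuple(q))
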