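"""Waveform-geometry and coverage-trend features for classification.

Each candidate (or labelled training region) is summarized over a
2000 bp window centred on it.  Waveform features are the mean and
variance, over all complete peaks in the window, of per-peak geometry:
area above the trough-to-trough chord, apex angle, spacing, height and
width.  Coverage features are the mean normalized coverage of the
central 600 bp and of the full window, plus the slope and intercept of
ordinary least-squares line fits over the whole window and its left
([0, 1200)) and right ([800, 2000)) portions — open chromatin shows a
V-shaped coverage profile whose two half-window slopes have opposite
signs, while mapping artefacts drop more abruptly.  The apex-angle
bisector of the window's central peak geometry is included as a
two-component direction feature.

Angles mix base pairs with unit-scaled WPS values, so an axis aspect
ratio must be fixed: x is measured in units of 10 bp, y in normalized
WPS units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from typing import Optional, Sequence

import numpy as np

from .peak_trough import Peak, Trough, attach_flanking_troughs
from .wps_signal import CoverageTrack, WpsTrack

WINDOW_HALF = 1000  # bp either side of the region centre
NARROW_HALF = 300  # central interval for narrow coverage
X_SCALE = 0.1  # bp -> angle-space x units (10 bp per unit)

FEATURE_NAMES: tuple[str, ...] = (
    "peak_area_mean",
    "peak_area_var",
    "peak_angle_mean",
    "peak_angle_var",
    "peak_spacing_mean",
    "peak_spacing_var",
    "peak_height_mean",
    "peak_height_var",
    "peak_width_mean",
    "peak_width_var",
    "narrow_interval_coverage",
    "broad_interval_coverage",
    "slope_full",
    "intercept_full",
    "slope_left",
    "intercept_left",
    "slope_right",
    "intercept_right",
    "bisector_dx",
    "bisector_dy",
    "geometry_missing",
)


@dataclass
class FeatureVector:
    """The per-region feature set, in the stable column order of FEATURE_NAMES."""

    peak_area_mean: float = 0.0
    peak_area_var: float = 0.0
    peak_angle_mean: float = 0.0
    peak_angle_var: float = 0.0
    peak_spacing_mean: float = 0.0
    peak_spacing_var: float = 0.0
    peak_height_mean: float = 0.0
    peak_height_var: float = 0.0
    peak_width_mean: float = 0.0
    peak_width_var: float = 0.0
    narrow_interval_coverage: float = 0.0
    broad_interval_coverage: float = 0.0
    slope_full: float = 0.0
    intercept_full: float = 0.0
    slope_left: float = 0.0
    intercept_left: float = 0.0
    slope_right: float = 0.0
    intercept_right: float = 0.0
    bisector_dx: float = 0.0
    bisector_dy: float = 0.0
    geometry_missing: float = 0.0

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in FEATURE_NAMES], dtype=float)

    def to_dict(self) -> dict[str, float]:
        return {n: float(getattr(self, n)) for n in FEATURE_NAMES}


def window_2000(
    region_center: int, contig_length: int | None = None, half: int = WINDOW_HALF
) -> tuple[int, int, bool]:
    """The feature window [centre - half, centre + half); flags clamping."""
    lo = region_center - half
    hi = region_center + half
    clamped = False
    if lo < 0:
        lo, clamped = 0, True
    if contig_length is not None and hi > contig_length:
        hi, clamped = contig_length, True
    return lo, hi, clamped


def peak_geometry(
    peak: Peak,
    left_trough: int,
    right_trough: int,
    track: WpsTrack,
    x_scale: float = X_SCALE,
) -> tuple[float, float, float, float]:
    """(area, angle, height, width) of one peak between its flanking troughs.

    width  = right trough - left trough (bp)
    height = WPS(apex) - mean WPS at the two troughs
    area   = trapezoidal integral of (WPS - chord between the troughs)
    angle  = apex angle in degrees between apex->left-trough and
             apex->right-trough vectors, with x scaled by ``x_scale``.
    """
    y = track.smoothed
    off = track.tile.padded_start
    il, ip, ir = left_trough - off, peak.apex - off, right_trough - off
    if not (0 <= il < ip < ir < y.shape[0]):
        raise ValueError("troughs must flank the peak inside the track")
    yl, yp, yr = float(y[il]), float(y[ip]), float(y[ir])
    width = float(right_trough - left_trough)
    height = yp - (yl + yr) / 2.0
    xs = np.arange(il, ir + 1)
    chord = yl + (y[ir] - y[il]) * (xs - il) / (ir - il)
    area = float(np.trapezoid(y[il : ir + 1] - chord))
    v1 = ((il - ip) * x_scale, yl - yp)
    v2 = ((ir - ip) * x_scale, yr - yp)
    n1 = math.hypot(*v1)
    n2 = math.hypot(*v2)
    if n1 == 0 or n2 == 0:
        angle = 0.0
    else:
        cosang = (v1[0] * v2[0] + v1[1] * v2[1]) / (n1 * n2)
        angle = math.degrees(math.acos(max(-1.0, min(1.0, cosang))))
    return area, angle, height, width


def _apex_bisector(
    peak: Peak, left_trough: int, right_trough: int, track: WpsTrack,
    x_scale: float = X_SCALE,
) -> tuple[float, float]:
    """Unit vector bisecting the apex angle, in scaled (x, y) coordinates."""
    y = track.smoothed
    off = track.tile.padded_start
    il, ip, ir = left_trough - off, peak.apex - off, right_trough - off
    v1 = np.array([(il - ip) * x_scale, float(y[il]) - float(y[ip])])
    v2 = np.array([(ir - ip) * x_scale, float(y[ir]) - float(y[ip])])
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        return 0.0, 0.0
    b = v1 / n1 + v2 / n2
    nb = np.linalg.norm(b)
    if nb == 0:
        return 0.0, 0.0
    b = b / nb
    return float(b[0]), float(b[1])


def coverage_trends(
    cov_window: np.ndarray,
    sub_intervals: Sequence[tuple[int, int]] = ((0, 2000), (0, 1200), (800, 2000)),
) -> tuple[float, ...]:
    """OLS slope/intercept of normalized coverage vs window-relative position.

    Returns (slope, intercept) for each sub-interval, clipped to the
    available window length.  x is in bp from the window start.
    """
    out: list[float] = []
    n = cov_window.shape[0]
    for lo, hi in sub_intervals:
        lo_c, hi_c = max(0, lo), min(n, hi)
        xs = np.arange(lo_c, hi_c, dtype=float)
        ys = np.asarray(cov_window[lo_c:hi_c], dtype=float)
        if xs.size < 2:
            out.extend([0.0, 0.0])
            continue
        slope, intercept = np.polyfit(xs, ys, 1)
        out.extend([float(slope), float(intercept)])
    return tuple(out)


def assemble_features(
    center: int,
    peaks: Sequence[Peak],
    troughs: Sequence[Trough],
    wps: WpsTrack,
    coverage: CoverageTrack,
    x_scale: float = X_SCALE,
) -> FeatureVector:
    """Build the full feature vector for a 2000 bp window around ``center``.

    Geometry statistics run over all peaks lying completely inside the
    window together with both flanking troughs; with no complete peak the
    geometry features stay 0 and ``geometry_missing`` is set.  Coverage
    features use the tile-standardized normalized layer.
    """
    if wps.smoothed is None:
        raise ValueError("WPS track must be smoothed")
    if coverage.normalized is None:
        raise ValueError("coverage track must be normalized")
    lo, hi, _ = window_2000(center, wps.tile.contig_length)

    annotated = attach_flanking_troughs(peaks, troughs)
    complete = [
        p
        for p in annotated
        if p.left_trough is not None
        and p.right_trough is not None
        and lo <= p.left_trough
        and p.right_trough < hi
    ]
    fv = FeatureVector()
    if complete:
        geoms = np.array(
            [
                peak_geometry(p, p.left_trough, p.right_trough, wps, x_scale)
                for p in complete
            ]
        )
        areas, angles, heights, widths = geoms.T
        fv.peak_area_mean = float(np.mean(areas))
        fv.peak_area_var = float(np.var(areas))
        fv.peak_angle_mean = float(np.mean(angles))
        fv.peak_angle_var = float(np.var(angles))
        fv.peak_height_mean = float(np.mean(heights))
        fv.peak_height_var = float(np.var(heights))
        fv.peak_width_mean = float(np.mean(widths))
        fv.peak_width_var = float(np.var(widths))
        apexes = np.array([p.apex for p in complete], dtype=float)
        if apexes.size >= 2:
            spacings = np.diff(np.sort(apexes))
            fv.peak_spacing_mean = float(np.mean(spacings))
            fv.peak_spacing_var = float(np.var(spacings))
        # bisector of the window's central peak geometry
        central = complete[int(np.argmin(np.abs(apexes - center)))]
        fv.bisector_dx, fv.bisector_dy = _apex_bisector(
            central, central.left_trough, central.right_trough, wps, x_scale
        )
    else:
        fv.geometry_missing = 1.0

    off = coverage.coord_to_index(lo)
    cov_win = coverage.normalized[off : off + (hi - lo)]
    fv.broad_interval_coverage = float(np.mean(cov_win)) if cov_win.size else 0.0
    c_off = coverage.coord_to_index(max(lo, center - NARROW_HALF))
    c_hi = coverage.coord_to_index(min(hi, center + NARROW_HALF))
    narrow = coverage.normalized[c_off:c_hi]
    fv.narrow_interval_coverage = float(np.mean(narrow)) if narrow.size else 0.0
    (
        fv.slope_full,
        fv.intercept_full,
        fv.slope_left,
        fv.intercept_left,
        fv.slope_right,
        fv.intercept_right,
    ) = coverage_trends(cov_win)
    return fv


def features_to_frame(vectors: Sequence[FeatureVector]):
    """Stack feature vectors into a DataFrame with the stable column order."""
    import pandas as pd

    return pd.DataFrame(
        [fv.to_dict() for fv in vectors], columns=list(FEATURE_NAMES)
    )
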