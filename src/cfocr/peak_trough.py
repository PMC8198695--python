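"""Peak and trough location on the smoothed WPS waveform.

Peaks (nucleosome wells) are local maxima passing height, spacing and
half-prominence-width constraints.  Troughs are proposed by a
three-window scan: three adjacent windows of w bp slide along the
signal, and wherever the middle window's sum is strictly below both
neighbours the minimum position inside the middle window is proposed.
Each proposal is then vetted against the preceding peak and trough by a
credibility predicate on (height drop, distance from the peak, distance
from the previous trough).

Detection parameters can be calibrated from the data itself: peak
heights across a sample of random regions are approximately normal, and
the mu - 3*sigma bound of that distribution gives the minimum height;
width and spacing bounds come from the matching central quantile band of
their (skewed) empirical distributions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import signal as sps
from scipy import stats

from .wps_signal import WpsTrack

DEFAULT_TROUGH_W = 5
# Credibility predicate bounds for a pending trough, on the normalized scale.
DEFAULT_TROUGH_MAX_HEIGHT = 0.58
DEFAULT_TROUGH_WIDTH_BOUNDS = (25, 100)
DEFAULT_PEAK_WIDTH_BOUNDS = (50, 220)


@dataclass(frozen=True, slots=True)
class Peak:
    """A located WPS maximum (nucleosome well)."""

    apex: int  # genomic coordinate
    height: float  # smoothed normalized WPS at the apex
    width: float  # bp at half prominence
    prominence: float = 0.0
    left_trough: Optional[int] = None
    right_trough: Optional[int] = None


@dataclass(frozen=True, slots=True)
class Trough:
    """A vetted WPS minimum between two peaks (linker / accessible DNA)."""

    position: int  # genomic coordinate
    depth: float  # previous peak height minus trough WPS
    width_from_peak: float  # bp from the previous peak apex


@dataclass
class PeakParams:
    """Peak-detection parameters on the normalized WPS scale.

    The constructor defaults are the values calibrated on deep (~100x)
    human plasma cfDNA; for other data (or simulations) prefer
    :func:`calibrate_params`, which re-derives them with the same
    mu +/- 3*sigma rule.
    """

    min_height: float = 0.28
    min_distance: int = 25
    width_range: tuple[float, float] = (115.0, 164.0)
    trough_window_w: int = DEFAULT_TROUGH_W

    def __post_init__(self) -> None:
        if self.min_distance <= 0 or self.trough_window_w <= 0:
            raise ValueError("distance and trough window must be positive")
        if not self.width_range[0] < self.width_range[1]:
            raise ValueError("width_range must be ascending")


def find_wps_peaks(track: WpsTrack, params: PeakParams) -> list[Peak]:
    """Locate peaks of the smoothed WPS waveform.

    Local maxima must satisfy height >= min_height, pairwise apex
    separation >= min_distance (the higher peak wins a conflict), and
    width at half prominence within width_range.  Output is sorted by
    coordinate.
    """
    if track.smoothed is None:
        raise ValueError("track must be smoothed before peak calling")
    idx, props = sps.find_peaks(
        track.smoothed,
        height=params.min_height,
        distance=params.min_distance,
        width=params.width_range,
        rel_height=0.5,
    )
    off = track.tile.padded_start
    return [
        Peak(
            apex=int(i) + off,
            height=float(h),
            width=float(w),
            prominence=float(p),
        )
        for i, h, w, p in zip(
            idx, props["peak_heights"], props["widths"], props["prominences"]
        )
    ]


def find_troughs(
    track: WpsTrack, start: int, end: int, w: int = DEFAULT_TROUGH_W
) -> list[int]:
    """Three-window trough scan; returns proposed positions (genomic coords).

    Three adjacent w-bp windows slide from ``start``; when the middle
    window's sum is strictly below both neighbours, the leftmost minimum
    inside the middle window is proposed.  The scan always advances by w.
    Proposals closer than w bp to the previous proposal are dropped.
    ``start``/``end`` are genomic coordinates within the track.
    """
    if track.smoothed is None:
        raise ValueError("track must be smoothed before trough scanning")
    if end - start < 3 * w:
        raise ValueError("scan span must cover at least three windows")
    y = track.smoothed
    off = track.tile.padded_start
    lo = max(start - off, 0)
    hi = min(end - off, y.shape[0])
    proposals: list[int] = []
    cur = lo
    while cur + 3 * w <= hi:
        s1 = float(np.sum(y[cur : cur + w]))
        s2 = float(np.sum(y[cur + w : cur + 2 * w]))
        s3 = float(np.sum(y[cur + 2 * w : cur + 3 * w]))
        if s1 > s2 and s3 > s2:
            mid = y[cur + w : cur + 2 * w]
            pos = cur + w + int(np.argmin(mid)) + off
            if not proposals or pos - proposals[-1] >= w:
                proposals.append(pos)
        cur += w
    return proposals


def is_credible_trough(
    track: WpsTrack,
    prev_peak: Optional[Peak],
    prev_trough: Optional[Trough],
    pending: int,
    max_height: float = DEFAULT_TROUGH_MAX_HEIGHT,
    width_bounds: tuple[float, float] = DEFAULT_TROUGH_WIDTH_BOUNDS,
    peak_width_bounds: tuple[float, float] = DEFAULT_PEAK_WIDTH_BOUNDS,
    inverted: bool = False,
) -> bool:
    """Vet a pending trough against the preceding landmarks.

    height   = WPS(prev peak apex) - WPS(pending)
    width    = coord(pending) - coord(prev peak apex)
    peakWidth = coord(pending) - coord(prev trough) (falls back to the
                previous peak distance when no trough precedes)

    Accepts iff height < max_height (or > with ``inverted``) and
    width_bounds[0] < width < width_bounds[1] and
    peak_width_bounds[0] < peakWidth < peak_width_bounds[1], all strict.
    Without a preceding peak the pending trough is rejected (boundary).
    """
    if prev_peak is None:
        return False
    y = track.smoothed
    off = track.tile.padded_start
    height = float(y[prev_peak.apex - off]) - float(y[pending - off])
    width = pending - prev_peak.apex
    peak_width = (
        pending - prev_trough.position if prev_trough is not None else width
    )
    height_ok = height > max_height if inverted else height < max_height
    return (
        height_ok
        and width_bounds[0] < width < width_bounds[1]
        and peak_width_bounds[0] < peak_width < peak_width_bounds[1]
    )


def reconcile_troughs(
    track: WpsTrack,
    peaks: Sequence[Peak],
    proposals: Sequence[int],
    max_height: float = DEFAULT_TROUGH_MAX_HEIGHT,
    width_bounds: tuple[float, float] = DEFAULT_TROUGH_WIDTH_BOUNDS,
    peak_width_bounds: tuple[float, float] = DEFAULT_PEAK_WIDTH_BOUNDS,
    inverted: bool = False,
) -> list[Trough]:
    """Run the credibility predicate over proposals in coordinate order."""
    y = track.smoothed
    off = track.tile.padded_start
    apexes = np.array([p.apex for p in peaks], dtype=np.int64)
    troughs: list[Trough] = []
    prev_trough: Optional[Trough] = None
    for pos in sorted(proposals):
        k = int(np.searchsorted(apexes, pos)) - 1
        prev_peak = peaks[k] if k >= 0 else None
        if is_credible_trough(
            track,
            prev_peak,
            prev_trough,
            pos,
            max_height=max_height,
            width_bounds=width_bounds,
            peak_width_bounds=peak_width_bounds,
            inverted=inverted,
        ):
            depth = float(y[prev_peak.apex - off]) - float(y[pos - off])
            t = Trough(
                position=pos,
                depth=depth,
                width_from_peak=float(pos - prev_peak.apex),
            )
            troughs.append(t)
            prev_trough = t
    return troughs


@dataclass
class CalibrationReport:
    """Summary of data-driven parameter calibration."""

    n_height_samples: int
    height_mean: float
    height_std: float
    normality_stat: float
    normality_p: float
    params: PeakParams = field(default=None)  # type: ignore[assignment]
    warnings: list[str] = field(default_factory=list)


def calibrate_from_samples(
    heights: np.ndarray,
    widths: np.ndarray | None = None,
    spacings: np.ndarray | None = None,
    sigma_mult: float = 3.0,
    trough_window_w: int = DEFAULT_TROUGH_W,
    fallback: PeakParams | None = None,
) -> tuple[PeakParams, CalibrationReport]:
    """Derive PeakParams from sampled peak statistics.

    ``min_height`` is mean - sigma_mult*std of the (approximately normal)
    height distribution.  Width and spacing distributions are skewed, so
    their bounds use the central quantile band that a normal would place
    at mu +/- sigma_mult*sigma (e.g. [0.135%, 99.865%] for sigma_mult=3);
    ``min_distance`` is the lower band edge of the spacing distribution.
    Missing width/spacing samples fall back to ``fallback`` (or the
    constructor defaults).
    """
    fb = fallback if fallback is not None else PeakParams()
    heights = np.asarray(heights, dtype=float)
    warns: list[str] = []
    if heights.size == 0:
        raise ValueError("no height samples to calibrate from")
    mu = float(np.mean(heights))
    sd = float(np.std(heights))
    if heights.size >= 8:
        stat, pval = stats.normaltest(heights)
    else:
        stat, pval = float("nan"), float("nan")
        warns.append("too few samples for a normality test")
    if sd == 0.0:
        warns.append("degenerate height distribution (sigma = 0); min_height = mean")
        min_height = mu
    else:
        min_height = mu - sigma_mult * sd
    min_height = max(min_height, 1e-6)

    q_lo = float(stats.norm.cdf(-sigma_mult))
    q_hi = float(stats.norm.cdf(sigma_mult))
    if widths is not None and np.asarray(widths).size >= 10:
        widths = np.asarray(widths, dtype=float)
        w_lo, w_hi = np.quantile(widths, [q_lo, q_hi])
        if w_hi <= w_lo:
            w_lo, w_hi = fb.width_range
            warns.append("degenerate width distribution; using fallback width_range")
        width_range = (float(w_lo), float(w_hi))
    else:
        width_range = fb.width_range
        if widths is not None:
            warns.append("too few width samples; using fallback width_range")
    if spacings is not None and np.asarray(spacings).size >= 10:
        spacings = np.asarray(spacings, dtype=float)
        min_distance = max(1, int(round(float(np.quantile(spacings, q_lo)))))
    else:
        min_distance = fb.min_distance
        if spacings is not None:
            warns.append("too few spacing samples; using fallback min_distance")

    params = PeakParams(
        min_height=float(min_height),
        min_distance=min_distance,
        width_range=width_range,
        trough_window_w=trough_window_w,
    )
    report = CalibrationReport(
        n_height_samples=int(heights.size),
        height_mean=mu,
        height_std=sd,
        normality_stat=float(stat),
        normality_p=float(pval),
        params=params,
        warnings=warns,
    )
    for w in warns:
        warnings.warn(w)
    return params, report


# Permissive parameters used only to harvest height/width/spacing samples
# during calibration: a small prominence floor suppresses pure noise
# wiggles without biasing the height distribution of genuine peaks.
_COLLECT_PROMINENCE = 0.1
_COLLECT_DISTANCE = 60
_COLLECT_MIN_WIDTH = 20


def collect_peak_samples(
    track: WpsTrack,
    region: tuple[int, int] | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Harvest (heights, widths, spacings) from one track for calibration."""
    if track.smoothed is None:
        raise ValueError("track must be smoothed")
    y = track.smoothed
    off = track.tile.padded_start
    lo, hi = 0, y.shape[0]
    if region is not None:
        lo = max(0, region[0] - off)
        hi = min(y.shape[0], region[1] - off)
    idx, props = sps.find_peaks(
        y[lo:hi],
        prominence=_COLLECT_PROMINENCE,
        distance=_COLLECT_DISTANCE,
        width=_COLLECT_MIN_WIDTH,
        rel_height=0.5,
    )
    heights = y[lo:hi][idx]
    widths = props["widths"]
    spacings = np.diff(idx).astype(float)
    return np.asarray(heights, dtype=float), np.asarray(widths, dtype=float), spacings


def calibrate_params(
    tracks: Sequence[WpsTrack],
    n_regions: int = 2000,
    region_size: int = 1000,
    sigma_mult: float = 3.0,
    trough_window_w: int = DEFAULT_TROUGH_W,
    rng: np.random.Generator | None = None,
) -> tuple[PeakParams, CalibrationReport]:
    """Calibrate PeakParams by sampling random regions from signal tiles.

    Draws ``n_regions`` random ``region_size``-bp regions (with
    replacement across tiles), harvests peak statistics from each, and
    applies the mu +/- sigma_mult*sigma rule.  Proceeds with a warning if
    fewer regions are available.
    """
    rng = rng if rng is not None else np.random.default_rng()
    usable = [t for t in tracks if t.smoothed is not None and not t.low_signal]
    if not usable:
        raise ValueError("no signal-bearing tracks to calibrate from")
    heights: list[np.ndarray] = []
    widths: list[np.ndarray] = []
    spacings: list[np.ndarray] = []
    max_regions = sum(max(t.smoothed.shape[0] // region_size, 1) for t in usable)
    n_draw = n_regions
    if max_regions < n_regions:
        warnings.warn(
            f"only ~{max_regions} distinct regions available; calibrating anyway"
        )
    for _ in range(n_draw):
        t = usable[int(rng.integers(len(usable)))]
        span = t.smoothed.shape[0]
        if span <= region_size:
            lo = 0
        else:
            lo = int(rng.integers(span - region_size))
        h, w, s = collect_peak_samples(
            t, (t.tile.padded_start + lo, t.tile.padded_start + lo + region_size)
        )
        heights.append(h)
        widths.append(w)
        spacings.append(s)
    return calibrate_from_samples(
        np.concatenate(heights) if heights else np.empty(0),
        np.concatenate(widths) if widths else None,
        np.concatenate(spacings) if spacings else None,
        sigma_mult=sigma_mult,
        trough_window_w=trough_window_w,
    )


def attach_flanking_troughs(
    peaks: Sequence[Peak], troughs: Sequence[Trough]
) -> list[Peak]:
    """Return peaks annotated with their nearest flanking trough positions."""
    positions = np.array([t.position for t in troughs], dtype=np.int64)
    out: list[Peak] = []
    for p in peaks:
        k = int(np.searchsorted(positions, p.apex))
        left = int(positions[k - 1]) if k > 0 else None
        right = int(positions[k]) if k < positions.size else None
        out.append(
            Peak(
                apex=p.apex,
                height=p.height,
                width=p.width,
                prominence=p.prominence,
                left_trough=left,
                right_trough=right,
            )
        )
    return out


def write_landmarks_bed(
    peaks: Sequence[Peak], troughs: Sequence[Trough], contig: str, path: str
) -> None:
    """Export peaks and troughs as BED6 (score = attribute scaled to 0-1000)."""
    rows = []
    for p in peaks:
        score = int(np.clip(round(1000 * p.height), 0, 1000))
        rows.append((p.apex, p.apex + 1, f"peak", score))
    for t in troughs:
        score = int(np.clip(round(1000 * t.depth), 0, 1000))
        rows.append((t.position, t.position + 1, "trough", score))
    rows.sort()
    with open(path, "w") as fh:
        for start, end, name, score in rows:
            fh.write(f"{contig}\t{start}\t{end}\t{name}\t{score}\t.\n")
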