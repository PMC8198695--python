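"""Window protection score (WPS) and coverage tracks.

The WPS at a coordinate x is the number of cfDNA fragments completely
spanning a fixed window (default 120 bp) centred at x, minus the number
of fragments with at least one endpoint inside that window.  Over a
nucleosome array the score oscillates with the nucleosome repeat: wells
of protection (peaks) alternate with linker troughs.  Inside open
chromatin, spanning fragments are depleted and fragment ends accumulate,
so the waveform flattens or dips below zero while sequencing coverage
drops.

Tracks are computed per genome tile (padded span), then detrended with a
running median, scaled to [-1, 1], and smoothed with a Savitzky-Golay
filter before peak calling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .io_fragments import Fragment, GenomeTile, fragments_to_arrays

DEFAULT_WPS_WINDOW = 120
DEFAULT_BASELINE_WINDOW = 1001
DEFAULT_SG_ORDER = 2
DEFAULT_SG_WINDOW = 31
DEFAULT_COV_NEIGHBORHOOD = 2000


@dataclass
class WpsTrack:
    """Per-base WPS over a tile's padded span, in three layers.

    ``raw`` is the integer score; ``normalized`` is the detrended,
    max-abs-scaled layer in [-1, 1]; ``smoothed`` is the Savitzky-Golay
    filtered normalized layer.  Index i maps to genomic coordinate
    ``tile.padded_start + i``.
    """

    tile: GenomeTile
    raw: np.ndarray
    window: int = DEFAULT_WPS_WINDOW
    normalized: np.ndarray | None = None
    smoothed: np.ndarray | None = None
    low_signal: bool = False

    def coord_to_index(self, coord: int) -> int:
        return coord - self.tile.padded_start

    def index_to_coord(self, index: int) -> int:
        return index + self.tile.padded_start


@dataclass
class CoverageTrack:
    """Per-base fragment coverage over a tile's padded span."""

    tile: GenomeTile
    depth: np.ndarray
    normalized: np.ndarray | None = None
    norm_ok: bool = True

    def coord_to_index(self, coord: int) -> int:
        return coord - self.tile.padded_start


def _add_ranges(diff: np.ndarray, lo: np.ndarray, hi: np.ndarray, val: int) -> None:
    """Accumulate `val` over half-open index ranges [lo, hi) into a diff array."""
    n = diff.shape[0] - 1
    lo = np.clip(lo, 0, n)
    hi = np.clip(hi, 0, n)
    keep = hi > lo
    if not np.any(keep):
        return
    np.add.at(diff, lo[keep], val)
    np.add.at(diff, hi[keep], -val)


def compute_wps(
    fragments: Sequence[Fragment],
    tile: GenomeTile,
    window: int = DEFAULT_WPS_WINDOW,
) -> WpsTrack:
    """Compute the raw WPS for every base of the tile's padded span.

    With half-window h = window//2, the window at x is W = [x-h, x+h).
    Per fragment [s, e): +1 where the fragment contains W, else -1 where
    either endpoint (s or e-1) lies in W, else 0.  A fragment contributes
    -1 at most once regardless of how many of its endpoints fall in W.
    """
    if window < 2 or window % 2 != 0:
        raise ValueError("WPS window must be an even integer >= 2")
    L = tile.span
    off = tile.padded_start
    diff = np.zeros(L + 1, dtype=np.int64)
    starts, ends = fragments_to_arrays(fragments)
    if starts.size:
        h = window // 2
        s = starts - off
        e = ends - off
        length = e - s
        spanning = length >= window
        ss, se = s[spanning], e[spanning]
        # +1 where fragment contains W: x in [s+h, e-h]
        _add_ranges(diff, ss + h, se - h + 1, 1)
        # -1 on endpoint regions minus the spanning range:
        #   start endpoint s in W for x in [s-h+1, s+h]; minus x=s+h -> [s-h+1, s+h-1]
        #   end endpoint e-1 in W for x in [e-h, e+h-1]; minus x=e-h -> [e-h+1, e+h-1]
        _add_ranges(diff, ss - h + 1, ss + h, -1)
        _add_ranges(diff, se - h + 1, se + h, -1)
        # short fragments (< window): no spanning range; endpoint regions merge
        # into one interval [s-h+1, e+h-1] (they always overlap when len < window)
        ns, ne = s[~spanning], e[~spanning]
        _add_ranges(diff, ns - h + 1, ne + h, -1)
    raw = np.cumsum(diff[:-1])
    return WpsTrack(tile=tile, raw=raw, window=window)


def compute_coverage(
    fragments: Sequence[Fragment], tile: GenomeTile
) -> CoverageTrack:
    """Per-base fragment depth: depth[x] = #{fragments with start <= x < end}."""
    L = tile.span
    off = tile.padded_start
    diff = np.zeros(L + 1, dtype=np.int64)
    starts, ends = fragments_to_arrays(fragments)
    if starts.size:
        _add_ranges(diff, starts - off, ends - off, 1)
    return CoverageTrack(tile=tile, depth=np.cumsum(diff[:-1]))


def running_median(values: np.ndarray, window: int) -> np.ndarray:
    """Centred running median; edge windows are truncated, not padded."""
    if window % 2 != 1:
        raise ValueError("running-median window must be odd")
    s = pd.Series(np.asarray(values, dtype=float))
    return s.rolling(window, center=True, min_periods=1).median().to_numpy()


def detrend_normalize(
    track: WpsTrack, baseline_window: int = DEFAULT_BASELINE_WINDOW
) -> WpsTrack:
    """Remove the baseline drift and scale the waveform onto [-1, 1].

    The baseline is a centred running median over ``baseline_window`` bp;
    the detrended signal is divided by its maximum absolute value over
    the tile.  A flat tile (zero amplitude after detrending) yields an
    all-zero normalized layer and is flagged ``low_signal``.
    """
    if baseline_window % 2 != 1:
        raise ValueError("baseline_window must be odd")
    if baseline_window >= track.raw.shape[0]:
        raise ValueError("baseline_window must be smaller than the tile span")
    detrended = track.raw.astype(float) - running_median(track.raw, baseline_window)
    amp = float(np.max(np.abs(detrended))) if detrended.size else 0.0
    if amp == 0.0:
        track.normalized = np.zeros_like(detrended)
        track.low_signal = True
    else:
        track.normalized = detrended / amp
        track.low_signal = False
    return track


def sg_smooth(
    track: WpsTrack,
    order: int = DEFAULT_SG_ORDER,
    window: int = DEFAULT_SG_WINDOW,
) -> WpsTrack:
    """Savitzky-Golay smoothing of the normalized layer.

    Each output point is the centre value of the least-squares polynomial
    of degree ``order`` fitted to the surrounding ``window`` points; edges
    use polynomial extrapolation of the final interior fit rather than
    signal reflection, so no artificial peaks appear at tile boundaries.
    """
    if track.normalized is None:
        raise ValueError("detrend_normalize must run before sg_smooth")
    if window % 2 != 1:
        raise ValueError("SG window must be odd")
    if order >= window:
        raise ValueError("SG order must be smaller than the window")
    if window >= track.normalized.shape[0]:
        raise ValueError("SG window must be smaller than the signal length")
    track.smoothed = savgol_filter(track.normalized, window, order, mode="interp")
    return track


def standardize_coverage(cov: CoverageTrack) -> CoverageTrack:
    """Scale depth to units of the tile-core mean depth (mean ~ 1).

    This is the tile-level standardized depth used for feature
    extraction; the candidate weak filter uses the sharper local
    neighbourhood normalization of :func:`normalize_coverage`.
    """
    core_lo = cov.coord_to_index(cov.tile.start)
    core_hi = cov.coord_to_index(cov.tile.end)
    mean = float(np.mean(cov.depth[core_lo:core_hi])) if core_hi > core_lo else 0.0
    if mean <= 0:
        cov.normalized = np.zeros_like(cov.depth, dtype=float)
        cov.norm_ok = False
    else:
        cov.normalized = cov.depth / mean
        cov.norm_ok = True
    return cov


def normalize_coverage(
    cov: CoverageTrack,
    center: tuple[int, int],
    neighborhood: int = DEFAULT_COV_NEIGHBORHOOD,
) -> CoverageTrack:
    """Normalize depth against the mean over a local neighbourhood.

    The neighbourhood is ``neighborhood`` bp centred on the midpoint of
    ``center`` (a genomic interval), extended symmetrically; its mean
    depth becomes 1.0 in the normalized layer.  A zero local mean flags
    the region as uncallable.
    """
    mid = (center[0] + center[1]) // 2
    half = neighborhood // 2
    lo = max(0, cov.coord_to_index(mid - half))
    hi = min(cov.depth.shape[0], cov.coord_to_index(mid + half))
    if hi <= lo:
        raise ValueError("neighbourhood does not intersect the track")
    mean = float(np.mean(cov.depth[lo:hi]))
    if mean <= 0:
        cov.normalized = np.zeros_like(cov.depth, dtype=float)
        cov.norm_ok = False
    else:
        cov.normalized = cov.depth / mean
        cov.norm_ok = True
    return cov


def local_mean_coverage(
    cov: CoverageTrack,
    span: tuple[int, int],
    neighborhood: int = DEFAULT_COV_NEIGHBORHOOD,
) -> float | None:
    """Mean depth over ``span`` in units of its neighbourhood mean.

    Returns None when the neighbourhood has zero depth (uncallable).
    """
    lo = max(0, cov.coord_to_index(span[0]))
    hi = min(cov.depth.shape[0], cov.coord_to_index(span[1]))
    if hi <= lo:
        return None
    mid = (span[0] + span[1]) // 2
    half = neighborhood // 2
    nlo = max(0, cov.coord_to_index(mid - half))
    nhi = min(cov.depth.shape[0], cov.coord_to_index(mid + half))
    neigh_mean = float(np.mean(cov.depth[nlo:nhi])) if nhi > nlo else 0.0
    if neigh_mean <= 0:
        return None
    return float(np.mean(cov.depth[lo:hi])) / neigh_mean


def write_bedgraph(
    track_values: np.ndarray, tile: GenomeTile, path: str, core_only: bool = True
) -> None:
    """Export a per-base track as bedGraph (run-length collapsed)."""
    off = tile.padded_start
    lo = tile.start - off if core_only else 0
    hi = tile.end - off if core_only else track_values.shape[0]
    vals = np.asarray(track_values[lo:hi])
    with open(path, "w") as fh:
        if vals.size == 0:
            return
        change = np.nonzero(np.diff(vals))[0] + 1
        bounds = np.concatenate(([0], change, [vals.size]))
        for a, b in zip(bounds[:-1], bounds[1:]):
            fh.write(
                f"{tile.contig}\t{off + lo + a}\t{off + lo + b}\t{vals[a]:g}\n"
            )


def write_wiggle(
    track_values: np.ndarray, tile: GenomeTile, path: str, core_only: bool = True
) -> None:
    """Export a per-base track as fixedStep wiggle (1-based start)."""
    off = tile.padded_start
    lo = tile.start - off if core_only else 0
    hi = tile.end - off if core_only else track_values.shape[0]
    with open(path, "w") as fh:
        fh.write(f"fixedStep chrom={tile.contig} start={off + lo + 1} step=1\n")
        for v in track_values[lo:hi]:
            fh.write(f"{v:g}\n")
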