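"""Candidate OCR calling from peak landscapes and coverage.

A stretch of genome where the nucleosome-peak train is interrupted —
adjacent WPS peaks more than ~250 bp apart (a missing nucleosome would
already widen the spacing beyond ~200 bp) — becomes a candidate when its
locally normalized coverage drops below a threshold and the flanking
arrays remain regular.  Candidates are emitted as fixed 600 bp intervals
centred on the inter-peak midpoint: a ~300 bp accessible core plus about
one nucleosome (167 bp) of positional tolerance per side.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from intervaltree import IntervalTree

from .peak_trough import Peak, Trough
from .wps_signal import CoverageTrack, local_mean_coverage

DEFAULT_MIN_GAP = 250
DEFAULT_MAX_COV = 0.6
DEFAULT_CALL_SIZE = 600
DEFAULT_COV_CORE = 300  # initial accessible core over which coverage is judged
DEFAULT_FLANK = 1000
DEFAULT_MIN_PEAKS_PER_SIDE = 3
DEFAULT_SPACING_RANGE = (120, 220)
DEFAULT_MERGE_OVERLAP = 300


@dataclass
class CandidateOCR:
    """A putative open chromatin region with its fixed 600 bp call interval."""

    contig: str
    gap_start: int  # apex of the left bounding peak
    gap_end: int  # apex of the right bounding peak
    center: int
    call_start: int
    call_end: int
    mean_norm_coverage: float
    flank_regular: bool = True
    tile_id: str = ""
    features: Optional[dict] = None
    score: Optional[float] = None

    @property
    def call_interval(self) -> tuple[int, int]:
        return (self.call_start, self.call_end)


def flank_regularity(
    peaks: Sequence[Peak],
    span: tuple[int, int],
    flank: int = DEFAULT_FLANK,
    min_peaks_per_side: int = DEFAULT_MIN_PEAKS_PER_SIDE,
    spacing_range: tuple[int, int] = DEFAULT_SPACING_RANGE,
) -> bool:
    """True iff both sides of ``span`` carry a regular nucleosome array.

    Walking outward from each span edge, consecutive peaks are chained
    while their spacing stays within ``spacing_range``; the side passes
    when the chain reaches ``min_peaks_per_side`` peaks, all within
    ``flank`` bp of the edge.
    """
    apexes = np.sort(np.array([p.apex for p in peaks], dtype=np.int64))
    lo, hi = span

    def _chain(side_apexes: np.ndarray) -> bool:
        if side_apexes.size < min_peaks_per_side:
            return False
        count = 1
        for a, b in zip(side_apexes[:-1], side_apexes[1:]):
            gap = abs(int(b) - int(a))
            if spacing_range[0] <= gap <= spacing_range[1]:
                count += 1
                if count >= min_peaks_per_side:
                    return True
            else:
                break
        return count >= min_peaks_per_side

    left = apexes[(apexes <= lo) & (apexes >= lo - flank)][::-1]  # nearest first
    right = apexes[(apexes >= hi) & (apexes <= hi + flank)]
    return _chain(left) and _chain(right)


def call_candidates(
    peaks: Sequence[Peak],
    troughs: Sequence[Trough],
    coverage: CoverageTrack,
    min_gap: int = DEFAULT_MIN_GAP,
    max_cov: float = DEFAULT_MAX_COV,
    call_size: int = DEFAULT_CALL_SIZE,
    flank: int = DEFAULT_FLANK,
    min_peaks_per_side: int = DEFAULT_MIN_PEAKS_PER_SIDE,
    spacing_range: tuple[int, int] = DEFAULT_SPACING_RANGE,
    cov_neighborhood: int = 2000,
    cov_core: int = DEFAULT_COV_CORE,
    tile_id: str = "",
    core_only: bool = True,
) -> list[CandidateOCR]:
    """Emit candidate OCRs from adjacent peak pairs.

    For every adjacent pair of peaks with apex separation > ``min_gap``,
    the inter-peak span is a candidate iff its mean coverage is below
    ``max_cov`` and both flanks carry regular peak arrays.  Coverage is
    measured over the central ``cov_core`` bp of the gap (the initial
    accessible core; the bounding apexes themselves sit on protected
    nucleosomes, so the full span would dilute the dip), in units of the
    mean over a ``cov_neighborhood`` bp region centred on the span
    midpoint.  The emitted interval is ``call_size`` bp centred on the
    span midpoint.  With ``core_only`` only candidates whose centre
    falls in the tile core are kept (cross-tile deduplication).
    """
    tile = coverage.tile
    out: list[CandidateOCR] = []
    sorted_peaks = sorted(peaks, key=lambda p: p.apex)
    half = call_size // 2
    for left, right in zip(sorted_peaks[:-1], sorted_peaks[1:]):
        gap = right.apex - left.apex
        if gap <= min_gap:
            continue
        mid = (left.apex + right.apex) // 2
        if core_only and not (tile.start <= mid < tile.end):
            continue
        half_core = min(cov_core, gap) // 2
        norm_cov = local_mean_coverage(
            coverage, (mid - half_core, mid + half_core), cov_neighborhood
        )
        if norm_cov is None:  # zero-coverage neighbourhood: uncallable
            continue
        regular = flank_regularity(
            sorted_peaks,
            (left.apex, right.apex),
            flank=flank,
            min_peaks_per_side=min_peaks_per_side,
            spacing_range=spacing_range,
        )
        if norm_cov < max_cov and regular:
            call_start = mid - half
            call_end = mid + call_size - half
            if call_start < 0:
                continue
            if tile.contig_length is not None and call_end > tile.contig_length:
                continue
            out.append(
                CandidateOCR(
                    contig=tile.contig,
                    gap_start=left.apex,
                    gap_end=right.apex,
                    center=mid,
                    call_start=call_start,
                    call_end=call_end,
                    mean_norm_coverage=float(norm_cov),
                    flank_regular=regular,
                    tile_id=tile_id,
                )
            )
    return out


def subtract_repeats(
    candidates: Sequence[CandidateOCR],
    repeat_regions: Sequence[tuple[str, int, int]],
    min_overlap_frac: float = 0.0,
) -> list[CandidateOCR]:
    """Drop candidates whose call interval overlaps an annotated repeat.

    With the default ``min_overlap_frac`` of 0, any overlap (>= 1 bp)
    removes the candidate; a positive fraction requires at least that
    share of the call interval to be repeat-covered.  Whole calls are
    dropped rather than truncated, preserving the fixed call size.
    Repeat regions may be given in any order.
    """
    trees: dict[str, IntervalTree] = {}
    for contig, start, end in repeat_regions:
        if end > start:
            trees.setdefault(contig, IntervalTree()).addi(start, end)
    out: list[CandidateOCR] = []
    for cand in candidates:
        tree = trees.get(cand.contig)
        if tree is None:
            out.append(cand)
            continue
        hits = tree.overlap(cand.call_start, cand.call_end)
        if not hits:
            out.append(cand)
            continue
        overlap = sum(
            min(iv.end, cand.call_end) - max(iv.begin, cand.call_start)
            for iv in hits
        )
        frac = overlap / (cand.call_end - cand.call_start)
        if min_overlap_frac > 0.0 and frac < min_overlap_frac:
            out.append(cand)
    return out


def merge_tile_calls(
    candidates: Sequence[CandidateOCR],
    min_overlap: int = DEFAULT_MERGE_OVERLAP,
    call_size: int = DEFAULT_CALL_SIZE,
) -> list[CandidateOCR]:
    """Deduplicate near-identical calls produced by neighbouring tiles.

    Calls on the same contig whose intervals overlap by at least
    ``min_overlap`` bp are merged: the merged call is re-centred on the
    midpoint of the union and re-extended to ``call_size`` bp.  The
    highest classifier score and the lowest coverage in a cluster are
    retained.  Output is sorted by (contig, start).
    """
    by_key = sorted(candidates, key=lambda c: (c.contig, c.call_start, c.call_end))
    out: list[CandidateOCR] = []
    cluster: list[CandidateOCR] = []
    cluster_union: tuple[int, int] | None = None

    def _flush() -> None:
        if not cluster:
            return
        if len(cluster) == 1:
            out.append(cluster[0])
            return
        lo, hi = cluster_union
        mid = (lo + hi) // 2
        half = call_size // 2
        scores = [c.score for c in cluster if c.score is not None]
        merged = replace(
            cluster[0],
            gap_start=min(c.gap_start for c in cluster),
            gap_end=max(c.gap_end for c in cluster),
            center=mid,
            call_start=mid - half,
            call_end=mid + call_size - half,
            mean_norm_coverage=min(c.mean_norm_coverage for c in cluster),
            score=max(scores) if scores else None,
        )
        out.append(merged)

    for cand in by_key:
        if (
            cluster
            and cand.contig == cluster[-1].contig
            and min(cluster_union[1], cand.call_end)
            - max(cluster_union[0], cand.call_start)
            >= min_overlap
        ):
            cluster.append(cand)
            cluster_union = (
                min(cluster_union[0], cand.call_start),
                max(cluster_union[1], cand.call_end),
            )
        else:
            _flush()
            cluster = [cand]
            cluster_union = (cand.call_start, cand.call_end)
    _flush()
    out.sort(key=lambda c: (c.contig, c.call_start))
    return out


def write_calls_bed(
    candidates: Sequence[CandidateOCR], path: str, name_prefix: str = "ocr"
) -> None:
    """Write calls as BED6; score = 1000 * classifier probability (or 0)."""
    with open(path, "w") as fh:
        for i, c in enumerate(
            sorted(candidates, key=lambda c: (c.contig, c.call_start))
        ):
            score = int(round(1000 * c.score)) if c.score is not None else 0
            fh.write(
                f"{c.contig}\t{c.call_start}\t{c.call_end}\t"
                f"{name_prefix}_{i + 1}\t{score}\t.\n"
            )
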