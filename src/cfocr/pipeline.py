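"""End-to-end detection pipeline.

Per 20 kb genome tile: fragments -> raw WPS + coverage -> baseline
detrending and [-1, 1] normalization -> Savitzky-Golay smoothing ->
peak/trough location -> candidate calling (peak-gap + coverage + flank
regularity) -> feature extraction.  Genome-wide: candidate merging
across tile boundaries, random-forest false-positive filtering, repeat
subtraction, and final BED/manifest output.  Peak parameters are either
given explicitly or calibrated from the data with the mu +/- 3*sigma
rule; all randomness flows from the single config seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import candidate_caller as cc
from . import feature_extract as fx
from . import peak_trough as pt
from . import rf_filter as rf
from . import wps_signal as ws
from .io_fragments import (
    DEFAULT_LENGTH_BOUNDS,
    Fragment,
    GenomeTile,
    read_fragments,
    tile_genome,
)

logger = logging.getLogger("cfocr")


@dataclass
class PipelineConfig:
    """Everything a detection run depends on, serializable to YAML."""

    tile: int = 20_000
    pad: int = 2_000
    wps_window: int = 120
    baseline_window: int = 1001
    sg_order: int = 2
    sg_window: int = 31
    length_bounds: tuple[int, int] = DEFAULT_LENGTH_BOUNDS
    min_mapq: int = 30
    # peak detection: None means "calibrate from the data"
    peak_params: Optional[pt.PeakParams] = None
    calibrate_n_regions: int = 2000
    calibrate_region_size: int = 1000
    trough_window_w: int = 5
    trough_predicate_inverted: bool = False
    # candidate weak filters
    min_gap: int = 250
    max_cov: float = 0.6
    call_size: int = 600
    flank: int = 1000
    min_peaks_per_side: int = 3
    spacing_range: tuple[int, int] = (120, 220)
    cov_neighborhood: int = 2000
    merge_min_overlap: int = 300
    # classifier
    keep_threshold: float = 0.5
    seed: int = 0

    def to_yaml(self, path: str) -> None:
        d = dataclasses.asdict(self)
        if self.peak_params is not None:
            d["peak_params"] = dataclasses.asdict(self.peak_params)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if d.get("peak_params") is not None:
            pp = d["peak_params"]
            pp["width_range"] = tuple(pp["width_range"])
            d["peak_params"] = pt.PeakParams(**pp)
        for key in ("length_bounds", "spacing_range"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


class FragmentIndex:
    """Sorted in-memory fragment store with fast per-tile slicing."""

    def __init__(self, fragments: Sequence[Fragment]):
        by_contig: dict[str, list[Fragment]] = {}
        for f in fragments:
            by_contig.setdefault(f.contig, []).append(f)
        self._store: dict[str, tuple[np.ndarray, list[Fragment]]] = {}
        self._max_len = max((f.length for f in fragments), default=0)
        for contig, frs in by_contig.items():
            frs.sort(key=lambda f: (f.start, f.end))
            starts = np.array([f.start for f in frs], dtype=np.int64)
            self._store[contig] = (starts, frs)

    def fetch(self, tile: GenomeTile) -> list[Fragment]:
        entry = self._store.get(tile.contig)
        if entry is None:
            return []
        starts, frs = entry
        lo = int(np.searchsorted(starts, tile.padded_start - self._max_len))
        hi = int(np.searchsorted(starts, tile.padded_end))
        return [
            f
            for f in frs[lo:hi]
            if f.end > tile.padded_start and f.start < tile.padded_end
        ]


@dataclass
class TileResult:
    """All per-tile intermediates needed downstream."""

    tile: GenomeTile
    wps: ws.WpsTrack
    coverage: ws.CoverageTrack
    peaks: list[pt.Peak] = field(default_factory=list)
    troughs: list[pt.Trough] = field(default_factory=list)
    candidates: list[cc.CandidateOCR] = field(default_factory=list)


def compute_tile_tracks(
    fragments: Sequence[Fragment], tile: GenomeTile, config: PipelineConfig
) -> TileResult:
    """Raw signals -> normalized -> smoothed for one tile."""
    wps = ws.compute_wps(fragments, tile, config.wps_window)
    cov = ws.compute_coverage(fragments, tile)
    ws.detrend_normalize(wps, config.baseline_window)
    ws.sg_smooth(wps, config.sg_order, config.sg_window)
    ws.standardize_coverage(cov)
    return TileResult(tile=tile, wps=wps, coverage=cov)


def call_tile(
    result: TileResult, params: pt.PeakParams, config: PipelineConfig
) -> TileResult:
    """Peaks, troughs and candidates for one tile (tracks precomputed)."""
    track = result.wps
    if track.low_signal:
        return result
    result.peaks = pt.find_wps_peaks(track, params)
    span = (track.tile.padded_start, track.tile.padded_end)
    if span[1] - span[0] >= 3 * params.trough_window_w:
        proposals = pt.find_troughs(track, span[0], span[1], params.trough_window_w)
        result.troughs = pt.reconcile_troughs(
            track,
            result.peaks,
            proposals,
            inverted=config.trough_predicate_inverted,
        )
    result.candidates = cc.call_candidates(
        result.peaks,
        result.troughs,
        result.coverage,
        min_gap=config.min_gap,
        max_cov=config.max_cov,
        call_size=config.call_size,
        flank=config.flank,
        min_peaks_per_side=config.min_peaks_per_side,
        spacing_range=config.spacing_range,
        cov_neighborhood=config.cov_neighborhood,
        tile_id=f"{result.tile.contig}:{result.tile.start}",
    )
    for cand in result.candidates:
        fv = fx.assemble_features(
            cand.center, result.peaks, result.troughs, track, result.coverage
        )
        cand.features = fv.to_dict()
    return result


@dataclass
class DetectionResult:
    """Final calls plus the bookkeeping manifest."""

    calls: list[cc.CandidateOCR]
    manifest: dict
    peak_params: pt.PeakParams
    tile_results: list[TileResult] = field(default_factory=list)


def detect(
    fragments: Sequence[Fragment] | str,
    contig_lengths: dict[str, int],
    config: PipelineConfig | None = None,
    model: Optional[rf.RFModel] = None,
    repeats: Sequence[tuple[str, int, int]] = (),
    keep_tile_results: bool = False,
) -> DetectionResult:
    """Run the full detection pipeline.

    ``fragments`` may be an in-memory list or a BAM/BED path.  When
    ``config.peak_params`` is None the peak parameters are calibrated
    from the data first.  ``model`` enables the random-forest
    false-positive filter; without it all weak-filter candidates pass
    through (classifier-free mode).
    """
    config = config if config is not None else PipelineConfig()
    tiles = tile_genome(contig_lengths, config.tile, config.pad)
    from_path = isinstance(fragments, (str, os.PathLike))
    index = None if from_path else FragmentIndex(fragments)

    results: list[TileResult] = []
    n_failed = 0
    for tile in tiles:
        try:
            frs = (
                read_fragments(
                    fragments, tile, config.length_bounds, config.min_mapq
                )
                if from_path
                else index.fetch(tile)
            )
            results.append(compute_tile_tracks(frs, tile, config))
        except Exception:
            logger.exception("tile %s:%d failed", tile.contig, tile.start)
            n_failed += 1
    if n_failed > 0.01 * len(tiles):
        raise RuntimeError(f"{n_failed}/{len(tiles)} tiles failed")

    if config.peak_params is not None:
        params = config.peak_params
        calibration = None
    else:
        rng = np.random.default_rng(config.seed)
        params, calibration = pt.calibrate_params(
            [r.wps for r in results],
            n_regions=config.calibrate_n_regions,
            region_size=config.calibrate_region_size,
            trough_window_w=config.trough_window_w,
            rng=rng,
        )

    for result in results:
        call_tile(result, params, config)

    initial = [c for r in results for c in r.candidates]
    initial = cc.merge_tile_calls(initial, config.merge_min_overlap, config.call_size)

    if model is not None and initial:
        X = pd.DataFrame(
            [c.features for c in initial], columns=list(fx.FEATURE_NAMES)
        )
        keep, probs = rf.apply_filter(model, X, config.keep_threshold)
        for c, p in zip(initial, probs):
            c.score = float(p)
        post_classifier = [c for c, k in zip(initial, keep) if k]
    else:
        post_classifier = list(initial)

    post_repeat = cc.subtract_repeats(post_classifier, repeats)
    final = sorted(post_repeat, key=lambda c: (c.contig, c.call_start))

    manifest = {
        "n_tiles": len(tiles),
        "n_tiles_failed": n_failed,
        "seed": config.seed,
        "peak_params": dataclasses.asdict(params),
        "calibrated": config.peak_params is None,
        "counts": {
            "initial_candidates": len(initial),
            "post_classifier": len(post_classifier),
            "post_repeat": len(post_repeat),
            "final": len(final),
        },
    }
    if calibration is not None:
        manifest["calibration"] = {
            "n_height_samples": calibration.n_height_samples,
            "height_mean": calibration.height_mean,
            "height_std": calibration.height_std,
            "normality_stat": calibration.normality_stat,
            "normality_p": calibration.normality_p,
        }
    return DetectionResult(
        calls=final,
        manifest=manifest,
        peak_params=params,
        tile_results=results if keep_tile_results else [],
    )


def write_outputs(
    result: DetectionResult, out_dir: str, config: PipelineConfig
) -> dict[str, str]:
    """Write the sorted BED6, the JSON manifest and the config snapshot."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "bed": os.path.join(out_dir, "ocr_calls.bed"),
        "manifest": os.path.join(out_dir, "manifest.json"),
        "config": os.path.join(out_dir, "config.yaml"),
    }
    cc.write_calls_bed(result.calls, paths["bed"])
    with open(paths["manifest"], "w") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True)
    config.to_yaml(paths["config"])
    return paths


def features_for_windows(
    fragments: Sequence[Fragment],
    centers: Sequence[tuple[str, int]],
    contig_lengths: dict[str, int],
    config: PipelineConfig | None = None,
    params: pt.PeakParams | None = None,
) -> pd.DataFrame:
    """Feature vectors for arbitrary labelled windows (training harness).

    Windows are grouped by tile; each tile's tracks and landmarks are
    computed once with the same settings the detection pipeline uses.
    When ``params`` is None, peak parameters are calibrated from the
    involved tiles.
    """
    config = config if config is not None else PipelineConfig()
    index = FragmentIndex(fragments)
    all_tiles = {
        (t.contig, t.start): t
        for t in tile_genome(contig_lengths, config.tile, config.pad)
    }
    needed: dict[tuple[str, int], list[int]] = {}
    for i, (contig, center) in enumerate(centers):
        key = (contig, (center // config.tile) * config.tile)
        needed.setdefault(key, []).append(i)

    tracks: dict[tuple[str, int], TileResult] = {}
    for key in needed:
        tile = all_tiles[key]
        tracks[key] = compute_tile_tracks(index.fetch(tile), tile, config)

    if params is None:
        rng = np.random.default_rng(config.seed)
        params, _ = pt.calibrate_params(
            [r.wps for r in tracks.values()],
            n_regions=config.calibrate_n_regions,
            region_size=config.calibrate_region_size,
            trough_window_w=config.trough_window_w,
            rng=rng,
        )

    rows: list[dict] = [None] * len(centers)  # type: ignore[list-item]
    for key, idxs in needed.items():
        result = call_tile(tracks[key], params, config)
        for i in idxs:
            _, center = centers[i]
            fv = fx.assemble_features(
                center, result.peaks, result.troughs, result.wps, result.coverage
            )
            rows[i] = fv.to_dict()
    return pd.DataFrame(rows, columns=list(fx.FEATURE_NAMES))
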