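"""Synthetic cfDNA fragment simulator with planted open chromatin regions.

The generator emulates the signal model behind cfDNA nucleosome
footprinting: the genome is covered by regularly spaced, well-positioned
nucleosome arrays (167 bp cores, short jittered linkers), and cfDNA
fragments are mononucleosome-protected molecules centred near dyads.
Inside a planted OCR there are no positioned nucleosomes: spanning
fragments are depleted to a configurable fraction of normal density and
the few fragments emitted there have uniform random endpoints, so they
contribute endpoint (negative WPS) signal rather than protection signal.
A global endpoint-noise process adds uniformly placed fragments
everywhere, mimicking random fragmentation and mapping noise.

"Distortion" intervals model the false-positive-like artefacts used as
negative training examples for the classifier: a local coverage dip with
the surrounding nucleosome periodicity destroyed, as produced by mapping
ambiguity over repeats, rather than true accessibility.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .io_fragments import Fragment


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated cfDNA data set."""

    genome_length: int = 2_000_000
    contig: str = "sim1"
    nucleosome_core: int = 167
    linker_mean: int = 20
    linker_jitter: int = 5  # uniform +/- jitter on each linker
    ocr_intervals: tuple[tuple[int, int], ...] = ()
    distortion_intervals: tuple[tuple[int, int], ...] = ()
    depth: float = 30.0
    frag_len_mean: float = 167.0
    frag_len_sd: float = 10.0
    frag_len_bounds: tuple[int, int] = (120, 180)
    frag_center_jitter: float = 5.0
    ocr_protection_factor: float = 0.2
    endpoint_noise_rate: float = 0.05  # uniform fragments, fraction of depth
    distortion_density: float = 0.5  # coverage inside a distortion core
    distortion_flank: int = 800  # bp of disordered array on each side
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 0:
            raise ValueError("depth must be non-negative")
        ivs = sorted(self.ocr_intervals)
        for (a, b) in ivs:
            if not (0 <= a < b <= self.genome_length):
                raise ValueError(f"OCR interval ({a}, {b}) outside genome")
        for (a1, b1), (a2, b2) in zip(ivs, ivs[1:]):
            if a2 < b1:
                raise ValueError("OCR intervals must be disjoint")

    @property
    def repeat_length(self) -> int:
        return self.nucleosome_core + self.linker_mean


@dataclass
class SimTruth:
    """Planted ground truth plus realized summary statistics."""

    config: SimConfig
    ocr_intervals: tuple[tuple[int, int], ...]
    distortion_intervals: tuple[tuple[int, int], ...]
    dyads: np.ndarray
    n_fragments: int = 0
    realized_depth: float = 0.0


def _in_any(pos: int, intervals: Sequence[tuple[int, int]]) -> bool:
    return any(a <= pos < b for a, b in intervals)


def place_nucleosomes(
    config: SimConfig, rng: np.random.Generator
) -> np.ndarray:
    """Place nucleosome dyads in regular arrays outside planted OCRs.

    Cores are spaced core + linker bp apart with the linker jittered
    uniformly by +/- linker_jitter; an array is interrupted at each OCR
    and resumes just past its end, so no dyad core overlaps an OCR.
    """
    core = config.nucleosome_core
    half = core // 2
    ocrs = sorted(config.ocr_intervals)
    dyads: list[int] = []
    pos = half  # dyad of the first core
    while pos + half <= config.genome_length:
        blocking = next(
            (iv for iv in ocrs if pos + half > iv[0] and pos - half < iv[1]), None
        )
        if blocking is not None:
            pos = blocking[1] + half  # resume the array after the OCR
            continue
        dyads.append(pos)
        linker = config.linker_mean + int(
            rng.integers(-config.linker_jitter, config.linker_jitter + 1)
        )
        pos += core + linker
    return np.asarray(dyads, dtype=np.int64)


def _draw_lengths(n: int, config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    lens = np.rint(rng.normal(config.frag_len_mean, config.frag_len_sd, n))
    return np.clip(lens, *config.frag_len_bounds).astype(np.int64)


def _fragments_from_centers(
    centers: np.ndarray, lengths: np.ndarray, config: SimConfig
) -> tuple[np.ndarray, np.ndarray]:
    starts = np.rint(centers).astype(np.int64) - lengths // 2
    ends = starts + lengths
    keep = (starts >= 0) & (ends <= config.genome_length)
    return starts[keep], ends[keep]


def sample_fragments(
    config: SimConfig,
    dyads: np.ndarray,
    rng: np.random.Generator | None = None,
) -> list[Fragment]:
    """Draw cfDNA fragments given dyad positions.

    Protected fragments: per-dyad count ~ Poisson(depth * repeat /
    frag_len_mean) so realized coverage matches ``depth``; each fragment
    is centred on its dyad with Gaussian jitter and has a clipped
    Gaussian length.  Dyads inside a distortion flank lose their
    positioning (uniform centre within +/- one repeat) and dyads inside a
    distortion core are additionally thinned to ``distortion_density``.
    OCR fragments: Poisson(ocr_protection_factor * depth * width /
    frag_len_mean) per OCR, uniform centres.  Endpoint noise: uniform
    fragments genome-wide at ``endpoint_noise_rate`` of nominal density.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    if config.depth == 0:
        return []
    all_starts: list[np.ndarray] = []
    all_ends: list[np.ndarray] = []

    if dyads.size:
        lam = config.depth * config.repeat_length / config.frag_len_mean
        lam_per_dyad = np.full(dyads.size, lam)
        disordered = np.zeros(dyads.size, dtype=bool)
        for a, b in config.distortion_intervals:
            core_mask = (dyads >= a) & (dyads < b)
            flank_mask = (dyads >= a - config.distortion_flank) & (
                dyads < b + config.distortion_flank
            )
            lam_per_dyad[core_mask] *= config.distortion_density
            disordered |= flank_mask
        counts = rng.poisson(lam_per_dyad)
        centers = np.repeat(dyads.astype(float), counts)
        disordered_rep = np.repeat(disordered, counts)
        n = centers.size
        jitter = rng.normal(0.0, config.frag_center_jitter, n)
        centers = centers + jitter
        if np.any(disordered_rep):
            m = int(np.sum(disordered_rep))
            centers[disordered_rep] = centers[disordered_rep] + rng.uniform(
                -config.repeat_length, config.repeat_length, m
            )
        lengths = _draw_lengths(n, config, rng)
        s, e = _fragments_from_centers(centers, lengths, config)
        all_starts.append(s)
        all_ends.append(e)

    for a, b in config.ocr_intervals:
        lam = config.ocr_protection_factor * config.depth * (b - a) / config.frag_len_mean
        n = int(rng.poisson(lam))
        if n == 0:
            continue
        centers = rng.uniform(a, b, n)
        lengths = _draw_lengths(n, config, rng)
        s, e = _fragments_from_centers(centers, lengths, config)
        all_starts.append(s)
        all_ends.append(e)

    n_noise = int(
        rng.poisson(
            config.endpoint_noise_rate
            * config.depth
            * config.genome_length
            / config.frag_len_mean
        )
    )
    if n_noise:
        centers = rng.uniform(0, config.genome_length, n_noise)
        lengths = _draw_lengths(n_noise, config, rng)
        s, e = _fragments_from_centers(centers, lengths, config)
        all_starts.append(s)
        all_ends.append(e)

    if not all_starts:
        return []
    starts = np.concatenate(all_starts)
    ends = np.concatenate(all_ends)
    order = np.lexsort((ends, starts))
    starts, ends = starts[order], ends[order]
    contig = config.contig
    return [Fragment(contig, int(s), int(e)) for s, e in zip(starts, ends)]


def simulate(config: SimConfig) -> tuple[list[Fragment], SimTruth]:
    """Run the full generator: nucleosome placement then fragment sampling."""
    rng = np.random.default_rng(config.seed)
    dyads = place_nucleosomes(config, rng)
    fragments = sample_fragments(config, dyads, rng)
    total_bp = sum(f.length for f in fragments)
    truth = SimTruth(
        config=config,
        ocr_intervals=tuple(sorted(config.ocr_intervals)),
        distortion_intervals=tuple(sorted(config.distortion_intervals)),
        dyads=dyads,
        n_fragments=len(fragments),
        realized_depth=total_bp / config.genome_length,
    )
    return fragments, truth


def downsample(
    fragments: Sequence[Fragment], fraction: float, seed: int
) -> list[Fragment]:
    """Bernoulli thinning: keep each fragment independently with `fraction`."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    if fraction == 1.0:
        return list(fragments)
    if fraction == 0.0:
        return []
    rng = np.random.default_rng(seed)
    keep = rng.random(len(fragments)) < fraction
    return [f for f, k in zip(fragments, keep) if k]


def plant_intervals(
    genome_length: int,
    n: int,
    width_range: tuple[int, int],
    rng: np.random.Generator,
    min_gap: int = 5_000,
    margin: int = 10_000,
) -> tuple[tuple[int, int], ...]:
    """Draw `n` disjoint intervals with at least `min_gap` bp between them."""
    widths = rng.integers(width_range[0], width_range[1] + 1, n)
    usable = genome_length - 2 * margin - int(np.sum(widths)) - (n - 1) * min_gap
    if usable < 0:
        raise ValueError("genome too small for the requested intervals")
    cuts = np.sort(rng.uniform(0, usable, n))
    out = []
    pos = margin
    prev_cut = 0.0
    for w, c in zip(widths, cuts):
        pos += int(c - prev_cut)
        out.append((pos, pos + int(w)))
        pos += int(w) + min_gap
        prev_cut = c
    return tuple(out)


def training_genome(
    n_pos: int = 400,
    n_neg: int = 400,
    seed: int = 0,
    depth: float = 30.0,
    region_spacing: int = 6_000,
    ocr_width_range: tuple[int, int] = (400, 600),
    distortion_width_range: tuple[int, int] = (300, 600),
) -> SimConfig:
    """Build a config with alternating planted OCRs and distortion regions.

    Used to generate labelled training windows for the false-positive
    classifier: positives are the planted OCRs, negatives the distortion
    artefacts.  Regions alternate along the genome with randomized
    offsets so the two classes share the same genomic context.
    """
    rng = np.random.default_rng(seed)
    n_regions = n_pos + n_neg
    genome_length = region_spacing * (n_regions + 2)
    ocrs: list[tuple[int, int]] = []
    distortions: list[tuple[int, int]] = []
    labels = np.array([1] * n_pos + [0] * n_neg)
    rng.shuffle(labels)
    for i, lab in enumerate(labels):
        anchor = region_spacing * (i + 1)
        offset = int(rng.integers(-500, 501))
        if lab:
            w = int(rng.integers(*ocr_width_range))
            ocrs.append((anchor + offset, anchor + offset + w))
        else:
            w = int(rng.integers(*distortion_width_range))
            distortions.append((anchor + offset, anchor + offset + w))
    return SimConfig(
        genome_length=genome_length,
        ocr_intervals=tuple(ocrs),
        distortion_intervals=tuple(distortions),
        depth=depth,
        seed=seed,
    )


def write_truth(truth: SimTruth, out_dir: str | os.PathLike) -> dict[str, str]:
    """Write truth BEDs and the config JSON; returns the paths written."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "ocr_bed": os.path.join(out_dir, "truth_ocrs.bed"),
        "distortion_bed": os.path.join(out_dir, "truth_distortions.bed"),
        "config_json": os.path.join(out_dir, "sim_config.json"),
        "contig_lengths": os.path.join(out_dir, "contigs.tsv"),
    }
    contig = truth.config.contig
    with open(paths["ocr_bed"], "w") as fh:
        for a, b in sorted(truth.ocr_intervals):
            fh.write(f"{contig}\t{a}\t{b}\n")
    with open(paths["distortion_bed"], "w") as fh:
        for a, b in sorted(truth.distortion_intervals):
            fh.write(f"{contig}\t{a}\t{b}\n")
    cfg = asdict(truth.config)
    cfg["n_fragments"] = truth.n_fragments
    cfg["realized_depth"] = truth.realized_depth
    with open(paths["config_json"], "w") as fh:
        json.dump(cfg, fh, indent=2, sort_keys=True, default=list)
    with open(paths["contig_lengths"], "w") as fh:
        fh.write(f"{contig}\t{truth.config.genome_length}\n")
    return paths


def read_truth_bed(path: str | os.PathLike) -> list[tuple[str, int, int]]:
    """Read a truth/reference BED3 into (contig, start, end) tuples."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            out.append((f[0], int(f[1]), int(f[2])))
    return out
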