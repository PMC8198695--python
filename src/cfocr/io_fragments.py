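"""Fragment-level input/output and genome tiling.

cfDNA fragments are represented as 0-based half-open genomic intervals
(BED convention).  Fragments can be read from a 3-column BED of fragment
coordinates or from a coordinate-sorted, indexed BAM of properly paired
reads, in which case one fragment per pair is taken as the outer template
span reported by the leftmost mate.

The genome is processed in fixed-size tiles (default 20 kb) carrying
symmetric padding so that window-based signals never see a tile edge.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

DEFAULT_LENGTH_BOUNDS = (120, 180)  # mononucleosome-sized cfDNA
DEFAULT_TILE = 20_000
DEFAULT_PAD = 2_000
DEFAULT_MIN_MAPQ = 30


@dataclass(frozen=True, slots=True)
class Fragment:
    """One sequenced cfDNA molecule as a genomic interval."""

    contig: str
    start: int  # 0-based inclusive
    end: int  # exclusive

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(f"invalid fragment interval [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True, slots=True)
class GenomeTile:
    """A processing window: a disjoint core plus `pad` bp of context per side.

    Cores partition each contig; padded spans of neighbouring tiles overlap,
    which lets per-tile signal computation be independent while calls are
    deduplicated on cores.
    """

    contig: str
    start: int  # core start
    end: int  # core end, exclusive
    pad: int = DEFAULT_PAD
    contig_length: int | None = None

    @property
    def padded_start(self) -> int:
        return max(0, self.start - self.pad)

    @property
    def padded_end(self) -> int:
        if self.contig_length is None:
            return self.end + self.pad
        return min(self.contig_length, self.end + self.pad)

    @property
    def span(self) -> int:
        return self.padded_end - self.padded_start


def tile_genome(
    contig_lengths: dict[str, int],
    tile: int = DEFAULT_TILE,
    pad: int = DEFAULT_PAD,
) -> list[GenomeTile]:
    """Partition every contig into `tile`-bp cores with `pad` bp context.

    The final tile of a contig may have a shorter core.  Raises if the tile
    size does not dominate the padding (tiles must be meaningful units).
    """
    if tile <= 2 * pad:
        raise ValueError(f"tile size {tile} must exceed twice the pad {pad}")
    tiles: list[GenomeTile] = []
    for contig, length in contig_lengths.items():
        if length <= 0:
            raise ValueError(f"contig {contig!r} has non-positive length {length}")
        for start in range(0, length, tile):
            tiles.append(
                GenomeTile(contig, start, min(start + tile, length), pad, length)
            )
    return tiles


def read_contig_lengths(path: str | os.PathLike) -> dict[str, int]:
    """Read contig lengths from a FASTA-index-style TSV (name, length, ...)."""
    lengths: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected at least 2 columns")
            lengths[fields[0]] = int(fields[1])
    return lengths


def _looks_like_bam(path: str) -> bool:
    return str(path).endswith((".bam", ".cram", ".sam"))


def read_fragments(
    path: str | os.PathLike,
    region: GenomeTile | None = None,
    length_bounds: tuple[int, int] = DEFAULT_LENGTH_BOUNDS,
    min_mapq: int = DEFAULT_MIN_MAPQ,
) -> list[Fragment]:
    """Read fragments overlapping ``region`` (padded span) from BAM or BED3.

    Fragments are filtered to ``length_bounds`` (inclusive).  For BAM input
    the fragment is the outer template span of a proper pair, taken once
    per pair from the leftmost mate; secondary/supplementary/duplicate
    reads and pairs below ``min_mapq`` are ignored.
    """
    if _looks_like_bam(str(path)):
        return _read_fragments_bam(str(path), region, length_bounds, min_mapq)
    return _read_fragments_bed(str(path), region, length_bounds)


def _in_bounds(length: int, bounds: tuple[int, int]) -> bool:
    return bounds[0] <= length <= bounds[1]


def _read_fragments_bed(
    path: str, region: GenomeTile | None, bounds: tuple[int, int]
) -> list[Fragment]:
    out: list[Fragment] = []
    lo = region.padded_start if region is not None else None
    hi = region.padded_end if region is not None else None
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: malformed BED line (<3 columns)")
            try:
                contig, start, end = fields[0], int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed BED line: {exc}") from exc
            if region is not None:
                if contig != region.contig:
                    continue
                if end <= lo or start >= hi:
                    continue
            if not _in_bounds(end - start, bounds):
                continue
            out.append(Fragment(contig, start, end))
    if region is not None and not out:
        # Distinguish "empty slice" from "contig absent" only loosely here;
        # genuinely unknown contigs are common when mixing assemblies.
        pass
    return out


def _read_fragments_bam(
    path: str, region: GenomeTile | None, bounds: tuple[int, int], min_mapq: int
) -> list[Fragment]:
    import pysam

    out: list[Fragment] = []
    with pysam.AlignmentFile(path) as bam:
        if region is not None:
            if region.contig not in bam.references:
                warnings.warn(
                    f"contig {region.contig!r} not present in {path}; returning no fragments"
                )
                return []
            if not bam.has_index():
                raise FileNotFoundError(
                    f"{path} has no index (.bai); run 'samtools index' first"
                )
            it = bam.fetch(region.contig, region.padded_start, region.padded_end)
        else:
            it = bam.fetch(until_eof=True)
        for read in it:
            if (
                read.is_unmapped
                or read.is_secondary
                or read.is_supplementary
                or read.is_duplicate
                or not read.is_proper_pair
            ):
                continue
            if read.mapping_quality < min_mapq:
                continue
            tlen = read.template_length
            if tlen <= 0:  # count each pair once, from the leftmost mate
                continue
            start = read.reference_start
            end = start + tlen
            if not _in_bounds(end - start, bounds):
                continue
            if region is not None and (
                end <= region.padded_start or start >= region.padded_end
            ):
                continue
            out.append(Fragment(read.reference_name, start, end))
    return out


def write_fragments_bed(
    fragments: Iterable[Fragment], path: str | os.PathLike
) -> None:
    """Write fragments as BED3, in the order given."""
    with open(path, "w") as fh:
        for f in fragments:
            fh.write(f"{f.contig}\t{f.start}\t{f.end}\n")


def fragments_to_arrays(
    fragments: Sequence[Fragment],
) -> tuple["np.ndarray", "np.ndarray"]:
    """Return (starts, ends) int64 arrays for vectorised signal computation."""
    import numpy as np

    if not fragments:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    starts = np.fromiter((f.start for f in fragments), dtype=np.int64, count=len(fragments))
    ends = np.fromiter((f.end for f in fragments), dtype=np.int64, count=len(fragments))
    return starts, ends
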