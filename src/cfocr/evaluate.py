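"""Scoring of calls against reference interval sets.

Implements the overlap-percentage metric (a reference interval counts as
detected when it shares at least one base with any call), the signed
distance distribution from call centres to the nearest TSS, and a
precision/recall harness against simulated truth with positional slack.
Strand is ignored throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from intervaltree import IntervalTree

Interval = tuple[str, int, int]  # (contig, start, end), 0-based half-open


@dataclass
class OverlapReport:
    """How many reference intervals are hit by at least one call."""

    n_reference: int
    n_overlapped: int
    percentage: float
    hits: np.ndarray  # per-reference boolean flags, in input order


def _build_trees(intervals: Sequence[Interval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for contig, start, end in intervals:
        if end > start:
            trees.setdefault(contig, IntervalTree()).addi(start, end)
    return trees


def _warn_contig_mismatch(
    calls: Sequence[Interval], reference: Sequence[Interval]
) -> None:
    call_contigs = {c for c, _, _ in calls}
    ref_contigs = {c for c, _, _ in reference}
    unmatched = ref_contigs - call_contigs
    if calls and unmatched:
        warnings.warn(
            f"reference contigs with no calls: {sorted(unmatched)}", stacklevel=3
        )


def overlap_percentage(
    calls: Sequence[Interval], reference: Sequence[Interval]
) -> OverlapReport:
    """Fraction of reference intervals intersecting (>= 1 bp) any call."""
    _warn_contig_mismatch(calls, reference)
    trees = _build_trees(calls)
    hits = np.zeros(len(reference), dtype=bool)
    for i, (contig, start, end) in enumerate(reference):
        tree = trees.get(contig)
        if tree is not None and tree.overlaps(start, end):
            hits[i] = True
    n_ref = len(reference)
    n_hit = int(np.sum(hits))
    pct = 100.0 * n_hit / n_ref if n_ref else 0.0
    return OverlapReport(n_ref, n_hit, pct, hits)


def expand_tss(
    tss: Sequence[tuple[str, int]], half: int = 1000
) -> list[Interval]:
    """Expand point TSSs to +/- half bp windows (promoter-scale regions)."""
    return [(c, max(0, p - half), p + half) for c, p in tss]


def tss_distance_distribution(
    calls: Sequence[Interval], tss: Sequence[tuple[str, int]]
) -> np.ndarray:
    """Signed distance from each call centre to its nearest TSS.

    Positive means the call centre lies downstream (higher coordinate)
    of the TSS.  Calls on contigs without any TSS are skipped.
    """
    by_contig: dict[str, np.ndarray] = {}
    for contig in {c for c, _ in tss}:
        by_contig[contig] = np.sort(
            np.array([p for c, p in tss if c == contig], dtype=np.int64)
        )
    distances: list[int] = []
    for contig, start, end in calls:
        positions = by_contig.get(contig)
        if positions is None or positions.size == 0:
            continue
        center = (start + end) // 2
        k = int(np.searchsorted(positions, center))
        cands = []
        if k > 0:
            cands.append(center - int(positions[k - 1]))
        if k < positions.size:
            cands.append(center - int(positions[k]))
        distances.append(min(cands, key=abs))
    return np.asarray(distances, dtype=np.int64)


def pr_against_truth(
    calls: Sequence[Interval],
    truth: Sequence[Interval],
    slack: int = 300,
) -> tuple[float, float]:
    """(precision, recall) of calls against truth intervals with slack.

    A truth interval is recalled when a call intersects it after both
    sides are widened by ``slack`` bp; a call is precise when it
    intersects any widened truth interval.  With no calls, precision is
    undefined and reported as NaN.
    """
    widened = [(c, max(0, s - slack), e + slack) for c, s, e in truth]
    recall_report = overlap_percentage(calls, widened)
    recall = recall_report.n_overlapped / len(truth) if truth else float("nan")
    if not calls:
        return float("nan"), recall
    truth_trees = _build_trees(widened)
    precise = sum(
        1
        for contig, start, end in calls
        if (t := truth_trees.get(contig)) is not None and t.overlaps(start, end)
    )
    return precise / len(calls), recall


def read_bed(path: str) -> list[Interval]:
    """Read BED3+ into interval tuples (extra columns ignored)."""
    out: list[Interval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 BED columns")
            out.append((f[0], int(f[1]), int(f[2])))
    return out


def read_tss(path: str) -> list[tuple[str, int]]:
    """Read TSS positions from BED (midpoint) or 2-column (contig, pos) TSV."""
    out: list[tuple[str, int]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) >= 3:
                try:
                    start, end = int(f[1]), int(f[2])
                except ValueError:
                    out.append((f[0], int(f[1])))
                    continue
                out.append((f[0], (start + end) // 2))
            else:
                out.append((f[0], int(f[1])))
    return out
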