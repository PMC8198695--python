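"""Independent brute-force oracles used to cross-check the implementation.

Every oracle here recomputes a quantity by a deliberately different,
simpler route (explicit per-window tests, per-window least squares,
quadratic all-pairs scans) than the production code path it checks.
"""

from __future__ import annotations

import numpy as np

from cfocr.io_fragments import Fragment, GenomeTile


def wps_brute_force(fragments, tile: GenomeTile, window: int = 120) -> np.ndarray:
    """Per-window explicit WPS: test every fragment against every window.

    Windows are vectorised over fragments (membership tests only); each
    window W = [x-h, x+h) is evaluated independently of every other.
    """
    h = window // 2
    L = tile.span
    off = tile.padded_start
    starts = np.array([f.start for f in fragments], dtype=np.int64)
    ends = np.array([f.end for f in fragments], dtype=np.int64)
    out = np.zeros(L, dtype=np.int64)
    for i in range(L):
        x = i + off
        wlo, whi = x - h, x + h
        if starts.size == 0:
            continue
        spans = (starts <= wlo) & (ends >= whi)
        endpoint = ((starts >= wlo) & (starts < whi)) | (
            (ends - 1 >= wlo) & (ends - 1 < whi)
        )
        out[i] = int(np.sum(spans)) - int(np.sum(endpoint & ~spans))
    return out


def coverage_brute_force(fragments, tile: GenomeTile) -> np.ndarray:
    """depth[x] = explicit count of fragments with start <= x < end."""
    L = tile.span
    off = tile.padded_start
    out = np.zeros(L, dtype=np.int64)
    for f in fragments:
        for x in range(max(f.start, off), min(f.end, off + L)):
            out[x - off] += 1
    return out


def running_median_naive(values: np.ndarray, window: int) -> np.ndarray:
    """Per-position sorted-window median with truncated edge windows."""
    h = window // 2
    n = len(values)
    return np.array(
        [np.median(values[max(0, i - h) : min(n, i + h + 1)]) for i in range(n)]
    )


def savgol_refit(values: np.ndarray, window: int, order: int) -> np.ndarray:
    """Interior SG smoothing by explicit per-window polynomial refit."""
    h = window // 2
    n = len(values)
    out = np.full(n, np.nan)
    xs = np.arange(-h, h + 1, dtype=float)
    for i in range(h, n - h):
        coef = np.polyfit(xs, values[i - h : i + h + 1], order)
        out[i] = np.polyval(coef, 0.0)
    return out


def trough_predicate(
    height: float,
    width: float,
    peak_width: float,
    max_height: float = 0.58,
) -> bool:
    """Direct evaluation of the printed trough credibility predicate."""
    return height < max_height and 25 < width < 100 and 50 < peak_width < 220


def overlap_quadratic(calls, reference) -> np.ndarray:
    """All-pairs overlap flags: reference i hit iff any call intersects it."""
    hits = np.zeros(len(reference), dtype=bool)
    for i, (rc, rs, re) in enumerate(reference):
        for cc_, cs, ce in calls:
            if cc_ == rc and min(re, ce) > max(rs, cs):
                hits[i] = True
                break
    return hits


def ols_normal_equations(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Closed-form simple-regression slope/intercept."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xbar, ybar = x.mean(), y.mean()
    slope = float(np.sum((x - xbar) * (y - ybar)) / np.sum((x - xbar) ** 2))
    return slope, float(ybar - slope * xbar)


def auc_trapezoid(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the trapezoidal area under the ROC curve (sklearn points)."""
    from sklearn.metrics import roc_curve

    fpr, tpr, _ = roc_curve(labels, scores)
    return float(np.trapezoid(tpr, fpr))


def flank_chain_oracle(apexes, span, flank, min_per_side, spacing_range):
    """Direct enumeration of the walk-outward flank-regularity predicate."""
    apexes = sorted(apexes)
    lo, hi = span

    def side_ok(side):
        if len(side) < min_per_side:
            return False
        count = 1
        for a, b in zip(side[:-1], side[1:]):
            if spacing_range[0] <= abs(b - a) <= spacing_range[1]:
                count += 1
                if count >= min_per_side:
                    return True
            else:
                return False
        return count >= min_per_side

    left = [a for a in apexes if lo - flank <= a <= lo][::-1]
    right = [a for a in apexes if hi <= a <= hi + flank]
    return side_ok(left) and side_ok(right)
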