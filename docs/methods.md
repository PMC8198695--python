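# Methods

## Signal model

cfDNA fragments are modelled as mononucleosome-protected molecules:
over chromatin packed in well-positioned arrays, fragment centres
cluster at nucleosome dyads spaced one repeat length apart (167 bp core
plus a short linker), while accessible chromatin produces few spanning
fragments and an excess of fragment endpoints. The window protection
score makes both effects visible in one track. For a window size `w`
(default 120, even) the window at coordinate `x` is `W = [x − w/2,
x + w/2)`; a fragment `[s, e)` contributes **+1** when it contains `W`
(`s ≤ x − w/2` and `e ≥ x + w/2`), otherwise **−1** when either
endpoint (`s` or `e − 1`) lies in `W`, otherwise 0. A fragment with
both endpoints inside the window still contributes a single −1: the
score counts fragments, not endpoints. Coverage is the plain per-base
fragment depth. Both tracks are computed by difference-array
accumulation, which the test suite checks base-by-base against an
explicit per-window oracle.

## Normalization and smoothing

Raw WPS drifts with local depth, so each tile's track is detrended by
subtracting a centred running median (window 1001 bp, truncated at the
edges) and scaled by its maximum absolute value onto [−1, 1]. This
scheme is a package choice — peak thresholds live on this unit scale,
and the scheme is pluggable because threshold portability across
normalizations cannot be assumed. A tile whose detrended amplitude is
zero is flagged low-signal and excluded from calling.

Denoising uses a Savitzky–Golay filter of order 2, window 31 samples
(bp). The filter replaces each point by the centre value of the
least-squares quadratic fitted to its window, preserving peak shape and
width; edges are handled by polynomial fits on the truncated edge
window (scipy's `interp` mode) rather than reflection, which would
fabricate edge peaks. Order-2 exactness on quadratics (to 1e-9) and
agreement with a per-window refit oracle are asserted in the tests.

## Peak and trough location

Peaks are local maxima of the smoothed track passing three constraints:
minimum height, minimum apex separation (the higher peak wins a
conflict), and width at half prominence within a band. Width is
measured at relative height 0.5 of prominence — the conventional
definition — because the published parameter names a band but not the
measurement height.

Troughs are proposed by a three-window scan with window `w = 5` bp:
wherever the sum over the middle window is strictly below both
neighbouring window sums, the leftmost minimum of the middle window is
proposed; the scan always advances by `w`. Each proposal is vetted
against the preceding landmarks: with `height` the drop from the
previous peak, `width` the distance from that peak's apex, and
`peakWidth` the distance from the previous accepted trough (falling
back to the peak distance when none precedes), a proposal is accepted
iff `height < 0.58 and 25 < width < 100 and 50 < peakWidth < 220`, all
comparisons strict. The direction of the height comparison is
surprising (it admits shallow dips and rejects deep ones), so the
implementation keeps the predicate exactly as stated but exposes
`trough_predicate_inverted` to flip it. Troughs without a preceding
peak are discarded. Candidate calling does not depend on troughs;
they feed the feature geometry only.

### Parameter calibration

Detection parameters are data-dependent. Following the μ ± 3σ recipe:
2000 random 1 kb regions are sampled from signal-bearing tiles, peak
statistics are harvested with permissive settings (prominence ≥ 0.1,
spacing ≥ 60 bp), a normality test is reported for the height
distribution, and `min_height = μ − 3σ` of the heights. Width and
spacing distributions are skewed, so their bounds use the central
quantile band a normal would place at μ ± 3σ (the [0.135%, 99.865%]
quantiles) — skew-robust and equivalent under normality. One deliberate
choice: the width band is calibrated from the *same* half-prominence
width statistic the peak filter consumes. Calibrating it from
trough-to-trough distances would mix two different measurands (~62 bp
half-prominence vs ~187 bp trough spacing on simulated arrays) and
reject every genuine peak. The constructor defaults of `PeakParams`
(height 0.28, distance 25, width [115, 164]) are the values this
procedure yields on deep (~100×) human plasma data; the pipeline
default is to recalibrate, which adapts the detector to the depth and
noise of the input at hand.

## Candidate calling

A missing nucleosome widens the apex spacing beyond ~200 bp, so every
adjacent peak pair separated by more than 250 bp is examined. Coverage
is measured over the central 300 bp of the gap — the initial accessible
core — rather than apex-to-apex: the bounding apexes sit on protected
nucleosomes, and including their footprints dilutes the dip (on
simulation, 0.77 vs 0.26 in normalized units, the difference between
calling nothing and calling correctly). The measurement is normalized
by mean depth over the 2000 bp neighbourhood centred on the gap
midpoint; below 0.6, and with at least 3 consecutively regular peaks
(spacings 120–220 bp, about one nucleosome repeat) within 1 kb on each
side, the gap becomes a candidate. Calls are emitted as exactly 600 bp
centred on the gap midpoint: a ~300 bp core plus one nucleosome (167
bp) of positional tolerance per side. Candidates whose centre falls in
a tile's padded context rather than its core are dropped (each call is
owned by exactly one tile); a residual merge step unions calls
overlapping ≥ 300 bp across tiles. Repeat-region subtraction drops
whole calls on any overlap (configurable fraction), preserving the
fixed call size.

## Features and the false-positive filter

Each candidate is summarized over a 2000 bp window centred on it, with
a 21-column vector (stable order in `feature_extract.FEATURE_NAMES`):

- mean and variance over all complete peaks in the window of peak
  area (trapezoidal integral above the trough-to-trough chord), apex
  angle, spacing, height (apex minus mean trough level) and width
  (trough-to-trough distance) — 10 columns;
- mean normalized coverage of the central 600 bp and of the full
  window — 2 columns. These use tile-standardized coverage (unit =
  tile-core mean) so that both are informative; normalizing by the
  window's own mean would pin the broad value at 1;
- OLS slope and intercept of coverage vs position over [0, 2000),
  [0, 1200) and [800, 2000) — 6 columns. True OCRs show a V-shaped
  profile (opposite-signed half-window slopes), deletions and mapping
  artefacts drop step-like;
- the unit bisector (dx, dy) of the apex angle of the window's central
  peak — 2 columns — and a `geometry_missing` flag set when no peak
  lies completely inside the window — 1 column.

Angles mix bp with unit-scaled WPS, which is meaningless without an
aspect ratio; x is fixed at 10 bp per unit (configurable). Peaks
partially outside the window are excluded from the statistics.

The classifier is a random forest with 100 trees, Gini impurity,
minimum split 2 (library defaults otherwise), trained on 400 positive
and 400 negative 2000 bp windows split 1:1 into train/test with 30% of
the training half held out for validation, all splits stratified and
seeded. Candidates are kept at positive probability ≥ 0.5 (the keep
threshold is a package choice; none is published). Models persist as
joblib plus a JSON sidecar carrying the feature schema, seed and
library version, and prediction refuses schema mismatches by name.

## The simulator

`cfocr.simulate` generates the study conditions end to end. Dyads are
placed every `167 + linker` bp (linker mean 20 bp, jittered uniformly
±5 bp), interrupted by planted OCRs; per-dyad fragment counts are
Poisson with rate `depth × repeat / fragment_length` so realized
coverage matches the configured depth; fragments are centred on their
dyad with 5 bp Gaussian jitter and have Gaussian lengths (167 ± 10,
clipped to 120–180). Inside OCRs, fragments appear at
`ocr_protection_factor` (default 0.2) of normal density with uniform
endpoints — endpoint signal without protection signal, the way WPS
actually sees accessibility. A global uniform fragment process (5% of
nominal density) models random fragmentation noise. The 187 bp repeat
is a simulator choice consistent with the 120–220 bp spacing band used
by the flank-regularity filter.

Negative training regions ("distortions") model mapping-artefact
coverage dips: fragment density halves inside the core and nucleosome
positioning is destroyed (uniform re-centring) within ±800 bp, so the
dip lacks the regular flanks and V-shaped profile of a real OCR. This
is a synthetic surrogate for false-positive-like regions; how such
regions are best mined from real data is left to the user.

What the simulator does **not** model: GC bias (an optional hook, off
by default), duplicated reads, mapping ambiguity over real repeat
families, CNV-driven coverage shifts, and tissue mixtures. Passing
end-to-end tests therefore demonstrates the pipeline's correctness
under its own signal model, not its calibration on clinical plasma.

## Problem sizes and numerical choices

The test suite and acceptance script run the full pipeline on a 2 Mb
genome at 30× with 20 planted OCRs (400–600 bp), the depth titration by
Bernoulli thinning to 20×/10×/5× of the same fragment set, and
classifier training on 400 + 400 windows over a ~4.8 Mb labelled
genome; these sizes exercise every code path with tight Monte-Carlo
noise. Ties in peak conflicts resolve toward the higher peak (scipy's
rule); trough proposals tie-break to the leftmost minimum; degenerate
inputs (all-constant tracks, zero-coverage neighbourhoods, σ = 0
calibration samples) are flagged and excluded rather than called. All
randomness descends from explicit integer seeds, and rerunning any
stage with the same seed reproduces its outputs byte-for-byte.

## Known limitations

- Below ~10× the waveform degrades faster than the calibration can
  adapt; recall falls sharply (the depth-5 titration point) while
  precision stays high.
- Thresholds quoted on the normalized scale (0.28, 0.58) are tied to
  the max-abs normalization; alternative normalizations require
  recalibration.
- The fixed 600 bp output cannot represent broader accessible domains;
  adjacent calls are left unmerged unless they overlap by ≥ 300 bp.
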