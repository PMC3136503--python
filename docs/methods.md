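# Methods

`fatrack` quantifies focal-adhesion (FA) dynamics in single-channel
fluorescence time-lapse movies of an adhesion marker (e.g. EGFP-Paxillin
imaged by TIRF microscopy), optionally with a paired whole-cell channel
(e.g. myr-RFP) for cell-edge segmentation.  This note documents the model
and procedure of every stage, the parameters that matter, the synthetic
data used for validation, and the known limits of both.

## Intensity scale

Camera counts are divided by the full-scale value `2^bit_depth − 1`
(inferred as the smallest of 8/12/16 bits holding the observed maximum,
overridable).  All intensities are therefore dimensionless in [0, 1] on a
*fixed absolute scale across frames*.  Per-frame rescaling (min/max or
percentile) would make one adhesion's intensity incomparable between
frames and corrupt the kinetic fits; it is deliberately not offered.

## Segmentation

1. **High-pass filter.**  Each frame is convolved with a flat round
   ("pillbox") kernel of radius `filter_radius_px` (default 11 px ≈ 2.4 µm
   at 0.215 µm/px), normalized to unit sum, with edge-replicated borders;
   the local average is subtracted from the frame.  This removes
   cytoplasmic background while preserving structures smaller than the
   kernel.
2. **Threshold.**  Pixels of the filtered image at or above
   `detection_threshold` (default 0.10, useful range ≈ 0.05–0.10) are
   adhesion candidates.
3. **Water segmentation.**  Each 8-connected candidate region is split at
   intensity saddle points: seeds are the local maxima (plateaus merged)
   of the Gaussian-smoothed frame (σ = 1 px) whose prominence exceeds
   `split_min_depth` (default 0.05); labels grow from the seeds by
   flooding in decreasing intensity order (watershed on the inverted
   smoothed image, restricted to the mask).  The prominence cut matters:
   without it, pixel noise on the flat top of a large adhesion spawns
   spurious seeds and shatters it.  0.05 is about four standard deviations
   of the smoothed reference noise (below), and half the default
   threshold; saddles shallower than that are indistinguishable from
   noise, so the two maxima are treated as one adhesion.
   Two post-passes follow: interior holes of each label are filled, and a
   pixel *bridging* two adhesions of ≥ `large_adhesion_px` (default 40 px
   = 1.85 µm²) — an articulation pixel whose removal disconnects them — is
   reassigned to the adhesion with the nearer centroid (ties to the lower
   label id).
4. **Measurement.**  Properties are measured on the *raw* normalized
   frame, not the filtered one (filtered values can be negative and are
   background-relative): pixel/µm² area, unweighted centroid, mean
   intensity, and axial ratio.  The axial ratio is √(λ₁/λ₂) of the
   intensity-weighted second-moment matrix with a 1/12 unit-square
   variance added per pixel, so a single pixel reports 1.0 and a 1×n line
   reports exactly n.

## Cell edge

The whole-cell channel is thresholded automatically: a 1000-bin intensity
histogram is smoothed by local quadratic regression over a 5%-of-bins
window (Savitzky–Golay, order 2, window 51), peaks with prominence above
1% of the histogram maximum are found (modes in the outermost bins
included), and the threshold is the minimum between the two
lowest-intensity modes (background and cell body).  Connected regions
under 10 px are discarded; when several regions survive, all are kept and
the union of their borders is the edge.  Edge pixels are body pixels with
a non-body 4-neighbor (the image border counts as non-body).  Distances
are unsigned Euclidean distances to the nearest edge pixel, in µm; an
inside/outside flag is carried separately.  A non-bimodal histogram
raises an error so the caller can fall back to an explicit threshold.

## Tracking

A sequential birth–death–merge model links blobs frame to frame:

- Each live adhesion claims the next-frame blob sharing the largest
  fraction of its own pixels (ties: larger candidate area, then lower
  id).  The overlap denominator is the *earlier* blob's area.
- An adhesion with no overlap claims the nearest centroid within
  `max_link_distance_px`.  The default cap is 3 px.  This cap is the one
  place where the implementation is deliberately conservative: at the
  reference noise level ~1.3% of background pixels exceed the default
  threshold, so a 10 px capture radius contains a false blob with
  probability ≈ 0.98 per frame and lineages would essentially never die —
  they would wander across background noise after the real adhesion
  disappears, inflating longevities and destroying disassembly fits.
  With 3 px the expected number of false candidates per frame is ≈ 0.36
  while a one-frame detection dropout of a stationary or slowly drifting
  adhesion is still bridged.  Set it to `inf` to recover the uncapped
  textbook rule.
- Next-frame blobs that were overlapped but claimed by nobody are *split
  births*; unclaimed, un-overlapped blobs are new births.
- When several lineages claim one target: claimants with zero pixel
  overlap die (`disappear`); among true merge partners the larger
  continues if areas differ by ≥ 10% (relative to the larger), otherwise
  the one whose centroid is nearer the target; losers die (`merged_into`).
- Lineages alive in the last frame are `censored`.

Greedy frame-order matching is used rather than global optimization; the
partition identity (every blob belongs to exactly one lineage) is checked
on every pipeline run.  There is no gap-closing across missing frames.

## Kinetics

FA assembly and disassembly are log-linear: over the assembly (resp.
disassembly) phase, mean intensity follows `I(t) ≈ I₀ e^{kt}` (resp.
decaying toward the death point).  For a window, the series is divided by
its anchor — first point for assembly, last for disassembly — and
log-transformed; ordinary least squares against time in minutes gives the
slope, whose magnitude is the rate in min⁻¹, with the standard two-sided
t-test p-value and adjusted R² `1 − (1−R²)(n−1)/(n−2)`.

Phase lengths are selected by exhaustive search: all assembly lengths
`a ≥ min_phase_length` anchored at the series start and disassembly
lengths `d ≥ min_phase_length` anchored at the end, with `a + d ≤ n`,
are scored by the sum of the two adjusted R² values; the best pair wins,
exact ties going to the largest `a + d`, then the larger `a`.  The
stability (maturity) phase is the gap between the two windows.  A series
too short for both phases keeps the single better-fitting phase.
Nonpositive intensities are floored at `eps × max(series)` before the log
and the series is flagged.  `min_phase_length` defaults to 10 frames for
analysis; the simulator-validation experiments use 5, which avoids
biasing the search toward long windows on short planted phases.

Lowess smoothing is available for display only and never feeds the fits.

## Results filters and statistics

Rate populations keep lineages with ≥ `min_rate_points` (default 20)
intensity points; split-born lineages are excluded from assembly rates,
merge-death lineages from disassembly rates, and fits with slope p-value
above `fit_alpha` (0.05) are dropped, as are non-positive rates.  Phase
length populations additionally require both phases present, a non-split
birth and a non-merge death.

Two-sample comparisons dispatch on size: groups with more than
`bootstrap_max_n` (2000) points use the two-sided tie-corrected
Wilcoxon/Mann-Whitney rank-sum test; smaller groups use a percentile
bootstrap of the median difference (default 50 000 replicates) with
p-value `2·min(P(Δ≤0), P(Δ≥0))` bounded to [2/reps, 1], plus percentile
CIs on each median and on the percent change.  Resampling is pooled over
adhesions; per-cell resampling is not implemented (the synthetic
experiments have no cell structure).  Null calibration is verified by
simulation (rejection rate 0.05 ± 0.02).  Censored lineages are excluded
from longevity summaries by default (right-censoring).

## Synthetic validation data

All simulators share a Gaussian background noise model (mean 0, variance
2×10⁻³, σ ≈ 0.045) that also perturbs adhesion pixels; negative pixels
are clipped to 0 and the clip fraction is logged.  Discs are rendered
with 16×16 subpixel area weighting, so sub-pixel radii carry physically
meaningful flux.  Simulators are seed-deterministic (bit-identical
stacks for equal seed and parameters).

- **Stationary**: a grid of unmoving discs, rows spanning radii 0.5–5 px
  (10 values) and columns spanning mean intensities 0.05–0.47 (15 values,
  step 0.03), every adhesion alive for exactly 25 frames at 1 frame/min,
  with 2 blank frames before and after so births and deaths are
  observable.  Grid spacing is 4× the largest radius.
- **Moving**: discs sliding at constant speed (one row per radius×speed
  pair) to probe tracking limits; truth records per-frame centers.
- **Kinetic**: replicate discs following exponential rise over
  `assembly_len` frames, a plateau of `stability_len` (default 5), and
  exponential fall over `disassembly_len`; the implied per-phase rate is
  `ln(peak/floor)/(len−1)` per frame.  Two floor conventions are used
  deliberately.  The *series-level* generator (`simulate_kinetic_series`,
  which emulates the mean-intensity trace a tracked lineage reports, with
  noise σ reduced by √area) uses floor = 10% of peak: steep log phases,
  the cleanest test of the window search itself.  *Imaged* kinetic movies
  (`simulate_kinetic`) use floor = 40% of peak (≈ 0.18 at the default
  peak 0.45) and radius 5 px: the stationary experiment shows intensities
  below ≈ 0.17 are not reliably detectable, so a schedule planted below
  that floor is unobservable by construction and cannot validate
  phase-length recovery through the imaging pipeline; 0.18–0.45 also
  matches the intensity range of real detected adhesions.  Both floors
  are recorded in the truth records and configurable.

**Scoring.**  For each planted adhesion, the lineage whose blob contains
the planted center in the most life frames is its recovered lineage;
`tracking_accuracy` is that coverage fraction, detection requires ≥ 90%
coverage, and "full life" coverage of every planted frame.  The
detection floor of a movie is the lowest planted intensity such that it
and every brighter level have at least half their radii detected.

What passing these benchmarks does *not* show: the simulators have no
photobleaching, focus drift, shot (Poisson) noise, adhesion shape change,
sliding-with-turnover, or crowded adhesion fields with frequent true
merges; real-data performance on those axes is not certified by this
suite.

## Standing validation results (recomputed by `scripts/acceptance.py`)

- Stationary grid: adhesions detected over their whole lifespan recover a
  median longevity of 25 min (the planted value); the reliable detection
  floor is 0.17 normalized intensity at the default threshold (median
  over five seeds).
- Kinetic grid (all 121 assembly×disassembly lengths 10–20, minimum
  phase length 5): the planted 5-frame stability phase is recovered as
  the median across the grid; series-level, median recovered phase
  lengths equal the planted lengths at every grid point and median rates
  are within 10% of the planted rates.
- Two-population contrast with planted rate ratio ≈ 0.65: the sign and
  approximate magnitude of the median-rate percent change are stable
  across detection thresholds 0.05–0.10, minimum phase lengths, and 2×
  frame decimation (with the minimum phase length reduced to 5 and the
  lifetime gate halved, since each remaining frame covers two minutes).

Problem sizes were chosen so the full suite and the acceptance script
each run in about a minute on a single core: one stationary movie of
220×320 px × 29 frames per seed, one 4-replicate kinetic movie per grid
point, 2000-replicate bootstraps in calibration loops (the p-value
resolution floor 2/reps is far below the 0.05 level being calibrated).

## Known limitations

- Phase-window recovery through the imaging pipeline degrades for dim or
  small adhesions: thresholded blobs of near-floor objects have upward-
  biased mean intensities, flattening the series ends; window lengths can
  then be off by 1–2 frames.  This is a property of threshold-based
  measurement, not of the window search (which is exact on clean series).
- Recovered longevities can exceed the planted value by a frame per end
  when a background noise blob overlaps the adhesion's footprint just
  before birth or after death; with the default link cap this is rare.
- The bimodal edge threshold requires a genuinely bimodal histogram;
  confluent fields or uneven illumination need an explicit threshold.
- No sub-pixel boundaries, no gap-closing, no adhesion sliding metrics,
  no multi-channel colocalization.
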