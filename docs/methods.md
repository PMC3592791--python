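# Methods

## The assay being modeled

`quenchfit` analyzes single-cell agonist dose-responses read out by a
halide-sensitive yellow fluorescent protein (YFP-I152L). Cells co-express
the reporter and a ligand-gated anion channel (the motivating system is the
glycine receptor, GlyR); opening the channel lets iodide in and quenches the
YFP signal. One well of a 384-well plate is imaged once in agonist-free
control solution — where the reporter is unquenched and brightest — and then
after each of ten increasing agonist additions, giving an 11-point
fluorescence-vs-concentration series for every cell in the field. Because
each cell yields its own curve, well-level heterogeneity (mixed receptor
isoforms, untransfected cells, debris) is resolved rather than averaged
away.

The package covers the computational half of such an experiment: synthetic
plate generation with known ground truth, cell segmentation, per-cell curve
fitting, quality filtering, well/plate summaries, and decision-tree
phenotyping. Wet-lab steps, hardware control and electrophysiology are out
of scope.

## Curve model and fitting

Each trace is fitted with the four-parameter logistic in concentration

    F(c) = F_max + (F_min − F_max) / (1 + (EC50 / c)^slope),    F(0) := F_max

where `F_max` is the unquenched plateau (lowest agonist), `F_min` the fully
quenched plateau (highest agonist), `EC50` the half-maximal concentration
(µM) and `slope` the Hill coefficient. The fluorescence *decreases* with
concentration, so the curve runs downhill; at `c = EC50` it passes through
the midpoint of the plateaus.

Fitting minimizes unweighted squared residuals with
`scipy.optimize.least_squares`. Choices that matter:

* **Bounded trust-region solver.** Parameter boxes — EC50 ∈ [1e−3, 1e6] µM,
  slope ∈ [0.05, 20], plateaus ∈ [0, 2·max(F)] — keep debris traces from
  diverging; the bounded TRF solver minimizes the same objective a
  Levenberg-Marquardt step would, and every fit is checked in the test
  suite against a brute-force grid oracle (below).
* **log10(EC50) as the optimization variable**, for conditioning across the
  4.5-decade ladder.
* **Initialization from the data**: plateaus from the trace min/max, EC50
  from the ladder point nearest the half-range crossing, slope 1. If the
  fitted midpoint rails more than one decade outside the sampled span —
  the signature of a spurious local minimum on a noisy trace — the fit is
  restarted from four log-spaced EC50 values across the ladder and the
  lowest-SSE solution kept.
* **The c = 0 control point is included** in the fit with model value
  `F_max` (the mathematical limit); the first image is taken in agonist-free
  solution, so it carries real information about the unquenched plateau.
* Non-convergence is recorded in a `converged` flag, never raised; such
  fits fail every downstream filter.

Derived measures: `R² = 1 − SSE/SST` with SST about the mean fluorescence
(NaN sentinel for zero-variance traces), and the dynamic range
`ΔF = 100·(F_max − F_min)/F_max` in percent.

### The grid-search reference fitter

`fit.grid_fit` is an exhaustive reference: on a 241×120 grid over
(log10 EC50 ∈ [−3, 6], slope ∈ [0.05, 20]) the model is linear in the
plateaus, so they are solved in closed form per node and the global SSE
minimum located by enumeration. It shares no code path with the iterative
fitter and serves as the independent oracle in tests and in the acceptance
script: the iterative minimum must never exceed the grid minimum.

## Quality filtering

Four closed-interval criteria, applied to every fit:

| criterion | window  | removes |
|-----------|---------|--------------------------------------|
| R²        | ≥ 0.9   | non-sigmoidal traces (debris, detached cells) |
| ΔF        | 20–100 % | reporter-only cells with no functional channel |
| slope     | 0.5–5   | physiologically implausible steepness |
| EC50      | 0.3–3000 µM | midpoints outside the workable assay window |

A cell is accepted only by the conjunction of all four. Endpoints are
inclusive (the R² criterion is stated as "≥", and ranges are read as closed
intervals). On a default synthetic well containing debris, non-responders
and detaching cells, the combined filter accepts roughly half of all
recognized objects — the qualitative regime such assays operate in.

## Segmentation

Cells are segmented once, on the control frame, and the pixel sets held
fixed across frames (cells are stationary on the few-minute time scale; a
detaching cell's trace collapses to background and is removed by the R²/ΔF
filters, so no tracking is needed). The algorithm is an iterative size- and
intensity-based threshold sweep:

1. Threshold at a high starting percentile of the control frame
   (default 99.5).
2. 8-connected components with area inside [min_area, max_area]
   (defaults 20–800 px at the 2×2-binned 10× scale of a 696×520 field) are
   accepted and masked out.
3. The threshold is lowered (by default in equal steps spanning from the
   start down to a robust background floor, median + 6·MAD·1.4826, over 25
   iterations) and the procedure repeats, so bright cells are claimed first
   and dim cells picked up later.

Two numerical details suppress duplicate detections on noisy images: the
binary mask is morphologically closed (3×3) before labeling so one cell
does not fragment into several in-gate components at a single threshold,
and any candidate within 2 px of an already-accepted object is treated as
that object's lower-threshold halo and skipped.

A configurable central-field crop (`central_fraction`) restricts analysis
to the middle of the frame, mirroring protocols that only evaluate cells
near the well center; the default is 1.0 (no crop) since detection quality
is benchmarked against the full truth table and no principled radius is
available.

Trace extraction is the mean of all pixel values inside a cell's fixed
pixel set, per frame.

## Synthetic data generator

The generator is first-class code: it defines the conditions under which
every downstream stage is validated.

* **Field and ladder.** 696×520 px, 16-bit, 11 frames; default ladder 0
  (control) plus 0.1, 0.3, 1, 3, 10, 30, 100, 300, 1000, 3000 µM — the
  leading ten points of the standard half-log agonist series. The two top
  concentrations (10000, 30000 µM) are available by explicit configuration.
* **Populations.** Per-cell log10(EC50) ~ Normal(log10(median), 0.15);
  published assays of this type report only medians ± SEM, so the spread is
  a calibration choice set to give visually distinct but realistically
  broad clusters in (EC50, slope) dot plots. Hill slope and ΔF are uniform
  over configurable ranges (defaults 0.8–2.0 and 30–70 %). Baseline
  fluorescence uniform 1000–4000 AU; cell radii 5–9 px (areas ≈ 80–250 px,
  inside the size gates).
* **Non-responders.** `fraction_responders` (default 0.85) models cells
  carrying the reporter but no functional channel — the dominant effect of
  imperfect co-transfection; their traces are flat.
* **Debris.** Small blobs (radius 1.2–2.2 px, below the minimum size gate)
  with independent multiplicative frame-to-frame intensity jitter
  (×0.4–1.6): bright, non-sigmoidal, the way dead cells and fluorescent
  junk behave.
* **Detachment.** With probability `detach_probability` a cell's trace
  drops abruptly to background from a uniformly drawn frame ≥ 1 onward —
  the simplest model of a cell washed away during perfusion.
* **Noise and background.** Additive Gaussian noise, sd =
  `noise_sd_frac` × baseline (default 2 % for traces; the image route adds
  the same sd as per-pixel noise). Background is flat at 5 % of the mean
  cell baseline. Gaussian rather than Poisson noise is adequate at 16-bit
  CCD scales; no optics (PSF), photobleaching or within-frame quench
  kinetics are simulated. Concentrations are final bath values — dilution
  bookkeeping is not modeled.
* **Two routes, one truth.** `generate_traces` emits per-cell tables
  directly; `render_image_series` draws the same latent cells (identical
  substream) as uniform discs placed by rejection sampling without overlap.
  Noise-free, the two routes agree to integer quantization, which is
  asserted in tests.

What passing tests on this generator do **not** show: robustness to uneven
illumination, focus drift, overlapping/touching cells, PSF blur, or
non-Gaussian noise — real images violate all of these to some degree, and
the segmentation defaults would need re-tuning per instrument.

## Summaries and statistics

Per well: median EC50 ± SEM (sd/√n) over accepted cells, median slope and
ΔF, and 5/25/75/95 % quantiles for box plots. A single accepted cell
reports SEM = 0 and is flagged degenerate; zero accepted cells yield NaN
statistics, flagged, never an exception. Two-group comparison is the
unpaired Student's t-test on raw per-cell EC50s (p < 0.05), matching how
such experiments are conventionally reported; Welch correction and
log-scale testing are exposed as options since EC50s are log-normally
distributed and the pooled-variance test on raw values is, strictly,
mis-specified. Plate maps arrange well medians on the row-letter ×
column-number grid; the color-scale orientation is a parameter
(`low_is_warm`, default warm = low EC50 = no drug block).

## Phenotype classification

Filter-accepted cells from pure populations, described by (log10 EC50,
slope), train an axis-aligned decision tree: entropy (information-gain)
splits with minimum leaf size 5, scikit-learn's `DecisionTreeClassifier`.
For two numeric features this produces decision surfaces equivalent in
practice to classic C4.5/J48 induction; gain-ratio and subtree-raising
refinements matter for categorical/many-feature problems, not here.
Accuracy is estimated by stratified 10-fold cross-validation (stratified
because class counts are unequal; seeded for determinism), reported per
class with the pooled confusion matrix, and the deployed model is refit on
the full training set. Mixture composition is estimated as the per-class
share of classified cells. log10(EC50) is a monotone transform, so it does
not change axis-aligned tree behavior, but it makes reported split
thresholds interpretable as decades of concentration.

## Pipeline and determinism

Stages communicate through plain-text files (CSV tables, JSON reports and
sidecars, YAML scenarios, multi-page TIFF for images). All randomness
derives from one global seed through named substreams
(`SeedSequence([seed, crc32(tag)])`), so every artifact is bit-identical
across reruns with the same configuration; the run manifest records
per-stage counts and SHA-256 hashes of every output. Figures (plate color
map, box plots) are opt-in; data behind every figure is always written as
CSV.

## Problem sizes

Validation uses wells of 100–300 cells (the density such fields typically
contain), 200 cells per isoform for recovery benchmarks, a 403-cell
training set and 500-cell mixtures for phenotyping, and a three-well demo
plate for end-to-end runs — sizes at which every quantity the tests assert
is stable under the seeds used.

## Known limitations

* Touching cells are not split (no watershed); the generator never places
  overlapping cells, so this path is untested by design.
* The fitter assumes a monotone single-site quench; biphasic or
  potentiating responses are out of scope.
* Filter windows are fixed empirical constants, not learned.
* The t-test default (raw EC50s, pooled variance) mirrors field convention
  rather than the statistically optimal choice; use `log_scale=True` /
  `welch=True` when the question demands it.
* Unsupervised discovery of an unknown number of subpopulations is not
  implemented; classification requires labeled pure-population training
  wells.
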