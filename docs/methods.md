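# Methods

## The segmentation model

A lesion on a 2D transversal PET slice is delineated by thresholding: the
region is the 8-connected component of `{intensity >= Threshold}` inside a
rectangular ROI that contains the ROI's hottest pixel. The threshold is not
fixed but produced by a *threshold-adjustment function* — a fitted mapping
from image-derived parameters to the threshold expressed as a percentage of
the region's mean intensity,

    %Tmean = 100 · Threshold / Tmean .

Predictors are intensity ratios against the lung background minimum `Bmin`
(`Tmean/Bmin` or `Tmax/Bmin`). `Bmin` is an empirical parameter: it needs no
manual background region (the lung mask comes from CT), which makes the
procedure fully repeatable on the same image. Eight published function
forms are bundled with their original coefficients: power laws on
`Tmean/Bmin` (#1, #5) and on `Tmax/Bmin` (#2, #6), linear `Tmax(Tmean)`
laws (#3, #7), and the composed forms (#4 = #2∘#3, #8 = #6∘#7) that
eliminate `Tmax` so the function can be driven by `Tmean` alone:

    %Tmean = A · (s·Tmean/Bmin + i/Bmin)^B .

Because `%Tmean` is a function of the region it defines, segmentation is a
fixed-point iteration: seed `Tmean := Tmax` of the ROI, compute
`Threshold = round(%Tmean/100 · Tmean)`, extract the region, re-measure
`Tmean`, repeat. The iteration stops when the *pixel set* repeats
(convergence), when a previously visited pixel set recurs without being the
immediate predecessor (a cycle — reported with `converged=False` rather
than silently averaged), or at `max_iter` (default 100; clinical and
synthetic cases converge in 2–4). Using the pixel set rather than the
floating-point `Tmean` as state identity makes the stopping rule exact and
immune to floating-point near-misses.

Assumptions worth stating: intensities are non-negative integers (gray
levels), the lesion is the hottest structure in its ROI, `Bmin > 0`, and a
single transversal slice represents the lesion (the slice with the greatest
segmented area; `select_slice` implements that choice).

## Calibration

For a reference lesion the calibration sweeps every unique intensity inside
the ROI as a candidate initial threshold (iTH). The candidate ladder of
unique pixel values visits every achievable region exactly once, so no
granularity parameter is needed. Thresholds whose region best matches the
reference — closest area to the CT-delineated area, or closest major axis
to the histological major axis — form the accepted set (aTH); *all* global
minimizers of the absolute difference are accepted, and the working
Threshold is the midpoint `(min aTH + max aTH)/2`. `Tmean`/`Tmax` are
measured on the region extracted at that midpoint (the alternative,
averaging per-aTH measurements, differs only within the accepted run of an
area-monotone ladder). For axis-calibrated samples the recorded PET area is
the mean area over the accepted thresholds.

Regression families available for fitting (x = predictor ratio,
y = %Tmean): linear, exponential, logarithmic, power, and quadratic
polynomial. Power and exponential laws are fitted by linear least squares
after a log transform — the spreadsheet trend-line convention, matched so
that refitted coefficients are comparable with the published ones — and R²
is always computed on the original y scale so transformed fits compete
fairly. The family with the largest R² wins; ties within 1e−12 go to the
earlier family in the declared order, making selection deterministic. A
moving average is not a closed-form predictor and cannot serve as a
threshold-adjustment function, so it is not offered. Composed models are
constructed, not fitted; `composed_r_squared` scores them as
1 − SSres/SStot against observed (Tmean, Bmin, %Tmean) triples.

## Validation metrics

`ΔVs(a, b) = 100·(a − b)/b` is the signed relative difference of a
measurement against its reference. The bundled validation tables (27
lesions split at a 20 mm histological axis) ship as CSV fixtures; every
published ΔVs cell reproduces from the raw columns to ±0.1 after 1-decimal
rounding (ties away from zero). Column summaries use the **population**
standard deviation (n in the denominator): the published spreads only
reproduce under that convention (e.g. 22.07 → ±22.1 and 9.03 → ±9.0, where
sample SD would give 23.3 and 9.3); the choice is asserted by a test, not
assumed. Uptake heterogeneity is summarized by COV = SD/mean of the
delineated region, also with population SD.

Degenerate operating points are reported, not hidden: a predicted
`%Tmean >= 100` (possible for small lesions at low `Tmean/Bmin`) collapses
the region to the single hottest pixel and sets `degenerate=True`,
mirroring the method's documented small-lesion failure mode.

## Synthetic phantoms

`generate_phantom` builds a paired CT/PET slice: a crisp elliptical lesion
(ground-truth mask, area, and max-pairwise-center major axis measured at CT
resolution, default 1 mm) inside a low-activity lung field with a
higher-activity body rim. The PET channel applies, in order: Gaussian PSF
blur at CT resolution (FWHM 7 mm, a typical clinical PET resolution), box
averaging down to the PET grid (4×4 mm² pixels) — blur happens in the
scanner before detector binning, so the order matters — then additive
Gaussian noise, clipping at zero, and rounding to integer gray levels.
Lesion uptake carries a smooth multiplicative texture (correlated Gaussian
field, correlation length 8 mm, fractional SD 0.2 by default) so delineated
regions show COV values in the clinically reported 0.1–0.4 range; a flat
ellipse cannot reproduce those.

Cohort generation (`generate_cohort`) draws geometry and activities from
ranges chosen to land on clinical operating points: lesion diameters
10–45 mm, lung background 250–650 with noise SD 10–30 (placing `Bmin` in
the clinical 150–780 range), and lesion activity coupled to size
(base 4000–9000 plus 250 counts per mm of diameter above 10 mm), which
reproduces the reported pattern that small lesions present mean intensities
around 2000–7000 and large ones up to ~19000. The lesion center is
jittered by up to half a PET pixel (±2 mm) so lesions sit randomly relative
to the detector grid; pinning every lesion to a pixel-corner junction is a
measurable artifact (it splits the peak four ways and systematically
changes small-lesion fixed points). All randomness flows from one explicit
seed; cohorts are bit-reproducible.

What the phantom deliberately does not model: respiratory motion, Poisson
counting statistics, reconstruction artifacts, and anatomical background
texture. Consequently the synthetic small-lesion failure is *milder* than
the clinical one: at half-max thresholds sub-resolution lesions
(10–14 mm) spill outward strongly while the bias fades toward 20 mm, and
with a calibrated function the 12–20 mm class shows a positive mean area
bias with large scatter, whereas clinically the overestimation (attributed
to partial volume effects and residual respiratory motion) is larger and
more uniform. Passing tests therefore demonstrate the algorithmic
machinery and the blur-driven size bias, not the full clinical error
budget.

## Numerical choices

- Pixel inclusion is `intensity >= threshold`, so thresholding at `Tmax`
  always retains the maximum pixel; connectivity is 8-neighbor; the
  component anchor is the ROI's maximum pixel with row-major tie-break.
- The major axis is the maximum Euclidean distance between member pixel
  centers (0 for a single pixel). On a 4 mm grid this reproduces the
  granularity of reported PET axes (14.4, 17.9, 25.6 …). Masks beyond 400
  pixels route through the convex hull before the pairwise scan.
- Thresholds are rounded to the nearest integer gray level, ties away from
  zero; `%Tmean` output is never clamped.
- "Closest to the reference" is absolute difference with a 1e−9 tie
  tolerance; polynomial degree is fixed at 2.
- Calibration measures `Tmean`/`Tmax` at the midpoint Threshold; `Bmin` is
  taken over the full lung mask including the lesion (a hot lesion cannot
  contain the lung minimum).
- Image spacing is always explicit (NIfTI header or sidecar/flags); areas
  are exact pixel-count multiples of dx·dy. Reported clinical areas that
  are not multiples of 16 mm² imply per-exam pixel sizes, so spacing is a
  required input with a 4×4 mm² default in the phantom only.

## Problem sizes

The test suite exercises the full pipeline at sizes chosen for fast,
deterministic runs: 48×48-pixel PET grids (192 mm field), cohorts of 30
calibration + 10–15 held-out phantoms for the round-trip accuracy checks,
20 phantoms for the fixed-point oracle sweep, and 100 replicates for
regression-recovery statistics. The whole suite completes in a few seconds
on one CPU.

## Known limitations

- Strictly 2D, single-slice: no volumetric segmentation or 3D axes.
- The fixed-point iteration seeded at `Tmax` descends onto the
  highest-threshold fixed point; when several fixed points exist (shallow,
  sub-resolution lesions) it picks the smallest such region, which is one
  mechanism behind small-lesion variance.
- Published coefficients are rounded to the printed precision, so
  worked-example `%Tmean` values reproduce to ±0.5 percentage points, not
  exactly.
- No uncertainty propagation on fitted coefficients, and no hypothesis
  testing on the validation tables (descriptive means/SDs only).
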