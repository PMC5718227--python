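# petthresh

Adaptive-threshold delineation of lung tumors on FDG-PET slices, with
threshold-adjustment functions calibrated from patient-derived references
(CT lesion areas or histological major axes) instead of phantom scans.

Delineating a tumor on a PET image means choosing an intensity threshold,
and no single fixed percentage works: the right cut-off depends on the
lesion's contrast against the lung background. This package implements an
adaptive strategy in which a fitted **threshold-adjustment function** maps
image-derived parameters to the threshold, expressed as a percentage of the
mean target intensity:

    %Tmean = 100 · Threshold / Tmean

with predictors `Tmean/Bmin` or `Tmax/Bmin`, where `Tmean`/`Tmax` are the
mean/maximum intensity of the segmented region and `Bmin` is the minimum
intensity inside the lung fields — an empirical background parameter that
needs no manual background ROI. Eight published function forms are built
in, e.g. the power law `%Tmean = 130.9·(Tmean/Bmin)^-0.23` and the composed
form `%Tmean = 136.09·[1.64·(Tmean/Bmin) − 1634.8/Bmin]^-0.22`.

Because `%Tmean` depends on the very region being segmented, segmentation is
a fixed-point iteration: seed `Tmean := Tmax`, compute the threshold, extract
the region growing from the hottest pixel, re-measure `Tmean`, and repeat
until the pixel set stops changing.

The package covers the full workflow:

- **imaging** — region statistics (Tmean, Tmax, area, Feret-style major
  axis, COV), thresholded connected regions, lung background minimum;
- **models** — the eight built-in threshold-adjustment functions,
  evaluation, composition, (de)serialization;
- **calibration** — accepted-threshold (aTH) sweeps against CT-area or
  histology-axis references, regression fitting (linear, exponential,
  logarithmic, power, quadratic) with R²-based family selection;
- **segmentation** — the iterative fixed-point algorithm with a full
  per-iteration trace, plus the per-lesion validation table (ΔVs, COV);
- **metrics** — relative differences ΔVs = 100·(a−b)/b, table summaries,
  difference surfaces between two functions;
- **phantom** — a synthetic PET/CT phantom generator (Gaussian PSF,
  detector binning, noise, uptake heterogeneity) so the whole pipeline is
  testable without patient data.

## Worked example

Segment a synthetic lesion with built-in function #4:

```python
import petthresh as pt

phantom = pt.generate_phantom(pt.PhantomSpec(a_mm=16, b_mm=12, seed=42))
lung = pt.LungContext.from_image(phantom.pet, phantom.lung_mask)
result = pt.segment_iterative(
    phantom.pet, lung, phantom.roi, pt.predefined_model(4)
)
for rec in result.trace:
    print(f"iter {rec.iteration}: %Tmean={rec.pct_tmean:.2f} "
          f"threshold={rec.threshold} Tmean={rec.t_mean:.1f} "
          f"pixels={rec.n_pixels}")
print(f"area={result.stats.area_mm2:.0f} mm^2 "
      f"(truth {phantom.truth_area_mm2:.0f} mm^2), "
      f"axis={result.stats.major_axis_mm:.1f} mm, cov={result.stats.cov:.2f}")
```

prints

```
iter 1: %Tmean=54.10 threshold=7703 Tmean=11405.5 pixels=36
iter 2: %Tmean=57.05 threshold=6506 Tmean=11405.5 pixels=36
area=576 mm^2 (truth 604 mm^2), axis=28.3 mm, cov=0.19
```

The first iteration seeds `Tmean` with the region maximum, so its threshold
is too high; as the measured mean drops the threshold relaxes, and the loop
stops as soon as the 36-pixel region maps back onto itself.  The recovered
area misses the ground truth by −4.6% — within the accuracy regime the
validation tables report for lesions above 20 mm.

The same run from the shell:

```
petthresh segment --image pet.nii --lung-mask lung.nii \
    --roi 14,34,14,34 --model predefined:4 --out mask.nii --trace trace.csv
```

Validation tables bundled with the package (the 27-lesion clinical
validation split at a 20 mm histological axis) are summarized with
`petthresh tables --fixture table2`, and the two composed functions are
compared over their printed operating points with
`petthresh compare-functions --points table1,table2`.

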