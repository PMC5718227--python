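"""Iterative fixed-point segmentation driven by a threshold-adjustment function.

The loop alternates between predicting a threshold from the current region
mean and re-extracting the region at that threshold:

1. seed ``Tmean := Tmax`` of the ROI;
2. ``%Tmean = f(Tmean, Bmin)`` from the model, ``Threshold = round(%Tmean/100 * Tmean)``;
3. grow the region at ``Threshold`` from the ROI's hottest pixel and
   re-measure ``Tmean``;
4. repeat until the pixel set stops changing.

State identity for convergence/cycle detection is the pixel set itself, not
the floating-point Tmean, which makes the stopping rule exact.  A threshold
above the ROI maximum (possible when the model returns %Tmean >= 100 at a
small Tmean/Bmin operating point) collapses the region to the single hottest
pixel and flags the result degenerate — small lesions are reported as
mis-segmented rather than silently clamped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import metrics
from .errors import GeometryError
from .imaging import (
    ImageSlice2D,
    LungContext,
    RegionMask,
    RegionStats,
    Roi,
    region_stats,
    threshold_region,
    _check_roi,
)
from .models import ThresholdFunctionModel, evaluate_pct, threshold_from_pct

__all__ = ["IterationRecord", "SegmentationResult", "segment_iterative", "run_validation"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class IterationRecord:
    """One pass of the threshold -> region -> Tmean loop."""

    iteration: int
    pct_tmean: float
    threshold: int
    t_mean: float
    n_pixels: int


@dataclass(frozen=True)
class SegmentationResult:
    """Final region plus the full iteration trace.

    ``converged`` is True when the pixel set reached a fixed point (the last
    two trace records describe the same region); False when a cycle was
    detected or ``max_iter`` ran out.  ``degenerate`` marks runs where the
    predicted threshold exceeded the ROI maximum at some step.
    """

    mask: RegionMask
    stats: RegionStats
    trace: tuple[IterationRecord, ...]
    converged: bool
    degenerate: bool


def segment_iterative(
    image: ImageSlice2D,
    lung: LungContext,
    roi: Roi,
    model: ThresholdFunctionModel,
    max_iter: int = 100,
    initial_t_mean: float | None = None,
) -> SegmentationResult:
    """Run the fixed-point segmentation on one ROI of one PET slice.

    The model must predict %Tmean from Tmean/Bmin (power-family on
    ``tmean_over_bmin`` or composed); Bmin is taken from ``lung`` and stays
    fixed across iterations.  By default the first iteration imposes
    ``Tmean := Tmax`` of the ROI; ``initial_t_mean`` overrides the seed
    (e.g. to resume from a converged state).  Deterministic: identical
    inputs produce identical traces.
    """
    if model.predictor not in ("tmean_over_bmin",):
        raise GeometryError(
            "segment_iterative needs a %Tmean model on tmean_over_bmin "
            f"(got predictor {model.predictor!r})"
        )
    r0, r1, c0, c1 = _check_roi(image, roi)
    t_max = float(image.values[r0:r1, c0:c1].max())
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")

    # first-iteration seed: Tmean imposed equal to Tmax unless overridden
    t_mean = t_max if initial_t_mean is None else float(initial_t_mean)
    trace: list[IterationRecord] = []
    seen: dict[bytes, int] = {}
    mask: RegionMask | None = None
    converged = False
    degenerate = False

    for i in range(1, max_iter + 1):
        pct = evaluate_pct(model, t_mean, lung.b_min)
        threshold = threshold_from_pct(pct, t_mean)
        if threshold > t_max:
            # Degenerate operating point: keep only the hottest pixel.
            degenerate = True
            mask = threshold_region(image, roi, t_max)
            single = np.zeros(image.shape, dtype=bool)
            rows, cols = np.nonzero(mask.array)
            flat = rows * image.shape[1] + cols
            peak = flat[np.argmax(image.values[rows, cols])]
            single[peak // image.shape[1], peak % image.shape[1]] = True
            mask = RegionMask(single)
        else:
            mask = threshold_region(image, roi, threshold)
        vals = image.values[mask.array]
        t_mean = float(vals.mean())
        trace.append(
            IterationRecord(
                iteration=i,
                pct_tmean=pct,
                threshold=threshold,
                t_mean=t_mean,
                n_pixels=int(vals.size),
            )
        )
        key = mask.key()
        prev = seen.get(key)
        if prev is not None:
            if prev == i - 1:  # immediate repeat: fixed point
                converged = True
            else:  # revisited an older state: cycle
                logger.warning(
                    "segmentation cycled back to iteration %d state at iteration %d",
                    prev,
                    i,
                )
                converged = False
            break
        seen[key] = i

    assert mask is not None
    return SegmentationResult(
        mask=mask,
        stats=region_stats(image, mask),
        trace=tuple(trace),
        converged=converged,
        degenerate=degenerate,
    )


#: run_validation reference column -> (PET column, ΔVs output column)
_COMPARISONS = [
    ("maaxis_pet_mm", "maaxis_hist_mm", "dvs_maaxis_pet_hist"),
    ("maaxis_ct_mm", "maaxis_hist_mm", "dvs_maaxis_ct_hist"),
    ("maaxis_pet_mm", "maaxis_ct_mm", "dvs_maaxis_pet_ct"),
    ("area_pet_mm2", "area_ct_mm2", "dvs_area_pet_ct"),
]


def run_validation(records) -> pd.DataFrame:
    """Build the per-lesion validation table from segmented measurements.

    ``records`` is an iterable of mappings (or a DataFrame) with measured
    columns ``maaxis_pet_mm``, ``area_pet_mm2``, ``cov`` and whichever
    reference columns are available (``maaxis_hist_mm``, ``maaxis_ct_mm``,
    ``area_ct_mm2``).  Each available (measurement, reference) pair yields a
    signed relative difference column; records with no reference at all are
    skipped with a warning.  Lesions are grouped by histological major axis
    at 20 mm (``<=20mm`` vs ``20-45mm``), mirroring the small/large split
    used for validation.
    """
    df = pd.DataFrame(records)
    if df.empty:
        return df
    keep = []
    for idx, row in df.iterrows():
        has_ref = any(
            pd.notna(row.get(ref)) for _, ref, _ in _COMPARISONS
        )
        if not has_ref:
            logger.warning("record %r has no reference measurement; skipped", idx)
            continue
        keep.append(idx)
    df = df.loc[keep].copy()
    for a_col, b_col, out_col in _COMPARISONS:
        if a_col in df.columns and b_col in df.columns:
            df[out_col] = [
                metrics.delta_vs(a, b) if pd.notna(a) and pd.notna(b) and b > 0 else np.nan
                for a, b in zip(df[a_col], df[b_col])
            ]
    if "maaxis_hist_mm" in df.columns:
        df["size_group"] = np.where(
            df["maaxis_hist_mm"] <= 20.0, "<=20mm", "20-45mm"
        )
        df.loc[df["maaxis_hist_mm"].isna(), "size_group"] = "ungrouped"
    return df
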