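"""Calibration of threshold-adjustment functions from reference measurements.

For each reference lesion the calibration scans every achievable threshold
(the "iTH ladder" — all unique intensities inside the lesion ROI), extracts
the region at each, and accepts the thresholds (aTH) whose region best
matches the reference: closest area to the CT-measured area, or closest
major axis to the histological major axis.  The working Threshold of the
lesion is the midpoint of the accepted set, and the sample records the
region's Tmean/Tmax, the lung background minimum Bmin, and
%Tmean = 100*Threshold/Tmean.

Regression families (linear, exponential, logarithmic, power, quadratic
polynomial) can then be fitted to (predictor, %Tmean) samples; the family
with the largest coefficient of determination — always computed on the
original %Tmean scale — is retained.  Power and exponential fits use the
spreadsheet convention of linear least squares after a log transform.  A
moving average is not a closed-form predictor and therefore cannot serve as
a threshold-adjustment function; it is not offered as a fittable family.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import (
    DegenerateFitError,
    ModelDomainError,
    NoFeasibleThresholdError,
    NoLesionFoundError,
)
from .imaging import (
    ImageSlice2D,
    LungContext,
    Roi,
    major_axis,
    region_stats,
    threshold_region,
    _check_roi,
)
from .models import ThresholdFunctionModel, evaluate_pct
from .segmentation import segment_iterative

__all__ = [
    "CalibrationSample",
    "RegressionFit",
    "FAMILY_ORDER",
    "accepted_thresholds_area",
    "accepted_thresholds_axis",
    "fit_family",
    "select_best",
    "composed_r_squared",
    "select_slice",
]

#: Deterministic fitting/tie-break order for select_best.
FAMILY_ORDER = ("linear", "exponential", "logarithmic", "power", "polynomial2")

#: Tolerance for "equally close to the reference" when collecting aTH.
_TIE_ATOL = 1e-9


@dataclass(frozen=True)
class CalibrationSample:
    """One reference lesion's calibration record.

    ``threshold`` is the midpoint of the accepted-threshold (aTH) range;
    Tmean/Tmax are measured on the region extracted at that midpoint, and
    ``pct_tmean`` = 100*threshold/t_mean.  ``area_pet_mm2`` is the region
    area at the midpoint for area-calibrated samples, and the mean area over
    the accepted thresholds for axis-calibrated samples.
    """

    reference_kind: str  # "ct_area" | "hist_axis"
    reference_value: float  # mm^2 or mm
    ath_min: float
    ath_max: float
    threshold: float
    t_mean: float
    t_max: float
    b_min: float
    pct_tmean: float
    area_pet_mm2: float

    def __post_init__(self) -> None:
        if not (self.ath_min <= self.threshold <= self.ath_max):
            raise ValueError("threshold must lie within [ath_min, ath_max]")


@dataclass(frozen=True)
class RegressionFit:
    """Best-family regression outcome: model, residuals, per-family R²."""

    model: ThresholdFunctionModel
    residuals: tuple[float, ...]
    family_scores: dict[str, float]


def _ith_ladder(image: ImageSlice2D, roi: Roi) -> np.ndarray:
    r0, r1, c0, c1 = _check_roi(image, roi)
    return np.unique(image.values[r0:r1, c0:c1])


def _accepted_thresholds(
    image: ImageSlice2D,
    roi: Roi,
    lung: LungContext,
    kind: str,
    reference_value: float,
    metric,
) -> CalibrationSample:
    """Shared iTH-sweep machinery; ``metric(mask) -> (score, area_mm2)``."""
    if reference_value < 0:
        raise ValueError("reference value must be non-negative")
    candidates: list[tuple[float, float, float]] = []  # (iTH, |score|, area)
    for ith in _ith_ladder(image, roi):
        mask = threshold_region(image, roi, float(ith))
        if mask.is_empty:
            continue
        score, area = metric(mask)
        candidates.append((float(ith), abs(score), area))
    if not candidates:
        raise NoFeasibleThresholdError("no threshold produced a non-empty region")
    best = min(score for _, score, _ in candidates)
    accepted = [(ith, area) for ith, score, area in candidates if score - best <= _TIE_ATOL]
    ath_values = [ith for ith, _ in accepted]
    ath_min, ath_max = min(ath_values), max(ath_values)
    threshold = (ath_min + ath_max) / 2.0
    stats = region_stats(image, threshold_region(image, roi, threshold))
    if kind == "hist_axis":
        area_pet = float(np.mean([area for _, area in accepted]))
    else:
        area_pet = stats.area_mm2
    return CalibrationSample(
        reference_kind=kind,
        reference_value=float(reference_value),
        ath_min=ath_min,
        ath_max=ath_max,
        threshold=threshold,
        t_mean=stats.t_mean,
        t_max=stats.t_max,
        b_min=lung.b_min,
        pct_tmean=100.0 * threshold / stats.t_mean,
        area_pet_mm2=area_pet,
    )


def accepted_thresholds_area(
    image: ImageSlice2D, roi: Roi, lung: LungContext, area_ct: float
) -> CalibrationSample:
    """Calibrate one lesion against its CT-measured area (mm²).

    Every unique ROI intensity is tried as an initial threshold; the
    thresholds whose region area is closest to ``area_ct`` (all global
    minimizers of the absolute difference) form the accepted set.
    """
    if area_ct <= 0:
        raise ValueError("area_ct must be positive")

    def metric(mask):
        area = mask.n_pixels * image.pixel_area_mm2
        return area - area_ct, area

    return _accepted_thresholds(image, roi, lung, "ct_area", area_ct, metric)


def accepted_thresholds_axis(
    image: ImageSlice2D, roi: Roi, lung: LungContext, maaxis_hist: float
) -> CalibrationSample:
    """Calibrate one lesion against its histological major axis (mm)."""

    def metric(mask):
        axis = major_axis(mask, image.dx, image.dy)
        return axis - maaxis_hist, mask.n_pixels * image.pixel_area_mm2

    return _accepted_thresholds(image, roi, lung, "hist_axis", maaxis_hist, metric)


def _r_squared(y: np.ndarray, pred: np.ndarray) -> float:
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0.0:
        raise DegenerateFitError("zero variance in the response")
    ss_res = float(((y - pred) ** 2).sum())
    return 1.0 - ss_res / ss_tot


def fit_family(
    samples: Sequence[tuple[float, float]],
    family: str,
    predictor: str = "tmean_over_bmin",
) -> ThresholdFunctionModel:
    """Least-squares fit of one regression family to (x, y) samples.

    Power and exponential laws are fitted by ordinary least squares after a
    log transform (the spreadsheet trend-line convention); R² is always
    computed on the original y scale, so transformed fits compete fairly
    with the direct ones.
    """
    if family not in FAMILY_ORDER:
        raise ValueError(f"unknown or unfittable family {family!r}")
    pts = np.asarray(samples, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise DegenerateFitError("need at least 3 (x, y) samples")
    x, y = pts[:, 0], pts[:, 1]
    if np.ptp(x) == 0.0:
        raise DegenerateFitError("singular design: all x identical")
    if family in ("logarithmic", "power") and np.any(x <= 0):
        raise ModelDomainError(f"{family} fit requires x > 0")
    if family in ("exponential", "power") and np.any(y <= 0):
        raise ModelDomainError(f"{family} fit requires y > 0")

    if family == "linear":
        slope, intercept = np.polyfit(x, y, 1)
        coeffs = (slope, intercept)
        pred = slope * x + intercept
    elif family == "polynomial2":
        c2, c1, c0 = np.polyfit(x, y, 2)
        coeffs = (c2, c1, c0)
        pred = c2 * x**2 + c1 * x + c0
    elif family == "logarithmic":
        a, b = np.polyfit(np.log(x), y, 1)
        coeffs = (a, b)
        pred = a * np.log(x) + b
    elif family == "power":
        b, log_a = np.polyfit(np.log(x), np.log(y), 1)
        coeffs = (math.exp(log_a), b)
        pred = coeffs[0] * x**b
    else:  # exponential
        b, log_a = np.polyfit(x, np.log(y), 1)
        coeffs = (math.exp(log_a), b)
        pred = coeffs[0] * np.exp(b * x)

    return ThresholdFunctionModel(
        family=family,
        coefficients=tuple(float(c) for c in coeffs),
        predictor=predictor,
        r_squared=_r_squared(y, np.asarray(pred)),
    )


def select_best(
    samples: Sequence[tuple[float, float]],
    candidate_families: Sequence[str] = FAMILY_ORDER,
    predictor: str = "tmean_over_bmin",
) -> RegressionFit:
    """Fit every applicable family and retain the one with the largest R².

    Families whose domain excludes the data (e.g. a power law with negative
    y) are skipped.  Ties within 1e-12 go to the earlier family in
    ``candidate_families``, making selection deterministic.
    """
    scores: dict[str, float] = {}
    fits: dict[str, ThresholdFunctionModel] = {}
    for family in candidate_families:
        try:
            model = fit_family(samples, family, predictor)
        except ModelDomainError:
            continue
        fits[family] = model
        scores[family] = model.r_squared
    if not fits:
        raise DegenerateFitError("no family applicable to these samples")
    best_score = max(scores.values())
    best_family = next(
        fam for fam in candidate_families
        if fam in scores and best_score - scores[fam] <= 1e-12
    )
    model = fits[best_family]
    pts = np.asarray(samples, dtype=float)
    x, y = pts[:, 0], pts[:, 1]
    pred = np.array([_predict(model, xi) for xi in x])
    return RegressionFit(
        model=model,
        residuals=tuple(float(r) for r in (y - pred)),
        family_scores=scores,
    )


def _predict(model: ThresholdFunctionModel, x: float) -> float:
    c = model.coefficients
    if model.family == "linear":
        return c[0] * x + c[1]
    if model.family == "polynomial2":
        return c[0] * x**2 + c[1] * x + c[2]
    if model.family == "logarithmic":
        return c[0] * math.log(x) + c[1]
    if model.family == "power":
        return c[0] * x ** c[1]
    if model.family == "exponential":
        return c[0] * math.exp(c[1] * x)
    raise ValueError(f"cannot predict with family {model.family!r}")


def composed_r_squared(
    model: ThresholdFunctionModel,
    samples: Sequence[tuple[float, float, float]],
) -> float:
    """R² of a model's %Tmean predictions against observed (Tmean, Bmin, %Tmean).

    This is the "manual" coefficient of determination used for composed
    functions, which are constructed rather than fitted: 1 - SSres/SStot on
    the observed %Tmean.
    """
    if len(samples) < 3:
        raise DegenerateFitError("need at least 3 samples")
    obs = np.array([s[2] for s in samples], dtype=float)
    pred = np.array([evaluate_pct(model, t, b) for t, b, _ in samples])
    return _r_squared(obs, pred)


def select_slice(
    slices: Sequence[ImageSlice2D],
    lungs: Sequence[LungContext],
    roi: Roi,
    model: ThresholdFunctionModel,
    max_iter: int = 100,
) -> int:
    """Index of the stack slice whose segmented lesion area is greatest.

    Each slice is segmented with the iterative algorithm; degenerate results
    (single-pixel collapse) do not count as lesions.  Ties go to the lowest
    index.  Used to pick the single transversal slice retained per lesion.
    """
    if len(slices) == 0:
        raise NoLesionFoundError("empty slice stack")
    if len(lungs) != len(slices):
        raise ValueError("need one lung context per slice")
    best_index: int | None = None
    best_area = -math.inf
    for idx, (image, lung) in enumerate(zip(slices, lungs)):
        try:
            result = segment_iterative(image, lung, roi, model, max_iter=max_iter)
        except ModelDomainError:
            continue
        if result.degenerate:
            continue
        if result.stats.area_mm2 > best_area:
            best_index = idx
            best_area = result.stats.area_mm2
    if best_index is None:
        raise NoLesionFoundError("all slices segmented degenerately")
    return best_index
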