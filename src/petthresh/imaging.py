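"""Pixel-level measurements on masked regions of 2D PET/CT slices.

The segmentation strategy works on a single transversal slice at a time.
Everything here is deliberately exact and convention-explicit, because the
calibration and segmentation stages reason about individual gray levels:

* pixel inclusion at a threshold is ``intensity >= threshold``, so thresholding
  at the region maximum always keeps at least the maximum pixel;
* connected components are 8-connected, anchored at the ROI's
  maximum-intensity pixel (ties broken in row-major order);
* the major axis of a region is the maximum Euclidean distance between pixel
  *centers*, in millimetres (0 for a single pixel) — a Feret-style diameter on
  the pixel lattice;
* COV (coefficient of variation, the uptake-heterogeneity proxy) is the
  population standard deviation divided by the mean.

Coordinates are 0-based and row-major; a rectangular ROI is the half-open box
``[row0, row1) x [col0, col1)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist

from .errors import EmptyRegionError, GeometryError

__all__ = [
    "ImageSlice2D",
    "RegionMask",
    "RegionStats",
    "LungContext",
    "region_stats",
    "min_in_mask",
    "threshold_region",
    "major_axis",
]

#: 8-neighbour connectivity structure for component labelling.
_EIGHT_CONNECTED = np.ones((3, 3), dtype=bool)

Roi = tuple[int, int, int, int]


@dataclass(frozen=True)
class ImageSlice2D:
    """A rectangular grid of non-negative intensities with physical spacing.

    Parameters
    ----------
    values
        2D array of finite, non-negative intensities (arbitrary PET counts
        or CT activity units).
    dx, dy
        Pixel width / height in millimetres (column / row spacing).
    """

    values: np.ndarray
    dx: float
    dy: float

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2 or values.size == 0:
            raise GeometryError("image must be a non-empty 2D grid")
        if not np.all(np.isfinite(values)):
            raise GeometryError("image intensities must be finite")
        if np.any(values < 0):
            raise GeometryError("image intensities must be non-negative")
        if not (self.dx > 0 and self.dy > 0):
            raise GeometryError("pixel spacing must be positive")
        values = values.copy()
        values.setflags(write=False)
        object.__setattr__(self, "values", values)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def pixel_area_mm2(self) -> float:
        return self.dx * self.dy


@dataclass(frozen=True)
class RegionMask:
    """Boolean membership grid paired (by shape) with an :class:`ImageSlice2D`."""

    array: np.ndarray

    def __post_init__(self) -> None:
        array = np.asarray(self.array, dtype=bool)
        if array.ndim != 2 or array.size == 0:
            raise GeometryError("mask must be a non-empty 2D grid")
        array = array.copy()
        array.setflags(write=False)
        object.__setattr__(self, "array", array)

    @property
    def shape(self) -> tuple[int, int]:
        return self.array.shape

    @property
    def n_pixels(self) -> int:
        return int(self.array.sum())

    @property
    def is_empty(self) -> bool:
        return not self.array.any()

    def key(self) -> bytes:
        """Hashable identity of the pixel set (used for fixed-point detection)."""
        return np.packbits(self.array).tobytes()


@dataclass(frozen=True)
class RegionStats:
    """Summary measurements of a segmented region.

    ``t_mean``/``t_max`` are the mean and maximum intensity (the Tmean/Tmax
    parameters of the threshold-adjustment functions), ``area_mm2`` the
    pixel-count area, ``major_axis_mm`` the maximum pixel-center distance,
    and ``cov`` the population-SD/mean coefficient of variation.
    """

    t_mean: float
    t_max: float
    area_mm2: float
    major_axis_mm: float
    cov: float
    n_pixels: int


@dataclass(frozen=True)
class LungContext:
    """Lung field on the PET slice plus its minimum intensity Bmin.

    Bmin — the minimum intensity over the lung mask — is the empirical
    background parameter of the threshold-adjustment functions.  The lung
    mask may include the lesion: a hot lesion can never contain the lung
    minimum, so the inclusion is harmless.
    """

    lung_mask: RegionMask
    b_min: float

    @classmethod
    def from_image(cls, image: ImageSlice2D, lung_mask: RegionMask) -> "LungContext":
        return cls(lung_mask=lung_mask, b_min=min_in_mask(image, lung_mask))


def _check_pairing(image: ImageSlice2D, mask: RegionMask) -> None:
    if image.shape != mask.shape:
        raise GeometryError(
            f"mask shape {mask.shape} does not match image shape {image.shape}"
        )


def _check_roi(image: ImageSlice2D, roi: Roi) -> Roi:
    r0, r1, c0, c1 = (int(v) for v in roi)
    nr, nc = image.shape
    if not (0 <= r0 < r1 <= nr and 0 <= c0 < c1 <= nc):
        raise GeometryError(
            f"roi [{r0},{r1})x[{c0},{c1}) is degenerate or outside a "
            f"{nr}x{nc} image"
        )
    return r0, r1, c0, c1


def _max_pairwise_distance_mm(rows: np.ndarray, cols: np.ndarray, dx: float, dy: float) -> float:
    if rows.size == 1:
        return 0.0
    pts = np.column_stack([cols * dx, rows * dy]).astype(float)
    if len(pts) > 400:
        # The diameter is attained on the convex hull; reduce before pdist.
        try:
            pts = pts[ConvexHull(pts).vertices]
        except QhullError:
            pass  # collinear masks: brute force is fine
    return float(pdist(pts).max())


def major_axis(mask: RegionMask, dx: float, dy: float) -> float:
    """Maximum Euclidean distance (mm) between centers of any two member pixels.

    Invariant under translation, and under 90-degree rotation when dx == dy.
    """
    if not (dx > 0 and dy > 0):
        raise GeometryError("pixel spacing must be positive")
    rows, cols = np.nonzero(mask.array)
    if rows.size == 0:
        raise EmptyRegionError("major_axis of an empty region")
    return _max_pairwise_distance_mm(rows, cols, dx, dy)


def region_stats(image: ImageSlice2D, mask: RegionMask) -> RegionStats:
    """Exact measurements of the masked region: Tmean, Tmax, area, axis, COV."""
    _check_pairing(image, mask)
    if mask.is_empty:
        raise EmptyRegionError("region_stats of an empty region")
    vals = image.values[mask.array]
    t_mean = float(vals.mean())
    sd = float(vals.std(ddof=0))
    cov = sd / t_mean if t_mean > 0 else 0.0
    return RegionStats(
        t_mean=t_mean,
        t_max=float(vals.max()),
        area_mm2=vals.size * image.pixel_area_mm2,
        major_axis_mm=major_axis(mask, image.dx, image.dy),
        cov=cov,
        n_pixels=int(vals.size),
    )


def min_in_mask(image: ImageSlice2D, mask: RegionMask) -> float:
    """Minimum intensity over the masked pixels (Bmin when the mask is a lung)."""
    _check_pairing(image, mask)
    if mask.is_empty:
        raise EmptyRegionError("min_in_mask of an empty region")
    return float(image.values[mask.array].min())


def roi_max(image: ImageSlice2D, roi: Roi) -> float:
    """Maximum intensity inside the ROI (the Tmax seed of the iteration)."""
    r0, r1, c0, c1 = _check_roi(image, roi)
    return float(image.values[r0:r1, c0:c1].max())


def threshold_region(image: ImageSlice2D, roi: Roi, threshold: float) -> RegionMask:
    """Region grown from the ROI's hottest pixel at a given threshold.

    Returns the 8-connected component of ``{pixels in roi with intensity >=
    threshold}`` containing the ROI's maximum-intensity pixel (row-major tie
    break).  If even that pixel is below the threshold the mask is empty.
    """
    r0, r1, c0, c1 = _check_roi(image, roi)
    sub = image.values[r0:r1, c0:c1]
    anchor = int(np.argmax(sub))  # first maximum in row-major order
    ar, ac = divmod(anchor, sub.shape[1])
    full = np.zeros(image.shape, dtype=bool)
    if sub[ar, ac] < threshold:
        return RegionMask(full)
    labels, _ = ndimage.label(sub >= threshold, structure=_EIGHT_CONNECTED)
    full[r0:r1, c0:c1] = labels == labels[ar, ac]
    return RegionMask(full)
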