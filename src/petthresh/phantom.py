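"""Synthetic PET/CT phantom slices with known lesion geometry.

Each phantom is a 2D transversal "slice" containing one elliptical lesion
inside a low-activity lung field, surrounded by a higher-activity body rim.
The CT channel carries the crisp, high-resolution geometry (it stands in
for the expert's manual CT delineation and provides the ground-truth mask,
area and major axis).  The PET channel emulates the physics that makes PET
delineation hard:

* the activity map is blurred at CT resolution with a Gaussian point-spread
  function (default FWHM 7 mm, a typical clinical PET resolution),
* then box-averaged down to the PET grid (default 4x4 mm² pixels) —
  scanner blur happens before detector binning, so this order matters,
* then additive Gaussian noise is applied, the result clipped at zero and
  rounded to integer gray levels.

Lesion uptake is not flat: a smooth multiplicative texture (correlated
Gaussian field) emulates intrinsic FDG-uptake heterogeneity, sized so that
delineated regions show clinically plausible coefficients of variation.
Cohort generation additionally couples lesion activity to lesion size
(larger lung lesions take up more FDG) and jitters the lesion center by a
sub-pixel offset so lesions sit randomly relative to the PET grid.

This reproduces the partial volume effect: small lesions lose peak
intensity and smear outward, which is exactly the regime in which adaptive
thresholding degrades.  What the phantom does *not* model: respiratory
motion, Poisson counting statistics, reconstruction artifacts, anatomical
background texture.

All randomness flows from the explicit ``seed`` field; no global state.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import GeometryError
from .imaging import ImageSlice2D, RegionMask, Roi, _max_pairwise_distance_mm

__all__ = ["PhantomSpec", "Phantom", "generate_phantom", "generate_cohort"]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and imaging parameters of one synthetic lesion slice.

    ``a_mm``/``b_mm`` are the lesion ellipse *semi*-axes; activities are in
    arbitrary PET counts chosen to match clinical gray-level magnitudes
    (lesions in the thousands, lung background in the hundreds).
    """

    a_mm: float = 15.0
    b_mm: float = 12.0
    rotation_deg: float = 0.0
    center_mm: tuple[float, float] = (0.0, 0.0)  # (x, y) offset from grid center
    lesion_activity: float = 10000.0
    lung_activity: float = 400.0
    body_activity: float = 1200.0
    noise_sd: float = 20.0
    heterogeneity: float = 0.2  # fractional SD of the lesion uptake texture
    texture_corr_mm: float = 8.0  # correlation length of the texture field
    psf_fwhm_mm: float = 7.0
    pet_spacing_mm: float = 4.0
    ct_spacing_mm: float = 1.0
    extent_mm: float = 192.0
    body_margin_mm: float = 16.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.a_mm > 0 and self.b_mm > 0):
            raise GeometryError("lesion semi-axes must be positive")
        if not (self.lesion_activity > self.lung_activity > 0):
            raise GeometryError("need lesion activity > lung background > 0")
        if self.psf_fwhm_mm < 0 or self.noise_sd < 0:
            raise GeometryError("psf fwhm and noise sd must be non-negative")
        if self.heterogeneity < 0 or self.texture_corr_mm <= 0:
            raise GeometryError("heterogeneity must be >= 0 with positive correlation length")
        if not (self.pet_spacing_mm > 0 and self.ct_spacing_mm > 0 and self.extent_mm > 0):
            raise GeometryError("spacings and extent must be positive")
        factor = self.pet_spacing_mm / self.ct_spacing_mm
        if abs(factor - round(factor)) > 1e-9 or round(factor) < 1:
            raise GeometryError("pet spacing must be an integer multiple of ct spacing")
        n_pet = self.extent_mm / self.pet_spacing_mm
        if abs(n_pet - round(n_pet)) > 1e-9:
            raise GeometryError("extent must be an integer number of PET pixels")


@dataclass(frozen=True)
class Phantom:
    """One generated phantom bundle."""

    spec: PhantomSpec
    pet: ImageSlice2D
    ct: ImageSlice2D
    lung_mask: RegionMask  # on the PET grid
    truth_mask_ct: RegionMask  # on the CT grid
    truth_area_mm2: float
    truth_major_axis_mm: float
    roi: Roi  # lesion ROI on the PET grid, with margin


def _pixel_centers(n: int, spacing: float, extent: float) -> np.ndarray:
    """Center coordinates (mm) of n pixels spanning [-extent/2, extent/2]."""
    return (np.arange(n) + 0.5) * spacing - extent / 2.0


def _ellipse_mask(xc: np.ndarray, yc: np.ndarray, spec: PhantomSpec) -> np.ndarray:
    xx, yy = np.meshgrid(xc - spec.center_mm[0], yc - spec.center_mm[1])
    theta = np.deg2rad(spec.rotation_deg)
    u = xx * np.cos(theta) + yy * np.sin(theta)
    v = -xx * np.sin(theta) + yy * np.cos(theta)
    return (u / spec.a_mm) ** 2 + (v / spec.b_mm) ** 2 <= 1.0


def generate_phantom(spec: PhantomSpec) -> Phantom:
    """Generate one paired PET/CT phantom slice (deterministic per seed)."""
    n_ct = int(round(spec.extent_mm / spec.ct_spacing_mm))
    xc = _pixel_centers(n_ct, spec.ct_spacing_mm, spec.extent_mm)
    lesion_ct = _ellipse_mask(xc, xc, spec)
    if not lesion_ct.any():
        raise GeometryError("lesion smaller than one CT pixel")

    margin = spec.body_margin_mm
    half = spec.extent_mm / 2.0 - margin
    lung_extent = half - spec.pet_spacing_mm  # keep blur tails off the body rim
    xx, yy = np.meshgrid(xc, xc)
    lung_ct = (np.abs(xx) <= half) & (np.abs(yy) <= half)
    if lesion_ct[~lung_ct].any():
        raise GeometryError("lesion does not fit inside the lung field")

    rng = np.random.default_rng(spec.seed)
    activity = np.where(lung_ct, spec.lung_activity, spec.body_activity)
    if spec.heterogeneity > 0:
        field_ = gaussian_filter(
            rng.normal(0.0, 1.0, activity.shape),
            spec.texture_corr_mm / spec.ct_spacing_mm,
            mode="wrap",
        )
        field_ /= field_.std()
        texture = np.clip(1.0 + spec.heterogeneity * field_, 0.2, None)
        activity[lesion_ct] = spec.lesion_activity * texture[lesion_ct]
    else:
        activity[lesion_ct] = spec.lesion_activity
    ct_img = ImageSlice2D(activity, dx=spec.ct_spacing_mm, dy=spec.ct_spacing_mm)

    # Truth from the crisp CT-resolution geometry.
    rows, cols = np.nonzero(lesion_ct)
    truth_area = rows.size * spec.ct_spacing_mm**2
    truth_axis = _max_pairwise_distance_mm(rows, cols, spec.ct_spacing_mm, spec.ct_spacing_mm)

    # PET: blur at CT resolution, bin to PET pixels, add noise, integerize.
    if spec.psf_fwhm_mm > 0:
        sigma_px = spec.psf_fwhm_mm * _FWHM_TO_SIGMA / spec.ct_spacing_mm
        blurred = gaussian_filter(activity.astype(float), sigma_px, mode="reflect")
    else:
        blurred = activity.astype(float)
    factor = int(round(spec.pet_spacing_mm / spec.ct_spacing_mm))
    n_pet = n_ct // factor
    pet_vals = blurred.reshape(n_pet, factor, n_pet, factor).mean(axis=(1, 3))
    if spec.noise_sd > 0:
        pet_vals = pet_vals + rng.normal(0.0, spec.noise_sd, pet_vals.shape)
    pet_vals = np.clip(np.rint(pet_vals), 0.0, None)
    pet_img = ImageSlice2D(pet_vals, dx=spec.pet_spacing_mm, dy=spec.pet_spacing_mm)

    # Lung mask on the PET grid: pixels whose centers fall in the lung field
    # (lesion included — it cannot contain the lung minimum).
    xp = _pixel_centers(n_pet, spec.pet_spacing_mm, spec.extent_mm)
    xxp, yyp = np.meshgrid(xp, xp)
    lung_pet = (np.abs(xxp) <= lung_extent) & (np.abs(yyp) <= lung_extent)
    lung_mask = RegionMask(lung_pet)

    # Lesion ROI on the PET grid: true ellipse bounding box plus blur margin.
    roi_margin = 2.0 * spec.psf_fwhm_mm + 2.0 * spec.pet_spacing_mm
    r_max = max(spec.a_mm, spec.b_mm) + roi_margin
    cx, cy = spec.center_mm
    rows_in = np.nonzero(np.abs(xp - cy) <= r_max)[0]
    cols_in = np.nonzero(np.abs(xp - cx) <= r_max)[0]
    roi = (
        int(rows_in[0]),
        int(rows_in[-1]) + 1,
        int(cols_in[0]),
        int(cols_in[-1]) + 1,
    )
    return Phantom(
        spec=spec,
        pet=pet_img,
        ct=ct_img,
        lung_mask=lung_mask,
        truth_mask_ct=RegionMask(lesion_ct),
        truth_area_mm2=truth_area,
        truth_major_axis_mm=truth_axis,
        roi=roi,
    )


#: cohort fields drawn uniformly from (low, high) ranges, in draw order
_RANGE_FIELDS = (
    "a_mm",
    "b_mm",
    "rotation_deg",
    "center_x_mm",
    "center_y_mm",
    "lesion_activity",
    "lesion_activity_base",
    "lung_activity",
    "noise_sd",
)

#: FDG uptake grows with lesion size in lung tumors; the cohort couples the
#: drawn activity base to the major diameter with this slope (counts per mm
#: above a 10 mm diameter).
ACTIVITY_SLOPE_PER_MM = 250.0

#: Realistic cohort defaults: lesion diameters ~10-45 mm, activities and
#: backgrounds of clinical gray-level magnitude (size-coupled uptake),
#: sub-pixel placement jitter, modest additive noise.
DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "a_mm": (5.0, 22.5),
    "b_mm": (5.0, 22.5),
    "rotation_deg": (0.0, 180.0),
    "center_x_mm": (-2.0, 2.0),
    "center_y_mm": (-2.0, 2.0),
    "lesion_activity_base": (4000.0, 9000.0),
    "lung_activity": (250.0, 650.0),
    "noise_sd": (10.0, 30.0),
}


def generate_cohort(
    n: int,
    ranges: dict[str, tuple[float, float]] | None = None,
    seed: int = 0,
    base_spec: PhantomSpec | None = None,
) -> list[Phantom]:
    """Generate ``n`` phantoms with spec fields drawn uniformly from ranges.

    A single master seed drives both the field draws and each phantom's
    noise seed, so a cohort is fully reproducible.  Fields not listed in
    ``ranges`` keep the values of ``base_spec`` (default spec if omitted).
    ``lesion_activity_base`` draws a size-coupled activity
    (base + slope * (major diameter - 10 mm)); pass a ``lesion_activity``
    range instead for size-independent uptake.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    ranges = dict(DEFAULT_RANGES if ranges is None else ranges)
    for name, (lo, hi) in ranges.items():
        if name not in _RANGE_FIELDS:
            raise ValueError(f"unknown or non-drawable field {name!r}")
        if not lo <= hi:
            raise ValueError(f"invalid range for {name!r}: ({lo}, {hi})")
    if "lesion_activity" in ranges and "lesion_activity_base" in ranges:
        raise ValueError("give either lesion_activity or lesion_activity_base, not both")
    base = base_spec if base_spec is not None else PhantomSpec()
    rng = np.random.default_rng(seed)
    phantoms = []
    for _ in range(n):
        draws: dict[str, float] = {}
        for name in _RANGE_FIELDS:  # fixed draw order for reproducibility
            if name in ranges:
                draws[name] = float(rng.uniform(*ranges[name]))
        cx = draws.pop("center_x_mm", base.center_mm[0])
        cy = draws.pop("center_y_mm", base.center_mm[1])
        if "lesion_activity_base" in draws:
            diameter = 2.0 * max(draws.get("a_mm", base.a_mm), draws.get("b_mm", base.b_mm))
            draws["lesion_activity"] = draws.pop("lesion_activity_base") + (
                ACTIVITY_SLOPE_PER_MM * (diameter - 10.0)
            )
        spec = replace(
            base,
            center_mm=(cx, cy),
            seed=int(rng.integers(0, 2**31 - 1)),
            **draws,
        )
        phantoms.append(generate_phantom(spec))
    return phantoms
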