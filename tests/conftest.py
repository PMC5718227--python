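"""Shared fixtures and independent oracles used across the suite."""

import numpy as np
import pytest

from petthresh.imaging import ImageSlice2D, RegionMask, threshold_region
from petthresh.models import evaluate_pct, threshold_from_pct


@pytest.fixture
def rng():
    return np.random.default_rng(1)


@pytest.fixture
def random_image(rng):
    """6x6 random intensity grid at 4 mm spacing."""
    return ImageSlice2D(rng.uniform(1.0, 100.0, (6, 6)), dx=4.0, dy=4.0)


def make_image(values, dx=4.0, dy=4.0):
    return ImageSlice2D(np.asarray(values, dtype=float), dx=dx, dy=dy)


def make_mask(shape, pixels):
    arr = np.zeros(shape, dtype=bool)
    for r, c in pixels:
        arr[r, c] = True
    return RegionMask(arr)


# ---------------------------------------------------------------------------
# Independent oracles (naive reimplementations used only for cross-checking)
# ---------------------------------------------------------------------------

def brute_force_stats(image, mask):
    """Per-pixel loop computing every RegionStats field independently."""
    pixels = [
        (r, c)
        for r in range(image.shape[0])
        for c in range(image.shape[1])
        if mask.array[r, c]
    ]
    values = [image.values[r, c] for r, c in pixels]
    n = len(values)
    mean = sum(values) / n
    var = sum((v - mean) ** 2 for v in values) / n
    axis = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            (r1, c1), (r2, c2) = pixels[i], pixels[j]
            d = (((c1 - c2) * image.dx) ** 2 + ((r1 - r2) * image.dy) ** 2) ** 0.5
            axis = max(axis, d)
    return {
        "t_mean": mean,
        "t_max": max(values),
        "area_mm2": n * image.dx * image.dy,
        "major_axis_mm": axis,
        "cov": (var**0.5) / mean if mean > 0 else 0.0,
        "n_pixels": n,
    }


def brute_force_component(image, roi, threshold):
    """BFS flood fill from the ROI max over >=threshold pixels, 8-connected."""
    r0, r1, c0, c1 = roi
    best = None
    for r in range(r0, r1):
        for c in range(c0, c1):
            if best is None or image.values[r, c] > image.values[best]:
                best = (r, c)
    if image.values[best] < threshold:
        return set()
    frontier, member = [best], {best}
    while frontier:
        r, c = frontier.pop()
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                nr, nc = r + dr, c + dc
                if (
                    r0 <= nr < r1
                    and c0 <= nc < c1
                    and (nr, nc) not in member
                    and image.values[nr, nc] >= threshold
                ):
                    member.add((nr, nc))
                    frontier.append((nr, nc))
    return member


def sweep_fixed_point(image, lung, roi, model):
    """Exhaustive threshold-sweep fixed-point oracle.

    Tests every unique ROI intensity T in descending order for the property
    that the region at T maps back onto itself through the model (its mean
    produces a threshold landing in the same region's intensity gap), and
    returns the first (highest-threshold) such region — the one the
    Tmax-seeded iteration descends onto.
    """
    r0, r1, c0, c1 = roi
    ladder = np.unique(image.values[r0:r1, c0:c1])[::-1]
    seen = set()
    for t in ladder:
        mask = threshold_region(image, roi, float(t))
        if mask.is_empty or mask.key() in seen:
            continue
        seen.add(mask.key())
        t_mean = float(image.values[mask.array].mean())
        try:
            pct = evaluate_pct(model, t_mean, lung.b_min)
            thr = threshold_from_pct(pct, t_mean)
        except Exception:
            continue
        if threshold_region(image, roi, float(thr)).key() == mask.key():
            return mask
    return None


def sweep_calibration(image, roi, score):
    """Exhaustive iTH sweep oracle: returns (aTH list, midpoint threshold).

    ``score(mask) -> float`` is the absolute closeness metric; all global
    minimizers are accepted.
    """
    r0, r1, c0, c1 = roi
    results = []
    for t in np.unique(image.values[r0:r1, c0:c1]):
        mask = threshold_region(image, roi, float(t))
        if mask.is_empty:
            continue
        results.append((float(t), score(mask)))
    best = min(s for _, s in results)
    ath = [t for t, s in results if s - best <= 1e-9]
    return ath, (min(ath) + max(ath)) / 2.0
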