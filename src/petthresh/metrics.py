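"""Comparison statistics for validating segmentations.

Provides the signed relative difference ΔVs = 100*(a-b)/b used to compare
PET-measured lesion sizes with CT and histological references, summary
statistics in the convention of the validation tables (population SD — the
convention is established empirically against the bundled tables, see
tests), and difference maps between two threshold-adjustment functions over
the clinical (Tmean, Bmin) domain.

Two lesion tables are bundled under ``petthresh/data``:

* ``table1.csv`` — 10 validation lesions with histological major axis <= 20 mm,
* ``table2.csv`` — 17 validation lesions with axis in 20-45 mm,

each with raw measurement columns and the published ΔVs columns for
cross-checking.  One cell of table2 (lesion 52's COV) was published with a
decimal comma and is stored as 0.36; see the fixture header.
"""

from __future__ import annotations

import logging
import math
from importlib import resources
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .errors import EmptyTableError, InvalidReferenceError, ModelDomainError
from .models import ThresholdFunctionModel, evaluate_pct

__all__ = [
    "delta_vs",
    "round_half_away",
    "SummaryStats",
    "summarize",
    "FunctionDifference",
    "function_difference",
    "difference_surface",
    "load_lesion_table",
    "recompute_delta_columns",
]

logger = logging.getLogger(__name__)

#: ΔVs output column -> (measurement column, reference column)
DELTA_COLUMNS = {
    "dvs_maaxis_pet_hist": ("maaxis_pet_mm", "maaxis_hist_mm"),
    "dvs_maaxis_ct_hist": ("maaxis_ct_mm", "maaxis_hist_mm"),
    "dvs_maaxis_pet_ct": ("maaxis_pet_mm", "maaxis_ct_mm"),
    "dvs_area_pet_ct": ("area_pet_mm2", "area_ct_mm2"),
}


def delta_vs(a: float, b: float) -> float:
    """Signed relative difference of ``a`` versus reference ``b``, in percent."""
    if b <= 0:
        raise InvalidReferenceError(f"reference must be positive, got {b}")
    return 100.0 * (a - b) / b


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero (display convention of the tables)."""
    factor = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


class SummaryStats(NamedTuple):
    """Column summary: mean, population SD, extremes, count.

    ``sd`` is 0.0 for a single record; ``sd_degenerate`` flags that case.
    """

    mean: float
    sd: float
    minimum: float
    maximum: float
    n: int
    sd_degenerate: bool


def summarize(values: Iterable[float]) -> SummaryStats:
    """Mean / population SD / min / max of a table column.

    Permutation-invariant; raises :class:`EmptyTableError` on no data.
    """
    arr = np.asarray([v for v in values if not (isinstance(v, float) and math.isnan(v))], dtype=float)
    if arr.size == 0:
        raise EmptyTableError("summarize of an empty column")
    return SummaryStats(
        mean=float(arr.mean()),
        sd=float(arr.std(ddof=0)) if arr.size > 1 else 0.0,
        minimum=float(arr.min()),
        maximum=float(arr.max()),
        n=int(arr.size),
        sd_degenerate=arr.size < 2,
    )


class FunctionDifference(NamedTuple):
    """Signed %Tmean differences ``m1 - m2`` at each point plus the max |diff|.

    Points where either model is outside its domain hold NaN and are listed
    in ``flagged``; they do not enter ``max_abs``.
    """

    differences: np.ndarray
    max_abs: float
    flagged: tuple[int, ...]


def function_difference(
    m1: ThresholdFunctionModel,
    m2: ThresholdFunctionModel,
    points: Sequence[tuple[float, float]],
) -> FunctionDifference:
    """Evaluate two threshold-adjustment functions at (Tmean, Bmin) points."""
    diffs = np.full(len(points), np.nan)
    flagged: list[int] = []
    for i, (t_mean, b_min) in enumerate(points):
        try:
            diffs[i] = evaluate_pct(m1, t_mean, b_min) - evaluate_pct(m2, t_mean, b_min)
        except ModelDomainError as exc:
            logger.warning("point %d (%g, %g) outside model domain: %s", i, t_mean, b_min, exc)
            flagged.append(i)
    finite = diffs[np.isfinite(diffs)]
    max_abs = float(np.abs(finite).max()) if finite.size else float("nan")
    return FunctionDifference(differences=diffs, max_abs=max_abs, flagged=tuple(flagged))


def difference_surface(
    m1: ThresholdFunctionModel,
    m2: ThresholdFunctionModel,
    t_mean_grid: Sequence[float],
    b_min_grid: Sequence[float],
) -> np.ndarray:
    """Dense %Tmean difference surface, shape (len(t_mean_grid), len(b_min_grid)).

    NaN where either model is undefined; intended for plotting/export.
    """
    out = np.full((len(t_mean_grid), len(b_min_grid)), np.nan)
    for i, t_mean in enumerate(t_mean_grid):
        for j, b_min in enumerate(b_min_grid):
            try:
                out[i, j] = evaluate_pct(m1, t_mean, b_min) - evaluate_pct(m2, t_mean, b_min)
            except ModelDomainError:
                pass
    return out


_BUNDLED = {"table1", "table2", "table1.csv", "table2.csv"}


def load_lesion_table(source: str | Path) -> pd.DataFrame:
    """Load a lesion table CSV (bundled name ``table1``/``table2`` or a path)."""
    name = str(source)
    if name in _BUNDLED:
        stem = name.removesuffix(".csv")
        with resources.files("petthresh.data").joinpath(f"{stem}.csv").open() as fh:
            return pd.read_csv(fh, comment="#")
    return pd.read_csv(source, comment="#")


def recompute_delta_columns(df: pd.DataFrame) -> pd.DataFrame:
    """Recompute every ΔVs column from the raw measurement columns.

    Returns a copy with ``<col>_recomputed`` columns alongside any published
    ones, enabling full-table consistency sweeps.
    """
    out = df.copy()
    for col, (a_col, b_col) in DELTA_COLUMNS.items():
        if a_col in df.columns and b_col in df.columns:
            out[f"{col}_recomputed"] = [
                delta_vs(a, b) for a, b in zip(df[a_col], df[b_col])
            ]
    return out
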