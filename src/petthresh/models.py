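"""Threshold-adjustment functions.

A threshold-adjustment function maps image-derived parameters to the
segmentation threshold expressed as a percentage of the region mean
intensity:

    %Tmean = 100 * Threshold / Tmean

The predictor is a ratio of target intensity to lung background minimum —
``Tmean/Bmin`` or ``Tmax/Bmin`` — or, for the auxiliary linear law that
estimates Tmax from Tmean, plain ``Tmean``.  Eight calibrated functions are
built in (:func:`predefined_model`); four families can also be re-fitted
from calibration samples (see :mod:`petthresh.calibration`).

The *composed* family eliminates Tmax from a ``Tmax/Bmin`` power law by
substituting the linear Tmax(Tmean) law into it:

    %Tmean = A * (s*Tmean/Bmin + i/Bmin) ** B

with coefficients ``(A, B, s, i)`` = (outer scale, outer exponent, linear
slope, linear intercept).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

from .errors import ModelDomainError

__all__ = [
    "ThresholdFunctionModel",
    "FAMILIES",
    "PREDICTORS",
    "predefined_model",
    "evaluate_pct",
    "predict_tmax",
    "threshold_from_pct",
    "compose",
    "model_to_config",
    "model_from_config",
]

FAMILIES = ("linear", "exponential", "logarithmic", "power", "polynomial2", "composed")
PREDICTORS = ("tmean_over_bmin", "tmax_over_bmin", "tmean")

_N_COEFFS = {
    "linear": 2,       # slope, intercept
    "exponential": 2,  # scale, rate:        y = a * exp(b*x)
    "logarithmic": 2,  # scale, offset:      y = a * ln(x) + b
    "power": 2,        # scale, exponent:    y = a * x**b
    "polynomial2": 3,  # c2, c1, c0:         y = c2*x^2 + c1*x + c0
    "composed": 4,     # A, B, slope, intercept
}


@dataclass(frozen=True)
class ThresholdFunctionModel:
    """A threshold-adjustment function (or the auxiliary Tmax law).

    ``r_squared`` is the coefficient of determination reported for (or
    measured during) the calibration that produced the model; ``None`` when
    the model was constructed rather than fitted.
    """

    family: str
    coefficients: tuple[float, ...]
    predictor: str
    r_squared: float | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.predictor not in PREDICTORS:
            raise ValueError(f"unknown predictor {self.predictor!r}")
        coeffs = tuple(float(c) for c in self.coefficients)
        if len(coeffs) != _N_COEFFS[self.family]:
            raise ValueError(
                f"family {self.family!r} takes {_N_COEFFS[self.family]} "
                f"coefficients, got {len(coeffs)}"
            )
        object.__setattr__(self, "coefficients", coeffs)


# The eight calibrated functions, with their published coefficients and R².
# 1-4 were calibrated against CT areas; 5-8 against histological major axes.
# 4 = 2 composed with 3; 8 = 6 composed with 7.
_PREDEFINED: dict[int, ThresholdFunctionModel] = {
    1: ThresholdFunctionModel("power", (130.9, -0.23), "tmean_over_bmin", 0.81),
    2: ThresholdFunctionModel("power", (136.09, -0.22), "tmax_over_bmin", 0.87),
    3: ThresholdFunctionModel("linear", (1.64, -1634.8), "tmean", 0.96),
    4: ThresholdFunctionModel(
        "composed", (136.09, -0.22, 1.64, -1634.8), "tmean_over_bmin", 0.82
    ),
    5: ThresholdFunctionModel("power", (152.93, -0.27), "tmean_over_bmin", 0.65),
    6: ThresholdFunctionModel("power", (151.62, -0.24), "tmax_over_bmin", 0.74),
    7: ThresholdFunctionModel("linear", (1.73, -1903.8), "tmean", 0.96),
    8: ThresholdFunctionModel(
        "composed", (151.62, -0.24, 1.73, -1903.8), "tmean_over_bmin", 0.99
    ),
}


def predefined_model(model_id: int) -> ThresholdFunctionModel:
    """Return built-in threshold-adjustment function #1..#8.

    Coefficients are stored exactly as published; note that worked-example
    %Tmean values carry a ~0.5 percentage-point tolerance because the
    published coefficients are rounded.
    """
    try:
        return _PREDEFINED[int(model_id)]
    except (KeyError, ValueError) as exc:
        raise ValueError(f"unknown predefined model id {model_id!r} (valid: 1..8)") from exc


def evaluate_pct(model: ThresholdFunctionModel, t: float, b_min: float) -> float:
    """Evaluate %Tmean at target intensity ``t`` and lung background ``b_min``.

    ``t`` is interpreted according to the model's predictor: the Tmean of the
    current region for ``tmean_over_bmin``/``composed`` models, the Tmax for
    ``tmax_over_bmin`` models.  The output is *not* clamped: values >= 100
    signal a degenerate operating point and are handled downstream by the
    segmentation loop.
    """
    if b_min <= 0:
        raise ModelDomainError(f"Bmin must be positive, got {b_min}")
    if model.predictor == "tmean":
        raise ModelDomainError(
            "model predicts Tmax, not %Tmean; use predict_tmax instead"
        )
    c = model.coefficients
    if model.family == "composed":
        a, b, slope, intercept = c
        base = (slope * t + intercept) / b_min
        if base <= 0:
            raise ModelDomainError(
                f"composed-model base {base:.4g} is non-positive at t={t}, b_min={b_min}"
            )
        return a * base**b
    x = t / b_min
    if model.family == "power":
        if x <= 0:
            raise ModelDomainError(f"power-law base {x:.4g} is non-positive")
        return c[0] * x ** c[1]
    if model.family == "exponential":
        return c[0] * math.exp(c[1] * x)
    if model.family == "logarithmic":
        if x <= 0:
            raise ModelDomainError(f"logarithm argument {x:.4g} is non-positive")
        return c[0] * math.log(x) + c[1]
    if model.family == "linear":
        return c[0] * x + c[1]
    # polynomial2
    return c[0] * x**2 + c[1] * x + c[2]


def predict_tmax(model: ThresholdFunctionModel, t_mean: float) -> float:
    """Evaluate an auxiliary linear Tmax(Tmean) law."""
    if model.family != "linear" or model.predictor != "tmean":
        raise ModelDomainError("predict_tmax requires a linear model on tmean")
    slope, intercept = model.coefficients
    return slope * t_mean + intercept


def threshold_from_pct(pct: float, t_mean: float) -> int:
    """Absolute threshold gray level from %Tmean: round(pct/100 * Tmean).

    PET intensities are integer gray levels, so the threshold is rounded to
    the nearest integer, ties away from zero.
    """
    if pct <= 0:
        raise ModelDomainError(f"%Tmean must be positive, got {pct}")
    if t_mean <= 0:
        raise ModelDomainError(f"Tmean must be positive, got {t_mean}")
    return int(math.floor(pct / 100.0 * t_mean + 0.5))


def compose(
    outer: ThresholdFunctionModel, tmax_law: ThresholdFunctionModel
) -> ThresholdFunctionModel:
    """Substitute a linear Tmax(Tmean) law into a Tmax/Bmin power law.

    The result is a composed model on Tmean/Bmin satisfying
    ``evaluate_pct(composed, tmean, bmin) == evaluate_pct(outer, tmax_law(tmean), bmin)``.
    """
    if outer.family != "power" or outer.predictor != "tmax_over_bmin":
        raise ModelDomainError("outer model must be a power law on tmax_over_bmin")
    if tmax_law.family != "linear" or tmax_law.predictor != "tmean":
        raise ModelDomainError("tmax_law must be a linear model on tmean")
    return ThresholdFunctionModel(
        family="composed",
        coefficients=outer.coefficients + tmax_law.coefficients,
        predictor="tmean_over_bmin",
        r_squared=None,
    )


def with_r_squared(model: ThresholdFunctionModel, r_squared: float) -> ThresholdFunctionModel:
    """Copy of the model with its coefficient of determination set."""
    return dataclasses.replace(model, r_squared=float(r_squared))


def model_to_config(model: ThresholdFunctionModel) -> str:
    """Serialize to a plain-text ``key = value`` block."""
    lines = [
        f"family = {model.family}",
        "coefficients = " + ", ".join(repr(c) for c in model.coefficients),
        f"predictor = {model.predictor}",
    ]
    if model.r_squared is not None:
        lines.append(f"r_squared = {model.r_squared!r}")
    return "\n".join(lines) + "\n"


def model_from_config(text: str) -> ThresholdFunctionModel:
    """Parse the plain-text block written by :func:`model_to_config`."""
    fields: dict[str, str] = {}
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"malformed model config line: {raw!r}")
        key, _, value = line.partition("=")
        fields[key.strip()] = value.strip()
    missing = {"family", "coefficients", "predictor"} - fields.keys()
    if missing:
        raise ValueError(f"model config missing keys: {sorted(missing)}")
    return ThresholdFunctionModel(
        family=fields["family"],
        coefficients=tuple(float(v) for v in fields["coefficients"].split(",")),
        predictor=fields["predictor"],
        r_squared=float(fields["r_squared"]) if "r_squared" in fields else None,
    )
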