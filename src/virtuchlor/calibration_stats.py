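"""Cross-meter calibration statistics.

A new transmittance meter is related to reference instruments (SPAD-502,
atLeaf CHL Plus) by measuring the same samples with every device and
regressing the reference readings on the device index M by ordinary least
squares.  Because all these meters compute (gained/offset) decadic log
ratios of NIR to red transmittance, the relation is affine to a very good
approximation, and the fitted line doubles as the unit-conversion equation

    V_target = slope * M + intercept

This module provides the Pearson correlation matrix used to justify the
linear model, the OLS fit with R², RMSE, residual norm and the t-based 95 %
prediction band, and the conversion models — including the published presets
fitted on lemon-tree leaves, young Brussels-sprouts leaves and uniform
colour filters ("non-leaves").
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import stats

__all__ = [
    "CorrelationMatrix",
    "CalibrationFit",
    "ConversionModel",
    "CONVERSION_PRESETS",
    "DEVICE_OUTPUT_RANGES",
    "get_preset",
    "pearson_matrix",
    "fit_linear",
    "prediction_interval",
    "coverage_fraction",
    "convert_units",
    "invert_units",
    "average_repeats",
]


@dataclass(frozen=True)
class CorrelationMatrix:
    """2x2 Pearson correlation matrix of paired meter readings."""

    rho: np.ndarray
    n: int

    @property
    def off_diagonal(self) -> float:
        return float(self.rho[0, 1])


@dataclass(frozen=True)
class CalibrationFit:
    """An OLS calibration of reference readings (y) on device output (x).

    ``rmse`` is the population form sqrt(SSE/n); ``rmse_sample`` divides by
    n−2 (the residual standard error, used for the prediction band);
    ``residual_norm`` is sqrt(SSE), so residual_norm = sqrt(n)·rmse.
    ``x_mean`` and ``sxx`` are retained so the prediction band can be
    evaluated at any abscissa.
    """

    slope: float
    intercept: float
    r2: float
    rmse: float
    rmse_sample: float
    residual_norm: float
    n: int
    alpha: float
    x_mean: float
    sxx: float

    def predict(self, x0: float) -> float:
        return self.slope * x0 + self.intercept


@dataclass(frozen=True)
class ConversionModel:
    """Affine map from device output M to SPAD or atLeaf units."""

    target: str  # "spad" or "atleaf"
    slope: float
    intercept: float
    provenance: str = "fitted"  # lemon | sprouts | nonleaves | fitted
    source: str = "device"

    def __post_init__(self) -> None:
        if self.target not in ("spad", "atleaf"):
            raise ValueError("target must be 'spad' or 'atleaf'")

    def convert(self, m: float) -> float:
        return self.slope * m + self.intercept

    def invert(self, value: float) -> float:
        if self.slope == 0.0:
            raise ZeroDivisionError("conversion model slope is zero; not invertible")
        return (value - self.intercept) / self.slope


# Published cross-calibration coefficients (reference units per device unit,
# and intercept in reference units), per sample family.
CONVERSION_PRESETS: dict[Tuple[str, str], ConversionModel] = {
    ("lemon", "spad"): ConversionModel("spad", 66.667, 13.547, provenance="lemon"),
    ("lemon", "atleaf"): ConversionModel("atleaf", 53.476, 23.577, provenance="lemon"),
    ("sprouts", "spad"): ConversionModel("spad", 60.241, 12.976, provenance="sprouts"),
    ("sprouts", "atleaf"): ConversionModel(
        "atleaf", 63.694, 18.892, provenance="sprouts"
    ),
    ("nonleaves", "spad"): ConversionModel(
        "spad", 62.893, 13.27, provenance="nonleaves"
    ),
    ("nonleaves", "atleaf"): ConversionModel(
        "atleaf", 67.567, 19.16, provenance="nonleaves"
    ),
}

# Device-output (M) ranges observed in each calibration experiment.
DEVICE_OUTPUT_RANGES: dict[str, Tuple[float, float]] = {
    "lemon": (-0.29, 0.92),
    "sprouts": (0.03, 0.58),
    "nonleaves": (-0.09, 0.82),
}


def get_preset(family: str, target: str) -> ConversionModel:
    """Look up a published conversion preset, e.g. ``get_preset('lemon', 'spad')``."""
    try:
        return CONVERSION_PRESETS[(family, target)]
    except KeyError:
        raise KeyError(
            f"no conversion preset for family={family!r}, target={target!r}; "
            f"known: {sorted(CONVERSION_PRESETS)}"
        ) from None


def pearson_matrix(a: Sequence[float], b: Sequence[float]) -> CorrelationMatrix:
    """Pearson correlation matrix of two paired reading vectors.

    Uses the sample (n−1) covariance convention.  Raises on constant input,
    where the correlation is undefined.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D vectors")
    if a.size < 3:
        raise ValueError("need at least 3 paired observations")
    for name, v in (("first", a), ("second", b)):
        if np.ptp(v) == 0.0:
            raise ValueError(f"{name} vector is constant; correlation undefined")
    rho = np.corrcoef(a, b)
    return CorrelationMatrix(rho=rho, n=int(a.size))


def fit_linear(
    x: Sequence[float], y: Sequence[float], alpha: float = 0.05
) -> CalibrationFit:
    """Ordinary least squares of reference readings y on device readings x.

    Returns slope/intercept, R², both RMSE conventions, the residual norm,
    and the sufficient statistics for the (1−alpha) prediction band.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 points for a calibration fit")
    if np.ptp(x) == 0.0:
        raise np.linalg.LinAlgError("device readings are constant; rank-deficient fit")
    res = stats.linregress(x, y)
    slope, intercept = float(res.slope), float(res.intercept)
    resid = y - (slope * x + intercept)
    sse = float(resid @ resid)
    sst = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 if sst == 0.0 else 1.0 - sse / sst
    return CalibrationFit(
        slope=slope,
        intercept=intercept,
        r2=r2,
        rmse=math.sqrt(sse / n),
        rmse_sample=math.sqrt(sse / (n - 2)) if n > 2 else float("nan"),
        residual_norm=math.sqrt(sse),
        n=n,
        alpha=alpha,
        x_mean=float(x.mean()),
        sxx=float(((x - x.mean()) ** 2).sum()),
    )


def prediction_interval(fit: CalibrationFit, x0: float) -> Tuple[float, float]:
    """Two-sided (1−alpha) prediction interval for a new observation at x0.

    Standard OLS form: yhat ± t_{1−alpha/2, n−2} · s · sqrt(1 + 1/n +
    (x0−x̄)²/Sxx), where s is the residual standard error.  The band is
    narrowest at the mean abscissa and widens with leverage.
    """
    yhat = fit.predict(x0)
    s = fit.rmse_sample
    if s == 0.0:
        return (yhat, yhat)
    tcrit = stats.t.ppf(1.0 - fit.alpha / 2.0, fit.n - 2)
    half = tcrit * s * math.sqrt(1.0 + 1.0 / fit.n + (x0 - fit.x_mean) ** 2 / fit.sxx)
    return (yhat - half, yhat + half)


def coverage_fraction(fit: CalibrationFit, points: Sequence[Tuple[float, float]]) -> float:
    """Fraction of (x, y) points lying inside the fit's prediction band."""
    pts = np.asarray(points, dtype=float)
    if pts.size == 0:
        raise ValueError("coverage_fraction requires at least one point")
    pts = pts.reshape(-1, 2)
    inside = 0
    for x0, y0 in pts:
        lo, hi = prediction_interval(fit, float(x0))
        inside += lo <= y0 <= hi
    return inside / len(pts)


def convert_units(m: float, model: ConversionModel) -> Tuple[float, float]:
    """Convert a device reading to reference units.

    Returns ``(exact, displayed)`` — the display form is rounded to one
    decimal, matching the three-digit precision of the commercial meters.
    """
    exact = model.convert(m)
    return exact, round(exact, 1)


def invert_units(value: float, model: ConversionModel) -> float:
    """Map a reference-unit value back to device units: (value − intercept)/slope."""
    return model.invert(value)


def average_repeats(table, value_cols: Optional[Sequence[str]] = None):
    """Average repeated measurements per (sample, area) before regression.

    The acquisition protocol takes 5 repeats at each marked leaf area or
    filter position and averages them prior to any statistical analysis;
    this is the fixed first step of the calibration pipeline.  ``table``
    is a tidy DataFrame with ``sample_id``, ``area_id`` and ``repeat``
    columns; remaining numeric columns (or ``value_cols``) are averaged.
    """
    import pandas as pd

    if value_cols is None:
        value_cols = [
            c
            for c in table.columns
            if c not in ("sample_id", "area_id", "repeat")
            and pd.api.types.is_numeric_dtype(table[c])
        ]
    return (
        table.groupby(["sample_id", "area_id"], sort=True)[list(value_cols)]
        .mean()
        .reset_index()
    )
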