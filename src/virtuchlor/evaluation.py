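"""Accuracy and repeatability evaluation on uniform (filter-style) samples.

Leaves are spatially heterogeneous and alive, so repeated clip-on readings
confound instrument error with sample variation.  The evaluation protocol
therefore uses near-uniform colour filters: for each filter (dataset), 5
repeated readings are taken at each of 10 random positions (areas).

* accuracy range — each dataset's own mean (over its 5-repeat area
  averages) is taken as ground truth; the global minimum and maximum of the
  deviations of area averages from that mean, across all datasets, bound
  the instrument's accuracy.  Deviations from an own mean necessarily
  straddle zero.
* repeatability — the dispersion of the 5 repeats at a fixed position;
  reported as the pooled standard deviation by default (the metrological
  convention), with the mean of per-point SDs as an alternative.

Results computed in native device units can be re-expressed in SPAD or
atLeaf units through a conversion model; only the slope matters, since
intercepts cancel in deviations and standard deviations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Dict, Sequence, Tuple

import numpy as np
import pandas as pd

from .calibration_stats import ConversionModel

__all__ = [
    "EvalDataset",
    "AccuracyReport",
    "area_averages",
    "accuracy_range",
    "repeatability",
    "express_in_units",
    "subset_filter",
]


@dataclass(frozen=True)
class EvalDataset:
    """Readings indexed by (dataset, area, repeat), e.g. 9 filters x 10 x 5."""

    readings: pd.DataFrame  # columns: dataset_id, area_id, repeat, value
    units: str = "device"

    REQUIRED = ("dataset_id", "area_id", "repeat", "value")

    def __post_init__(self) -> None:
        missing_cols = [c for c in self.REQUIRED if c not in self.readings.columns]
        if missing_cols:
            raise ValueError(f"readings table is missing columns: {missing_cols}")
        self._check_complete()

    def _check_complete(self) -> None:
        counts = self.readings.groupby(["dataset_id", "area_id"])["repeat"].count()
        if counts.empty:
            raise ValueError("evaluation dataset is empty")
        if counts.nunique() != 1:
            bad = counts[counts != counts.mode().iloc[0]]
            raise ValueError(
                "incomplete crossing: uneven repeat counts at cells "
                f"{list(bad.index)}"
            )
        per_ds = self.readings.groupby("dataset_id")["area_id"].nunique()
        if per_ds.nunique() != 1:
            raise ValueError("incomplete crossing: uneven area counts across datasets")

    @classmethod
    def from_readings_table(
        cls, table: pd.DataFrame, value_col: str = "M", units: str = "device"
    ) -> "EvalDataset":
        """Adapt a simulated readings table (sample_id/area_id/repeat) to an EvalDataset."""
        df = table.rename(columns={"sample_id": "dataset_id", value_col: "value"})[
            ["dataset_id", "area_id", "repeat", "value"]
        ].copy()
        return cls(readings=df, units=units)

    @property
    def dataset_ids(self) -> list:
        return sorted(self.readings["dataset_id"].unique().tolist())


@dataclass(frozen=True)
class AccuracyReport:
    """Accuracy bounds and repeatability of one instrument on an EvalDataset."""

    accuracy_low: float
    accuracy_high: float
    repeatability: float
    per_dataset_means: Dict[str, float]
    n_points: int
    units: str = "device"

    def __post_init__(self) -> None:
        if not self.accuracy_low <= 0.0 <= self.accuracy_high:
            raise ValueError("accuracy bounds must straddle 0")
        if self.repeatability < 0.0:
            raise ValueError("repeatability must be non-negative")


def area_averages(ds: EvalDataset) -> pd.Series:
    """Mean over repeats for each (dataset, area) cell."""
    return ds.readings.groupby(["dataset_id", "area_id"])["value"].mean()


def accuracy_range(ds: EvalDataset) -> Tuple[float, float]:
    """Global min and max deviation of area averages from their dataset mean."""
    avgs = area_averages(ds)
    if avgs.groupby(level="dataset_id").size().min() < 2:
        raise ValueError("accuracy_range needs at least 2 areas per dataset")
    deviations = avgs - avgs.groupby(level="dataset_id").transform("mean")
    return (float(deviations.min()), float(deviations.max()))


def repeatability(ds: EvalDataset, method: str = "pooled") -> float:
    """Dispersion of the repeats at a fixed measurement position.

    ``pooled``: sqrt of the mean per-point sample variance (default);
    ``mean_sd``: mean of the per-point sample SDs.
    """
    grouped = ds.readings.groupby(["dataset_id", "area_id"])["value"]
    if grouped.count().min() < 2:
        raise ValueError("repeatability needs at least 2 repeats per position")
    variances = grouped.var(ddof=1)
    if method == "pooled":
        return float(math.sqrt(variances.mean()))
    if method == "mean_sd":
        return float(np.sqrt(variances).mean())
    raise ValueError("method must be 'pooled' or 'mean_sd'")


def evaluate(ds: EvalDataset, method: str = "pooled") -> AccuracyReport:
    """Full protocol: accuracy range plus repeatability on one dataset."""
    low, high = accuracy_range(ds)
    means = area_averages(ds).groupby(level="dataset_id").mean()
    return AccuracyReport(
        accuracy_low=low,
        accuracy_high=high,
        repeatability=repeatability(ds, method=method),
        per_dataset_means={str(k): float(v) for k, v in means.items()},
        n_points=int(len(ds.readings)),
        units=ds.units,
    )


def express_in_units(report: AccuracyReport, model: ConversionModel) -> AccuracyReport:
    """Re-express a device-unit report in SPAD or atLeaf units.

    Accuracy bounds and repeatability are differences/dispersions, so only
    the conversion slope applies; the intercept cancels.  Per-dataset means
    are full affine conversions of level values.
    """
    if report.units != "device":
        raise ValueError("report must be in device units before conversion")
    if model.slope <= 0.0:
        raise ValueError("conversion slope must be positive")
    return AccuracyReport(
        accuracy_low=report.accuracy_low * model.slope,
        accuracy_high=report.accuracy_high * model.slope,
        repeatability=report.repeatability * model.slope,
        per_dataset_means={
            k: model.convert(v) for k, v in report.per_dataset_means.items()
        },
        n_points=report.n_points,
        units=model.target,
    )


def subset_filter(ds: EvalDataset, keep: Sequence) -> EvalDataset:
    """Restrict to the named datasets (e.g. drop the blue filters)."""
    keep = list(keep)
    if not keep:
        raise ValueError("keep list must be nonempty")
    present = set(ds.readings["dataset_id"].unique())
    unknown = [k for k in keep if k not in present]
    if unknown:
        raise KeyError(f"unknown dataset ids: {unknown}")
    df = ds.readings[ds.readings["dataset_id"].isin(keep)].reset_index(drop=True)
    return replace(ds, readings=df)
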