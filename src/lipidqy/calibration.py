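"""Standard curves: linear calibration of fluorescence readouts against
gravimetric lipid content.

A standard curve maps one fluorescence parameter — peak intensity ``I_E``,
emission area ``A_E`` or quantum yield ``phi_fl`` — to lipid content in
% w/w of dry biomass, fitted on an OD_600 dilution series whose lipid content
was determined gravimetrically.  Lipid content is regressed *on* the
fluorescence value, so quantifying an unknown sample is direct evaluation of
the fitted line rather than inverse interpolation.

Curves are keyed by (strain, medium, parameter, month): calibrations are
strain- and session-specific, and applying a curve across keys requires an
explicit override at the orchestration layer.
"""

from __future__ import annotations

import enum
import json
import math
import os
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import (
    DegenerateDesignError,
    IncomparableCurvesError,
    InsufficientDataError,
    NonInvertibleCurveError,
)

__all__ = [
    "FluorescenceParameter",
    "CalibrationPoint",
    "StandardCurve",
    "LipidEstimate",
    "CurveComparison",
    "fit_standard_curve",
    "estimate_lipid",
    "compare_curves",
    "CurveRegistry",
]


class FluorescenceParameter(str, enum.Enum):
    """Which fluorescence readout a calibration curve is built on."""

    I_E = "I_E"
    A_E = "A_E"
    PHI_FL = "PHI_FL"


@dataclass(frozen=True)
class CalibrationPoint:
    """One dilution-series point: a fluorescence value paired with the
    gravimetric lipid content of the same diluted cell sample."""

    fluorescence_value: float
    lipid_content: float  # % w/w of dry biomass
    od_600: float | None = None
    sample_id: str = ""

    def __post_init__(self) -> None:
        if not math.isfinite(self.fluorescence_value):
            raise ValueError("fluorescence_value must be finite")
        if self.lipid_content < 0:
            raise ValueError("lipid_content must be >= 0")


@dataclass(frozen=True)
class StandardCurve:
    """Fitted linear map lipid(%) = slope * fluorescence + intercept."""

    parameter: FluorescenceParameter
    slope: float
    intercept: float
    r_squared: float
    residual_sd: float
    slope_se: float
    n_points: int
    strain: str = ""
    medium: str = ""
    month: str = ""
    x_min: float = float("nan")
    x_max: float = float("nan")

    @property
    def key(self) -> tuple[str, str, str, str]:
        return (self.strain, self.medium, self.parameter.value, self.month)


@dataclass(frozen=True)
class LipidEstimate:
    """Point estimate with a prediction-uncertainty half-width.

    Negative point estimates are returned as-is with ``below_zero`` set:
    silently clamping to zero would hide curve misuse (e.g. a month-7 reading
    pushed through a month-1 intensity curve after the lamp decayed).
    """

    lipid_pct: float
    half_width: float
    below_zero: bool


@dataclass(frozen=True)
class CurveComparison:
    """Differences between two curves built on the same parameter."""

    slope_ratio: float
    intercept_difference: float
    max_prediction_discrepancy: float
    x_range: tuple[float, float]


def fit_standard_curve(
    points: Sequence[CalibrationPoint],
    parameter: FluorescenceParameter | str,
    strain: str = "",
    medium: str = "",
    month: str = "",
) -> StandardCurve:
    """Ordinary least-squares fit of lipid content on a fluorescence readout.

    Requires at least 3 points with non-zero variance in the fluorescence
    values.  Returns slope, intercept, the coefficient of determination R^2
    and the residual standard deviation (n - 2 denominator; 0 when n = 2
    would be degenerate and is excluded by the n >= 3 requirement).
    """
    parameter = FluorescenceParameter(parameter)
    if len(points) < 3:
        raise InsufficientDataError(
            f"standard curve needs >= 3 calibration points, got {len(points)}"
        )
    x = np.array([p.fluorescence_value for p in points], dtype=float)
    y = np.array([p.lipid_content for p in points], dtype=float)
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx == 0.0:
        raise DegenerateDesignError(
            "all fluorescence values identical: cannot fit a calibration line"
        )
    sxy = float(np.sum((x - x.mean()) * (y - y.mean())))
    slope = sxy / sxx
    intercept = float(y.mean() - slope * x.mean())
    resid = y - (slope * x + intercept)
    sse = float(resid @ resid)
    sst = float(np.sum((y - y.mean()) ** 2))
    r_squared = 1.0 if sst == 0.0 else 1.0 - sse / sst
    # guard tiny negative round-off
    r_squared = min(1.0, max(0.0, r_squared))
    residual_sd = math.sqrt(sse / (len(points) - 2))
    return StandardCurve(
        parameter=parameter,
        slope=slope,
        intercept=intercept,
        r_squared=r_squared,
        residual_sd=residual_sd,
        slope_se=residual_sd / math.sqrt(sxx),
        n_points=len(points),
        strain=strain,
        medium=medium,
        month=month,
        x_min=float(x.min()),
        x_max=float(x.max()),
    )


def estimate_lipid(
    curve: StandardCurve,
    fluorescence_value: float,
    coverage_sd: float = 2.0,
) -> LipidEstimate:
    """Lipid content (% w/w) predicted from a fluorescence value.

    The half-width is ``coverage_sd * residual_sd`` — a pragmatic prediction
    band from the calibration's residual scale (default two residual SDs).
    """
    if curve.slope == 0:
        raise NonInvertibleCurveError(
            "curve slope is zero: fluorescence carries no lipid information"
        )
    point = curve.slope * fluorescence_value + curve.intercept
    return LipidEstimate(
        lipid_pct=float(point),
        half_width=float(coverage_sd * curve.residual_sd),
        below_zero=point < 0,
    )


def compare_curves(
    curve_a: StandardCurve,
    curve_b: StandardCurve,
    n_grid: int = 201,
) -> CurveComparison:
    """Compare two standard curves built on the same fluorescence parameter.

    Reports the slope ratio (b/a), intercept difference (b - a) and the
    maximum absolute difference in predicted lipid content over the common
    fluorescence range (falling back to the union of ranges when the curves'
    calibration ranges do not overlap).
    """
    if curve_a.parameter != curve_b.parameter:
        raise IncomparableCurvesError(
            f"cannot compare {curve_a.parameter.value} curve with "
            f"{curve_b.parameter.value} curve"
        )
    lo = max(curve_a.x_min, curve_b.x_min)
    hi = min(curve_a.x_max, curve_b.x_max)
    if not (math.isfinite(lo) and math.isfinite(hi)) or lo >= hi:
        lo = min(curve_a.x_min, curve_b.x_min)
        hi = max(curve_a.x_max, curve_b.x_max)
    grid = np.linspace(lo, hi, n_grid)
    pred_a = curve_a.slope * grid + curve_a.intercept
    pred_b = curve_b.slope * grid + curve_b.intercept
    return CurveComparison(
        slope_ratio=curve_b.slope / curve_a.slope,
        intercept_difference=curve_b.intercept - curve_a.intercept,
        max_prediction_discrepancy=float(np.max(np.abs(pred_b - pred_a))),
        x_range=(float(lo), float(hi)),
    )


class CurveRegistry:
    """Persistent registry of fitted standard curves, keyed by
    (strain, medium, parameter, month), serialised as JSON."""

    def __init__(self, curves: Iterable[StandardCurve] = ()) -> None:
        self._curves: dict[tuple[str, str, str, str], StandardCurve] = {}
        for c in curves:
            self.add(c)

    def add(self, curve: StandardCurve) -> None:
        self._curves[curve.key] = curve

    def get(self, strain: str, medium: str,
            parameter: FluorescenceParameter | str, month: str) -> StandardCurve | None:
        return self._curves.get((strain, medium, FluorescenceParameter(parameter).value, month))

    def __len__(self) -> int:
        return len(self._curves)

    def __iter__(self):
        return iter(self._curves.values())

    def save(self, path: str | os.PathLike) -> None:
        records = []
        for c in self._curves.values():
            rec = asdict(c)
            rec["parameter"] = c.parameter.value
            records.append(rec)
        Path(path).write_text(json.dumps({"curves": records}, indent=2) + "\n",
                              encoding="utf-8")

    @classmethod
    def load(cls, path: str | os.PathLike) -> "CurveRegistry":
        data = json.loads(Path(path).read_text(encoding="utf-8"))
        curves = []
        for rec in data.get("curves", []):
            rec = dict(rec)
            rec["parameter"] = FluorescenceParameter(rec["parameter"])
            rec["x_min"] = rec.get("x_min", float("nan"))
            rec["x_max"] = rec.get("x_max", float("nan"))
            rec["slope_se"] = rec.get("slope_se", float("nan"))
            curves.append(StandardCurve(**rec))
        return cls(curves)
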