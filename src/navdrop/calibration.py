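"""Linear capacitance-to-elongation calibration of the strain sensor.

The sensor's capacitance varies linearly with the extension of its
strainable section, so calibration is an ordinary least-squares line of
extension (mm) on capacitance (pF) fitted to a bench sweep, or — for
everyday use — a line through just two measurements.  The module also
quantifies slope drift between calibrations and propagates it to a
worst-case navicular-drop error.
"""
from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateSweepError, InvalidProfileError
from .series import StrainSeries

__all__ = [
    "CalibrationModel",
    "fit_calibration",
    "two_point_calibrate",
    "apply_calibration",
    "slope_drift",
    "drift_to_accuracy",
]


@dataclass(frozen=True)
class CalibrationModel:
    """Affine capacitance -> extension map.

    ``extension_mm = slope_mm_per_pf * capacitance_pF + intercept_mm``.
    ``r_squared`` is None for two-point calibrations: a line through two
    points fits them exactly, so an R² of 1.0 there would claim a fit
    quality that was never measured.
    """

    slope_mm_per_pf: float
    intercept_mm: float
    r_squared: float | None
    n_points: int
    label: str = ""

    def __post_init__(self) -> None:
        if not np.isfinite(self.slope_mm_per_pf) or self.slope_mm_per_pf == 0:
            raise InvalidProfileError("calibration slope must be finite and nonzero")
        if self.r_squared is not None and not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise InvalidProfileError("r_squared must lie in [0, 1]")
        if self.n_points < 2:
            raise InvalidProfileError("calibration needs at least 2 points")

    def predict_mm(self, capacitance_pf: np.ndarray) -> np.ndarray:
        return self.slope_mm_per_pf * np.asarray(capacitance_pf, dtype=float) + self.intercept_mm

    def to_dict(self) -> dict:
        return asdict(self)


def _as_sweep(sweep) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(sweep, pd.DataFrame):
        c = sweep["capacitance_pF"].to_numpy(dtype=float)
        e = sweep["extension_mm"].to_numpy(dtype=float)
    else:
        arr = np.asarray(sweep, dtype=float)
        c, e = arr[:, 0], arr[:, 1]
    return c, e


def fit_calibration(sweep, label: str = "") -> CalibrationModel:
    """Least-squares line of extension on capacitance for a bench sweep.

    ``sweep`` is a DataFrame with columns ``capacitance_pF`` /
    ``extension_mm`` or an (n, 2) array in that column order.  Collinear
    input is recovered exactly (R² = 1).
    """
    c, e = _as_sweep(sweep)
    if c.size < 2 or np.ptp(c) == 0:
        raise DegenerateSweepError("need >= 2 distinct capacitance values")
    res = sps.linregress(c, e)
    ss_res = float(np.sum((e - (res.slope * c + res.intercept)) ** 2))
    ss_tot = float(np.sum((e - e.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)
    return CalibrationModel(
        slope_mm_per_pf=float(res.slope),
        intercept_mm=float(res.intercept),
        r_squared=min(1.0, r2),
        n_points=int(c.size),
        label=label,
    )


def two_point_calibrate(
    p_low: tuple[float, float], p_high: tuple[float, float], label: str = ""
) -> CalibrationModel:
    """Everyday two-point calibration: the line through two (pF, mm) points."""
    (c0, e0), (c1, e1) = p_low, p_high
    if c0 == c1:
        raise DegenerateSweepError("two-point calibration needs distinct capacitances")
    slope = (e1 - e0) / (c1 - c0)
    return CalibrationModel(
        slope_mm_per_pf=float(slope),
        intercept_mm=float(e0 - slope * c0),
        r_squared=None,
        n_points=2,
        label=label,
    )


def apply_calibration(series: StrainSeries, model: CalibrationModel) -> StrainSeries:
    """Convert a capacitance record to calibrated elongation, timestamps untouched."""
    if series.capacitance_pF is None:
        raise InvalidProfileError("series carries no capacitance channel")
    return StrainSeries(
        t_s=series.t_s.copy(),
        capacitance_pF=series.capacitance_pF.copy(),
        elongation_mm=model.predict_mm(series.capacitance_pF),
        rate_hz=series.rate_hz,
    )


def slope_drift(model_a: CalibrationModel, model_b: CalibrationModel) -> float:
    """Absolute percent slope change from calibration A to calibration B."""
    if model_a.slope_mm_per_pf == 0:
        raise InvalidProfileError("reference slope is zero")
    return 100.0 * abs(model_b.slope_mm_per_pf - model_a.slope_mm_per_pf) / abs(
        model_a.slope_mm_per_pf
    )


def drift_to_accuracy(drift_pct: float, nd_mm: float) -> float:
    """Worst-case navicular-drop error implied by a relative slope drift.

    A slope error of ``drift_pct`` percent scales every measured elongation
    by the same factor, so a drop of ``nd_mm`` is off by at most
    ``nd_mm * drift_pct / 100`` — e.g. 4% drift on a 10 mm drop is 0.4 mm.
    """
    if drift_pct < 0 or nd_mm < 0:
        raise InvalidProfileError("drift_pct and nd_mm must be >= 0")
    return nd_mm * drift_pct / 100.0
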