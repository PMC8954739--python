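"""Cross-platform correlation of MSI abundances and LC-MS/MS concentrations.

Mean section abundance from imaging is regressed (ordinary least squares,
free intercept) on the absolute tissue concentration of the matched
specimen; the same machinery compares the two imaging modalities against
each other.  Diagnostics follow the standard reading of such
cross-technique plots: a positive x-intercept shift flags poorer
detection/quantification limits of the technique on the x-axis, a positive
y-intercept shift flags chemical background on the y-axis technique, and
the slope is the relative sensitivity (slope 1 with zero intercept being a
balanced response).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .io import ValidationError
from .quantify import DetectionLimits

__all__ = [
    "RegressionResult",
    "ols_regression",
    "confidence_band",
    "diagnostics",
    "cross_modality",
]


@dataclass
class RegressionResult:
    """Simple OLS fit y = intercept + slope * x with the quantities needed
    for confidence bands and cross-technique diagnostics."""

    slope: float
    intercept: float
    r_squared: Optional[float]
    n: int
    residual_sd: float
    se_slope: float
    se_intercept: float
    x_mean: float
    sxx: float
    confidence_level: float = 0.95

    @property
    def x_intercept(self) -> Optional[float]:
        """Where the fitted line crosses y = 0; None for a flat line."""
        if self.slope == 0:
            return None
        return -self.intercept / self.slope

    @property
    def r_squared_defined(self) -> bool:
        return self.r_squared is not None


def ols_regression(
    x: Sequence[float],
    y: Sequence[float],
    confidence_level: float = 0.95,
) -> RegressionResult:
    """Ordinary least squares of y on x (free intercept).

    R-squared is flagged undefined (None) when y is constant; constant x is
    an error since the slope is unidentifiable.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1-D of equal length")
    if x.size < 2:
        raise ValidationError("need at least two points")
    if np.ptp(x) == 0:
        raise ValidationError("x is constant; slope unidentifiable")

    fit = sm.OLS(y, sm.add_constant(x)).fit()
    intercept, slope = fit.params
    n = x.size
    sst = float(((y - y.mean()) ** 2).sum())
    ssr = float((fit.resid**2).sum())
    r2 = None if sst == 0 else 1.0 - ssr / sst
    s = math.sqrt(ssr / (n - 2)) if n > 2 else float("nan")
    se_intercept, se_slope = fit.bse
    return RegressionResult(
        slope=float(slope),
        intercept=float(intercept),
        r_squared=r2,
        n=n,
        residual_sd=s,
        se_slope=float(se_slope),
        se_intercept=float(se_intercept),
        x_mean=float(x.mean()),
        sxx=float(((x - x.mean()) ** 2).sum()),
        confidence_level=confidence_level,
    )


def confidence_band(
    reg: RegressionResult, x_grid: Sequence[float]
) -> Tuple[np.ndarray, np.ndarray]:
    """Pointwise confidence band for the mean response of the fitted line.

    At each x: yhat +/- t_{1-alpha/2, n-2} * s * sqrt(1/n + (x-xbar)^2/Sxx).
    This is the band drawn around regression lines in calibration plots (not
    a prediction band for new observations).
    """
    if reg.n < 3:
        raise ValidationError("confidence band needs n >= 3")
    x_grid = np.asarray(x_grid, dtype=float)
    yhat = reg.intercept + reg.slope * x_grid
    tcrit = stats.t.ppf(0.5 + reg.confidence_level / 2.0, reg.n - 2)
    half = tcrit * reg.residual_sd * np.sqrt(
        1.0 / reg.n + (x_grid - reg.x_mean) ** 2 / reg.sxx
    )
    return yhat - half, yhat + half


def diagnostics(
    reg: RegressionResult,
    limits: Optional[DetectionLimits] = None,
    y: Optional[Sequence[float]] = None,
    tol: float = 1e-9,
) -> Dict[str, object]:
    """Interpret a cross-technique regression.

    Reports both intercepts with shift labels, the slope as relative
    sensitivity, and — given detection limits for the y-axis technique —
    flags a positive y-intercept as chemical background and counts data
    points below the LOD or between LOD and LLOQ.
    """
    report: Dict[str, object] = {
        "slope": reg.slope,
        "y_intercept": reg.intercept,
        "x_intercept": reg.x_intercept,
        "r_squared": reg.r_squared,
    }
    balanced = abs(reg.slope - 1.0) <= tol and abs(reg.intercept) <= tol
    report["sensitivity"] = (
        "balanced response"
        if balanced
        else (
            "y-axis technique more sensitive"
            if reg.slope > 1
            else "x-axis technique more sensitive"
        )
    )
    xi = reg.x_intercept
    report["x_shift"] = (
        "positive x-intercept shift: higher LOD/LLOQ of the x-axis technique"
        if xi is not None and xi > tol
        else "no positive x-intercept shift"
    )
    flags: List[str] = []
    if reg.intercept > tol:
        msg = "positive y-intercept shift"
        if limits is not None and limits.lod > 0:
            msg += (
                ": consistent with unspecific/chemical background on the "
                "y-axis technique"
            )
            flags.append("chemical_background")
        report["y_shift"] = msg
    else:
        report["y_shift"] = "no positive y-intercept shift"
    if limits is not None and y is not None:
        y = np.asarray(y, dtype=float)
        report["n_below_lod"] = int((y < limits.lod).sum())
        report["n_between_lod_lloq"] = int(
            ((y >= limits.lod) & (y < limits.lloq)).sum()
        )
    report["flags"] = flags
    return report


def cross_modality(
    maldi_means: Mapping[str, float],
    desi_means: Mapping[str, float],
) -> RegressionResult:
    """OLS of DESI mean abundances on MALDI mean abundances over the
    specimens both modalities measured (matched by specimen ID)."""
    shared = sorted(set(maldi_means) & set(desi_means))
    if len(shared) < 2:
        raise ValidationError(
            f"need >= 2 matched specimens, got {len(shared)}"
        )
    x = [maldi_means[s] for s in shared]
    y = [desi_means[s] for s in shared]
    return ols_regression(x, y)
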