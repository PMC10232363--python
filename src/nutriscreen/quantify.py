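"""Absolute quantification of fluid metabolites from external standard curves.

Chemical standards serially diluted over a wide range (5 mM down to 1 μM
in the reference workflow) define a linear relationship between
normalized peak area and concentration; sample responses are inverted
through that line.  Values outside the calibrated range are returned with
an extrapolation flag rather than refused — interstitial-fluid levels can
legitimately sit below the lowest standard.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import linregress

from .errors import DataError, DegenerateDesignError, UnquantifiableError
from .stratify import welch_t

R2_WARN = 0.98


@dataclass
class StandardCurve:
    analyte: str
    conc: np.ndarray
    response: np.ndarray
    slope: float
    intercept: float
    r_squared: float
    calibrated_range: tuple[float, float]


def fit_standard_curve(conc, response, analyte: str = "") -> StandardCurve:
    """OLS fit response = slope * conc + intercept over >= 3 distinct levels."""
    conc = np.asarray(conc, dtype=float)
    response = np.asarray(response, dtype=float)
    if conc.shape != response.shape or conc.ndim != 1:
        raise DataError("conc and response must be 1-D vectors of equal length")
    if np.unique(conc).size < 3:
        raise DegenerateDesignError(
            f"{analyte or 'standard curve'}: need >= 3 distinct concentration levels"
        )
    fit = linregress(conc, response)
    r2 = float(fit.rvalue**2)
    if r2 < R2_WARN:
        warnings.warn(
            f"{analyte or 'standard curve'}: r^2 = {r2:.4f} below {R2_WARN}", stacklevel=2
        )
    return StandardCurve(
        analyte=analyte,
        conc=conc,
        response=response,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=r2,
        calibrated_range=(float(conc.min()), float(conc.max())),
    )


def interpolate_concentration(curve: StandardCurve, response):
    """Invert the standard curve: (concentration, extrapolated flag).

    Negative concentrations (responses below the fitted blank) are
    returned flagged, never silently clipped.
    """
    if curve.slope == 0:
        raise UnquantifiableError(f"{curve.analyte}: zero-slope standard curve")
    response = np.asarray(response, dtype=float)
    conc = (response - curve.intercept) / curve.slope
    lo, hi = curve.calibrated_range
    extrapolated = (conc < lo) | (conc > hi)
    if conc.ndim == 0:
        return float(conc), bool(extrapolated)
    return conc, extrapolated


def summarize_fluid(
    concentrations: pd.DataFrame,
    value_col: str = "conc",
    group_col: str = "group",
    expected_groups: list[str] | None = None,
) -> pd.DataFrame:
    """Per-group median and IQR; a Welch t comparison when exactly 2 groups.

    Returns one row per group with columns n, median, q1, q3, iqr, and
    (for two-group designs) the shared t_stat and p_value.
    """
    if concentrations.empty:
        raise DataError("no concentrations to summarize")
    if expected_groups is not None:
        present = set(concentrations[group_col])
        if empty := [g for g in expected_groups if g not in present]:
            raise DataError(f"empty groups: {empty}")
    rows = []
    for g, sub in concentrations.groupby(group_col, sort=False):
        v = sub[value_col].to_numpy(float)
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        rows.append({"group": g, "n": v.size, "median": med, "q1": q1, "q3": q3,
                     "iqr": q3 - q1})
    out = pd.DataFrame(rows)
    if len(out) == 2:
        ga, gb = out["group"]
        a = concentrations.loc[concentrations[group_col] == ga, value_col]
        b = concentrations.loc[concentrations[group_col] == gb, value_col]
        if len(a) >= 2 and len(b) >= 2:
            t, p = welch_t(a, b)
            out["t_stat"], out["p_value"] = t, p
    return out
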