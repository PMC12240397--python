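"""Regressions of described-species numbers on density and taxonomist counts.

Five spreadsheet-trendline families are supported — linear, logarithmic,
exponential, power ("potential") and second-degree polynomial — and the best
family for a predictor/response pair is the applicable one with the highest
r-squared.  Exponential and power fits are performed on the log-transformed
response (power also log-transforms the predictor), and their r-squared is
reported on the fitting (transformed) scale, the trendline convention; the
back-transformed r-squared is available as a diagnostic.

Two analysis windows are used: the cumulative series over the full
1753-2020 window, and per-decade counts over the recent 1961-2020 decades.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from floragap.discovery_curves import DecadeSeries

__all__ = [
    "FAMILIES",
    "FamilyInapplicableError",
    "RegressionFit",
    "fit_family",
    "best_family",
    "window_modes",
]

FAMILIES = ("linear", "logarithmic", "exponential", "power", "polynomial2")

_N_PARAMS = {
    "linear": 2,
    "logarithmic": 2,
    "exponential": 2,
    "power": 2,
    "polynomial2": 3,
}


class FamilyInapplicableError(ValueError):
    """The family's transform requires positivity the data lack."""


@dataclass
class RegressionFit:
    predictor: str
    response_mode: str
    family: str
    coefficients: tuple[float, ...]
    r2: float
    n: int
    window: tuple[int, int] | None = None
    r2_back_transformed: float | None = None

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        c = self.coefficients
        if self.family == "linear":
            return c[0] + c[1] * x
        if self.family == "logarithmic":
            return c[0] + c[1] * np.log(x)
        if self.family == "exponential":
            return c[0] * np.exp(c[1] * x)
        if self.family == "power":
            return c[0] * x ** c[1]
        if self.family == "polynomial2":
            return c[0] + c[1] * x + c[2] * x**2
        raise ValueError(self.family)


def _r2(y: np.ndarray, yhat: np.ndarray) -> float:
    sst = float(np.sum((y - y.mean()) ** 2))
    # guard against float dust when the response is constant (sst ~ ulp^2)
    if sst <= 1e-12 * max(1.0, float(np.sum(y * y))):
        return 0.0  # degenerate constant response
    sse = float(np.sum((y - yhat) ** 2))
    return 1.0 - sse / sst


def fit_family(
    x,
    y,
    family: str,
    predictor: str = "x",
    response_mode: str = "cumulative",
    window: tuple[int, int] | None = None,
) -> RegressionFit:
    """Least-squares fit of one trendline family (>= 4 paired points)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be aligned 1-D arrays")
    if len(x) < 4:
        raise ValueError("need at least 4 paired points")
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}; choose from {FAMILIES}")
    if family in {"logarithmic", "power"} and np.any(x <= 0):
        raise FamilyInapplicableError(f"{family} requires positive x")
    if family in {"exponential", "power"} and np.any(y <= 0):
        raise FamilyInapplicableError(f"{family} requires positive y")

    back_r2 = None
    if family == "linear":
        coef = np.polyfit(x, y, 1)
        coefs = (float(coef[1]), float(coef[0]))
        r2 = _r2(y, coefs[0] + coefs[1] * x)
    elif family == "logarithmic":
        lx = np.log(x)
        coef = np.polyfit(lx, y, 1)
        coefs = (float(coef[1]), float(coef[0]))
        r2 = _r2(y, coefs[0] + coefs[1] * lx)
    elif family == "exponential":
        ly = np.log(y)
        coef = np.polyfit(x, ly, 1)
        coefs = (float(np.exp(coef[1])), float(coef[0]))
        r2 = _r2(ly, coef[1] + coef[0] * x)
        back_r2 = _r2(y, coefs[0] * np.exp(coefs[1] * x))
    elif family == "power":
        lx, ly = np.log(x), np.log(y)
        coef = np.polyfit(lx, ly, 1)
        coefs = (float(np.exp(coef[1])), float(coef[0]))
        r2 = _r2(ly, coef[1] + coef[0] * lx)
        back_r2 = _r2(y, coefs[0] * x ** coefs[1])
    else:  # polynomial2
        coef = np.polyfit(x, y, 2)
        coefs = (float(coef[2]), float(coef[1]), float(coef[0]))
        r2 = _r2(y, coefs[0] + coefs[1] * x + coefs[2] * x**2)

    return RegressionFit(
        predictor=predictor, response_mode=response_mode, family=family,
        coefficients=coefs, r2=float(r2), n=len(x), window=window,
        r2_back_transformed=back_r2,
    )


def best_family(
    x,
    y,
    families=FAMILIES,
    predictor: str = "x",
    response_mode: str = "cumulative",
    window: tuple[int, int] | None = None,
) -> RegressionFit:
    """Applicable family with maximal r-squared; ties go to fewer parameters.

    The result is invariant to the order families are supplied (the final
    tie-break is the family name).
    """
    fits = []
    for fam in families:
        try:
            fits.append(
                fit_family(x, y, fam, predictor=predictor,
                           response_mode=response_mode, window=window)
            )
        except FamilyInapplicableError:
            continue
    if not fits:
        raise FamilyInapplicableError("no regression family applicable to the data")
    fits.sort(key=lambda f: (-f.r2, _N_PARAMS[f.family], f.family))
    return fits[0]


def window_modes(
    series: DecadeSeries, recent_start: int = 1961
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """The two analysis windows used for predictor regressions.

    Returns ``(full_starts, cumulative_full, recent_starts, per_decade_recent)``:
    the cumulative series over every decade in the input window, and the raw
    per-decade counts for decades starting at *recent_start* or later
    (1961-1970 ... 2011-2020 for the default window, six points).
    """
    full_starts = series.decade_start
    cumulative = series.cumulative
    recent = series.decade_start >= recent_start
    return full_starts, cumulative, series.decade_start[recent], series.described[recent]
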