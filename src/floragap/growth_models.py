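"""Asymptotic growth models for cumulative discovery curves.

Four nonlinear forms are fitted to the cumulative number of species described
per decade (abscissa t = decade index 1..n by default):

    gompertz3p:  y = a * exp(-exp(-b (t - c)))
    gompertz4p:  y = d + (a - d) * exp(-exp(-b (t - c)))
    logistic3p:  y = a / (1 + exp(-b (t - c)))
    weibull:     y = a * (1 - exp(-(t / b)^c))

The asymptote ``a`` is read as the total (described + undescribed) species
richness.  Fits are ordinary least squares with a multi-start grid over the
asymptote ({1.05, 1.2, 1.5, 2, 4} x max cumulative) because these curves are
prone to non-convergence on right-censored series; failures are captured and
reported, never raised.  Model support uses Gaussian-error information
criteria

    AIC  = n ln(RSS/n) + 2k,   AICc = AIC + 2k(k+1)/(n-k-1),
    BIC  = n ln(RSS/n) + k ln(n),

with k = number of curve parameters + 1 (residual variance).  A perfect fit
(RSS = 0) is reported with a -inf criterion sentinel and wins any weighting,
the limit behaviour of the Gaussian criterion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import OptimizeWarning, curve_fit

from floragap.discovery_curves import DecadeSeries

__all__ = [
    "MODELS",
    "ModelFit",
    "fit_growth_model",
    "akaike_weights",
    "information_criteria",
    "fits_to_frame",
]

_Z95 = 1.959963984540054  # two-sided 95% normal quantile


def gompertz3p(t, a, b, c):
    return a * np.exp(-np.exp(-b * (t - c)))


def gompertz4p(t, a, b, c, d):
    return d + (a - d) * np.exp(-np.exp(-b * (t - c)))


def logistic3p(t, a, b, c):
    return a / (1.0 + np.exp(-b * (t - c)))


def weibull_growth(t, a, b, c):
    with np.errstate(invalid="ignore"):
        return a * (1.0 - np.exp(-((np.asarray(t, dtype=float) / b) ** c)))


MODELS = {
    "gompertz3p": (gompertz3p, 3),
    "gompertz4p": (gompertz4p, 4),
    "logistic3p": (logistic3p, 3),
    "weibull": (weibull_growth, 3),
}

_RSS_ZERO = 1e-10  # below this the fit is treated as exact


@dataclass
class ModelFit:
    """One nonlinear model's parameters, fit statistics and asymptote."""

    model_id: str
    params: np.ndarray | None
    n: int
    k: int
    rss: float | None
    aic: float | None
    aicc: float | None
    bic: float | None
    asymptote: float | None
    asymptote_se: float | None
    converged: bool
    message: str = ""
    cov: np.ndarray | None = field(default=None, repr=False)

    @property
    def ci95(self) -> tuple[float, float] | None:
        if self.asymptote is None or self.asymptote_se is None:
            return None
        half = _Z95 * self.asymptote_se
        return (self.asymptote - half, self.asymptote + half)


def information_criteria(rss: float, n: int, k: int) -> tuple[float, float, float]:
    """Gaussian-error AIC, AICc, BIC from a residual sum of squares."""
    if rss <= _RSS_ZERO:
        return (-np.inf, -np.inf, -np.inf)
    aic = n * np.log(rss / n) + 2 * k
    aicc = aic + (2 * k * (k + 1)) / (n - k - 1) if n - k - 1 > 0 else np.inf
    bic = n * np.log(rss / n) + k * np.log(n)
    return (aic, aicc, bic)


def _starts_for(model_id: str, t: np.ndarray, y: np.ndarray) -> list[np.ndarray]:
    """Multi-start initial parameter vectors from curve geometry."""
    ymax = float(np.max(y)) if np.max(y) > 0 else 1.0
    span = float(t[-1] - t[0]) or 1.0
    starts = []
    for fa in (1.05, 1.2, 1.5, 2.0, 4.0):
        a0 = fa * ymax
        # abscissa where the curve crosses half the candidate asymptote
        half = a0 / 2.0
        c0 = float(t[np.argmin(np.abs(y - half))])
        b0 = 4.0 / span  # gentle default rate; refined by the optimizer
        if model_id == "gompertz3p":
            starts.append(np.array([a0, b0, c0]))
            starts.append(np.array([a0, 2 * b0, c0]))
        elif model_id == "gompertz4p":
            starts.append(np.array([a0, b0, c0, 0.0]))
            starts.append(np.array([a0, 2 * b0, c0, float(y[0])]))
        elif model_id == "logistic3p":
            starts.append(np.array([a0, b0, c0]))
            starts.append(np.array([a0, 2 * b0, c0]))
        elif model_id == "weibull":
            b0w = max(c0, 1.0)
            starts.append(np.array([a0, b0w, 2.0]))
            starts.append(np.array([a0, b0w, 1.0]))
    return starts


def fit_growth_model(
    series: DecadeSeries,
    model_id: str,
    abscissa: str = "index",
) -> ModelFit:
    """Least-squares fit of one asymptotic model to a cumulative series.

    ``abscissa`` is ``"index"`` (t = 1..n, the default) or ``"year"``
    (calendar decade start).  Non-convergence and non-finite asymptotes are
    captured in the returned :class:`ModelFit`, never raised.
    """
    if model_id not in MODELS:
        raise ValueError(f"unknown model {model_id!r}; choose from {sorted(MODELS)}")
    func, n_par = MODELS[model_id]
    k = n_par + 1
    y = series.cumulative.astype(float)
    n = len(y)
    if n < k + 2:
        raise ValueError(f"need at least {k + 2} decades to fit {model_id}, got {n}")
    if np.any(np.diff(y) < 0):
        raise ValueError("cumulative series must be non-decreasing")
    t = series.t_index.astype(float) if abscissa == "index" else series.decade_start.astype(float)

    if np.ptp(y) == 0:
        # a flat series has reached its plateau: the only identified quantity
        # is the plateau itself; shape parameters are degenerate
        return ModelFit(
            model_id=model_id, params=None, n=n, k=k, rss=0.0, aic=-np.inf,
            aicc=-np.inf, bic=-np.inf, asymptote=float(y[0]), asymptote_se=None,
            converged=True, message="degenerate: constant series",
        )

    best: tuple[float, np.ndarray, np.ndarray] | None = None
    lower = np.full(n_par, -np.inf)
    upper = np.full(n_par, np.inf)
    lower[0] = 0.0  # asymptote non-negative
    if model_id == "weibull":
        lower[1] = 1e-9  # scale must stay positive
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", OptimizeWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        for p0 in _starts_for(model_id, t, y):
            try:
                popt, pcov = curve_fit(
                    func, t, y, p0=p0, bounds=(lower, upper), maxfev=20000
                )
            except (RuntimeError, ValueError):
                continue
            resid = y - func(t, *popt)
            rss = float(resid @ resid)
            if not np.isfinite(rss):
                continue
            if best is None or rss < best[0]:
                best = (rss, popt, pcov)

    if best is None or not np.isfinite(best[1][0]):
        return ModelFit(
            model_id=model_id, params=None, n=n, k=k, rss=None, aic=None,
            aicc=None, bic=None, asymptote=None, asymptote_se=None,
            converged=False, message="no start converged",
        )
    rss, popt, pcov = best
    aic, aicc, bic = information_criteria(rss, n, k)
    var_a = pcov[0, 0] if np.all(np.isfinite(pcov)) else np.nan
    se = float(np.sqrt(var_a)) if np.isfinite(var_a) and var_a >= 0 else None
    return ModelFit(
        model_id=model_id, params=popt, n=n, k=k, rss=rss, aic=aic, aicc=aicc,
        bic=bic, asymptote=float(popt[0]), asymptote_se=se, converged=True,
        cov=pcov,
    )


def akaike_weights(fits: list[ModelFit], criterion: str = "aicc") -> np.ndarray:
    """Akaike weights w_i = exp(-D_i/2) / sum_j exp(-D_j/2).

    D_i is the criterion difference to the best converged fit; non-converged
    fits get weight 0.  When one or more fits carry the exact-fit -inf
    sentinel, the weight is shared equally among them.
    """
    if criterion not in {"aic", "aicc", "bic"}:
        raise ValueError(f"criterion must be aic, aicc or bic, not {criterion!r}")
    ics = np.array(
        [getattr(f, criterion) if f.converged else np.nan for f in fits], dtype=float
    )
    conv = ~np.isnan(ics)
    if not conv.any():
        raise ValueError("no converged fits: the data support no model")
    weights = np.zeros(len(fits))
    if np.isneginf(ics[conv]).any():
        exact = conv & np.isneginf(ics)
        weights[exact] = 1.0 / exact.sum()
        return weights
    delta = ics - np.nanmin(ics)
    rel = np.where(conv, np.exp(-delta / 2.0), 0.0)
    return rel / rel.sum()


def fits_to_frame(fits: list[ModelFit]) -> pd.DataFrame:
    """Fit report mirroring the published table layout (absent values for
    non-converged fits)."""
    rows = []
    for f in fits:
        ci = f.ci95
        rows.append(
            {
                "model": f.model_id,
                "asymptote": f.asymptote,
                "ci95_low": ci[0] if ci else None,
                "ci95_high": ci[1] if ci else None,
                "rss": f.rss,
                "aic": f.aic,
                "aicc": f.aicc,
                "bic": f.bic,
                "converged": f.converged,
            }
        )
    return pd.DataFrame(rows)
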