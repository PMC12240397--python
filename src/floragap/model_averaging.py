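"""Akaike-weight model averaging, completeness indices and aggregation.

The averaged asymptote is the weight-mixed estimate
``theta_bar = sum_i w_i a_i`` with unconditional standard error

    se_u = sqrt( sum_i w_i (se_i^2 + (a_i - theta_bar)^2) ),

which carries both within-model variance and between-model spread.  The
Completeness Index expresses observed richness as a percentage of estimated
total richness, ``100 S_obs / (S_obs + remaining)``; its conservative
counterpart divides by the upper 95% bound of the asymptote instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from floragap.growth_models import ModelFit, _Z95

__all__ = [
    "AveragedEstimate",
    "AggregateReport",
    "average_models",
    "completeness_index",
    "aggregate",
]


@dataclass
class AveragedEstimate:
    """Weighted-asymptote estimate and derived completeness figures for one stratum."""

    stratum: str
    s_obs: float
    theta_bar: float
    se_u: float
    ci_low: float
    ci_high: float
    flags: tuple[str, ...] = ()

    @property
    def remaining(self) -> float:
        return self.theta_bar - self.s_obs

    @property
    def remaining_upper(self) -> float:
        return self.ci_high - self.s_obs

    @property
    def completeness_pct(self) -> float:
        return completeness_index(self.s_obs, self.remaining)

    @property
    def completeness_lower_pct(self) -> float:
        return completeness_index(self.s_obs, self.remaining_upper)

    @classmethod
    def from_remaining(
        cls, stratum: str, s_obs: float, remaining: float, remaining_upper: float
    ) -> "AveragedEstimate":
        """Build an estimate directly from remaining-species figures (as
        printed in published summary tables)."""
        theta = s_obs + remaining
        upper = s_obs + remaining_upper
        se = (upper - theta) / _Z95 if remaining_upper >= remaining else 0.0
        return cls(
            stratum=stratum, s_obs=s_obs, theta_bar=theta, se_u=se,
            ci_low=theta - (upper - theta), ci_high=upper,
        )


def completeness_index(s_obs: float, predicted_remaining: float) -> float:
    """Percentage of the estimated total richness already catalogued.

    ``100 * S_obs / (S_obs + remaining)``; strictly decreasing in the
    predicted remaining count for fixed S_obs.
    """
    if s_obs <= 0:
        raise ValueError("observed richness must be positive")
    denom = s_obs + predicted_remaining
    if denom <= 0:
        raise ValueError("estimated total richness must be positive")
    return 100.0 * s_obs / denom


def average_models(
    fits: list[ModelFit],
    weights: np.ndarray,
    s_obs: float,
    stratum: str = "all",
) -> AveragedEstimate:
    """Combine model fits into one asymptote estimate with unconditional SE.

    Fits with zero weight are excluded.  A positive-weight fit lacking an SE
    (singular covariance) has its variance term replaced by the largest
    available variance among positive-weight fits — a conservative inflation;
    if no fit carries an SE the within-model terms are zero and the estimate
    is flagged ``no_within_model_se``.
    """
    weights = np.asarray(weights, dtype=float)
    if len(weights) != len(fits):
        raise ValueError("one weight per fit required")
    active = [(f, w) for f, w in zip(fits, weights) if w > 0]
    if not active or not any(f.converged for f, _ in active):
        raise ValueError("no converged fits with positive weight")
    flags: list[str] = []
    ses = [f.asymptote_se for f, _ in active]
    known = [s for s in ses if s is not None]
    if not known:
        fill = 0.0
        flags.append("no_within_model_se")
    else:
        fill = max(known)
        if len(known) < len(ses):
            flags.append("se_inflated")
    theta = sum(w * f.asymptote for f, w in active) / sum(w for _, w in active)
    var = sum(
        w * (((f.asymptote_se if f.asymptote_se is not None else fill) ** 2)
             + (f.asymptote - theta) ** 2)
        for f, w in active
    ) / sum(w for _, w in active)
    se_u = float(np.sqrt(var))
    est = AveragedEstimate(
        stratum=stratum, s_obs=float(s_obs), theta_bar=float(theta), se_u=se_u,
        ci_low=float(theta - _Z95 * se_u), ci_high=float(theta + _Z95 * se_u),
        flags=tuple(flags),
    )
    if est.remaining < 0:
        est.flags = est.flags + ("negative_remaining",)
    return est


@dataclass
class AggregateReport:
    """Per-stratum table plus exact totals of remaining-species figures."""

    table: pd.DataFrame
    total_remaining: float
    total_remaining_upper: float
    total_media: float

    @property
    def media(self) -> pd.Series:
        return self.table["media"]


def aggregate(estimates: list[AveragedEstimate]) -> AggregateReport:
    """Aggregate per-stratum averaged estimates into totals.

    Totals are exact sums of their addends; the per-stratum *media* is the
    midpoint (remaining + remaining_upper) / 2.  Rounding is left to
    presentation.
    """
    if not estimates:
        raise ValueError("at least one stratum required")
    rows = []
    for e in estimates:
        rows.append(
            {
                "stratum": e.stratum,
                "s_obs": e.s_obs,
                "theta_bar": e.theta_bar,
                "remaining": e.remaining,
                "remaining_upper": e.remaining_upper,
                "media": (e.remaining + e.remaining_upper) / 2.0,
                "completeness_pct": e.completeness_pct,
                "completeness_lower_pct": e.completeness_lower_pct,
            }
        )
    table = pd.DataFrame(rows)
    return AggregateReport(
        table=table,
        total_remaining=float(table["remaining"].sum()),
        total_remaining_upper=float(table["remaining_upper"].sum()),
        total_media=float(table["media"].sum()),
    )
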