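"""Historical dose-trend analysis.

Entrance surface air kerma of a pelvic radiograph has fallen by orders of
magnitude since the 1890s; the decline is well described by a simple
exponential,

    ESAK(year) = a0 × exp(−k × (year − reference_year)),

fitted by ordinary least squares on log-transformed doses.  Companion
diagnostics: the decline factor between two years, interquartile spread of
dose distributions (the 75th percentile being the conventional diagnostic
reference level), and quadrature combination of the relative errors of a
multi-parameter dose reconstruction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError

__all__ = [
    "TrendPoint",
    "TrendFit",
    "fit_exponential_trend",
    "decline_factor",
    "percentile_spread",
    "combine_relative_errors",
]

DEFAULT_REFERENCE_YEAR = 1896


@dataclass(frozen=True)
class TrendPoint:
    """One (year, entrance surface air kerma) observation; ESAK in mGy."""

    year: float
    esak: float

    def __post_init__(self):
        if not 1890 <= self.year <= 2100:
            raise ValidationError("year outside [1890, 2100]", field="year")
        if self.esak <= 0:
            raise ValidationError("esak must be > 0 (log fit)", field="esak")


@dataclass(frozen=True)
class TrendFit:
    """Exponential decline ESAK(y) = a0 × exp(−k × (y − reference_year)).

    a0 : fitted ESAK at the reference year, mGy.
    k : decline rate per year (positive = dose decreasing).
    residual_sd_log : standard deviation of the log residuals
        (sqrt(SSR / (n − 2))).
    k_stderr : standard error of k from the OLS fit.
    """

    a0: float
    k: float
    reference_year: float
    residual_sd_log: float
    k_stderr: float = math.nan
    n_points: int = 0

    def __post_init__(self):
        if self.a0 <= 0:
            raise ValidationError("must be > 0", field="a0")
        if self.residual_sd_log < 0:
            raise ValidationError("must be >= 0", field="residual_sd_log")

    def predict(self, year: float | np.ndarray) -> float | np.ndarray:
        return self.a0 * np.exp(-self.k * (np.asarray(year) - self.reference_year))


def fit_exponential_trend(
    points: list[TrendPoint], reference_year: float = DEFAULT_REFERENCE_YEAR
) -> TrendFit:
    """OLS fit of ln(ESAK) on (year − reference_year).

    Requires at least three points spanning at least two distinct years.
    """
    if len(points) < 3:
        raise ValidationError("need at least 3 points to fit a trend")
    years = np.array([p.year for p in points], dtype=float)
    if np.unique(years).size < 2:
        raise ValidationError("points must span at least 2 distinct years")
    x = years - reference_year
    y = np.log(np.array([p.esak for p in points], dtype=float))
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    n = len(points)
    ssr = float(resid @ resid)
    sd = math.sqrt(ssr / (n - 2)) if n > 2 else 0.0
    sxx = float(((x - x.mean()) ** 2).sum())
    se_k = sd / math.sqrt(sxx) if sxx > 0 else math.nan
    return TrendFit(
        a0=math.exp(intercept),
        k=-slope,
        reference_year=reference_year,
        residual_sd_log=sd,
        k_stderr=se_k,
        n_points=n,
    )


def decline_factor(fit: TrendFit, year_from: float, year_to: float) -> float:
    """Factor by which the fitted dose fell between two years:
    exp(k × (year_to − year_from))."""
    return math.exp(fit.k * (year_to - year_from))


def percentile_spread(
    doses: list[float] | np.ndarray, p_low: float = 25.0, p_high: float = 75.0
) -> tuple[float, float, float]:
    """(q_low, q_high, q_high / q_low) of a dose distribution.

    Quantiles use linear interpolation between order statistics (the
    common "type 7" rule).  A wide interquartile ratio (> 2 is typical of
    national dose surveys decades after reference levels were introduced)
    signals unexploited optimisation potential.
    """
    arr = np.asarray(doses, dtype=float)
    if arr.size == 0:
        raise ValidationError("dose list is empty")
    if np.any(arr <= 0):
        raise ValidationError("all doses must be > 0", field="doses")
    if not 0 < p_low < p_high < 100:
        raise ValidationError("need 0 < p_low < p_high < 100")
    q_low, q_high = np.percentile(arr, [p_low, p_high])
    return float(q_low), float(q_high), float(q_high / q_low)


def combine_relative_errors(relative_sds: list[float]) -> float:
    """Quadrature combination sqrt(Σ σᵢ²) of independent relative errors.

    Models a dose reconstructed as the product of several parameters, each
    with an independent multiplicative (log-space) uncertainty; e.g. seven
    parameters at 20% each combine to ~53%.
    """
    if len(relative_sds) == 0:
        raise ValidationError("need at least one relative sd")
    for v in relative_sds:
        if v < 0:
            raise ValidationError("relative sd must be >= 0", field="relative_sds")
    return math.sqrt(sum(v * v for v in relative_sds))
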