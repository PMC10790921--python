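"""Nonparametric trend analysis for vigilance performance curves.

The analysis chain applied to each (mode x screen) ensemble curve:

* **Durbin-Watson** — residual first-order autocorrelation of an OLS line
  fit on bucket index, with the 5% one-regressor Savin-White bounds
  (d_L, d_U).  The standard three-zone verdict is reported (D < d_L:
  positive autocorrelation; d_L <= D <= d_U: inconclusive; D > d_U: none
  detected) together with the simpler binary rule D < d_U
  (``du_rule_significant``) for comparability with reports that use it.
* **Mann-Kendall** — S = sum of pairwise sign differences, tie-corrected
  variance, continuity-corrected normal deviate Z, two-sided p, and a
  trend direction (positive/negative when p < 0.05, else none).
* **Sen's slope** — median of all pairwise slopes, with the rank-based
  confidence band driven by the Mann-Kendall variance.
* **split-half reliability** — Pearson correlation between the odd- and
  even-timestamp halves of the pooled minute-level series.

Missing (NaN) values are dropped pairwise; pairwise slopes keep their
original bucket spacing in the denominator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.stattools import durbin_watson as _dw_stat

from .scoring import VigilanceCurve, ensemble_average

__all__ = [
    "MannKendallResult",
    "SenSlopeResult",
    "DurbinWatsonResult",
    "mann_kendall",
    "sens_slope",
    "durbin_watson",
    "dw_bounds",
    "split_half_reliability",
    "trend_report",
]


@dataclass(frozen=True)
class MannKendallResult:
    S: int
    var_S: float
    se: float
    Z: float
    p_two_sided: float
    direction: str  # positive | negative | none
    n: int


@dataclass(frozen=True)
class SenSlopeResult:
    slope: float
    ci_lower: float
    ci_upper: float
    alpha: float
    n_pairs: int


@dataclass(frozen=True)
class DurbinWatsonResult:
    D: float
    d_lower: float
    d_upper: float
    verdict: str  # positive_autocorrelation | inconclusive | none_detected
    du_rule_significant: bool
    n: int


def _clean(series: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(series, dtype=float)
    idx = np.arange(len(x), dtype=float)
    keep = ~np.isnan(x)
    return idx[keep], x[keep]


def mk_variance(values: np.ndarray) -> float:
    """Tie-corrected null variance of the Mann-Kendall S statistic:
    [n(n-1)(2n+5) - sum_p t_p(t_p-1)(2t_p+5)] / 18 over tie groups of
    size t_p."""
    n = len(values)
    var = n * (n - 1) * (2 * n + 5)
    _, tie_counts = np.unique(values, return_counts=True)
    for tp in tie_counts[tie_counts > 1]:
        var -= tp * (tp - 1) * (2 * tp + 5)
    return var / 18.0


def mann_kendall(series: Sequence[float]) -> MannKendallResult:
    """Mann-Kendall monotonic-trend test with continuity correction.

    NaNs are dropped (order preserved).  Requires >= 4 non-missing
    values.  The direction is called only when the two-sided p-value is
    below 0.05.
    """
    _, x = _clean(series)
    n = len(x)
    if n < 4:
        raise ValueError(f"need >= 4 non-missing values, got {n}")
    s = int(np.sign(x[None, :] - x[:, None])[np.triu_indices(n, k=1)].sum())
    var_s = mk_variance(x)
    se = math.sqrt(var_s)
    if s > 0:
        z = (s - 1) / se
    elif s < 0:
        z = (s + 1) / se
    else:
        z = 0.0
    p = 2.0 * stats.norm.sf(abs(z))
    if p < 0.05:
        direction = "positive" if s > 0 else "negative"
    else:
        direction = "none"
    return MannKendallResult(S=s, var_S=var_s, se=se, Z=z, p_two_sided=p, direction=direction, n=n)


def sens_slope(series: Sequence[float], alpha: float = 0.05) -> SenSlopeResult:
    """Sen's slope: the median of all pairwise slopes, in series units per
    bucket, with the rank-method confidence band.

    With N pairwise slopes and C = z_{1-alpha/2} * sqrt(var_S), the band
    runs from the M1-th smallest slope to the (M2+1)-th, where
    M1 = (N - C)/2 and M2 = (N + C)/2 (ranks rounded to the nearest
    integer and clipped to the available range).
    """
    idx, x = _clean(series)
    n = len(x)
    if n < 4:
        raise ValueError(f"need >= 4 non-missing values, got {n}")
    dx = x[None, :] - x[:, None]
    di = idx[None, :] - idx[:, None]
    iu = np.triu_indices(n, k=1)
    slopes = np.sort(dx[iu] / di[iu])
    n_pairs = len(slopes)
    slope = float(np.median(slopes))
    c = stats.norm.ppf(1.0 - alpha / 2.0) * math.sqrt(mk_variance(x))
    m1 = int(round((n_pairs - c) / 2.0))
    m2 = int(round((n_pairs + c) / 2.0))
    lo = slopes[min(max(m1, 1), n_pairs) - 1]
    hi = slopes[min(m2 + 1, n_pairs) - 1]
    return SenSlopeResult(
        slope=slope, ci_lower=float(lo), ci_upper=float(hi), alpha=alpha, n_pairs=n_pairs
    )


# Savin-White 5% Durbin-Watson significance bounds for a regression with an
# intercept and one regressor, n = 15..100 (standard published table);
# untabulated n are linearly interpolated.
_SAVIN_WHITE_K1 = {
    15: (1.077, 1.361), 16: (1.106, 1.371), 17: (1.133, 1.381), 18: (1.158, 1.391),
    19: (1.180, 1.401), 20: (1.201, 1.411), 21: (1.221, 1.420), 22: (1.239, 1.429),
    23: (1.257, 1.437), 24: (1.273, 1.446), 25: (1.288, 1.454), 26: (1.302, 1.461),
    27: (1.316, 1.469), 28: (1.328, 1.476), 29: (1.341, 1.483), 30: (1.352, 1.489),
    31: (1.363, 1.496), 32: (1.373, 1.502), 33: (1.383, 1.508), 34: (1.393, 1.514),
    35: (1.402, 1.519), 36: (1.411, 1.525), 37: (1.419, 1.530), 38: (1.427, 1.535),
    39: (1.435, 1.540), 40: (1.442, 1.544), 45: (1.475, 1.566), 50: (1.503, 1.585),
    55: (1.528, 1.601), 60: (1.549, 1.616), 65: (1.567, 1.629), 70: (1.583, 1.641),
    75: (1.598, 1.652), 80: (1.611, 1.662), 85: (1.624, 1.671), 90: (1.635, 1.679),
    95: (1.645, 1.687), 100: (1.654, 1.694),
}


def dw_bounds(n: int) -> tuple[float, float]:
    """5% Durbin-Watson (d_L, d_U) bounds for one regressor at sample size
    ``n``, linearly interpolating between tabulated sizes."""
    ns = sorted(_SAVIN_WHITE_K1)
    if n < ns[0] or n > ns[-1]:
        raise ValueError(f"n={n} outside tabulated range [{ns[0]}, {ns[-1]}]")
    if n in _SAVIN_WHITE_K1:
        return _SAVIN_WHITE_K1[n]
    lo = max(m for m in ns if m < n)
    hi = min(m for m in ns if m > n)
    w = (n - lo) / (hi - lo)
    dl = _SAVIN_WHITE_K1[lo][0] * (1 - w) + _SAVIN_WHITE_K1[hi][0] * w
    du = _SAVIN_WHITE_K1[lo][1] * (1 - w) + _SAVIN_WHITE_K1[hi][1] * w
    return (dl, du)


def durbin_watson(series: Sequence[float]) -> DurbinWatsonResult:
    """Durbin-Watson autocorrelation diagnostic on the residuals of an OLS
    line fit against bucket index.

    Requires >= 6 non-missing values and a non-degenerate fit (a perfect
    line leaves no residual variance and the statistic is undefined).
    """
    idx, x = _clean(series)
    n = len(x)
    if n < 6:
        raise ValueError(f"need >= 6 non-missing values, got {n}")
    coef = np.polyfit(idx, x, 1)
    resid = x - np.polyval(coef, idx)
    denom = float(np.sum(resid**2))
    if denom <= 1e-12 * max(1.0, float(np.sum(x**2))):
        raise ValueError("zero residual variance: Durbin-Watson statistic undefined")
    d = float(_dw_stat(resid))
    dl, du = dw_bounds(n)
    if d < dl:
        verdict = "positive_autocorrelation"
    elif d <= du:
        verdict = "inconclusive"
    else:
        verdict = "none_detected"
    return DurbinWatsonResult(
        D=d, d_lower=dl, d_upper=du, verdict=verdict, du_rule_significant=d < du, n=n
    )


def split_half_reliability(minute_series: Sequence[float]) -> float:
    """Split-half reliability of a 60-value minute-level series: Pearson r
    between the 30 odd-timestamp values (minutes 1, 3, ..., 59) and the 30
    even-timestamp values (minutes 2, 4, ..., 60), paired in rank order."""
    x = np.asarray(minute_series, dtype=float)
    if len(x) != 60:
        raise ValueError(f"expected a 60-value minute series, got {len(x)}")
    if np.isnan(x).any():
        raise ValueError("minute series contains missing values")
    odd = x[0::2]  # minutes 1, 3, ..., 59
    even = x[1::2]  # minutes 2, 4, ..., 60
    if np.std(odd) == 0 or np.std(even) == 0:
        raise ValueError("zero variance in a half: reliability undefined")
    r, _ = stats.pearsonr(odd, even)
    return float(r)


# ---------------------------------------------------------------------------
# The full trend report (8 columns: mode x screen scope)
# ---------------------------------------------------------------------------

_REPORT_ROWS = [
    "Durbin-Watson D Statistic",
    "D-lower",
    "D-upper",
    "Autocorrelation verdict",
    "Significant autocorrelation (D < d_upper)",
    "Mann-Kendall MK statistic",
    "Standard Error",
    "Z-stat",
    "P-value",
    "Trend",
    "Sens slope s statistic",
    "S-lower",
    "S-upper",
]

_REPORT_COLUMNS = [
    ("dynamic", "total", "Dynamic across all screens"),
    ("static", "total", "Static across all screens"),
    ("dynamic", "left", "Dynamic left"),
    ("static", "left", "Static left"),
    ("dynamic", "center", "Dynamic center"),
    ("static", "center", "Static center"),
    ("dynamic", "right", "Dynamic right"),
    ("static", "right", "Static right"),
]


def trend_report(
    static_curves: Sequence[VigilanceCurve],
    dynamic_curves: Sequence[VigilanceCurve],
) -> pd.DataFrame:
    """Full trend-analysis table over the two cohort ensembles.

    Eight result columns (dynamic/static x all-screens/left/center/right)
    by thirteen statistic rows: the Durbin-Watson diagnostic with bounds
    and both verdicts, the Mann-Kendall test, and Sen's slope with its
    confidence band.  Input is the per-trial curve sets of each mode; the
    ensemble average of each is analyzed.
    """
    if not static_curves or not dynamic_curves:
        raise ValueError("need curves for both static and dynamic modes")
    ensembles = {
        "static": ensemble_average(list(static_curves)),
        "dynamic": ensemble_average(list(dynamic_curves)),
    }
    data = {}
    for mode, scope, label in _REPORT_COLUMNS:
        series = ensembles[mode].series(scope)
        mk = mann_kendall(series)
        sen = sens_slope(series)
        try:
            dw = durbin_watson(series)
            dw_cells = [
                round(dw.D, 3), round(dw.d_lower, 3), round(dw.d_upper, 3),
                dw.verdict, "yes" if dw.du_rule_significant else "no",
            ]
        except ValueError:
            dw_cells = [float("nan"), float("nan"), float("nan"), "undefined", "no"]
        data[label] = dw_cells + [
            mk.S,
            round(mk.se, 3),
            round(mk.Z, 3),
            round(mk.p_two_sided, 4),
            mk.direction.capitalize(),
            round(sen.slope, 3),
            round(sen.ci_lower, 3),
            round(sen.ci_upper, 3),
        ]
    return pd.DataFrame(data, index=pd.Index(_REPORT_ROWS, name="Assumption tests and trend analyses"))
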