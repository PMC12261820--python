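"""Cohort-level missingness characterization: MAR vs MNAR.

Summing the missingness flags item-by-item across respondents turns the
cohort into an ordered series over item location.  If respondents break off
(quit and never return), each quitter stays missing for every later item, so
the series trends upward — an order-dependent, non-stationary signal, i.e.
missingness that depends on the unobserved responses themselves (MNAR).
Scattered item skipping leaves the series fluctuating around a constant
level (MAR).  The augmented Dickey-Fuller (ADF) unit-root test formalizes
the distinction: failing to reject the unit root reads as MNAR, rejecting it
as MAR.

The module also exposes the two summary-statistic comparisons used alongside
the verdict: a pooled two-sample t-test on per-person missingness and an
uncorrected Pearson chi-square on non-completion rates, both callable from
printed summary numbers alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.tsa.stattools import adfuller

from .survey import MissingFlagMatrix

__all__ = [
    "DegenerateDataError",
    "StationarityResult",
    "summed_missingness_series",
    "adf_test",
    "compare_missingness_t",
    "compare_rates_chi2",
]


class DegenerateDataError(ValueError):
    """Input carries no information for the requested test."""


@dataclass(frozen=True)
class StationarityResult:
    """ADF test outcome with the MAR/MNAR reading.

    verdict is "MNAR" exactly when p_value >= alpha (unit root not rejected).
    """

    adf_statistic: float
    p_value: float
    n_lags_used: int
    regression_terms: str
    alpha: float
    verdict: str


def summed_missingness_series(matrix: MissingFlagMatrix | np.ndarray) -> np.ndarray:
    """Per-item count of missing responses across respondents (column sums)."""
    flags = matrix.flags if isinstance(matrix, MissingFlagMatrix) else np.asarray(matrix)
    return flags.sum(axis=0, dtype=np.int64)


def adf_test(
    series, alpha: float = 0.05, regression: str = "c", autolag: str = "AIC"
) -> StationarityResult:
    """Augmented Dickey-Fuller test of the summed missingness series.

    Uses a constant deterministic term (no trend — a trend term would absorb
    exactly the drift that distinguishes MNAR) and AIC lag selection up to
    statsmodels' default Schwert rule-of-thumb maximum.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or x.size < 20:
        raise ValueError("series must be 1-D with at least 20 observations")
    if np.ptp(x) == 0:
        raise DegenerateDataError("series is constant; stationarity is undefined")
    stat, pvalue, usedlag, *_ = adfuller(x, regression=regression, autolag=autolag)
    verdict = "MNAR" if pvalue >= alpha else "MAR"
    return StationarityResult(
        adf_statistic=float(stat),
        p_value=float(pvalue),
        n_lags_used=int(usedlag),
        regression_terms=regression,
        alpha=alpha,
        verdict=verdict,
    )


def compare_missingness_t(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> tuple[float, int, float]:
    """Pooled-variance (Student) two-sample t-test from summary statistics.

    Returns (t, df, p) with df = n1 + n2 - 2.  Pooling (rather than Welch) is
    what the integer df of the headline comparison implies.  When both SDs
    are zero and the means coincide, t is defined as 0.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need at least 2 observations")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be non-negative")
    df = n1 + n2 - 2
    if sd1 == 0 and sd2 == 0:
        if mean1 == mean2:
            return 0.0, df, 1.0
        raise DegenerateDataError("zero variance with unequal means: t is unbounded")
    t, p = stats.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2, equal_var=True)
    return float(t), df, float(p)


def compare_rates_chi2(
    events1: int, n1: int, events2: int, n2: int
) -> tuple[float, int, float]:
    """Uncorrected Pearson chi-square on a 2x2 table of event rates.

    Returns (chi2, df=1, p).  No continuity correction: the uncorrected
    statistic is the one reproducible from printed counts.
    """
    for e, n in ((events1, n1), (events2, n2)):
        if n <= 0:
            raise ValueError("group sizes must be positive")
        if not 0 <= e <= n:
            raise ValueError("event counts must lie in [0, n]")
    total_events = events1 + events2
    if total_events == 0 or total_events == n1 + n2:
        raise DegenerateDataError("all or none of the observations are events")
    table = np.array([[events1, n1 - events1], [events2, n2 - events2]])
    chi2, p, df, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), int(df), float(p)
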