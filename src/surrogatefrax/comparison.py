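"""Statistical comparison of a surrogate model against a reference model.

Probabilities from both models over the same scenario grid are compared
three ways, per (age, sex, outcome) stratum:

* piecewise linear regression of surrogate on reference probabilities, on
  the percent scale, continuous at a fixed knot (default 40%), with the
  Pearson correlation of the paired probabilities;
* the value of both models at a percentile of the *reference* distribution
  (default the median), with the relative difference in percent using the
  reference value as denominator;
* a distribution-free tolerance interval over the surrogate values of the
  profiles ranked near that reference percentile.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from surrogatefrax.errors import (
    DegenerateDataError,
    EmptySelectionError,
    InsufficientDataError,
)

DEFAULT_KNOT = 40.0

REPORT_COLUMNS = [
    "age",
    "sex",
    "outcome",
    "reference_median",
    "surrogate_median",
    "relative_difference_pct",
    "ti_lo",
    "ti_hi",
    "r",
]


@dataclass(frozen=True)
class PiecewiseFit:
    """Continuous two-segment linear fit with a fixed knot.

    The model is y = intercept + slope_below * x for x <= knot and continues
    with slope_above beyond it (continuity at the knot is built into the
    hinge basis {1, x, max(0, x - knot)}).  ``r`` is the Pearson correlation
    between x and y.  When all points fall on one side of the knot the other
    segment is not identifiable: the fit reduces to simple linear regression,
    both slopes are reported equal, and ``degenerate`` is set.
    """

    knot: float
    intercept: float
    slope_below: float
    slope_above: float
    r: float
    n: int
    degenerate: bool = False

    def predict(self, x):
        x = np.asarray(x, dtype=float)
        return (
            self.intercept
            + self.slope_below * x
            + (self.slope_above - self.slope_below) * np.maximum(0.0, x - self.knot)
        )


@dataclass(frozen=True)
class ToleranceInterval:
    """Order-statistic tolerance interval; iterates as (lo, hi)."""

    lo: float
    hi: float
    under_covered: bool = False

    def __iter__(self):
        return iter((self.lo, self.hi))


@dataclass(frozen=True)
class PercentileComparison:
    """Both models' values at one percentile of the reference distribution."""

    percentile: float
    value_reference: float
    value_surrogate: float
    relative_difference_pct: float
    tolerance_interval: ToleranceInterval


def piecewise_fit(x, y, knot: float = DEFAULT_KNOT) -> PiecewiseFit:
    """Least-squares fit of y on the hinge basis {1, x, max(0, x - knot)}.

    x and y are paired probabilities on the percent scale.  Requires at
    least 3 points and non-zero variance in x.  With every point on one
    side of the knot the hinge (or the below-knot segment) is not
    identifiable; the hinge coefficient is then fixed at zero — an ordinary
    simple regression — and the result is flagged ``degenerate``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d arrays of equal length")
    n = x.size
    if n < 3:
        raise InsufficientDataError(f"piecewise fit needs >= 3 points, got {n}")
    if np.ptp(x) == 0.0:
        raise DegenerateDataError("x has zero variance")
    hinge = np.maximum(0.0, x - knot)
    # Both segments are identifiable only if points lie strictly on each side.
    degenerate = not (np.any(x > knot) and np.any(x < knot))
    if degenerate:
        design = np.column_stack([np.ones(n), x])
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        intercept = float(coef[0])
        slope_below = slope_above = float(coef[1])
    else:
        design = np.column_stack([np.ones(n), x, hinge])
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        intercept = float(coef[0])
        slope_below = float(coef[1])
        slope_above = float(coef[1] + coef[2])
    if np.ptp(y) == 0.0:
        r = float("nan")
    elif np.array_equal(x, y):
        r = 1.0  # exact on the line of identity; avoids rounding at the ulp
    else:
        r = float(stats.pearsonr(x, y).statistic)
    return PiecewiseFit(
        knot=float(knot),
        intercept=intercept,
        slope_below=slope_below,
        slope_above=slope_above,
        r=r,
        n=n,
        degenerate=degenerate,
    )


def tolerance_interval(values, coverage: float = 0.95, confidence: float = 0.95) -> ToleranceInterval:
    """Two-sided distribution-free tolerance interval from order statistics.

    Chooses the innermost symmetric pair of order statistics (the k-th
    smallest and k-th largest) whose random coverage — Beta(n + 1 - 2k, 2k)
    distributed for a continuous parent — is at least ``coverage`` with
    probability at least ``confidence``.  If even the sample extremes fail
    that guarantee the interval (min, max) is returned flagged
    ``under_covered``.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise InsufficientDataError("tolerance interval needs >= 2 values")
    if not (0.0 < coverage < 1.0 and 0.0 < confidence < 1.0):
        raise ValueError("coverage and confidence must lie in (0, 1)")
    ordered = np.sort(values)
    n = ordered.size
    best_k = 0
    for k in range(1, n // 2 + 1):
        # P(coverage of [X_(k), X_(n+1-k)] >= coverage level)
        achieved = float(stats.beta.sf(coverage, n + 1 - 2 * k, 2 * k))
        if achieved >= confidence:
            best_k = k
        else:
            break
    if best_k == 0:
        return ToleranceInterval(float(ordered[0]), float(ordered[-1]), under_covered=True)
    return ToleranceInterval(float(ordered[best_k - 1]), float(ordered[n - best_k]))


def _stratum(grid: pd.DataFrame, outcome: str, age: int, sex: str) -> pd.DataFrame:
    sel = grid[(grid["outcome"] == outcome) & (grid["age"] == age) & (grid["sex"] == sex)]
    return sel.set_index("profile_id")


def percentile_compare(
    reference: pd.DataFrame,
    surrogate: pd.DataFrame,
    outcome: str,
    age: int,
    sex: str,
    percentile: float = 50.0,
    ti_coverage: float = 0.95,
    ti_confidence: float = 0.95,
    rank_window: int = 10,
) -> PercentileComparison:
    """Compare the two models at a percentile of the reference distribution.

    Profiles are ranked by their *reference* probability (ties broken by
    profile id for determinism).  The percentile value uses linear
    interpolation between closest ranks — the even-count median is the mean
    of the two central order statistics — and the surrogate value is the
    same interpolation applied to the surrogate probabilities of the
    identically ranked profiles, so both models are read at the same
    clinical scenarios.  The relative difference uses the reference value as
    denominator.  The tolerance interval is computed over the surrogate
    values of profiles within ``rank_window`` ranks of the percentile rank.
    """
    ref = _stratum(reference, outcome, age, sex)
    sur = _stratum(surrogate, outcome, age, sex)
    common = ref.index.intersection(sur.index)
    if len(common) == 0:
        raise EmptySelectionError(
            f"no matching profiles for outcome={outcome}, age={age}, sex={sex}"
        )
    if not (0.0 <= percentile <= 100.0):
        raise ValueError("percentile must lie in [0, 100]")
    ref_p = ref.loc[common, "probability"]
    sur_p = sur.loc[common, "probability"]
    order = sorted(common, key=lambda pid: (ref_p[pid], pid))
    ref_sorted = ref_p[order].to_numpy()
    sur_sorted = sur_p[order].to_numpy()
    n = len(order)

    h = (n - 1) * percentile / 100.0
    lo_i = math.floor(h)
    hi_i = math.ceil(h)
    w = h - lo_i
    value_reference = (1 - w) * ref_sorted[lo_i] + w * ref_sorted[hi_i]
    value_surrogate = (1 - w) * sur_sorted[lo_i] + w * sur_sorted[hi_i]

    if value_reference == 0.0:
        rel = 0.0 if value_surrogate == 0.0 else math.inf
    else:
        rel = 100.0 * (value_surrogate - value_reference) / value_reference

    win_lo = max(0, lo_i - rank_window)
    win_hi = min(n - 1, hi_i + rank_window)
    window_values = sur_sorted[win_lo : win_hi + 1]
    if window_values.size >= 2:
        ti = tolerance_interval(window_values, coverage=ti_coverage, confidence=ti_confidence)
    else:
        v = float(window_values[0])
        ti = ToleranceInterval(v, v, under_covered=True)

    return PercentileComparison(
        percentile=float(percentile),
        value_reference=float(value_reference),
        value_surrogate=float(value_surrogate),
        relative_difference_pct=float(rel),
        tolerance_interval=ti,
    )


def comparison_report(
    reference: pd.DataFrame,
    surrogate: pd.DataFrame,
    knot: float = DEFAULT_KNOT,
    percentile: float = 50.0,
    ti_coverage: float = 0.95,
    ti_confidence: float = 0.95,
    rank_window: int = 10,
) -> pd.DataFrame:
    """Per-(age, sex, outcome) comparison table on the percent scale.

    One row per stratum present in both grids, carrying both models'
    medians (or the requested percentile), the relative difference, the
    tolerance-interval bounds on the surrogate value, and the Pearson r of
    the paired probabilities from the piecewise fit.
    """
    strata = (
        reference[["age", "sex", "outcome"]]
        .drop_duplicates()
        .sort_values(["outcome", "age", "sex"], ascending=[True, True, False])
    )
    rows = []
    for age, sex, outcome in strata[["age", "sex", "outcome"]].itertuples(index=False):
        cmp_ = percentile_compare(
            reference, surrogate, outcome, age, sex,
            percentile=percentile, ti_coverage=ti_coverage,
            ti_confidence=ti_confidence, rank_window=rank_window,
        )
        ref = _stratum(reference, outcome, age, sex)
        sur = _stratum(surrogate, outcome, age, sex)
        common = ref.index.intersection(sur.index)
        fit = piecewise_fit(
            100.0 * ref.loc[common, "probability"].to_numpy(),
            100.0 * sur.loc[common, "probability"].to_numpy(),
            knot=knot,
        )
        rows.append(
            {
                "age": age,
                "sex": sex,
                "outcome": outcome,
                "reference_median": 100.0 * cmp_.value_reference,
                "surrogate_median": 100.0 * cmp_.value_surrogate,
                "relative_difference_pct": cmp_.relative_difference_pct,
                "ti_lo": 100.0 * cmp_.tolerance_interval.lo,
                "ti_hi": 100.0 * cmp_.tolerance_interval.hi,
                "r": fit.r,
            }
        )
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)
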