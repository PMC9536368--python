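"""Criterion-concurrent validity: correlations, shared variance, regression.

Pearson correlations carry a Fisher-z confidence interval and a magnitude
label on |r| (trivial < 0.1 ≤ small < 0.3 ≤ moderate < 0.5 ≤ large < 0.7 ≤
very large < 0.9 ≤ nearly perfect < 1 = perfect); the sign is reported
separately.  Shared variance is 100·r², always computed from the unrounded r.

Cross-prediction equations between two tests can be fitted either from raw
paired vectors or from summary statistics alone (means, SDs, r), which gives
identical coefficients: slope = r·sd_y/sd_x, intercept = mean_y − slope·mean_x,
standard error of estimate = sd_y·sqrt(1−r²)·sqrt((n−1)/(n−2)).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidInputError

logger = logging.getLogger(__name__)

#: Left-closed magnitude buckets on |r|.
MAGNITUDE_THRESHOLDS = (
    (0.1, "trivial"),
    (0.3, "small"),
    (0.5, "moderate"),
    (0.7, "large"),
    (0.9, "very large"),
    (1.0, "nearly perfect"),
)


@dataclass
class SummaryStats:
    """Bivariate summary sufficient for an OLS line: x predicts y."""

    mean_x: float
    sd_x: float
    mean_y: float
    sd_y: float
    r: float
    n: int

    def __post_init__(self) -> None:
        if self.sd_x <= 0 or self.sd_y <= 0:
            raise InvalidInputError("summary SDs must be positive")
        if abs(self.r) > 1:
            raise InvalidInputError("|r| cannot exceed 1")
        if self.n < 3:
            raise InvalidInputError("n must be >= 3")


def magnitude_label(r: float) -> str:
    """Correlation magnitude bucket on |r|; exactly 1 is "perfect"."""
    a = abs(r)
    if a > 1:
        raise InvalidInputError("|r| cannot exceed 1")
    if a == 1.0:
        return "perfect"
    for upper, label in MAGNITUDE_THRESHOLDS:
        if a < upper:
            return label
    return "nearly perfect"


def pearson_with_ci(x: np.ndarray, y: np.ndarray, alpha: float = 0.05) -> dict:
    """Pearson r with t-based p-value and Fisher-z confidence interval."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidInputError("x and y must be equal-length vectors")
    if x.size < 4:
        raise InvalidInputError("need n >= 4 for a correlation CI")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise InvalidInputError("non-finite values in input")
    if x.std(ddof=1) == 0 or y.std(ddof=1) == 0:
        return {"r": np.nan, "p": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                "magnitude": None, "r_squared_pct": np.nan, "n": int(x.size)}
    n = x.size
    r, p = stats.pearsonr(x, y)
    r = float(r)
    if abs(r) < 1:
        z = math.atanh(r)
        half = stats.norm.ppf(1 - alpha / 2) / math.sqrt(n - 3)
        lo, hi = math.tanh(z - half), math.tanh(z + half)
    else:
        lo = hi = r
    return {
        "r": r,
        "p": float(p),
        "ci_low": float(lo),
        "ci_high": float(hi),
        "magnitude": magnitude_label(r),
        "r_squared_pct": 100.0 * r * r,
        "n": int(n),
    }


def ols_from_summary(summary: SummaryStats) -> dict:
    """Simple-regression line of y on x from summary statistics only.

    Returns slope, intercept, the standard error of estimate (``see``) and the
    standard error of the intercept (``intercept_se``); the latter is the
    "±" term some published regression tables print next to the equation.
    """
    slope = summary.r * summary.sd_y / summary.sd_x
    intercept = summary.mean_y - slope * summary.mean_x
    n = summary.n
    if abs(summary.r) < 1 and n > 2:
        see = summary.sd_y * math.sqrt(1 - summary.r ** 2) * math.sqrt((n - 1) / (n - 2))
        ssx = (n - 1) * summary.sd_x ** 2
        intercept_se = see * math.sqrt(1.0 / n + summary.mean_x ** 2 / ssx)
    else:
        see = 0.0
        intercept_se = 0.0
    return {"slope": float(slope), "intercept": float(intercept),
            "see": float(see), "intercept_se": float(intercept_se)}


def ols_from_raw(x: np.ndarray, y: np.ndarray) -> dict:
    """Least-squares line of y on x from raw vectors (adds the slope's p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise InvalidInputError("need equal-length vectors with n >= 3")
    if x.std(ddof=1) == 0:
        raise InvalidInputError("constant predictor")
    n = x.size
    if y.std(ddof=1) == 0:
        return {"slope": 0.0, "intercept": float(y[0]), "see": 0.0,
                "intercept_se": 0.0, "p": 1.0, "r": 0.0}
    res = stats.linregress(x, y)
    summary = SummaryStats(
        mean_x=float(x.mean()), sd_x=float(x.std(ddof=1)),
        mean_y=float(y.mean()), sd_y=float(y.std(ddof=1)),
        r=float(res.rvalue), n=n,
    )
    out = ols_from_summary(summary)
    out["p"] = float(res.pvalue)
    out["r"] = float(res.rvalue)
    return out


def correlation_table(
    wide: pd.DataFrame,
    pairs: list[tuple[str, str]],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Long validity table: one row per (x, y) column pair of ``wide``."""
    rows = []
    for xcol, ycol in pairs:
        sub = wide[[xcol, ycol]].dropna()
        row = {"pair": f"{ycol}~{xcol}", "x": xcol, "y": ycol}
        try:
            row.update(pearson_with_ci(sub[xcol].to_numpy(),
                                       sub[ycol].to_numpy(), alpha))
        except InvalidInputError as exc:
            logger.warning("correlation %s~%s reported missing: %s",
                           ycol, xcol, exc)
            row.update({"r": np.nan, "p": np.nan, "ci_low": np.nan,
                        "ci_high": np.nan, "magnitude": None,
                        "r_squared_pct": np.nan, "n": len(sub)})
        rows.append(row)
    return pd.DataFrame(rows)


def regression_table(
    wide: pd.DataFrame,
    pairs: list[tuple[str, str]],
) -> pd.DataFrame:
    """Cross-prediction equations, one row per (predictor, response) pair."""
    rows = []
    for xcol, ycol in pairs:
        sub = wide[[xcol, ycol]].dropna()
        row = {"response": ycol, "predictor": xcol}
        try:
            row.update(ols_from_raw(sub[xcol].to_numpy(), sub[ycol].to_numpy()))
        except InvalidInputError as exc:
            logger.warning("equation %s~%s reported missing: %s", ycol, xcol, exc)
            row.update({"slope": np.nan, "intercept": np.nan, "see": np.nan,
                        "intercept_se": np.nan, "p": np.nan, "r": np.nan})
        row["n"] = len(sub)
        rows.append(row)
    return pd.DataFrame(rows)
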