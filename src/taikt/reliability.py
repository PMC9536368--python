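"""Test–retest reliability statistics.

Relative reliability is the intraclass correlation from a two-way,
single-measure ANOVA decomposition.  Two model variants are provided:

* ``"agreement"`` — two-way model, absolute agreement (systematic session
  shifts count as error): ICC = (MSR − MSE) / (MSR + (k−1)MSE + k(MSC − MSE)/n)
* ``"consistency"`` — two-way model, consistency (session shifts ignored):
  ICC = (MSR − MSE) / (MSR + (k−1)MSE)

with MSR/MSC/MSE the subject, session and error mean squares of n subjects
by k sessions.  95% CIs come from the usual F-distribution bounds.

Absolute reliability: SEM = SD × sqrt(1 − ICC).  Which SD feeds the formula
is configurable: the default is the SD of test–retest difference scores (the
variant whose numbers this battery's reference outputs reproduce); the
between-subject SD is available via ``sd_source="between_subject"``.  The
smallest worthwhile change is 0.2 / 0.6 / 1.2 times the between-subject SD
(mean of the test and retest SDs), the minimal detectable change is
MDC95 = 1.96 × SEM × sqrt(2), and usefulness compares SEM against each SWC
("good" below, "satisfactory" comparable, "marginal" above).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import AnalysisConfig
from .errors import InvalidInputError

logger = logging.getLogger(__name__)

@dataclass
class PairedSample:
    variable_name: str
    test_values: np.ndarray
    retest_values: np.ndarray

    def __post_init__(self) -> None:
        self.test_values = np.asarray(self.test_values, dtype=float)
        self.retest_values = np.asarray(self.retest_values, dtype=float)
        if self.test_values.shape != self.retest_values.shape:
            raise InvalidInputError("test and retest must have equal length")
        if self.test_values.ndim != 1 or self.test_values.size < 2:
            raise InvalidInputError("need >= 2 paired observations")
        if np.isnan(self.test_values).any() or np.isnan(self.retest_values).any():
            raise InvalidInputError("missing values must be filtered before analysis")

    @property
    def n(self) -> int:
        return self.test_values.size


def icc_band(icc: float) -> str:
    if icc < 0.40:
        return "low"
    if icc < 0.70:
        return "acceptable"
    if icc <= 0.90:  # "excellent" is strictly > 0.90 as printed
        return "good"
    return "excellent"


def normality_screen(values: np.ndarray, alpha: float = 0.05) -> dict:
    """One-sample Kolmogorov–Smirnov screen against a fitted normal.

    Returns ``parametric=True`` when the test does not reject (p > alpha).
    A constant vector is flagged non-parametric without error.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise InvalidInputError("need >= 3 observations")
    sd = values.std(ddof=1)
    if sd == 0:
        return {"parametric": False, "statistic": np.nan, "p": np.nan}
    stat, p = stats.kstest(values, "norm", args=(values.mean(), sd))
    return {"parametric": bool(p > alpha), "statistic": float(stat), "p": float(p)}


def paired_comparison(sample: PairedSample) -> dict:
    """Paired t-test on test − retest differences (df = n − 1)."""
    diff = sample.test_values - sample.retest_values
    n = sample.n
    mean_diff = float(diff.mean())
    sd_diff = float(diff.std(ddof=1))
    if sd_diff == 0:
        logger.warning(
            "%s: zero variance of difference scores; p reported as 1.0",
            sample.variable_name,
        )
        return {"mean_diff": mean_diff, "sd_diff": 0.0, "t": np.nan,
                "df": n - 1, "p": 1.0}
    t = mean_diff / (sd_diff / math.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), n - 1)
    return {"mean_diff": mean_diff, "sd_diff": sd_diff, "t": float(t),
            "df": n - 1, "p": float(p)}


def _mean_squares(sample: PairedSample) -> tuple[float, float, float, int, int]:
    """Two-way ANOVA mean squares for an n-subject × k-session table (k = 2)."""
    data = np.column_stack([sample.test_values, sample.retest_values])
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ssr = k * ((row_means - grand) ** 2).sum()
    ssc = n * ((col_means - grand) ** 2).sum()
    sst = ((data - grand) ** 2).sum()
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    return msr, msc, mse, n, k


def icc_estimate(
    sample: PairedSample,
    model: str = "agreement",
    alpha: float = 0.05,
) -> dict:
    """Single-measure two-way ICC with a 95% (1 − alpha) F-based CI.

    ``model="agreement"`` treats a systematic test→retest shift as error;
    ``model="consistency"`` does not (so retest = test + c gives ICC = 1).
    """
    if model not in ("agreement", "consistency"):
        raise InvalidInputError(f"unknown ICC model {model!r}")
    if sample.n < 5:
        logger.warning(
            "%s: n = %d < 5, ICC confidence interval unreliable%s",
            sample.variable_name, sample.n,
            " and reported missing" if sample.n < 3 else "",
        )
    msr, msc, mse, n, k = _mean_squares(sample)
    if msr == 0:
        logger.warning("%s: zero between-subject variance, ICC undefined",
                       sample.variable_name)
        return {"icc": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                "band": None, "model": model}

    if model == "consistency":
        icc = (msr - mse) / (msr + (k - 1) * mse)
        if mse == 0:
            lo = hi = icc
        else:
            df1, df2 = n - 1, (n - 1) * (k - 1)
            f = msr / mse
            fl = f / stats.f.ppf(1 - alpha / 2, df1, df2)
            fu = f * stats.f.ppf(1 - alpha / 2, df2, df1)
            lo = (fl - 1) / (fl + k - 1)
            hi = (fu - 1) / (fu + k - 1)
    else:
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
        icc = (msr - mse) / denom
        if mse == 0 and msc == 0:
            lo = hi = icc
        else:
            # Satterthwaite df for the session+error composite (McGraw & Wong)
            fj = msc / mse if mse > 0 else np.inf
            a = k * icc / (n * (1 - icc)) if icc < 1 else np.inf
            b = 1 + k * icc * (n - 1) / (n * (1 - icc)) if icc < 1 else np.inf
            if np.isfinite(fj) and icc < 1:
                v_num = (a * fj + b) ** 2
                v_den = a ** 2 * fj ** 2 / (k - 1) + b ** 2 / ((n - 1) * (k - 1))
                v = v_num / v_den
                f_u = stats.f.ppf(1 - alpha / 2, n - 1, v)
                f_l = stats.f.ppf(1 - alpha / 2, v, n - 1)
                lo = n * (msr - f_u * mse) / (
                    f_u * (k * msc + (k * n - k - n) * mse) + n * msr
                )
                hi = n * (f_l * msr - mse) / (
                    k * msc + (k * n - k - n) * mse + n * f_l * msr
                )
            else:
                lo = hi = icc
    icc_f = float(icc)
    if n < 3:
        lo = hi = np.nan
        return {"icc": icc_f, "ci_low": np.nan, "ci_high": np.nan,
                "band": icc_band(icc_f), "model": model}
    return {
        "icc": icc_f,
        "ci_low": float(min(lo, icc_f)),
        "ci_high": float(max(hi, icc_f)),
        "band": icc_band(icc_f),
        "model": model,
    }


def sem_estimate(sd: float, icc: float) -> float:
    """Standard error of measurement: SD × sqrt(1 − ICC)."""
    if not 0.0 <= icc <= 1.0:
        raise InvalidInputError("icc must be within [0, 1]")
    if sd < 0:
        raise InvalidInputError("sd must be non-negative")
    return sd * math.sqrt(1.0 - icc)


def swc_estimate(sd_test: float, sd_retest: float, factor: float = 0.2) -> float:
    """Smallest worthwhile change: factor × mean(test SD, retest SD)."""
    if sd_test < 0 or sd_retest < 0:
        raise InvalidInputError("SDs must be non-negative")
    return factor * 0.5 * (sd_test + sd_retest)


def usefulness_rating(sem: float, swc: float, tolerance: float = 0.005) -> str:
    """"good" when SEM < SWC, "marginal" when SEM > SWC, "satisfactory" when
    comparable (within ±tolerance)."""
    if sem < 0 or swc < 0:
        raise InvalidInputError("sem and swc must be non-negative")
    if sem < swc - tolerance:
        return "good"
    if sem > swc + tolerance:
        return "marginal"
    return "satisfactory"


def mdc_estimate(sem: float) -> float:
    """Minimal detectable change at 95% confidence: 1.96 × SEM × sqrt(2)."""
    if sem < 0:
        raise InvalidInputError("sem must be non-negative")
    return 1.96 * sem * math.sqrt(2.0)


def reliability_row(sample: PairedSample, config: AnalysisConfig | None = None) -> dict:
    """All test–retest statistics for one variable, as a flat dict."""
    config = config or AnalysisConfig()
    x, y = sample.test_values, sample.retest_values
    paired = paired_comparison(sample)
    icc = icc_estimate(sample, model=config.icc_model, alpha=config.alpha)
    sd_test = float(x.std(ddof=1))
    sd_retest = float(y.std(ddof=1))
    if math.isnan(icc["icc"]):
        sem = np.nan
    else:
        sd_for_sem = (
            paired["sd_diff"]
            if config.sem_sd_source == "difference_scores"
            else 0.5 * (sd_test + sd_retest)
        )
        sem = sem_estimate(sd_for_sem, min(max(icc["icc"], 0.0), 1.0))
    row = {
        "variable": sample.variable_name,
        "n": sample.n,
        "mean_test": float(x.mean()),
        "sd_test": sd_test,
        "mean_retest": float(y.mean()),
        "sd_retest": sd_retest,
        "mean_diff": paired["mean_diff"],
        "sd_diff": paired["sd_diff"],
        "p_paired": paired["p"],
        "icc": icc["icc"],
        "icc_ci_low": icc["ci_low"],
        "icc_ci_high": icc["ci_high"],
        "icc_band": icc["band"],
        "icc_model": icc["model"],
        "sem": sem,
    }
    for factor in config.swc_factors:
        swc = swc_estimate(sd_test, sd_retest, factor)
        row[f"swc_{factor}"] = swc
        row[f"usefulness_{factor}"] = (
            None if math.isnan(sem)
            else usefulness_rating(sem, swc, config.usefulness_tolerance)
        )
    row["mdc95"] = np.nan if math.isnan(sem) else mdc_estimate(sem)
    return row


def reliability_report(
    indices: pd.DataFrame,
    variables: list[str],
    config: AnalysisConfig | None = None,
    test_label: str = "test",
    retest_label: str = "retest",
) -> pd.DataFrame:
    """Test–retest reliability table: one row per variable.

    ``indices`` is a tidy per-trial table with ``athlete_id`` and ``session``
    columns (e.g. the output of :func:`taikt.scoring.score_dataframe` for one
    test).  Athletes missing either session, or with a missing value for a
    variable, are dropped for that variable with a logged count.
    """
    config = config or AnalysisConfig()
    rows = []
    for var in variables:
        wide = indices.pivot_table(
            index="athlete_id", columns="session", values=var, aggfunc="first"
        )
        if test_label not in wide.columns or retest_label not in wide.columns:
            raise InvalidInputError(
                f"variable {var!r}: both sessions required for reliability"
            )
        paired = wide[[test_label, retest_label]].dropna()
        dropped = len(wide) - len(paired)
        if dropped:
            logger.warning("%s: dropped %d athlete(s) without complete pairs",
                           var, dropped)
        sample = PairedSample(var, paired[test_label].to_numpy(),
                              paired[retest_label].to_numpy())
        rows.append(reliability_row(sample, config))
    return pd.DataFrame(rows)
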