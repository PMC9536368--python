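"""Construct-discriminant validity: elite vs sub-elite comparisons and ROC.

The empirical ROC sweeps every observed value as a candidate cutoff; its
area equals the Mann–Whitney statistic U/(n1·n2) with ties counted one half,
i.e. the probability that a randomly chosen elite athlete outscores a
randomly chosen sub-elite one.  The AUC standard error uses the
Hanley–McNeil exponential approximation by default, with DeLong's
covariance-based estimator as an option; an AUC of at least 0.70 is deemed
"good" discriminative ability.  The reported cutoff maximises Youden's
J = sensitivity + specificity − 1, stated as "> v" when larger values mark
elite athletes and "≤ v" otherwise (the cutoff value itself is classified
on the favourable side).

Effect size is pooled-SD Cohen's d with the (sub-elite − elite) numerator,
so a variable where elite athletes score higher prints a negative d; bands
are |d| < 0.2 very small, then small / medium / large / very large / huge at
0.2 / 0.5 / 0.8 / 1.2 / 2.0.
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

D_BANDS = (
    (0.2, "very small"),
    (0.5, "small"),
    (0.8, "medium"),
    (1.2, "large"),
    (2.0, "very large"),
)


@dataclass
class TwoGroupSample:
    variable_name: str
    elite_values: np.ndarray
    subelite_values: np.ndarray
    higher_is_better: bool = True

    def __post_init__(self) -> None:
        self.elite_values = np.asarray(self.elite_values, dtype=float)
        self.subelite_values = np.asarray(self.subelite_values, dtype=float)
        if self.elite_values.size < 2 or self.subelite_values.size < 2:
            raise InvalidInputError("each group needs >= 2 observations")

    @property
    def n1(self) -> int:
        return self.elite_values.size

    @property
    def n2(self) -> int:
        return self.subelite_values.size


def d_band(d: float) -> str:
    a = abs(d)
    for upper, label in D_BANDS:
        if a < upper:
            return label
    return "huge"


def unpaired_comparison(sample: TwoGroupSample, equal_var: bool = False) -> dict:
    """Two-sample t-test, elite vs sub-elite.

    ``equal_var=False`` (default) uses the unpooled standard error with
    Welch–Satterthwaite df; ``equal_var=True`` the classic pooled form with
    df = n1 + n2 − 2.
    """
    x, y = sample.elite_values, sample.subelite_values
    n1, n2 = sample.n1, sample.n2
    if n1 + n2 < 5:
        raise InvalidInputError("need n1 + n2 >= 5")
    mean_diff = float(x.mean() - y.mean())
    v1, v2 = x.var(ddof=1), y.var(ddof=1)
    if v1 == 0 and v2 == 0:
        logger.warning("%s: zero variance in both groups; p reported as 1.0",
                       sample.variable_name)
        return {"mean_diff": mean_diff, "se_diff": 0.0, "t": np.nan,
                "df": n1 + n2 - 2, "p": 1.0}
    if equal_var:
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        se = math.sqrt(sp2 * (1 / n1 + 1 / n2))
        df: float = n1 + n2 - 2
    else:
        se = math.sqrt(v1 / n1 + v2 / n2)
        df = (v1 / n1 + v2 / n2) ** 2 / (
            (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
        )
    t = mean_diff / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return {"mean_diff": mean_diff, "se_diff": float(se), "t": float(t),
            "df": float(df), "p": float(p)}


def cohens_d_pooled(sample: TwoGroupSample) -> dict:
    """Pooled-SD Cohen's d, (sub-elite − elite) / SD_pooled, with band label."""
    x, y = sample.elite_values, sample.subelite_values
    n1, n2 = sample.n1, sample.n2
    sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
    if sp2 == 0:
        logger.warning("%s: zero pooled variance, Cohen's d undefined",
                       sample.variable_name)
        return {"d": np.nan, "band": None}
    d = float((y.mean() - x.mean()) / math.sqrt(sp2))
    return {"d": d, "band": d_band(d)}


def auc_mann_whitney(pos: np.ndarray, neg: np.ndarray) -> float:
    """AUC as the tie-corrected Mann–Whitney probability P(pos > neg) + ½P(=).

    Computed from midranks of the pooled sample, equivalent to the all-pairs
    count U/(n1·n2) but O((n1+n2) log(n1+n2)).
    """
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    n1, n2 = pos.size, neg.size
    if n1 == 0 or n2 == 0:
        raise InvalidInputError("both groups must be non-empty")
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    u = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n2))


def _hanley_mcneil_se(auc: float, n1: int, n2: int) -> float:
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc * auc / (1.0 + auc)
    var = (auc * (1 - auc) + (n1 - 1) * (q1 - auc * auc)
           + (n2 - 1) * (q2 - auc * auc)) / (n1 * n2)
    return math.sqrt(max(var, 0.0))


def _delong_se(pos: np.ndarray, neg: np.ndarray) -> float:
    # placement values: V10_i = P(neg < pos_i) + 0.5 P(neg == pos_i)
    v10 = np.array([np.mean((neg < p) + 0.5 * (neg == p)) for p in pos])
    v01 = np.array([np.mean((pos > n) + 0.5 * (pos == n)) for n in neg])
    var = (np.var(v10, ddof=1) / pos.size) + (np.var(v01, ddof=1) / neg.size)
    return math.sqrt(max(var, 0.0))


def roc_curve_points(sample: TwoGroupSample) -> pd.DataFrame:
    """Empirical ROC points (one per candidate cutoff) for plotting/export."""
    pos, neg, _ = _oriented(sample)
    cuts = np.unique(np.concatenate([pos, neg]))
    rows = [{"cutoff": -np.inf, "sensitivity": 1.0, "specificity": 0.0}]
    for c in cuts:
        rows.append({
            "cutoff": float(c),
            "sensitivity": float(np.mean(pos > c)),
            "specificity": float(np.mean(neg <= c)),
        })
    return pd.DataFrame(rows)


def _oriented(sample: TwoGroupSample) -> tuple[np.ndarray, np.ndarray, int]:
    """Orient values so larger = more elite; return (elite, sub, sign)."""
    sign = 1 if sample.higher_is_better else -1
    return sign * sample.elite_values, sign * sample.subelite_values, sign


def roc_analysis(
    sample: TwoGroupSample,
    criterion: float = 0.70,
    se_method: str = "hanley_mcneil",
    alpha: float = 0.05,
) -> dict:
    """Empirical ROC of elite vs sub-elite for one variable.

    Returns AUC (tie-corrected Mann–Whitney), its SE and normal-approximation
    CI, a p-value against AUC = 0.5, the Youden-optimal cutoff with its
    direction string, sensitivity/specificity at the cutoff, and whether the
    AUC meets the discriminative-ability criterion.
    """
    pos, neg, sign = _oriented(sample)
    auc = auc_mann_whitney(pos, neg)
    if se_method == "delong":
        se = _delong_se(pos, neg)
    elif se_method == "hanley_mcneil":
        se = _hanley_mcneil_se(auc, sample.n1, sample.n2)
    else:
        raise InvalidInputError(f"unknown se_method {se_method!r}")
    z = stats.norm.ppf(1 - alpha / 2)
    ci_low = max(0.0, auc - z * se)
    ci_high = min(1.0, auc + z * se)
    p = 2.0 * stats.norm.sf(abs(auc - 0.5) / se) if se > 0 else (
        0.0 if auc != 0.5 else 1.0)

    # Youden-optimal cutoff over observed values on the original scale:
    # "elite if value > c" when higher is better, "elite if value <= c"
    # otherwise (the cutoff itself classified on the favourable side).
    # Ties broken toward the first cutoff reaching the highest J.
    elite, subelite = sample.elite_values, sample.subelite_values
    cuts = np.unique(np.concatenate([elite, subelite]))
    best = None
    for c in cuts:
        if sample.higher_is_better:
            sens = float(np.mean(elite > c))
            spec = float(np.mean(subelite <= c))
        else:
            sens = float(np.mean(elite <= c))
            spec = float(np.mean(subelite > c))
        j = sens + spec - 1.0
        if best is None or j > best[0] + 1e-12:
            best = (j, c, sens, spec)
    assert best is not None
    _, cut, sens, spec = best
    cutoff = float(cut)
    direction = ">" if sample.higher_is_better else "<="
    return {
        "variable": sample.variable_name,
        "auc": auc,
        "se_auc": float(se),
        "ci_low": float(ci_low),
        "ci_high": float(ci_high),
        "p_vs_half": float(p),
        "cutoff": cutoff,
        "cutoff_direction": direction,
        "sensitivity": sens,
        "specificity": spec,
        "discriminative": bool(auc >= criterion),
    }


def discrimination_report(
    wide: pd.DataFrame,
    variables: list[str],
    group_col: str = "group",
    elite_label: str = "elite",
    subelite_label: str = "sub_elite",
    higher_is_better: dict[str, bool] | None = None,
    equal_var: bool = False,
    criterion: float = 0.70,
    se_method: str = "hanley_mcneil",
) -> pd.DataFrame:
    """Group comparison + effect size + ROC for each variable; one row each.

    ``higher_is_better`` marks variables where smaller values indicate better
    performance (e.g. a fatigue index) as False; default True for all.
    """
    higher_is_better = higher_is_better or {}
    rows = []
    for var in variables:
        sub = wide[[group_col, var]].dropna()
        elite = sub.loc[sub[group_col] == elite_label, var].to_numpy()
        subelite = sub.loc[sub[group_col] == subelite_label, var].to_numpy()
        sample = TwoGroupSample(var, elite, subelite,
                                higher_is_better.get(var, True))
        t_res = unpaired_comparison(sample, equal_var=equal_var)
        d_res = cohens_d_pooled(sample)
        roc = roc_analysis(sample, criterion=criterion, se_method=se_method)
        rows.append({
            "variable": var,
            "n_elite": sample.n1,
            "n_subelite": sample.n2,
            "mean_elite": float(elite.mean()),
            "sd_elite": float(elite.std(ddof=1)),
            "mean_subelite": float(subelite.mean()),
            "sd_subelite": float(subelite.std(ddof=1)),
            "mean_diff": t_res["mean_diff"],
            "se_diff": t_res["se_diff"],
            "p": t_res["p"],
            "cohens_d": d_res["d"],
            "d_band": d_res["band"],
            **{k: roc[k] for k in (
                "auc", "se_auc", "ci_low", "ci_high", "p_vs_half", "cutoff",
                "cutoff_direction", "sensitivity", "specificity",
                "discriminative")},
        })
    return pd.DataFrame(rows)
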