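"""Scoring of intermittent anaerobic kick tests and the 30-s continuous jump test.

A kick trial is six 5-s sets of maximal roundhouse kicks on an instrumented
target, with 10-s active recovery between sets.  The mechanical power of one
set treats the lower limb as the moving mass travelling the foot-to-target
projection distance ``d`` once per validated kick::

    P (W) = LLM * (d * N_kicks)**2 / t**3

with ``LLM`` the single lower-limb mass (kg), ``d`` in metres and ``t`` the
set duration in seconds.  Trial-level indices are the peak, mean and minimum
set power, the fatigue index ``(P_peak - P_min) / P_min * 100`` and
allometrically scaled relative powers ``P / BM**0.67``.

The continuous jump trial is scored from the ordered per-jump power sequence:
mean of the first four jumps, mean of all jumps, mean of the last four jumps,
and the fatigue index ``(first4 - last4) / first4 * 100`` — note the jump-test
fatigue index divides by the *first-four* mean while the kick-test one divides
by the minimum set power; both forms are deliberate and kept distinct.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .config import ProtocolConfig
from .errors import InvalidInputError, SchemaError

logger = logging.getLogger(__name__)

KICK_TESTS = ("taikt_head", "taikt_chest")
JUMP_TESTS = ("cj30s",)

#: Raw long-format schema: one row per (athlete, test, session, set) for kick
#: tests, one row per jump for jump tests.
KICK_COLUMNS = [
    "athlete_id", "sex", "body_mass_kg", "group", "test", "session",
    "set_index", "n_kicks", "x_m", "y_m",
    "hr_peak_bpm", "lactate_mmol_l", "rpe",
]
JUMP_COLUMNS = [
    "athlete_id", "sex", "body_mass_kg", "group", "test", "session",
    "set_index", "jump_power_w", "hr_peak_bpm", "lactate_mmol_l", "rpe",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class Anthropometry:
    athlete_id: str
    sex: str
    body_mass: float  # kg
    segment_percentages: dict[str, float]  # thigh / lower_leg / foot, % BM
    height: float | None = None  # cm

    def __post_init__(self) -> None:
        if self.body_mass <= 0:
            raise InvalidInputError("body_mass must be positive")
        total = sum(self.segment_percentages.values())
        if not 0.0 < total < 100.0:
            raise InvalidInputError("segment percentages must sum to (0, 100)")


@dataclass
class StrikeGeometry:
    """Foot-to-target geometry: horizontal stand-off x, contact height y,
    projection distance d = sqrt(x**2 + y**2).

    d may be given directly (x and y omitted) or derived; if both are given
    and disagree beyond ``tolerance`` metres, the record is rejected.
    """

    x: float | None = None
    y: float | None = None
    d: float | None = None
    tolerance: float = 1e-9

    def __post_init__(self) -> None:
        if self.x is not None or self.y is not None:
            if self.x is None or self.y is None:
                raise InvalidInputError("x and y must be supplied together")
            if self.x < 0 or self.y < 0:
                raise InvalidInputError("x and y must be non-negative")
            if self.x == 0 and self.y == 0:
                raise InvalidInputError("x and y cannot both be zero")
            derived = math.hypot(self.x, self.y)
            if self.d is None:
                self.d = derived
            elif abs(self.d - derived) > self.tolerance:
                raise InvalidInputError(
                    f"supplied d={self.d} inconsistent with sqrt(x^2+y^2)={derived}"
                )
        elif self.d is None:
            raise InvalidInputError("either (x, y) or d is required")
        if self.d <= 0:
            raise InvalidInputError("projection distance must be positive")


@dataclass
class PhysioRecord:
    hr_peak: float | None = None       # bpm
    lactate: float | None = None       # mmol/l, 3-min post
    rpe: float | None = None           # 0-10
    hr_series: Sequence[float] | None = None  # bpm every 5 s

    def __post_init__(self) -> None:
        if self.hr_series is not None:
            peak = max(self.hr_series)
            if self.hr_peak is None:
                self.hr_peak = peak
            elif self.hr_peak != peak:
                raise InvalidInputError("hr_peak must equal max(hr_series)")


@dataclass
class KickTestTrial:
    athlete_id: str
    test: str                       # taikt_head | taikt_chest
    session: str                    # test | retest
    kicks_per_set: Sequence[int]
    geometry: StrikeGeometry | Sequence[StrikeGeometry]
    physio: PhysioRecord = field(default_factory=PhysioRecord)
    set_duration: float = 5.0
    recovery_duration: float = 10.0

    def __post_init__(self) -> None:
        if self.set_duration <= 0:
            raise InvalidInputError("set_duration must be positive")
        if any(k < 0 or int(k) != k for k in self.kicks_per_set):
            raise InvalidInputError("kick counts must be non-negative integers")
        if not isinstance(self.geometry, StrikeGeometry):
            if len(self.geometry) != len(self.kicks_per_set):
                raise InvalidInputError("one geometry per set required")

    def set_geometries(self) -> list[StrikeGeometry]:
        if isinstance(self.geometry, StrikeGeometry):
            return [self.geometry] * len(self.kicks_per_set)
        return list(self.geometry)


@dataclass
class JumpTestTrial:
    athlete_id: str
    session: str
    jump_powers: Sequence[float]    # W, in jump order
    physio: PhysioRecord = field(default_factory=PhysioRecord)

    def __post_init__(self) -> None:
        if any(p <= 0 for p in self.jump_powers):
            raise InvalidInputError("jump powers must be positive")


@dataclass
class PowerIndices:
    """Trial-level kick-test indices (absolute W, relative W·kg^-exponent)."""

    athlete_id: str
    test: str
    session: str
    set_powers: list[float]
    p_peak: float
    p_mean: float
    p_min: float
    fatigue_index: float | None     # %, None when p_min == 0
    p_peak_rel: float
    p_mean_rel: float


@dataclass
class JumpIndices:
    athlete_id: str
    session: str
    p_mean_4j: float
    p_mean: float
    p_mean_end4j: float
    fatigue_index: float            # %
    p_mean_4j_rel: float | None = None
    p_mean_rel: float | None = None


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def lower_limb_mass(anthro: Anthropometry) -> float:
    """Single lower-limb mass (kg): (thigh + shank + foot %BM) * BM / 100."""
    if anthro.body_mass <= 0:
        raise InvalidInputError("body_mass must be positive")
    pct = sum(anthro.segment_percentages.values())
    return pct * anthro.body_mass / 100.0


def projection_distance(x: float, y: float) -> float:
    """Euclidean foot-to-target distance d = sqrt(x^2 + y^2)."""
    if x < 0 or y < 0:
        raise InvalidInputError("x and y must be non-negative")
    if x == 0 and y == 0:
        raise InvalidInputError("x and y cannot both be zero")
    return math.hypot(x, y)


def set_power(llm: float, d: float, n_kicks: int, duration: float = 5.0) -> float:
    """Mechanical power of one kicking set: llm * (d * n_kicks)^2 / duration^3."""
    if duration <= 0:
        raise InvalidInputError("duration must be positive")
    if llm <= 0:
        raise InvalidInputError("lower-limb mass must be positive")
    if d <= 0:
        raise InvalidInputError("projection distance must be positive")
    if n_kicks < 0:
        raise InvalidInputError("kick count must be non-negative")
    return llm * (d * n_kicks) ** 2 / duration ** 3


def relative_power(p: float, body_mass: float, exponent: float = 0.67) -> float:
    """Allometrically scaled power p / body_mass**exponent."""
    if body_mass <= 0:
        raise InvalidInputError("body_mass must be positive")
    return p / body_mass ** exponent


def summarize_kick_trial(
    trial: KickTestTrial,
    anthro: Anthropometry,
    config: ProtocolConfig | None = None,
) -> PowerIndices:
    """Score one kick trial: per-set powers, peak/mean/min, FI, relative powers.

    The kick-test fatigue index is (P_peak - P_min) / P_min * 100; when the
    weakest set produced no valid kicks (P_min = 0) the ratio is undefined and
    the index is reported missing with a logged warning.
    """
    config = config or ProtocolConfig()
    llm = lower_limb_mass(anthro)
    powers = [
        set_power(llm, g.d, int(n), trial.set_duration)
        for g, n in zip(trial.set_geometries(), trial.kicks_per_set)
    ]
    p_peak = max(powers)
    p_min = min(powers)
    p_mean = sum(powers) / len(powers)
    if p_min > 0:
        fi: float | None = (p_peak - p_min) / p_min * 100.0
    else:
        fi = None
        logger.warning(
            "trial %s/%s/%s: P_min = 0, fatigue index undefined",
            trial.athlete_id, trial.test, trial.session,
        )
    exp = config.allometric_exponent
    return PowerIndices(
        athlete_id=trial.athlete_id,
        test=trial.test,
        session=trial.session,
        set_powers=powers,
        p_peak=p_peak,
        p_mean=p_mean,
        p_min=p_min,
        fatigue_index=fi,
        p_peak_rel=relative_power(p_peak, anthro.body_mass, exp),
        p_mean_rel=relative_power(p_mean, anthro.body_mass, exp),
    )


def summarize_jump_trial(
    trial: JumpTestTrial,
    body_mass: float | None = None,
    config: ProtocolConfig | None = None,
) -> JumpIndices:
    """Score one continuous-jump trial.

    The jump-test fatigue index is (first4 - last4) / first4 * 100 — the
    denominator is the first-four mean, not the minimum.
    """
    config = config or ProtocolConfig()
    powers = np.asarray(trial.jump_powers, dtype=float)
    if powers.size < config.min_jumps:
        raise InvalidInputError(
            f"at least {config.min_jumps} jumps required, got {powers.size}"
        )
    p4 = float(powers[:4].mean())
    p_end4 = float(powers[-4:].mean())
    p_all = float(powers.mean())
    fi = (p4 - p_end4) / p4 * 100.0
    exp = config.allometric_exponent
    rel4 = rel_all = None
    if body_mass is not None:
        rel4 = relative_power(p4, body_mass, exp)
        rel_all = relative_power(p_all, body_mass, exp)
    return JumpIndices(
        athlete_id=trial.athlete_id,
        session=trial.session,
        p_mean_4j=p4,
        p_mean=p_all,
        p_mean_end4j=p_end4,
        fatigue_index=fi,
        p_mean_4j_rel=rel4,
        p_mean_rel=rel_all,
    )


# ---------------------------------------------------------------------------
# dataframe interface (long raw CSV -> tidy per-trial indices)
# ---------------------------------------------------------------------------

def _segment_pct(sex: pd.Series, config: ProtocolConfig) -> pd.Series:
    pct = {s: sum(v.values()) for s, v in config.segment_percentages.items()}
    unknown = set(sex.unique()) - set(pct)
    if unknown:
        raise SchemaError(f"unknown sex values {sorted(unknown)}")
    return sex.map(pct)


def _validate(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing columns {missing}")


_TRIAL_KEY = ["athlete_id", "test", "session"]
_META = ["sex", "body_mass_kg", "group", "hr_peak_bpm", "lactate_mmol_l", "rpe"]


def score_dataframe(
    raw: pd.DataFrame, config: ProtocolConfig | None = None
) -> pd.DataFrame:
    """Score a long-format raw trial table into one tidy row per trial.

    Kick-test rows (tests in :data:`KICK_TESTS`) need kick counts and
    geometry; jump rows (:data:`JUMP_TESTS`) need ``jump_power_w``.  Output
    columns: trial keys, passthrough metadata, and the index columns
    ``p_peak_w, p_mean_w, p_min_w, fi_pct, p_peak_rel, p_mean_rel`` for kick
    trials and ``p_mean_4j_w, p_mean_w, p_mean_end4j_w, fi_pct,
    p_mean_4j_rel, p_mean_rel`` for jump trials.
    """
    config = config or ProtocolConfig()
    _validate(raw, ["athlete_id", "test", "session", "set_index"], "raw table")
    known = set(KICK_TESTS) | set(JUMP_TESTS)
    bad = set(raw["test"].unique()) - known
    if bad:
        raise SchemaError(f"unknown test labels {sorted(bad)}")

    frames = []
    kick = raw[raw["test"].isin(KICK_TESTS)]
    if len(kick):
        frames.append(_score_kick_rows(kick, config))
    jump = raw[raw["test"].isin(JUMP_TESTS)]
    if len(jump):
        frames.append(_score_jump_rows(jump, config))
    if not frames:
        raise SchemaError("no scoreable rows")
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(_TRIAL_KEY).reset_index(drop=True)


def _score_kick_rows(kick: pd.DataFrame, config: ProtocolConfig) -> pd.DataFrame:
    _validate(kick, KICK_COLUMNS[:10], "kick rows")
    kick = kick.copy()
    bad = kick[(kick["n_kicks"] < 0) | (kick["n_kicks"] % 1 != 0)]
    if len(bad):
        raise SchemaError(
            f"non-integer or negative kick counts in rows {bad.index.tolist()[:10]}"
        )
    counts = kick.groupby(_TRIAL_KEY)["set_index"].count()
    wrong = counts[counts != config.n_sets]
    if len(wrong):
        raise SchemaError(
            f"trials without exactly {config.n_sets} sets: {wrong.index.tolist()[:10]}"
        )
    llm = _segment_pct(kick["sex"], config) * kick["body_mass_kg"] / 100.0
    d = np.hypot(kick["x_m"], kick["y_m"])
    if (d <= 0).any():
        raise SchemaError("zero strike geometry in kick rows")
    t = config.set_duration_s
    kick["_power_w"] = llm * (d * kick["n_kicks"]) ** 2 / t ** 3

    g = kick.groupby(_TRIAL_KEY, sort=False)
    out = g.agg(
        p_peak_w=("_power_w", "max"),
        p_mean_w=("_power_w", "mean"),
        p_min_w=("_power_w", "min"),
        **{c: (c, "first") for c in _META if c in kick.columns},
    ).reset_index()
    zero_min = out["p_min_w"] == 0
    if zero_min.any():
        logger.warning(
            "%d kick trial(s) with P_min = 0: fatigue index reported missing",
            int(zero_min.sum()),
        )
    out["fi_pct"] = np.where(
        zero_min, np.nan, (out["p_peak_w"] - out["p_min_w"]) / out["p_min_w"] * 100.0
    )
    bm_pow = out["body_mass_kg"] ** config.allometric_exponent
    out["p_peak_rel"] = out["p_peak_w"] / bm_pow
    out["p_mean_rel"] = out["p_mean_w"] / bm_pow
    return out


def _score_jump_rows(jump: pd.DataFrame, config: ProtocolConfig) -> pd.DataFrame:
    _validate(jump, ["jump_power_w"], "jump rows")
    jump = jump.sort_values(_TRIAL_KEY + ["set_index"])
    if (jump["jump_power_w"] <= 0).any():
        raise SchemaError("non-positive jump powers")
    g = jump.groupby(_TRIAL_KEY, sort=False)
    short = g.size()[g.size() < config.min_jumps]
    if len(short):
        raise SchemaError(
            f"jump trials with < {config.min_jumps} jumps: {short.index.tolist()[:10]}"
        )

    def head4(s: pd.Series) -> float:
        return float(s.iloc[:4].mean())

    def tail4(s: pd.Series) -> float:
        return float(s.iloc[-4:].mean())

    out = g.agg(
        p_mean_4j_w=("jump_power_w", head4),
        p_mean_w=("jump_power_w", "mean"),
        p_mean_end4j_w=("jump_power_w", tail4),
        **{c: (c, "first") for c in _META if c in jump.columns},
    ).reset_index()
    out["fi_pct"] = (out["p_mean_4j_w"] - out["p_mean_end4j_w"]) / out["p_mean_4j_w"] * 100.0
    bm_pow = out["body_mass_kg"] ** config.allometric_exponent
    out["p_mean_4j_rel"] = out["p_mean_4j_w"] / bm_pow
    out["p_mean_rel"] = out["p_mean_w"] / bm_pow
    return out
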