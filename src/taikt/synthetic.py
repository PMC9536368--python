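"""Synthetic athlete cohorts with a calibrated test–retest and cross-test
statistical structure.

The generator emulates a two-group (elite / sub-elite) taekwondo cohort
performing two kick tests (head- and chest-target) and a 30-s continuous
jump test, twice each (test / retest).  It works backwards from the indices
the scoring module computes:

1.  Each athlete gets a sex, body mass and height, and one latent factor per
    variable *family* (power, fatigue index, heart rate, lactate, RPE);
    families are mutually independent, and a variable with loading λ on its
    family correlates λ·λ′ with any other variable of the same family —
    loadings are chosen so the implied cross-test correlations approximate
    the published validity structure (e.g. r ≈ 0.74 between head- and
    chest-test mean power, r ≈ 0.84 with the jump test).
2.  Latent true scores per variable are factor draws scaled to per-group
    means and SDs; session observations add white measurement noise with
    variance σ²_e = V·(1 − ICC)/ICC, where V is the cohort-level latent
    variance (groups mixed), so the expected cohort ICC equals the target.
3.  Raw records are back-solved so that scoring reproduces the intended
    session indices: six set powers are laid on a monotone decay profile
    (curvature per athlete × test) pinned to the session's mean power and
    fatigue index; each set's kick count is the rounded total-distance /
    preferred-distance ratio and the per-set projection distance is re-fit
    within [0.8, 2.0] m, which regenerates the target power exactly in the
    normal range.  Jump trials pin the first-four and last-four plateaus
    and interpolate linearly between them.

With a fixed seed the output is byte-identical across runs.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import ProtocolConfig
from .errors import InvalidInputError

logger = logging.getLogger(__name__)

GROUPS = ("elite", "sub_elite")


@dataclass
class VariableSpec:
    """Latent mean/SD per group, family loading and target test–retest ICC."""

    family: str
    loading: float
    mean_elite: float
    sd_elite: float
    mean_subelite: float
    sd_subelite: float
    icc: float
    lo: float = -np.inf
    hi: float = np.inf
    integer: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.icc <= 1.0:
            raise InvalidInputError("target ICC must be in (0, 1]")
        if not 0.0 <= self.loading <= 1.0:
            raise InvalidInputError("loading must be in [0, 1]")
        if self.sd_elite < 0 or self.sd_subelite < 0:
            raise InvalidInputError("SDs must be non-negative")


def _default_variables() -> dict[str, dict[str, VariableSpec]]:
    """Study-condition defaults: group means/SDs from the published cohort
    (overall 27 athletes, 15 elite / 12 sub-elite), loadings chosen to match
    the published cross-test correlation magnitudes."""
    v = VariableSpec
    return {
        "taikt_head": {
            "p_mean_w": v("power", 0.92, 16.20, 4.46, 12.26, 3.08, 0.99, lo=1.0),
            "fi_pct": v("fatigue", 0.73, 24.88, 5.43, 25.58, 2.20, 0.99, lo=3.0, hi=90.0),
            "hr_peak_bpm": v("hr", 0.87, 181, 12, 184, 7, 0.91, lo=120, hi=220, integer=True),
            "lactate_mmol_l": v("lactate", 0.85, 9.7, 2.9, 10.0, 2.8, 0.95, lo=1.0, hi=22.0),
            "rpe": v("rpe", 0.80, 5, 2, 5, 1, 0.87, lo=0.0, hi=10.0),
        },
        "taikt_chest": {
            "p_mean_w": v("power", 0.80, 9.71, 4.20, 5.17, 2.90, 0.99, lo=0.5),
            "fi_pct": v("fatigue", 0.72, 62.08, 18.41, 62.08, 18.41, 0.98, lo=5.0, hi=150.0),
            "hr_peak_bpm": v("hr", 0.83, 183, 9, 183, 9, 0.91, lo=120, hi=220, integer=True),
            "lactate_mmol_l": v("lactate", 0.85, 10.5, 2.2, 10.5, 2.2, 0.95, lo=1.0, hi=22.0),
            "rpe": v("rpe", 0.80, 6, 1, 6, 1, 0.87, lo=0.0, hi=10.0),
        },
        "cj30s": {
            "p_mean_4j_w": v("power", 0.91, 3038.0, 550.0, 2420.0, 480.0, 0.97, lo=500.0),
            "fi_pct": v("fatigue", 0.88, 17.5, 4.57, 17.5, 4.57, 0.97, lo=2.0, hi=60.0),
            "hr_peak_bpm": v("hr", 0.85, 182, 8, 182, 8, 0.91, lo=120, hi=220, integer=True),
            "lactate_mmol_l": v("lactate", 0.64, 6.2, 1.7, 6.2, 1.7, 0.95, lo=1.0, hi=22.0),
            "rpe": v("rpe", 0.54, 5, 1, 5, 1, 0.87, lo=0.0, hi=10.0),
        },
    }


@dataclass
class CohortSpec:
    """Everything the generator needs; defaults emulate the study cohort."""

    n_elite: int = 15
    n_subelite: int = 12
    seed: int = 0
    male_fraction: dict[str, float] = field(
        default_factory=lambda: {"elite": 12 / 15, "sub_elite": 9 / 12}
    )
    #: body mass (kg) and height (cm) mean/SD per sex
    body_mass: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"male": (64.3, 8.6), "female": (54.3, 2.3)}
    )
    height: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"male": (181.9, 5.7), "female": (165.3, 2.3)}
    )
    variables: dict[str, dict[str, VariableSpec]] = field(
        default_factory=_default_variables
    )
    n_jumps: int = 30
    #: per-set projection distance is kept inside these bounds (m)
    d_bounds: tuple[float, float] = (0.8, 2.0)

    def __post_init__(self) -> None:
        if self.n_elite < 2 or self.n_subelite < 2:
            raise InvalidInputError("need at least 2 athletes per group")
        if self.n_jumps < 8:
            raise InvalidInputError("n_jumps must be >= 8")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _group_weights(spec: CohortSpec) -> np.ndarray:
    n = spec.n_elite + spec.n_subelite
    return np.array([spec.n_elite / n, spec.n_subelite / n])


def _marginal_latent_variance(spec: CohortSpec, vs: VariableSpec) -> float:
    w = _group_weights(spec)
    means = np.array([vs.mean_elite, vs.mean_subelite])
    sds = np.array([vs.sd_elite, vs.sd_subelite])
    mbar = float(w @ means)
    return float(w @ sds ** 2 + w @ (means - mbar) ** 2)


def noise_sd(spec: CohortSpec, vs: VariableSpec) -> float:
    """Measurement-noise SD giving the target cohort-level ICC."""
    if vs.icc == 1.0:
        return 0.0
    v = _marginal_latent_variance(spec, vs)
    return float(np.sqrt(v * (1.0 - vs.icc) / vs.icc))


def expected_auc(spec: CohortSpec, test: str, var: str) -> float:
    """Closed-form AUC of elite vs sub-elite single-session observations:
    Phi(|Δμ| / sqrt(σ1² + σ2² + 2σ_e²))."""
    vs = spec.variables[test][var]
    se2 = noise_sd(spec, vs) ** 2
    delta = abs(vs.mean_elite - vs.mean_subelite)
    denom = np.sqrt(vs.sd_elite ** 2 + vs.sd_subelite ** 2 + 2 * se2)
    return float(stats.norm.cdf(delta / denom))


def expected_correlation(
    spec: CohortSpec, pair: tuple[tuple[str, str], tuple[str, str]]
) -> float:
    """Expected cohort correlation between two observed variables (same
    session), combining the factor structure and the group-mean separation."""
    (t1, v1), (t2, v2) = pair
    a, b = spec.variables[t1][v1], spec.variables[t2][v2]
    w = _group_weights(spec)
    shared = a.loading * b.loading if a.family == b.family else 0.0
    cov_within = shared * float(
        w @ (np.array([a.sd_elite, a.sd_subelite])
             * np.array([b.sd_elite, b.sd_subelite]))
    )
    ma = np.array([a.mean_elite, a.mean_subelite])
    mb = np.array([b.mean_elite, b.mean_subelite])
    cov_between = float(w @ ((ma - w @ ma) * (mb - w @ mb)))
    var_a = _marginal_latent_variance(spec, a) + noise_sd(spec, a) ** 2
    var_b = _marginal_latent_variance(spec, b) + noise_sd(spec, b) ** 2
    return (cov_within + cov_between) / float(np.sqrt(var_a * var_b))


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _decay_weights(gamma: np.ndarray, n_sets: int) -> np.ndarray:
    """Monotone decay profile weights w_1 = 1 ... w_n = 0, curvature gamma."""
    base = (np.arange(n_sets)[::-1] / (n_sets - 1))[None, :]
    return base ** gamma[:, None]


def _set_powers(p_mean: np.ndarray, fi_pct: np.ndarray, gamma: np.ndarray,
                n_sets: int) -> np.ndarray:
    """Six set powers with exact mean ``p_mean`` and fatigue index ``fi_pct``.

    p_mean, fi_pct: (n, s) per athlete and session; gamma: (n,) per athlete.
    Returns (n, s, n_sets).
    """
    w = _decay_weights(gamma, n_sets)              # (n, n_sets)
    wbar = w.mean(axis=1)                          # (n,)
    f = fi_pct / 100.0                             # (n, s)
    p_min = p_mean / (1.0 + f * wbar[:, None])     # (n, s)
    return p_min[:, :, None] * (1.0 + f[:, :, None] * w[:, None, :])


def _backsolve_kicks(
    powers: np.ndarray, llm: np.ndarray, d0: np.ndarray,
    duration: float, d_bounds: tuple[float, float],
) -> tuple[np.ndarray, np.ndarray]:
    """Integer kick counts and per-set distances reproducing target powers.

    powers: (n, s, k); llm, d0: (n,).  Returns (n_kicks, d) of the same shape.
    Distance = sqrt(P t^3 / LLM) is split into N kicks of length d ≈ d0; d is
    then re-fit (= D/N) and kept inside ``d_bounds``; any residual power
    mismatch above 0.5% is warned about.
    """
    lo, hi = d_bounds
    total = np.sqrt(powers * duration ** 3 / llm[:, None, None])
    n = np.maximum(np.rint(total / d0[:, None, None]), 1.0)
    d = total / n
    over = d > hi
    n = np.where(over, np.ceil(total / hi), n)
    d = total / n
    under = d < lo
    n = np.where(under, np.maximum(np.floor(total / lo), 1.0), n)
    d = np.clip(total / n, lo, hi)
    achieved = llm[:, None, None] * (d * n) ** 2 / duration ** 3
    rel_err = np.abs(achieved - powers) / powers
    bad = rel_err > 0.005
    if bad.any():
        logger.warning(
            "%d set(s) with back-solve power mismatch > 0.5%% "
            "(max %.2f%%): target powers outside the feasible distance range",
            int(bad.sum()), 100 * rel_err.max(),
        )
    return n.astype(int), d


def _jump_profile(p4: np.ndarray, fi_pct: np.ndarray, n_jumps: int) -> np.ndarray:
    """Per-jump powers: first-four plateau p4, last-four plateau p4(1-FI/100),
    linear decline in between.  p4, fi_pct: (n, s); returns (n, s, n_jumps)."""
    b = p4 * (1.0 - fi_pct / 100.0)
    j = np.arange(n_jumps, dtype=float)
    # flat through jump 4, reaches the bottom plateau at jump n_jumps-3
    frac = np.clip((j - 3.0) / (n_jumps - 7.0), 0.0, 1.0)
    return p4[:, :, None] + (b - p4)[:, :, None] * frac[None, None, :]


def generate_cohort(
    spec: CohortSpec | None = None,
    protocol: ProtocolConfig | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Generate a raw long-format trial table plus a ground-truth record.

    Returns ``(raw, truth)`` where ``raw`` follows the scoring-module CSV
    schema (kick rows per set, jump rows per jump) and ``truth`` holds, per
    (test, variable): the latent session values actually embedded, the
    target ICC, the noise SD, and closed-form expected AUC / correlations
    for parameter-recovery checks.
    """
    spec = spec or CohortSpec()
    protocol = protocol or ProtocolConfig()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_elite + spec.n_subelite

    group = np.array(["elite"] * spec.n_elite + ["sub_elite"] * spec.n_subelite)
    sex = np.empty(n, dtype=object)
    for g in GROUPS:
        idx = np.where(group == g)[0]
        n_male = int(round(spec.male_fraction[g] * idx.size))
        picked = rng.permutation(idx)[:n_male]
        sex[idx] = "female"
        sex[picked] = "male"
    bm = np.empty(n)
    height = np.empty(n)
    for s in ("male", "female"):
        m = sex == s
        mu, sd = spec.body_mass[s]
        bm[m] = np.clip(rng.normal(mu, sd, m.sum()), 40.0, 110.0)
        mu, sd = spec.height[s]
        height[m] = np.clip(rng.normal(mu, sd, m.sum()), 150.0, 210.0)
    pct = {s: sum(v.values()) for s, v in protocol.segment_percentages.items()}
    llm = np.array([pct[s] for s in sex]) * bm / 100.0
    athlete_id = np.array([f"ath{i:04d}" for i in range(1, n + 1)])

    families = sorted({vs.family for test in spec.variables.values()
                       for vs in test.values()})
    z = {f: rng.standard_normal(n) for f in families}

    is_elite = group == "elite"
    latent: dict[tuple[str, str], np.ndarray] = {}
    observed: dict[tuple[str, str], np.ndarray] = {}
    truth_vars: dict = {}
    for test, varset in spec.variables.items():
        for var, vs in varset.items():
            eps = rng.standard_normal(n)
            u = vs.loading * z[vs.family] + np.sqrt(1 - vs.loading ** 2) * eps
            mu = np.where(is_elite, vs.mean_elite, vs.mean_subelite)
            sd = np.where(is_elite, vs.sd_elite, vs.sd_subelite)
            lat = mu + sd * u
            se = noise_sd(spec, vs)
            obs = lat[:, None] + se * rng.standard_normal((n, 2))
            obs = np.clip(obs, vs.lo, vs.hi)
            if vs.integer:
                obs = np.rint(obs)
            latent[(test, var)] = lat
            observed[(test, var)] = obs
            truth_vars[(test, var)] = {
                "target_icc": vs.icc,
                "noise_sd": se,
                "mean_elite": vs.mean_elite,
                "mean_subelite": vs.mean_subelite,
                "expected_auc": expected_auc(spec, test, var),
            }

    frames = []
    sessions = np.array(["test", "retest"])
    t = protocol.set_duration_s
    k = protocol.n_sets

    # kick tests: back-solve counts and geometry from the intended set powers
    for test, theta_range in (("taikt_head", (40.0, 60.0)),
                              ("taikt_chest", (20.0, 40.0))):
        p_mean = np.clip(observed[(test, "p_mean_w")], 0.05, None)
        fi = observed[(test, "fi_pct")]
        gamma = np.exp(rng.normal(0.0, 0.2, n))
        powers = _set_powers(p_mean, fi, gamma, k)          # (n, 2, k)
        d0 = np.clip(0.0075 * height + rng.normal(0.0, 0.05, n), 0.9, 1.9)
        n_kicks, d = _backsolve_kicks(powers, llm, d0, t, spec.d_bounds)
        theta = np.deg2rad(rng.uniform(*theta_range, n))
        x = d * np.cos(theta)[:, None, None]
        y = d * np.sin(theta)[:, None, None]
        idx_a, idx_s, idx_k = np.meshgrid(
            np.arange(n), np.arange(2), np.arange(k), indexing="ij")
        frames.append(pd.DataFrame({
            "athlete_id": athlete_id[idx_a.ravel()],
            "sex": sex[idx_a.ravel()],
            "body_mass_kg": bm[idx_a.ravel()],
            "group": group[idx_a.ravel()],
            "test": test,
            "session": sessions[idx_s.ravel()],
            "set_index": idx_k.ravel() + 1,
            "n_kicks": n_kicks.ravel(),
            "x_m": x.ravel(),
            "y_m": y.ravel(),
            "jump_power_w": np.nan,
            "hr_peak_bpm": observed[(test, "hr_peak_bpm")][idx_a.ravel(), idx_s.ravel()],
            "lactate_mmol_l": observed[(test, "lactate_mmol_l")][idx_a.ravel(), idx_s.ravel()],
            "rpe": observed[(test, "rpe")][idx_a.ravel(), idx_s.ravel()],
        }))

    # jump test
    nj = spec.n_jumps
    p4 = np.clip(observed[("cj30s", "p_mean_4j_w")], 10.0, None)
    fi_j = observed[("cj30s", "fi_pct")]
    jumps = _jump_profile(p4, fi_j, nj)                     # (n, 2, nj)
    idx_a, idx_s, idx_j = np.meshgrid(
        np.arange(n), np.arange(2), np.arange(nj), indexing="ij")
    frames.append(pd.DataFrame({
        "athlete_id": athlete_id[idx_a.ravel()],
        "sex": sex[idx_a.ravel()],
        "body_mass_kg": bm[idx_a.ravel()],
        "group": group[idx_a.ravel()],
        "test": "cj30s",
        "session": sessions[idx_s.ravel()],
        "set_index": idx_j.ravel() + 1,
        "n_kicks": np.nan,
        "x_m": np.nan,
        "y_m": np.nan,
        "jump_power_w": jumps.ravel(),
        "hr_peak_bpm": observed[("cj30s", "hr_peak_bpm")][idx_a.ravel(), idx_s.ravel()],
        "lactate_mmol_l": observed[("cj30s", "lactate_mmol_l")][idx_a.ravel(), idx_s.ravel()],
        "rpe": observed[("cj30s", "rpe")][idx_a.ravel(), idx_s.ravel()],
    }))

    raw = pd.concat(frames, ignore_index=True)
    raw = raw.sort_values(["athlete_id", "test", "session", "set_index"],
                          kind="mergesort").reset_index(drop=True)

    truth = {
        "seed": spec.seed,
        "variables": truth_vars,
        "latent": latent,
        "observed": observed,
        "athletes": pd.DataFrame({
            "athlete_id": athlete_id, "group": group, "sex": sex,
            "body_mass_kg": bm, "height_cm": height,
        }),
        "expected_correlation": {
            pair: expected_correlation(spec, pair)
            for pair in (
                (("taikt_head", "p_mean_w"), ("taikt_chest", "p_mean_w")),
                (("taikt_head", "p_mean_w"), ("cj30s", "p_mean_4j_w")),
                (("taikt_head", "fi_pct"), ("taikt_chest", "fi_pct")),
                (("taikt_head", "fi_pct"), ("cj30s", "fi_pct")),
                (("taikt_head", "hr_peak_bpm"), ("cj30s", "hr_peak_bpm")),
                (("taikt_head", "lactate_mmol_l"), ("cj30s", "lactate_mmol_l")),
            )
        },
    }
    return raw, truth
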