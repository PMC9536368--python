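"""End-to-end orchestration: score -> reliability -> validity -> discrimination.

One :func:`run_pipeline` call reads a long-format raw trial CSV and writes a
report bundle: the tidy scored indices, the test-retest reliability table,
the cross-test correlation and regression tables, and the elite vs sub-elite
discrimination table (with ROC summaries), plus a JSON run log echoing the
configuration.  The run is a pure function of (input, config): repeated runs
produce identical artifacts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .config import AnalysisConfig, ProtocolConfig
from .discrimination import discrimination_report
from .errors import SchemaError
from .reliability import reliability_report
from .scoring import JUMP_TESTS, KICK_TESTS, score_dataframe
from .validity import correlation_table, regression_table

logger = logging.getLogger(__name__)

KICK_VARS = ["p_peak_w", "p_peak_rel", "p_mean_w", "p_mean_rel", "fi_pct",
             "hr_peak_bpm", "lactate_mmol_l", "rpe"]
JUMP_VARS = ["p_mean_4j_w", "p_mean_4j_rel", "p_mean_w", "p_mean_rel", "fi_pct",
             "hr_peak_bpm", "lactate_mmol_l", "rpe"]

#: matched head-test vs criterion-test column pairs for the validity tables
VALIDITY_PAIRS = [
    ("taikt_chest.p_peak_w", "taikt_head.p_peak_w"),
    ("taikt_chest.p_peak_rel", "taikt_head.p_peak_rel"),
    ("taikt_chest.p_mean_w", "taikt_head.p_mean_w"),
    ("taikt_chest.p_mean_rel", "taikt_head.p_mean_rel"),
    ("taikt_chest.fi_pct", "taikt_head.fi_pct"),
    ("taikt_chest.hr_peak_bpm", "taikt_head.hr_peak_bpm"),
    ("taikt_chest.lactate_mmol_l", "taikt_head.lactate_mmol_l"),
    ("taikt_chest.rpe", "taikt_head.rpe"),
    ("cj30s.p_mean_4j_w", "taikt_head.p_peak_w"),
    ("cj30s.p_mean_4j_rel", "taikt_head.p_peak_rel"),
    ("cj30s.p_mean_w", "taikt_head.p_mean_w"),
    ("cj30s.p_mean_rel", "taikt_head.p_mean_rel"),
    ("cj30s.fi_pct", "taikt_head.fi_pct"),
    ("cj30s.hr_peak_bpm", "taikt_head.hr_peak_bpm"),
    ("cj30s.lactate_mmol_l", "taikt_head.lactate_mmol_l"),
    ("cj30s.rpe", "taikt_head.rpe"),
]

#: cross-prediction equations head<->chest, (predictor, response)
REGRESSION_PAIRS = [
    (f"taikt_chest.{v}", f"taikt_head.{v}")
    for v in ("p_peak_w", "p_peak_rel", "p_mean_w", "p_mean_rel", "fi_pct")
] + [
    (f"taikt_head.{v}", f"taikt_chest.{v}")
    for v in ("p_peak_w", "p_peak_rel", "p_mean_w", "p_mean_rel", "fi_pct")
]

DISCRIMINATION_VARS = ["p_peak_w", "p_peak_rel", "p_mean_w", "p_mean_rel",
                       "fi_pct", "hr_peak_bpm", "lactate_mmol_l", "rpe"]
#: lower fatigue index is the better performance
HIGHER_IS_BETTER = {"fi_pct": False}


@dataclass
class RunConfig:
    input_csv: str | Path
    out_dir: str | Path
    protocol: ProtocolConfig = field(default_factory=ProtocolConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    discrimination_test: str = "taikt_head"
    session_for_validity: str = "test"


def indices_to_wide(indices: pd.DataFrame, session: str = "test") -> pd.DataFrame:
    """One row per athlete, one ``test.variable`` column per index."""
    sub = indices[indices["session"] == session]
    value_cols = [c for c in sub.columns
                  if c not in ("athlete_id", "test", "session", "sex", "group",
                               "body_mass_kg")]
    wide = sub.pivot(index="athlete_id", columns="test", values=value_cols)
    wide.columns = [f"{test}.{var}" for var, test in wide.columns]
    meta = sub.groupby("athlete_id")[["sex", "group", "body_mass_kg"]].first()
    out = meta.join(wide).reset_index()
    return out.dropna(axis=1, how="all")


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run the whole battery; returns a name -> path map of written artifacts."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    raw = pd.read_csv(config.input_csv)
    artifacts: dict[str, Path] = {}

    indices = score_dataframe(raw, config.protocol)
    artifacts["indices"] = out_dir / "indices.csv"
    indices.to_csv(artifacts["indices"], index=False)

    rel_frames = []
    for test in indices["test"].unique():
        sub = indices[indices["test"] == test]
        if set(sub["session"].unique()) < {"test", "retest"}:
            logger.warning("test %s: missing a session, reliability skipped", test)
            continue
        variables = JUMP_VARS if test in JUMP_TESTS else KICK_VARS
        variables = [v for v in variables if v in sub.columns
                     and not sub[v].isna().all()]
        rep = reliability_report(sub, variables, config.analysis)
        rep.insert(0, "test", test)
        rel_frames.append(rep)
    if rel_frames:
        reliability = pd.concat(rel_frames, ignore_index=True)
        artifacts["reliability"] = out_dir / "reliability.csv"
        reliability.to_csv(artifacts["reliability"], index=False)
        artifacts["reliability_json"] = out_dir / "reliability.json"
        artifacts["reliability_json"].write_text(
            reliability.to_json(orient="records", indent=2))

    wide = indices_to_wide(indices, config.session_for_validity)
    corr_pairs = [(x, y) for x, y in VALIDITY_PAIRS
                  if x in wide.columns and y in wide.columns]
    if corr_pairs:
        corr = correlation_table(wide, corr_pairs, alpha=config.analysis.alpha)
        artifacts["correlations"] = out_dir / "validity_correlations.csv"
        corr.to_csv(artifacts["correlations"], index=False)
    reg_pairs = [(x, y) for x, y in REGRESSION_PAIRS
                 if x in wide.columns and y in wide.columns]
    if reg_pairs:
        reg = regression_table(wide, reg_pairs)
        artifacts["equations"] = out_dir / "validity_equations.csv"
        reg.to_csv(artifacts["equations"], index=False)

    groups = set(wide["group"].dropna().unique()) if "group" in wide else set()
    if {"elite", "sub_elite"} <= groups:
        prefix = f"{config.discrimination_test}."
        disc_vars = [prefix + v for v in DISCRIMINATION_VARS
                     if prefix + v in wide.columns]
        disc = discrimination_report(
            wide, disc_vars,
            higher_is_better={prefix + k: v for k, v in HIGHER_IS_BETTER.items()},
            equal_var=config.analysis.equal_var,
            criterion=config.analysis.auc_criterion,
            se_method=config.analysis.auc_se_method,
        )
        artifacts["discrimination"] = out_dir / "discrimination.csv"
        disc.to_csv(artifacts["discrimination"], index=False)
        artifacts["discrimination_json"] = out_dir / "discrimination.json"
        artifacts["discrimination_json"].write_text(
            disc.to_json(orient="records", indent=2))
    else:
        logger.warning("group labels incomplete (%s): discrimination skipped",
                       sorted(groups))

    log = {
        "version": __version__,
        "input": str(config.input_csv),
        "protocol": config.protocol.to_dict(),
        "analysis": config.analysis.to_dict(),
        "artifacts": {k: str(v) for k, v in artifacts.items()},
    }
    artifacts["run_log"] = out_dir / "run_log.json"
    artifacts["run_log"].write_text(json.dumps(log, indent=2))
    return artifacts
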