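"""Protocol constants and run configuration.

The kick-test power formula needs the moving mass of one lower limb,
obtained from anthropometric segment-mass percentages (thigh, shank, foot,
as % of whole-body mass).  Those percentages are population estimates from
cadaver/photogrammetric tables and differ by sex, so they are configuration,
not code: the defaults below are the widely used single-limb values
(male: thigh 10.5, shank 4.75, foot 1.43; female: thigh 11.75, shank 5.35,
foot 1.33) and can be overridden from YAML.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import InvalidInputError

#: Single-limb segment masses as % of body mass, by sex.
DEFAULT_SEGMENT_PERCENTAGES: dict[str, dict[str, float]] = {
    "male": {"thigh": 10.5, "lower_leg": 4.75, "foot": 1.43},
    "female": {"thigh": 11.75, "lower_leg": 5.35, "foot": 1.33},
}


@dataclass
class ProtocolConfig:
    """Constants of the kick/jump field-test protocols.

    Parameters
    ----------
    set_duration_s : execution time of one kicking set (s).
    recovery_duration_s : active recovery between sets (s).
    n_sets : number of kicking sets per trial.
    allometric_exponent : body-mass exponent for relative power
        (power is divided by ``body_mass ** exponent``).
    min_jumps : minimum jumps required to score a continuous-jump trial
        (first-four and last-four means must not overlap).
    segment_percentages : per-sex thigh/lower_leg/foot %BM for lower-limb mass.
    geometry_tolerance_m : maximal allowed inconsistency between a supplied
        projection distance and the one recomputed from (x, y).
    """

    set_duration_s: float = 5.0
    recovery_duration_s: float = 10.0
    n_sets: int = 6
    allometric_exponent: float = 0.67
    min_jumps: int = 8
    segment_percentages: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            sex: dict(v) for sex, v in DEFAULT_SEGMENT_PERCENTAGES.items()
        }
    )
    geometry_tolerance_m: float = 1e-9

    def __post_init__(self) -> None:
        if self.set_duration_s <= 0:
            raise InvalidInputError("set_duration_s must be positive")
        if self.n_sets < 1:
            raise InvalidInputError("n_sets must be >= 1")
        if self.min_jumps < 8:
            raise InvalidInputError("min_jumps must be >= 8")
        for sex, segs in self.segment_percentages.items():
            total = sum(segs.values())
            if not 0.0 < total < 100.0:
                raise InvalidInputError(
                    f"segment percentages for {sex!r} must sum to (0, 100), got {total}"
                )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class AnalysisConfig:
    """Knobs of the statistical battery (defaults reproduce the study's choices)."""

    alpha: float = 0.05
    icc_model: str = "agreement"  # or "consistency"
    sem_sd_source: str = "difference_scores"  # or "between_subject"
    swc_factors: tuple[float, ...] = (0.2, 0.6, 1.2)
    usefulness_tolerance: float = 0.005  # half of the last printed decimal (2 dp)
    auc_criterion: float = 0.70
    auc_se_method: str = "hanley_mcneil"  # or "delong"
    d_sign_convention: str = "sub_minus_elite"
    equal_var: bool = False  # Welch two-sample t by default

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise InvalidInputError("alpha must be in (0, 1)")
        if self.icc_model not in ("agreement", "consistency"):
            raise InvalidInputError(f"unknown icc_model {self.icc_model!r}")
        if self.sem_sd_source not in ("difference_scores", "between_subject"):
            raise InvalidInputError(f"unknown sem_sd_source {self.sem_sd_source!r}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["swc_factors"] = list(self.swc_factors)
        return d


def load_protocol_config(path: str | Path | None) -> ProtocolConfig:
    """Load a :class:`ProtocolConfig` from YAML; ``None`` gives defaults."""
    if path is None:
        return ProtocolConfig()
    data = yaml.safe_load(Path(path).read_text()) or {}
    return ProtocolConfig(**data)


def load_analysis_config(path: str | Path | None) -> AnalysisConfig:
    if path is None:
        return AnalysisConfig()
    data = yaml.safe_load(Path(path).read_text()) or {}
    if "swc_factors" in data:
        data["swc_factors"] = tuple(data["swc_factors"])
    return AnalysisConfig(**data)
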