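import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from taikt.config import ProtocolConfig
from taikt.errors import InvalidInputError
from taikt.scoring import (
    Anthropometry,
    JumpTestTrial,
    KickTestTrial,
    PowerIndices,
    StrikeGeometry,
    lower_limb_mass,
    projection_distance,
    relative_power,
    score_dataframe,
    set_power,
    summarize_jump_trial,
    summarize_kick_trial,
)


def anthro(bm=70.0, pct=(10.5, 4.75, 1.43), sex="male"):
    return Anthropometry(
        athlete_id="a1", sex=sex, body_mass=bm,
        segment_percentages={"thigh": pct[0], "lower_leg": pct[1], "foot": pct[2]},
    )


class TestLowerLimbMass:
    @pytest.mark.parametrize("bm,pct,expected", [
        (100.0, (10.0, 7.0, 3.0), 20.0),
        (70.0, (10.5, 4.75, 1.43), 11.676),   # 0.1668 * 70 by hand
        (70.0, (0.001, 0.001, 0.001), 70.0 * 0.003 / 100),
    ])
    def test_examples(self, bm, pct, expected):
        assert lower_limb_mass(anthro(bm, pct)) == pytest.approx(expected, abs=1e-9)

    def test_nonpositive_mass_rejected(self):
        with pytest.raises(InvalidInputError):
            anthro(bm=-1.0)


class TestProjectionDistance:
    @pytest.mark.parametrize("x,y,expected", [
        (3.0, 4.0, 5.0),
        (1.2, 0.9, 1.5),
        (1.0, 1.0, math.sqrt(2.0)),
    ])
    def test_examples(self, x, y, expected):
        assert projection_distance(x, y) == pytest.approx(expected, rel=1e-12)

    def test_negative_rejected(self):
        with pytest.raises(InvalidInputError):
            projection_distance(-0.1, 1.0)

    def test_zero_zero_rejected(self):
        with pytest.raises(InvalidInputError):
            projection_distance(0.0, 0.0)

    @given(st.floats(0, 10), st.floats(0, 10))
    @settings(max_examples=50, deadline=None)
    def test_dominates_components(self, x, y):
        if x == 0 and y == 0:
            return
        d = projection_distance(x, y)
        assert d >= max(x, y) - 1e-12


class TestSetPower:
    @pytest.mark.parametrize("llm,d,n,t,expected", [
        (10.0, 1.0, 5, 5.0, 2.0),
        (11.676, 1.5, 6, 5.0, 11.676 * 81 / 125),
        (10.0, 1.5, 0, 5.0, 0.0),
    ])
    def test_examples(self, llm, d, n, t, expected):
        assert set_power(llm, d, n, t) == pytest.approx(expected, rel=1e-12)

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(InvalidInputError):
            set_power(10.0, 1.0, 5, 0.0)

    @given(
        llm=st.floats(0.5, 30), d=st.floats(0.5, 2.5),
        n=st.integers(1, 20), t=st.floats(1, 30),
    )
    @settings(max_examples=100, deadline=None)
    def test_homogeneity(self, llm, d, n, t):
        """P scales linearly in LLM, quadratically in d and N, as t^-3."""
        p = set_power(llm, d, n, t)
        assert set_power(2 * llm, d, n, t) == pytest.approx(2 * p, rel=1e-9)
        assert set_power(llm, 2 * d, n, t) == pytest.approx(4 * p, rel=1e-9)
        assert set_power(llm, d, 2 * n, t) == pytest.approx(4 * p, rel=1e-9)
        assert set_power(llm, d, n, 2 * t) == pytest.approx(p / 8, rel=1e-9)


class TestRelativePower:
    @pytest.mark.parametrize("p,bm,expected", [
        (5.0, 1.0, 5.0),
        (16.0, 62.1, 16.0 / 62.1 ** 0.67),
        (0.0, 70.0, 0.0),
    ])
    def test_examples(self, p, bm, expected):
        assert relative_power(p, bm) == pytest.approx(expected, rel=1e-12)

    def test_exponent_zero_is_identity(self):
        assert relative_power(12.3, 77.0, exponent=0.0) == 12.3

    def test_nonpositive_mass_rejected(self):
        with pytest.raises(InvalidInputError):
            relative_power(1.0, 0.0)


class TestStrikeGeometry:
    def test_d_derived_from_xy(self):
        assert StrikeGeometry(x=3.0, y=4.0).d == pytest.approx(5.0)

    def test_inconsistent_d_rejected(self):
        with pytest.raises(InvalidInputError):
            StrikeGeometry(x=3.0, y=4.0, d=5.1)

    def test_d_alone_accepted(self):
        assert StrikeGeometry(d=1.4).d == 1.4


def kick_trial_for_powers(powers, llm=None, t=5.0):
    """Trial whose per-set powers equal ``powers`` (unit kick, fitted d)."""
    if llm is None:
        llm = lower_limb_mass(anthro())
    geoms = [StrikeGeometry(d=math.sqrt(p * t ** 3 / llm)) for p in powers]
    return KickTestTrial(
        athlete_id="a1", test="taikt_head", session="test",
        kicks_per_set=[1] * len(powers), geometry=geoms, set_duration=t,
    )


class TestKickTrialSummary:
    def test_constant_sets_have_zero_fatigue(self):
        res = summarize_kick_trial(kick_trial_for_powers([2.0] * 6), anthro())
        assert res.p_peak == res.p_mean == res.p_min == pytest.approx(2.0)
        assert res.fatigue_index == pytest.approx(0.0)

    def test_direct_arithmetic_case(self):
        res = summarize_kick_trial(
            kick_trial_for_powers([12, 11, 10.5, 10, 10, 10.5]), anthro())
        assert res.p_peak == pytest.approx(12.0)
        assert res.p_min == pytest.approx(10.0)
        assert res.p_mean == pytest.approx(64.0 / 6)
        assert res.fatigue_index == pytest.approx(20.0)

    def test_fatigue_index_formula(self):
        res = summarize_kick_trial(
            kick_trial_for_powers([16, 14, 13.5, 13, 12.9, 12.8]), anthro())
        assert res.fatigue_index == pytest.approx((16 - 12.8) / 12.8 * 100)

    def test_zero_min_power_gives_missing_fi(self, caplog):
        trial = KickTestTrial(
            athlete_id="a1", test="taikt_head", session="test",
            kicks_per_set=[5, 5, 5, 5, 5, 0], geometry=StrikeGeometry(d=1.4),
        )
        with caplog.at_level("WARNING"):
            res = summarize_kick_trial(trial, anthro())
        assert res.fatigue_index is None
        assert "undefined" in caplog.text

    @given(st.permutations(list(range(6))))
    @settings(max_examples=30, deadline=None)
    def test_permutation_invariance(self, order):
        base = [12.0, 11.0, 10.5, 10.0, 9.5, 13.0]
        ref = summarize_kick_trial(kick_trial_for_powers(base), anthro())
        perm = summarize_kick_trial(
            kick_trial_for_powers([base[i] for i in order]), anthro())
        for attr in ("p_peak", "p_mean", "p_min", "fatigue_index"):
            assert getattr(perm, attr) == pytest.approx(getattr(ref, attr))

    @given(st.floats(0.1, 10.0))
    @settings(max_examples=30, deadline=None)
    def test_fi_scale_invariant(self, c):
        base = [12.0, 11.0, 10.5, 10.0, 9.5, 13.0]
        ref = summarize_kick_trial(kick_trial_for_powers(base), anthro())
        scaled = summarize_kick_trial(
            kick_trial_for_powers([c * p for p in base]), anthro())
        assert scaled.fatigue_index == pytest.approx(ref.fatigue_index, rel=1e-6)


class TestJumpTrialSummary:
    def test_two_plateau_case(self):
        trial = JumpTestTrial("a1", "test", [100] * 4 + [80] * 4)
        res = summarize_jump_trial(trial)
        assert res.p_mean_4j == 100 and res.p_mean_end4j == 80
        assert res.fatigue_index == pytest.approx(20.0)

    def test_equal_jumps_zero_fatigue(self):
        res = summarize_jump_trial(JumpTestTrial("a1", "test", [250.0] * 12))
        assert res.fatigue_index == 0.0

    def test_declining_sequence(self):
        res = summarize_jump_trial(
            JumpTestTrial("a1", "test", [120, 110, 100, 90, 85, 80, 75, 70]))
        assert res.p_mean_4j == pytest.approx(105.0)
        assert res.p_mean_end4j == pytest.approx(77.5)
        assert res.p_mean == pytest.approx(91.25)
        assert res.fatigue_index == pytest.approx((105 - 77.5) / 105 * 100)

    def test_too_few_jumps_rejected(self):
        with pytest.raises(InvalidInputError):
            summarize_jump_trial(JumpTestTrial("a1", "test", [100.0] * 7))

    def test_jump_fi_denominator_is_first_four(self):
        """Kick FI divides by the minimum, jump FI by the first-four mean."""
        jumps = [100] * 4 + [60] * 22 + [80] * 4
        res = summarize_jump_trial(JumpTestTrial("a1", "test", jumps))
        assert res.fatigue_index == pytest.approx(20.0)  # not (100-60)/60


class TestDataFrameScoring:
    def test_matches_per_trial_summaries(self, small_raw):
        """Vectorised CSV scoring equals the per-trial object route."""
        config = ProtocolConfig()
        indices = score_dataframe(small_raw, config)
        kick = small_raw[small_raw["test"] == "taikt_head"]
        for (aid, session), grp in kick.groupby(["athlete_id", "session"]):
            grp = grp.sort_values("set_index")
            trial = KickTestTrial(
                athlete_id=aid, test="taikt_head", session=session,
                kicks_per_set=grp["n_kicks"].astype(int).tolist(),
                geometry=[StrikeGeometry(x=r.x_m, y=r.y_m)
                          for r in grp.itertuples()],
                set_duration=config.set_duration_s,
            )
            sex = grp["sex"].iloc[0]
            pct = config.segment_percentages[sex]
            res = summarize_kick_trial(trial, anthro(
                bm=grp["body_mass_kg"].iloc[0],
                pct=(pct["thigh"], pct["lower_leg"], pct["foot"]), sex=sex))
            row = indices[(indices.athlete_id == aid)
                          & (indices.test == "taikt_head")
                          & (indices.session == session)].iloc[0]
            assert row.p_peak_w == pytest.approx(res.p_peak, rel=1e-12)
            assert row.p_mean_w == pytest.approx(res.p_mean, rel=1e-12)
            assert row.fi_pct == pytest.approx(res.fatigue_index, rel=1e-12)
            assert row.p_mean_rel == pytest.approx(res.p_mean_rel, rel=1e-12)

    def test_relative_power_uses_allometric_exponent(self, small_raw):
        indices = score_dataframe(small_raw)
        row = indices[indices.test == "taikt_head"].iloc[0]
        assert row.p_mean_rel == pytest.approx(
            row.p_mean_w / row.body_mass_kg ** 0.67, rel=1e-12)
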