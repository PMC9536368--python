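import numpy as np
import pandas as pd
import pytest

from conftest import vector_with_moments
from taikt.config import AnalysisConfig
from taikt.errors import InvalidInputError
from taikt.reliability import (
    PairedSample,
    icc_band,
    icc_estimate,
    mdc_estimate,
    normality_screen,
    paired_comparison,
    reliability_report,
    reliability_row,
    sem_estimate,
    swc_estimate,
    usefulness_rating,
)


class TestNormalityScreen:
    def test_normal_draws_pass(self):
        hits = 0
        for seed in range(50):
            x = np.random.default_rng(seed).standard_normal(200)
            hits += normality_screen(x)["parametric"]
        assert hits >= 45

    def test_two_point_mass_fails(self):
        x = np.random.default_rng(0).choice([0.0, 1.0], size=200)
        assert not normality_screen(x)["parametric"]

    def test_constant_vector_flagged_nonparametric(self):
        res = normality_screen(np.full(10, 3.3))
        assert res["parametric"] is False


class TestPairedComparison:
    def test_identical_sessions_degenerate(self, caplog):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        with caplog.at_level("WARNING"):
            res = paired_comparison(PairedSample("v", x, x.copy()))
        assert res["mean_diff"] == 0.0 and res["p"] == 1.0

    def test_published_difference_stats(self):
        """n=27 differences with mean 0.152, SD 1.379 give p close to 0.572."""
        diff = vector_with_moments(27, 0.152, 1.379)
        x = np.zeros(27) + diff
        res = paired_comparison(PairedSample("p_peak_w", x, np.zeros(27)))
        assert res["df"] == 26
        assert res["p"] == pytest.approx(0.572, abs=0.002)

    def test_constant_differences_warn(self, caplog):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        with caplog.at_level("WARNING"):
            res = paired_comparison(PairedSample("v", x + 1.0, x))
        assert res["sd_diff"] == 0.0 and res["p"] == 1.0
        assert "zero variance" in caplog.text


class TestIcc:
    def test_perfect_agreement(self):
        x = np.array([1.0, 2.0, 5.0, 9.0, 4.0])
        res = icc_estimate(PairedSample("v", x, x.copy()))
        assert res["icc"] == pytest.approx(1.0)
        assert res["band"] == "excellent"

    def test_shuffled_retest_near_zero(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=1000)
        y = rng.permutation(x)
        res = icc_estimate(PairedSample("v", x, y))
        assert abs(res["icc"]) < 0.1

    def test_additive_shift_model_contrast(self):
        """A constant test->retest shift is error under the agreement model
        but invisible to the consistency model."""
        x = np.array([1.0, 2.0, 5.0, 9.0, 4.0, 7.0])
        s = PairedSample("v", x, x + 2.0)
        assert icc_estimate(s, "consistency")["icc"] == pytest.approx(1.0)
        assert icc_estimate(s, "agreement")["icc"] < 1.0

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(7)
        lat = rng.normal(10, 3, 27)
        x = lat + rng.normal(0, 1, 27)
        y = lat + 0.4 + rng.normal(0, 1, 27)
        df = pd.DataFrame({
            "targets": np.tile(np.arange(27), 2),
            "raters": np.repeat(["t", "r"], 27),
            "ratings": np.concatenate([x, y]),
        })
        ref = pg.intraclass_corr(data=df, targets="targets", raters="raters",
                                 ratings="ratings").set_index("Type")
        s = PairedSample("v", x, y)
        mine_a = icc_estimate(s, "agreement")
        mine_c = icc_estimate(s, "consistency")
        assert mine_a["icc"] == pytest.approx(ref.loc["ICC(A,1)", "ICC"], abs=1e-10)
        assert mine_c["icc"] == pytest.approx(ref.loc["ICC(C,1)", "ICC"], abs=1e-10)
        lo, hi = ref.loc["ICC(A,1)", "CI95"]
        assert mine_a["ci_low"] == pytest.approx(lo, abs=5e-3)
        assert mine_a["ci_high"] == pytest.approx(hi, abs=5e-3)

    def test_parameter_recovery(self):
        """Mean estimate over replicates recovers the generating ICC and the
        95% CI covers it at close to nominal rate."""
        rng = np.random.default_rng(42)
        for target in (0.5, 0.8, 0.95):
            n, reps = 2000, 100
            noise_sd = np.sqrt((1 - target) / target)
            estimates, covered = [], 0
            for _ in range(reps):
                lat = rng.standard_normal(n)
                x = lat + noise_sd * rng.standard_normal(n)
                y = lat + noise_sd * rng.standard_normal(n)
                res = icc_estimate(PairedSample("v", x, y))
                estimates.append(res["icc"])
                covered += res["ci_low"] <= target <= res["ci_high"]
            assert np.mean(estimates) == pytest.approx(target, abs=0.01)
            assert covered / reps == pytest.approx(0.95, abs=0.05)

    def test_band_boundaries(self):
        assert icc_band(0.39) == "low"
        assert icc_band(0.40) == "acceptable"
        assert icc_band(0.70) == "good"
        assert icc_band(0.87) == "good"
        assert icc_band(0.90) == "good"
        assert icc_band(0.901) == "excellent"


class TestAbsoluteReliability:
    @pytest.mark.parametrize("sd,icc,expected", [
        (1.0, 0.0, 1.0),
        (3.7, 1.0, 0.0),
        (0.817, 0.99, 0.0817),   # difference-score SD route
    ])
    def test_sem(self, sd, icc, expected):
        assert sem_estimate(sd, icc) == pytest.approx(expected, abs=5e-4)

    def test_sem_rejects_icc_outside_unit_interval(self):
        with pytest.raises(InvalidInputError):
            sem_estimate(1.0, 1.2)

    @pytest.mark.parametrize("sd1,sd2,factor,expected", [
        (1.0, 1.0, 0.2, 0.2),
        (4.33, 4.21, 0.6, 2.562),
        (4.65, 4.53, 1.2, 5.508),
    ])
    def test_swc(self, sd1, sd2, factor, expected):
        assert swc_estimate(sd1, sd2, factor) == pytest.approx(expected, abs=1e-3)

    @pytest.mark.parametrize("sem,swc,expected", [
        (0.21, 0.92, "good"),
        (0.32, 0.26, "marginal"),
        (0.50, 0.50, "satisfactory"),
    ])
    def test_usefulness(self, sem, swc, expected):
        assert usefulness_rating(sem, swc) == expected

    @pytest.mark.parametrize("sem,expected", [
        (0.0, 0.0), (0.21, 0.582), (1.48, 4.102),
    ])
    def test_mdc(self, sem, expected):
        assert mdc_estimate(sem) == pytest.approx(expected, abs=1e-3)

    def test_mdc_monotone_in_sd_and_icc(self):
        sds = np.linspace(0.1, 5, 20)
        vals = [mdc_estimate(sem_estimate(s, 0.9)) for s in sds]
        assert np.all(np.diff(vals) > 0)
        iccs = np.linspace(0.0, 0.99, 20)
        vals = [mdc_estimate(sem_estimate(1.0, i)) for i in iccs]
        assert np.all(np.diff(vals) < 0)


def _indices_frame(values: dict[str, np.ndarray]) -> pd.DataFrame:
    n = len(next(iter(values.values()))[0])
    rows = []
    for session_i, session in enumerate(("test", "retest")):
        for i in range(n):
            row = {"athlete_id": f"a{i}", "session": session}
            for var, pair in values.items():
                row[var] = pair[session_i][i]
            rows.append(row)
    return pd.DataFrame(rows)


class TestReliabilityReport:
    def test_swc_triple_proportionality(self):
        rng = np.random.default_rng(1)
        lat = rng.normal(15, 4, 30)
        df = _indices_frame({"p": (lat + rng.normal(0, 0.5, 30),
                                   lat + rng.normal(0, 0.5, 30))})
        row = reliability_report(df, ["p"]).iloc[0]
        assert row["swc_0.6"] == pytest.approx(3 * row["swc_0.2"], rel=1e-12)
        assert row["swc_1.2"] == pytest.approx(6 * row["swc_0.2"], rel=1e-12)
        assert row["mdc95"] == pytest.approx(1.96 * row["sem"] * np.sqrt(2), rel=1e-12)

    def test_identical_retest(self):
        x = np.array([3.0, 5.0, 8.0, 2.0, 7.0])
        row = reliability_report(_indices_frame({"p": (x, x.copy())}), ["p"]).iloc[0]
        assert row["icc"] == pytest.approx(1.0)
        assert row["sem"] == 0.0 and row["mdc95"] == 0.0

    def test_unpaired_athletes_dropped(self, caplog):
        df = _indices_frame({"p": (np.arange(6.0), np.arange(6.0) + 0.1)})
        df = df.drop(df[(df.athlete_id == "a0") & (df.session == "retest")].index)
        with caplog.at_level("WARNING"):
            row = reliability_report(df, ["p"]).iloc[0]
        assert row["n"] == 5
        assert "dropped 1" in caplog.text

    def test_two_athlete_cohort_degenerate(self, caplog):
        df = _indices_frame({"p": (np.array([1.0, 2.0]), np.array([1.1, 2.2]))})
        with caplog.at_level("WARNING"):
            row = reliability_report(df, ["p"]).iloc[0]
        assert np.isnan(row["icc_ci_low"]) and np.isnan(row["icc_ci_high"])

    def test_sd_source_config(self):
        rng = np.random.default_rng(2)
        lat = rng.normal(15, 4, 40)
        df = _indices_frame({"p": (lat + rng.normal(0, 0.5, 40),
                                   lat + rng.normal(0, 0.5, 40))})
        row_d = reliability_report(df, ["p"], AnalysisConfig()).iloc[0]
        row_b = reliability_report(
            df, ["p"], AnalysisConfig(sem_sd_source="between_subject")).iloc[0]
        # difference-score SD is far smaller than between-subject SD here
        assert row_d["sem"] < row_b["sem"]
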