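"""Descriptives, contingency odds ratios and the logistic model ladder."""

import numpy as np
import pandas as pd
import pytest

from actipheno import stats as st
from actipheno import synthetic as syn
from actipheno.errors import (
    MalformedInputError,
    RankDeficiencyError,
    SeparationError,
    ZeroCellError,
)

# group sizes and depressive-symptom prevalences printed for the four
# behaviors, used to reconstruct the 4x2 contingency table
GROUP_SIZES = {"AD dominant": 1012, "M dominant": 1444, "AD+M dominant": 1075, "E dominant": 711}
PREV_PCT = {"AD dominant": 8.40, "M dominant": 6.99, "AD+M dominant": 8.56, "E dominant": 15.75}


def _analysis_cohort(n=2500, seed=0, **kw):
    """Complete-case style analysis frame from the generator's truth tables."""
    cfg = syn.SimConfig(n_participants=n, seed=seed, **kw)
    _, cohort, truth = syn.simulate_cohort(cfg, include_activity=False)
    tp = truth["participants"]
    name_map = {"AD_dom": "AD dominant", "M_dom": "M dominant",
                "ADM_dom": "AD+M dominant", "E_dom": "E dominant"}
    df = cohort.merge(tp, on="participant_id")
    df["behavior"] = df["true_behavior"].map(name_map)
    df["depressed"] = df["true_depression"].astype(int)
    rng = np.random.default_rng(1_000_000 + seed)  # stream disjoint from test-level rngs
    df["total_activity"] = rng.normal(12000, 4000, len(df)).clip(500)
    return df


class TestTotalActivity:
    def test_zero_week(self):
        assert st.total_activity(np.zeros((7, 24))) == 0.0

    def test_constant_week(self):
        assert st.total_activity(np.full((7, 24), 60.0)) == 1440.0

    def test_linearity(self):
        rng = np.random.default_rng(0)
        w = rng.poisson(100, (7, 24)).astype(float)
        assert st.total_activity(2 * w) == pytest.approx(2 * st.total_activity(w))

    def test_incomplete_week_rejected(self):
        with pytest.raises(MalformedInputError):
            st.total_activity(np.zeros((6, 24)))


class TestContingency:
    def test_counting(self):
        table = st.build_contingency(
            pd.Series(["M", "M", "E"]), pd.Series([False, True, True])
        )
        assert table.loc["M", "yes"] == 1 and table.loc["M", "no"] == 1
        assert table.loc["E", "yes"] == 1 and table.loc["E", "no"] == 0

    def test_empty_input(self):
        table = st.build_contingency(pd.Series(dtype=object), pd.Series(dtype=bool))
        assert table.to_numpy().sum() == 0

    def test_reconstructed_margins(self):
        table = st.contingency_from_margins(GROUP_SIZES, PREV_PCT)
        assert table["yes"].to_dict() == {
            "AD dominant": 85, "M dominant": 101, "AD+M dominant": 92, "E dominant": 112
        }
        assert int(table["yes"].sum()) == 390
        assert int(table.to_numpy().sum()) == sum(GROUP_SIZES.values())


class TestCrudeOddsRatio:
    def test_identical_rows_unit_or(self):
        table = pd.DataFrame({"yes": [10, 10], "no": [90, 90]}, index=["A", "B"])
        table.index.name = "behavior"
        or_, lo, hi = st.crude_odds_ratio(table, "A", "B")
        assert or_ == pytest.approx(1.0)
        assert lo < 1.0 < hi

    def test_reconstructed_evening_or(self):
        table = st.contingency_from_margins(GROUP_SIZES, PREV_PCT)
        or_, lo, hi = st.crude_odds_ratio(table, "E dominant", "M dominant")
        assert or_ == pytest.approx(2.486, abs=0.01)
        assert lo == pytest.approx(1.86, abs=0.02)
        assert hi == pytest.approx(3.30, abs=0.03)

    def test_reconstructed_adm_or(self):
        table = st.contingency_from_margins(GROUP_SIZES, PREV_PCT)
        or_, _, _ = st.crude_odds_ratio(table, "AD+M dominant", "M dominant")
        assert or_ == pytest.approx(1.244, abs=0.01)

    def test_zero_cell_error(self):
        table = pd.DataFrame({"yes": [0, 10], "no": [90, 90]}, index=["A", "B"])
        with pytest.raises(ZeroCellError):
            st.crude_odds_ratio(table, "A", "B")


class TestFitLogistic:
    def test_single_binary_predictor_equals_2x2(self):
        """exp(coef) of a one-predictor logistic equals the closed-form 2x2 OR."""
        rng = np.random.default_rng(1)
        x = rng.integers(0, 2, 800)
        p = np.where(x == 1, 0.3, 0.12)
        y = (rng.random(800) < p).astype(int)
        design = pd.DataFrame({"x": x.astype(float)})
        fit = st.fit_logistic(y, design)
        a = int(((x == 1) & (y == 1)).sum()); b = int(((x == 1) & (y == 0)).sum())
        c = int(((x == 0) & (y == 1)).sum()); d = int(((x == 0) & (y == 0)).sum())
        oracle = (a / b) / (c / d)
        assert float(fit.or_["x"]) == pytest.approx(oracle, abs=1e-6)

    def test_null_model_type_one_error(self):
        """Independent outcome: |coef| < 3 SE in >= 95% of 200 replicates."""
        rng = np.random.default_rng(2)
        hits = 0
        for _ in range(200):
            x = rng.integers(0, 2, 5000).astype(float)
            y = (rng.random(5000) < 0.1).astype(int)
            fit = st.fit_logistic(y, pd.DataFrame({"x": x}))
            if abs(float(fit.params["x"])) < 3 * float(fit.bse["x"]):
                hits += 1
        assert hits >= 190

    def test_constant_outcome_rejected(self):
        with pytest.raises(SeparationError):
            st.fit_logistic(np.zeros(50), pd.DataFrame({"x": np.arange(50.0)}))

    def test_collinear_design_rejected(self):
        x = np.arange(60.0)
        with pytest.raises(RankDeficiencyError):
            st.fit_logistic(
                (x > 30).astype(int), pd.DataFrame({"x": x, "y": 2 * x})
            )

    def test_wald_ci_brackets_or(self):
        df = _analysis_cohort(2000, seed=3)
        fit = st.fit_logistic(df["depressed"], st.build_design(df, ["behavior"]))
        for t in fit.params.index:
            assert fit.ci_low[t] < fit.or_[t] < fit.ci_high[t]


class TestModelLadders:
    def test_model1_equals_crude_ors(self):
        """One-factor logistic reproduces every 2x2 OR to 1e-6."""
        df = _analysis_cohort(3000, seed=4)
        crude = st.fit_logistic(df["depressed"], st.build_design(df, ["behavior"]), "Model 1")
        table = st.build_contingency(df["behavior"], df["depressed"].astype(bool))
        for b in ["AD dominant", "AD+M dominant", "E dominant"]:
            oracle, _, _ = st.crude_odds_ratio(table, b, "M dominant")
            assert float(crude.or_[f"behavior[{b}]"]) == pytest.approx(oracle, abs=1e-6)

    def test_term_ladder_structure(self):
        df = _analysis_cohort(5000, seed=4)
        fits = st.sequential_models(df)
        assert len(fits) == 6
        expected = ["behavior"]
        for i, cov in enumerate(["age", "bmi", "gender", "work", "total_activity"]):
            got_covs = {t.split("[")[0] for t in fits[i + 1].terms}
            expected.append(cov)
            assert got_covs == set(expected)
        assert fits[0].model_id == "Model 1" and fits[5].model_id == "Model 6"

    def test_unconfounded_adjustment_stays_in_crude_ci(self):
        """Covariates independent of behavior barely move the E-dominant OR."""
        df = _analysis_cohort(5000, seed=5)
        rng = np.random.default_rng(6)
        for col, (mu, sd) in [("age", (45, 15)), ("bmi", (28, 6))]:
            df[col] = rng.normal(mu, sd, len(df))
        df["gender"] = np.where(rng.random(len(df)) < 0.5, "Male", "Female")
        df["work"] = rng.choice(st.WORK_LEVELS, len(df))
        fits = st.sequential_models(df)
        term = "behavior[E dominant]"
        crude = fits[0]
        assert float(crude.ci_low[term]) < float(fits[5].or_[term]) < float(crude.ci_high[term])

    def test_sensitivity_models_one_covariate_each(self):
        df = _analysis_cohort(5000, seed=7)
        sens = st.sensitivity_models(df)
        assert len(sens) == 5
        for fit, cov in zip(sens, ["age", "bmi", "gender", "work", "total_activity"]):
            extra = {t.split("[")[0] for t in fit.terms} - {"behavior"}
            assert extra == {cov}
        term = "behavior[E dominant]"
        crude = st.sequential_models(df)[0]
        for fit in sens:
            assert abs(float(fit.or_[term]) - float(crude.or_[term])) < 0.3

    def test_empty_covariate_list_rejected(self):
        df = _analysis_cohort(500, seed=8)
        with pytest.raises(MalformedInputError):
            st.sensitivity_models(df, covariates=[])


class TestCohortSummary:
    def test_identical_groups_f_zero(self):
        df = pd.DataFrame(
            {"behavior": np.repeat(["A", "B", "C", "D"], 10), "age": 30.0,
             "bmi": 25.0, "gender": "Female", "work": "Working"}
        )
        summary = st.cohort_summary(df)
        assert summary["continuous"]["age"]["F"] == 0.0
        assert summary["continuous"]["age"]["p"] == 1.0

    def test_independent_table_chi2_zero(self):
        df = pd.DataFrame(
            {"behavior": ["A"] * 20 + ["B"] * 20,
             "gender": (["Male"] * 10 + ["Female"] * 10) * 2,
             "age": 30.0, "bmi": 25.0, "work": "Working"}
        )
        summary = st.cohort_summary(df)
        assert summary["categorical"]["gender"]["chi2"] == pytest.approx(0.0, abs=1e-12)

    def test_reconstructed_depression_table_significant(self):
        """Chi-square on the reconstructed 4x2 depressive-symptom table: p < 1e-4."""
        table = st.contingency_from_margins(GROUP_SIZES, PREV_PCT)
        chi2, p = st._chi2(table.to_numpy())
        assert p < 1e-4

    def test_percentages_sum_to_100(self):
        df = _analysis_cohort(1000, seed=9)
        summary = st.cohort_summary(df)
        for var in summary["categorical"]:
            for b in summary["behaviors"]:
                assert sum(summary["categorical"][var]["pct"][b].values()) == pytest.approx(
                    100.0, abs=0.1
                )
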