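"""Domain model fits: phase/group LMMs, retention differential, US
habituation, ratings CLMM wiring, awareness rule, sensitivity variants."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from fearcond.models import (ModelSpec, awareness_column, contingency_aware,
                             fit_group_lmm, fit_phase_lmm, fit_ratings_clmm,
                             fit_us_habituation, retention_early_differential,
                             sensitivity_suite)
from conftest import make_lmm_dataset


class TestPhaseLmm:
    def test_matches_ols_when_no_subject_variance(self):
        df = make_lmm_dataset(n_subjects=40, tau=0.0, beta_cs=0.1,
                              beta_trial=-0.01, beta_interaction=0.02, seed=1)
        fit = fit_phase_lmm(df, "acquisition")
        iscs = (df["cs"] == "CS+").astype(float)
        X = np.column_stack([np.ones(len(df)), iscs, df["trial"],
                             iscs * df["trial"]])
        ols = sm.OLS(df["scr_sqrt"].to_numpy(), X).fit()
        assert np.allclose(fit.table["estimate"], ols.params, rtol=1e-4, atol=1e-6)

    def test_planted_interaction_recovered(self):
        df = make_lmm_dataset(n_subjects=40, beta_interaction=0.03, seed=2)
        fit = fit_phase_lmm(df, "acquisition")
        row = fit.coef("cs:CS+:trial")
        assert row["estimate"] == pytest.approx(0.03, abs=3 * row["se"])
        assert row["p"] < 0.05

    def test_terms_use_cs_minus_reference(self):
        df = make_lmm_dataset(n_subjects=10, seed=3)
        fit = fit_phase_lmm(df, "acquisition")
        assert list(fit.table["term"]) == ["Intercept", "cs:CS+", "trial",
                                           "cs:CS+:trial"]

    def test_missing_rows_dropped(self):
        df = make_lmm_dataset(n_subjects=10, seed=4)
        df.loc[df.index[:17], "scr_sqrt"] = np.nan
        fit = fit_phase_lmm(df, "acquisition")
        assert fit.n_obs == len(df) - 17

    def test_too_few_subjects_rejected(self):
        df = make_lmm_dataset(n_subjects=1, seed=5)
        with pytest.raises(ValueError):
            fit_phase_lmm(df, "acquisition")


@pytest.fixture(scope="module")
def grouped():
    return make_lmm_dataset(n_subjects=45, beta_interaction=0.02,
                            groups=["child", "adolescent", "adult"],
                            beta_group=0.3, seed=6)


class TestGroupLmm:

    def test_reference_switch_is_reparameterization(self, grouped):
        f_adol = fit_group_lmm(grouped, "acquisition", "adolescent")
        f_child = fit_group_lmm(grouped, "acquisition", "child")
        assert f_adol.loglik == pytest.approx(f_child.loglik, abs=1e-6)
        assert f_adol.variance_components["residual_var"] == pytest.approx(
            f_child.variance_components["residual_var"], rel=1e-6)

    def test_planted_group_level_effect_sign(self, grouped):
        fit = fit_group_lmm(grouped, "acquisition", "adult")
        # children were planted 0.3 above the rest: sign recovered, estimate
        # consistent with the plant
        row = fit.coef("group:child")
        assert float(row["estimate"]) > 0
        assert float(row["estimate"]) == pytest.approx(0.3, abs=3 * float(row["se"]))

    def test_group_column_required(self):
        df = make_lmm_dataset(n_subjects=10, seed=7).drop(columns=["group"])
        with pytest.raises(ValueError):
            fit_group_lmm(df, "acquisition")


class TestRetentionDifferential:
    @staticmethod
    def retention_frame(values):
        rows = []
        for sid, (plus, minus, group) in values.items():
            for i, v in enumerate(plus, start=1):
                rows.append({"subject": sid, "group": group, "phase": "retention",
                             "cs": "CS+", "trial": i, "scr_sqrt": v})
            for i, v in enumerate(minus, start=1):
                rows.append({"subject": sid, "group": group, "phase": "retention",
                             "cs": "CS-", "trial": i, "scr_sqrt": v})
        return pd.DataFrame(rows)

    def test_score_arithmetic(self):
        df = self.retention_frame({
            "s1": ((0.3, 0.5), (0.1, 0.1), "child"),
            "s2": ((0.2, 0.2), (0.2, 0.2), "adult"),
            "s3": ((0.4, 0.6), (0.2, 0.4), "adolescent"),
        })
        scores, fit = retention_early_differential(df)
        by_id = {s.subject_id: s.early_diff for s in scores}
        assert by_id["s1"] == pytest.approx(0.3)
        assert by_id["s2"] == pytest.approx(0.0)

    def test_incomplete_subject_excluded_by_default(self):
        df = self.retention_frame({
            "s1": ((0.3, np.nan), (0.1, 0.1), "child"),
            "s2": ((0.2, 0.2), (0.2, 0.2), "adult"),
            "s3": ((0.4, 0.6), (0.2, 0.4), "adolescent"),
        })
        scores, _ = retention_early_differential(df)
        by_id = {s.subject_id: s.early_diff for s in scores}
        assert by_id["s1"] is None
        scores_ac, _ = retention_early_differential(df, require_complete=False)
        by_id_ac = {s.subject_id: s.early_diff for s in scores_ac}
        assert by_id_ac["s1"] == pytest.approx(0.3 - 0.1)

    def test_group_regression_has_overall_f(self):
        rng = np.random.default_rng(0)
        values = {f"s{i}": ((rng.normal(0.3, 0.05), rng.normal(0.3, 0.05)),
                            (rng.normal(0.1, 0.05), rng.normal(0.1, 0.05)),
                            ["child", "adolescent", "adult"][i % 3])
                  for i in range(30)}
        _, fit = retention_early_differential(self.retention_frame(values))
        f_row = fit.table[fit.table["term"] == "group (overall F)"]
        assert len(f_row) == 1 and 0 <= float(f_row["p"].iloc[0]) <= 1


class TestUsHabituation:
    def test_negative_slope_recovered(self):
        rng = np.random.default_rng(8)
        rows = []
        for i in range(40):
            b = rng.normal(0, 0.2)
            for t in range(1, 9):
                rows.append({"subject": f"s{i}", "group": "adult",
                             "phase": "acquisition", "cs": "US", "trial": t,
                             "scr_sqrt": 0.9 - 0.04 * t + b + rng.normal(0, 0.15)})
        fit = fit_us_habituation(pd.DataFrame(rows))
        row = fit.coef("trial")
        assert row["estimate"] < 0 and row["p"] < 0.05

    def test_single_trial_degenerate_input_rejected(self):
        df = pd.DataFrame([{"subject": f"s{i}", "group": "adult",
                            "phase": "acquisition", "cs": "US", "trial": 1,
                            "scr_sqrt": 0.5} for i in range(10)])
        with pytest.raises(ValueError):
            fit_us_habituation(df)


class TestRatingsClmm:
    def test_planted_cs_effect_recovered(self):
        from fearcond.synthetic import RatingParams, SubjectSpec, simulate_ratings
        rng = np.random.default_rng(10)
        params = RatingParams()
        frames = []
        for i in range(80):
            spec = SubjectSpec(f"s{i:03d}", "adult",
                               rating_intercept=float(rng.normal(0, params.subject_sd)))
            frames.append(simulate_ratings(spec, params, rng))
        ratings = pd.concat(frames, ignore_index=True)
        fit = fit_ratings_clmm(ratings)
        cs_row = fit.coef("cs:CS+")
        planted = params.beta_cs_by_phase["post_acquisition"]
        assert cs_row["estimate"] == pytest.approx(planted, abs=3 * cs_row["se"])
        assert cs_row["p"] < 0.01

    def test_out_of_range_ratings_rejected(self):
        df = pd.DataFrame({"subject": ["a", "b"] * 3, "cs": ["CS+", "CS-"] * 3,
                           "phase": ["post_acquisition"] * 6, "rating": [1, 2, 3, 4, 5, 6]})
        with pytest.raises(ValueError):
            fit_ratings_clmm(df)


class TestContingencyAwareness:
    @pytest.mark.parametrize("plus,minus,expected", [
        ("yes", "no", True),
        ("yes", "yes", False),
        ("no", "no", False),
        ("no", "yes", False),
        (None, "no", None),
        ("yes", None, None),
    ])
    def test_rule(self, plus, minus, expected):
        assert contingency_aware(plus, minus) is expected

    def test_vectorized_column(self):
        meta = pd.DataFrame({"cs_plus_screamed": ["yes", "yes", "no"],
                             "cs_minus_screamed": ["no", "yes", "no"]})
        assert list(awareness_column(meta)) == [True, False, False]


@pytest.fixture(scope="module")
def cohort_tables():
    df = make_lmm_dataset(n_subjects=30, beta_interaction=0.02,
                          groups=["child", "adolescent", "adult"], seed=11)
    # clone acquisition rows into the other phases so every re-fit runs
    frames = [df]
    for phase in ("extinction", "retention"):
        alt = df.copy()
        alt["phase"] = phase
        frames.append(alt)
    trials = pd.concat(frames, ignore_index=True)
    subjects = sorted(trials["subject"].unique())
    rng = np.random.default_rng(12)
    meta = pd.DataFrame({
        "subject": subjects,
        "group": [trials.loc[trials["subject"] == s, "group"].iloc[0]
                  for s in subjects],
        "ses": rng.normal(7, 1.5, len(subjects)),
        "us_sound_level": rng.normal(40, 10, len(subjects)),
        "days_between_sessions": rng.integers(1, 14, len(subjects)).astype(float),
        "cs_plus_screamed": ["yes"] * 20 + ["no"] * 10,
        "cs_minus_screamed": ["no"] * 30,
    })
    return trials, meta


class TestSensitivitySuite:

    def test_variants_present_and_awareness_subset_counts(self, cohort_tables):
        trials, meta = cohort_tables
        out = sensitivity_suite(trials, pd.DataFrame(), meta)
        assert {"base", "with_ses", "with_us_sound_level",
                "retention_with_days", "aware_only", "comparison"} <= set(out)
        # awareness filter drops exactly the 10 unaware subjects
        assert out["aware_only"]["phase_acquisition"].n_subjects == 20
        assert out["base"]["phase_acquisition"].n_subjects == 30

    def test_uncorrelated_covariate_leaves_cs_estimate(self, cohort_tables):
        trials, meta = cohort_tables
        out = sensitivity_suite(trials, pd.DataFrame(), meta)
        base = out["base"]["phase_acquisition"].coef("cs:CS+")
        adj = out["with_ses"]["phase_acquisition"].coef("cs:CS+")
        assert adj["estimate"] == pytest.approx(base["estimate"],
                                                abs=2 * float(base["se"]))

    def test_constant_covariate_dropped_with_note(self, cohort_tables):
        trials, meta = cohort_tables
        meta2 = meta.assign(ses=5.0)
        out = sensitivity_suite(trials, pd.DataFrame(), meta2)
        assert "note" in out["with_ses"]

    def test_generator_awareness_rates_match_configured(self):
        # binomial check of the cohort generator's awareness probabilities
        from fearcond.synthetic import GROUP_PROFILES, CohortParams, simulate_cohort, subject_metadata
        params = CohortParams(group_sizes={"child": 60, "adolescent": 60, "adult": 60},
                              sampling_rate_hz=100.0)
        # only metadata is needed; reuse the subject draw via cohort simulation
        subs = simulate_cohort(params, 21)
        meta = subject_metadata(subs)
        aware = awareness_column(meta)
        for group, label in (("child", "child"), ("adolescent", "adolescent"),
                             ("adult", "adult")):
            p = GROUP_PROFILES[group]["aware_p"]
            rate = aware[meta["group"] == label].mean()
            se = np.sqrt(p * (1 - p) / 60)
            assert abs(rate - p) < 3 * se + 1e-9
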