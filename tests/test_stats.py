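import numpy as np
import pandas as pd
import pytest
from scipy import special

import pvsq
from pvsq.stats import (
    age_regression,
    bonferroni,
    build_paired_deltas,
    fit_full_model,
    flag_outliers,
    group_summaries,
)
from pvsq.stats import test_deltas as evaluate_deltas  # avoid pytest collection


def _noise_free_params(**over):
    base = dict(
        n_patients=60,
        intercept=10.0,
        tp_effects={"0M": 0.0, "3M": 0.5, "12M": -1.2, "FollowUp": -0.5},
        anesthesia_effect=-0.5,
        shunt_effect=-1.1,
        sex_effect=0.6,
        age_slope=0.18,
        dose_effects={"RD": 0.0, "SD": 0.3, "HD": -0.4},
        patient_sd=0.0,
        residual_sd=0.0,
        missingness={"0M": 0.0, "3M": 0.0, "12M": 0.0, "FollowUp": 0.0},
    )
    base.update(over)
    return pvsq.CohortSimParams(**base)


class TestFullModel:
    def test_noiseless_exact_recovery(self):
        df = pvsq.generate_cohort(_noise_free_params(), seed=2)
        fit = fit_full_model(df)
        assert fit.method == "ols-degenerate"
        coef = fit.coefficients
        assert abs(coef["C(anesthesia)[T.yes]"] - (-0.5)) < 1e-6
        assert abs(coef["C(shunt)[T.yes]"] - (-1.1)) < 1e-6
        assert abs(coef["C(sex)[T.M]"] - 0.6) < 1e-6
        assert abs(coef["age_years"] - 0.18) < 1e-6
        assert abs(coef["C(tp, Treatment('0M'))[T.3M]"] - 0.5) < 1e-6
        assert abs(coef["C(dose, Treatment('RD'))[T.HD]"] - (-0.4)) < 1e-6
        assert fit.random_intercept_variance == 0.0

    def test_mixed_model_close_to_ols_without_patient_effects(self):
        # with no between-patient variance the REML fixed effects match
        # pooled OLS
        import statsmodels.formula.api as smf

        params = _noise_free_params(patient_sd=0.0, residual_sd=0.8, n_patients=120)
        df = pvsq.generate_cohort(params, seed=8)
        fit = fit_full_model(df)
        formula = (
            "pvs_ratio_permil ~ C(tp, Treatment('0M')) + C(anesthesia) + C(shunt)"
            " + C(sex) + age_years + C(dose, Treatment('RD'))"
        )
        ols = smf.ols(formula, data=df).fit()
        for name in fit.coefficients.index:
            assert abs(fit.coefficients[name] - ols.params[name]) < 1e-4

    def test_estimates_and_bonferroni_structure(self, cohort_default):
        fit = fit_full_model(cohort_default)
        assert fit.method == "mixedlm-reml"
        assert fit.converged
        assert fit.n_patients > 200
        # six TP pairs, three dose pairs, three single tests
        counts = fit.contrasts["family"].value_counts().to_dict()
        assert counts["tp"] == 6 and counts["dose"] == 3
        tp = fit.contrasts[fit.contrasts.family == "tp"]
        np.testing.assert_allclose(
            tp["p_adj"], np.minimum(1.0, 6 * tp["p_value"]), atol=1e-12
        )
        assert (fit.contrasts["p_adj"] >= fit.contrasts["p_value"] - 1e-12).all()

    def test_single_level_covariate_dropped_with_warning(self):
        df = pvsq.generate_cohort(_noise_free_params(residual_sd=0.5), seed=3)
        df["shunt"] = "no"
        with pytest.warns(UserWarning, match="shunt"):
            fit = fit_full_model(df)
        assert not any("shunt" in n for n in fit.coefficients.index)

    def test_missing_responses_dropped_and_counted(self, cohort_default):
        df = cohort_default.copy()
        df.loc[df.index[:10], "pvs_ratio_permil"] = np.nan
        fit = fit_full_model(df)
        assert fit.n_dropped == 10
        assert fit.n_obs == len(df) - 10

    def test_volume_response_supported(self, cohort_default):
        fit = fit_full_model(cohort_default, response="pvs_volume_cm3")
        assert abs(fit.coefficients["age_years"] - 0.14) < 0.05


class TestGroupSummaries:
    def test_hand_arithmetic(self):
        df = pd.DataFrame(
            {
                "patient_id": ["A", "B"],
                "tp": ["0M", "0M"],
                "age_years": [5.0, 6.0],
                "sex": ["F", "F"],
                "dose": ["RD", "RD"],
                "anesthesia": ["no", "no"],
                "shunt": ["no", "no"],
                "pvs_ratio_permil": [9.0, 11.0],
                "pvs_volume_cm3": [4.0, 5.0],
            }
        )
        out = group_summaries(df, "tp")
        row = out[out.level == "0M"].iloc[0]
        assert row["mean"] == pytest.approx(10.0)
        assert row["sd"] == pytest.approx(np.sqrt(2.0))
        assert row["n"] == 2

    def test_empty_level_marked(self):
        df = pvsq.generate_cohort(pvsq.CohortSimParams(n_patients=10), seed=0)
        df = df[df.tp != "FollowUp"]
        out = group_summaries(df, "tp")
        fu = out[out.level == "FollowUp"].iloc[0]
        assert fu["n"] == 0 and np.isnan(fu["mean"])

    def test_unknown_grouping_rejected(self, cohort_default):
        with pytest.raises(ValueError):
            group_summaries(cohort_default, "patient_id")


class TestAgeRegression:
    def test_exact_line(self):
        ages = np.array([4.0, 8.0, 12.0, 16.0])
        df = pd.DataFrame(
            {
                "patient_id": [f"P{i}" for i in range(4)],
                "tp": ["0M"] * 4,
                "age_years": ages,
                "sex": ["F"] * 4,
                "dose": ["RD"] * 4,
                "anesthesia": ["no"] * 4,
                "shunt": ["no"] * 4,
                "pvs_ratio_permil": 0.2 * ages + 5.0,
                "pvs_volume_cm3": 0.1 * ages + 2.0,
            }
        )
        slope, intercept, r = age_regression(df)
        assert slope == pytest.approx(0.2)
        assert intercept == pytest.approx(5.0)
        assert r == pytest.approx(1.0)

    def test_simulated_slopes_near_generating_values(self, cohort_default):
        slope_r, _, _ = age_regression(cohort_default)
        slope_v, _, _ = age_regression(cohort_default, response="pvs_volume_cm3")
        assert abs(slope_r - 0.18) < 0.05
        assert abs(slope_v - 0.14) < 0.04

    def test_too_few_distinct_ages_rejected(self):
        df = pd.DataFrame(
            {
                "patient_id": ["A", "B"],
                "tp": ["0M", "3M"],
                "age_years": [5.0, 5.0],
                "sex": ["F", "F"],
                "dose": ["RD", "RD"],
                "anesthesia": ["no", "no"],
                "shunt": ["no", "no"],
                "pvs_ratio_permil": [9.0, 9.5],
                "pvs_volume_cm3": [4.0, 4.2],
            }
        )
        with pytest.raises(ValueError):
            age_regression(df)


def _toy_paired_table():
    """Four patients; P2 switches anesthesia between 0M and 3M."""
    rows = []
    cov = dict(sex="F", dose="SD", shunt="no")
    for pid, tps, anesthesia in [
        ("P1", ["0M", "3M", "12M"], ["yes", "yes", "yes"]),
        ("P2", ["0M", "3M", "12M"], ["yes", "no", "no"]),
        ("P3", ["0M", "3M"], ["no", "no"]),
        ("P4", ["0M"], ["no"]),
    ]:
        for i, (tp, an) in enumerate(zip(tps, anesthesia)):
            rows.append(
                dict(
                    patient_id=pid, tp=tp, age_years=6.0 + 0.25 * i,
                    anesthesia=an, pvs_ratio_permil=9.0 + i,
                    pvs_volume_cm3=4.0 + 0.5 * i, **cov,
                )
            )
    return pd.DataFrame(rows)


class TestPairedModel:
    def test_pair_construction_rules(self):
        deltas = build_paired_deltas(_toy_paired_table())
        got = set(zip(deltas.patient_id, deltas.period))
        # P2 excluded from 0M-3M (anesthesia switch) but kept in 3M-12M;
        # P4 has no pair at all
        assert got == {("P1", "0M-3M"), ("P1", "3M-12M"),
                       ("P2", "3M-12M"), ("P3", "0M-3M")}
        assert (deltas.delta_ratio_permil == 1.0).all()  # later minus earlier

    def test_missing_measurement_excludes_pair(self):
        df = _toy_paired_table()
        df.loc[(df.patient_id == "P1") & (df.tp == "3M"), "pvs_ratio_permil"] = np.nan
        deltas = build_paired_deltas(df)
        assert ("P1", "0M-3M") not in set(zip(deltas.patient_id, deltas.period))

    def test_symmetric_deltas_give_null_t(self):
        deltas = pd.DataFrame(
            {
                "patient_id": ["a", "b"],
                "period": ["0M-3M"] * 2,
                "dose": ["RD"] * 2,
                "delta_ratio_permil": [-1.0, 1.0],
                "delta_volume_cm3": [0.1, 0.1],
            }
        )
        out = evaluate_deltas(deltas)
        row = out[(out.period == "0M-3M") & (out.dose == "RD")].iloc[0]
        assert row.mean_delta == pytest.approx(0.0)
        assert row.t_stat == pytest.approx(0.0)
        assert row.p_value == pytest.approx(1.0)

    def test_t_statistic_closed_form(self):
        # {1,2,3,4}: t = mean/(sd/sqrt(n)) = 2.5/(1.2910/2) = 3.873,
        # p from an independent evaluation of the t CDF
        x = np.array([1.0, 2.0, 3.0, 4.0])
        deltas = pd.DataFrame(
            {
                "patient_id": list("abcd"),
                "period": ["0M-3M"] * 4,
                "dose": ["SD"] * 4,
                "delta_ratio_permil": x,
                "delta_volume_cm3": x,
            }
        )
        out = evaluate_deltas(deltas)
        row = out[(out.dose == "SD")].iloc[0]
        t_manual = x.mean() / (x.std(ddof=1) / np.sqrt(len(x)))
        assert row.t_stat == pytest.approx(t_manual, abs=1e-9)
        assert row.t_stat == pytest.approx(3.873, abs=5e-4)
        assert row.df == 3
        p_indep = 2.0 * special.stdtr(3, -abs(t_manual))
        assert row.p_value == pytest.approx(p_indep, abs=1e-12)
        assert row.p_value == pytest.approx(0.0305, abs=5e-4)

    def test_untestable_cells_flagged_not_raised(self):
        deltas = pd.DataFrame(
            {
                "patient_id": ["a"],
                "period": ["0M-3M"],
                "dose": ["HD"],
                "delta_ratio_permil": [0.4],
                "delta_volume_cm3": [0.2],
            }
        )
        out = evaluate_deltas(deltas)
        row = out[out.dose == "HD"].iloc[0]
        assert not row.testable and np.isnan(row.t_stat)

    def test_anova_across_doses(self, cohort_default):
        deltas = build_paired_deltas(cohort_default)
        out = evaluate_deltas(deltas)
        chemo = out[out.period == "3M-12M"]
        assert chemo["anova_F"].notna().all()
        # chemotherapy-period decrease is detected in every dose group
        assert (chemo["mean_delta"] < 0).all()

    def test_full_and_paired_views_agree_on_direction(self, cohort_default):
        fit = fit_full_model(cohort_default)
        deltas = build_paired_deltas(cohort_default)
        out = evaluate_deltas(deltas)
        tp_coef = fit.coefficients
        d_full = (
            tp_coef["C(tp, Treatment('0M'))[T.12M]"]
            - tp_coef["C(tp, Treatment('0M'))[T.3M]"]
        )
        d_paired = out[out.period == "3M-12M"]["mean_delta"].mean()
        assert np.sign(d_full) == np.sign(d_paired) == -1


class TestOutliers:
    def test_constant_input_no_outliers(self):
        assert flag_outliers([10, 10, 10, 10]).flagged == []

    def test_clear_outlier_flagged(self):
        # {0 x9, 100}: mean 10, sd 31.6 -> |100-10| > 2 sd
        rep = flag_outliers([0] * 9 + [100])
        assert rep.flagged == [9]

    def test_borderline_case_not_flagged(self):
        # {0,0,0,0,100}: mean 20, sd ~44.7 -> 80 < 2*44.7, nothing flagged
        assert flag_outliers([0, 0, 0, 0, 100]).flagged == []

    def test_review_sample_seeded_and_in_range(self):
        x = list(range(100)) + [10_000]
        a = flag_outliers(x, seed=5)
        b = flag_outliers(x, seed=5)
        assert a.review_sample == b.review_sample
        assert len(a.review_sample) == 20
        assert 100 not in a.review_sample  # the outlier is not reviewed as in-range

    def test_k_parameter(self):
        x = [0, 0, 0, 0, 100]
        assert flag_outliers(x, k=1.5).flagged == [4]


class TestBonferroni:
    def test_cap_and_monotonicity(self):
        assert bonferroni(0.3, 6) == 1.0
        assert bonferroni(0.01, 6) == pytest.approx(0.06)
        assert bonferroni(0.02, 1) == pytest.approx(0.02)
        ps = np.linspace(0.001, 0.2, 50)
        adj = [bonferroni(p, 6) for p in ps]
        assert all(a2 >= a1 for a1, a2 in zip(adj, adj[1:]))
        assert all(a >= p for p, a in zip(ps, adj))
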