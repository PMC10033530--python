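"""Tests for the factorial ANOVA, Bonferroni contrasts and correlations."""

import itertools
import logging

import numpy as np
import pandas as pd
import pytest

from regenfit import (
    CohortSpec,
    correlate_params,
    fit_factorial,
    generate_cohort,
    pairwise_contrasts,
)
from regenfit.cohort_stats import RankDeficiencyError, significance_stars


def balanced_frame(rng=None, reps=6, sex_effect=0.0, noise=1.0,
                   times=(0.0, 24.0)):
    """Fully crossed 2x2x|times| design with ``reps`` animals per cell."""
    rng = rng or np.random.default_rng(0)
    rows = []
    for sex, diet, t in itertools.product(("male", "female"),
                                          ("ethanol", "control"), times):
        for r in range(reps):
            y = (sex_effect if sex == "male" else 0.0) \
                + noise * rng.normal()
            rows.append({"sex": sex, "diet": diet, "t_hours": t,
                         "rel_volume": y})
    return pd.DataFrame(rows)


def cohort_volume_frame(seed):
    animals = generate_cohort(CohortSpec(seed=seed))
    return pd.DataFrame([
        {"animal_id": a.animal_id, "sex": a.sex, "diet": a.diet,
         "t_hours": t, "rel_volume": v}
        for a in animals for t, v in zip(a.t_hours, a.rel_volume)
        if t >= 0])


class TestFactorialFit:
    def test_terms_are_the_full_three_way_factorial(self):
        fit = fit_factorial(balanced_frame(), "rel_volume")
        terms = set(fit.anova.index) - {"Residual"}
        assert terms == {
            "C(sex)", "C(diet)", "C(time)", "C(sex):C(diet)",
            "C(sex):C(time)", "C(diet):C(time)",
            "C(sex):C(diet):C(time)"}

    def test_balanced_design_matches_hand_computed_f(self):
        # balanced data: type-II SS reduce to the textbook marginal-mean
        # decomposition, computed here from first principles
        data = balanced_frame(np.random.default_rng(5), reps=8,
                              sex_effect=1.0)
        fit = fit_factorial(data, "rel_volume")
        y = data["rel_volume"].to_numpy()
        grand = y.mean()
        ss_sex = sum(
            (data.loc[data.sex == s, "rel_volume"].mean() - grand) ** 2
            * (data.sex == s).sum() for s in ("male", "female"))
        cell_means = data.groupby(["sex", "diet", "t_hours"])[
            "rel_volume"].transform("mean")
        ss_resid = float(((y - cell_means) ** 2).sum())
        df_resid = len(y) - 8  # 2*2*2 cells
        f_hand = (ss_sex / 1.0) / (ss_resid / df_resid)
        assert fit.anova.loc["C(sex)", "F"] == pytest.approx(f_hand,
                                                             rel=1e-9)
        assert fit.df_resid == df_resid

    def test_constant_response_shows_no_effects(self):
        data = balanced_frame(noise=0.0)
        data["rel_volume"] = 0.5
        fit = fit_factorial(data, "rel_volume")
        # all variation vanishes: every term's SS is numerically zero and
        # nothing can be called significant (F ratios of zeros are noise)
        assert (fit.anova["sum_sq"].abs() < 1e-20).all()
        assert not (fit.anova["PR(>F)"].drop("Residual") < 0.05).any()

    def test_pure_noise_rarely_extreme(self):
        data = balanced_frame(np.random.default_rng(17), reps=10)
        fit = fit_factorial(data, "rel_volume")
        assert not (fit.anova["PR(>F)"].drop("Residual") < 0.001).any()

    def test_sum_of_squares_decomposition_balanced(self):
        data = balanced_frame(np.random.default_rng(3), reps=5,
                              sex_effect=0.7)
        fit = fit_factorial(data, "rel_volume")
        total = ((data["rel_volume"] - data["rel_volume"].mean())**2).sum()
        assert fit.anova["sum_sq"].sum() == pytest.approx(total, rel=1e-9)

    def test_relabeling_factor_levels_preserves_f(self):
        data = balanced_frame(np.random.default_rng(23), reps=6,
                              sex_effect=0.4)
        fit1 = fit_factorial(data, "rel_volume")
        relabeled = data.replace({"sex": {"male": "zzz", "female": "aaa"}})
        fit2 = fit_factorial(relabeled, "rel_volume")
        assert np.allclose(fit1.anova["F"].drop("Residual"),
                           fit2.anova["F"].drop("Residual"))

    def test_type_iii_switch_runs(self):
        fit = fit_factorial(balanced_frame(), "rel_volume", ss_type="III")
        assert fit.ss_type == "III"
        assert "C(sex, Sum)" in "".join(fit.anova.index)

    def test_empty_cell_is_an_informative_error(self):
        data = balanced_frame()
        data = data[~((data.sex == "male") & (data.diet == "ethanol")
                      & (data.t_hours == 0.0))]
        with pytest.raises(RankDeficiencyError, match="male"):
            fit_factorial(data, "rel_volume")

    def test_single_level_factor_rejected(self):
        data = balanced_frame()
        with pytest.raises(ValueError, match="diet"):
            fit_factorial(data[data.diet == "ethanol"], "rel_volume")

    def test_interaction_detected_when_diet_acts_in_males_only(self):
        # the study design: a diet effect present only in males must light
        # up sex:diet; power >= 90% over seeded replicates
        hits = 0
        n_rep = 100
        for rep in range(n_rep):
            data = cohort_volume_frame(seed=1000 + rep)
            fit = fit_factorial(data, "rel_volume")
            hits += fit.anova.loc["C(sex):C(diet)", "PR(>F)"] < 0.05
        assert hits >= 0.90 * n_rep


class TestContrasts:
    def test_adjustment_is_bonferroni_with_cap(self):
        data = cohort_volume_frame(seed=4)
        table = pairwise_contrasts(data, "rel_volume")
        m = table["n_comparisons"]
        expected = np.minimum(1.0, table["p_raw"] * m)
        assert np.allclose(table["p_adj"], expected, equal_nan=True)
        assert (table["p_adj"] <= 1.0 + 1e-12).all()
        assert (table["p_adj"] >= table["p_raw"] - 1e-12).all()

    def test_family_is_pairs_within_time_point(self):
        data = cohort_volume_frame(seed=4)
        table = pairwise_contrasts(data, "rel_volume")
        # 6 sex-diet groups -> 15 pairs at each time point
        assert (table["n_comparisons"] == 15).all()
        per_time = table.groupby("t_hours").size()
        assert (per_time == 15).all()

    def test_two_groups_single_comparison_unchanged(self):
        rng = np.random.default_rng(8)
        rows = [{"sex": "male", "diet": d, "t_hours": 0.0,
                 "rel_volume": rng.normal(loc)} for d, loc in
                [("ethanol", 0.0), ("control", 0.5)] for _ in range(10)]
        table = pairwise_contrasts(pd.DataFrame(rows), "rel_volume")
        assert len(table) == 1
        assert table.loc[0, "p_adj"] == pytest.approx(
            table.loc[0, "p_raw"])

    def test_ethanol_male_contrast_significant_at_one_week(self):
        data = cohort_volume_frame(seed=12)
        table = pairwise_contrasts(data, "rel_volume")
        row = table[(table.t_hours == 168.0)
                    & (table.group1 == "male:control")
                    & (table.group2 == "male:ethanol")]
        assert row["p_adj"].iloc[0] < 0.01
        assert row["estimate"].iloc[0] > 0.1  # controls recover more

    def test_stars(self):
        assert significance_stars(2e-4) == "***"
        assert significance_stars(0.004) == "**"
        assert significance_stars(0.04) == "*"
        assert significance_stars(0.5) == "ns"


class TestCorrelations:
    def test_exact_linear_relation_gives_r_one(self):
        fits = pd.DataFrame({"animal_id": list("abcde"),
                             "best_M_unweighted": [5., 9., 13., 20., 25.],
                             "best_Kcd_unweighted": [0.1] * 5})
        pre = pd.DataFrame({"animal_id": list("abcde"),
                            "pv_flow": 2 * np.array([5., 9., 13., 20., 25.])
                            + 1})
        table = correlate_params(fits, pre)
        r = table[table.parameter == "best_M_unweighted"]["R"].iloc[0]
        assert r == pytest.approx(1.0)

    def test_hand_computed_pearson_on_small_table(self):
        x = np.array([9.0, 12.0, 15.0, 21.0, 27.0])
        y = np.array([1.9, 1.4, 1.6, 1.1, 0.9])
        fits = pd.DataFrame({"animal_id": list("abcde"),
                             "best_M_unweighted": x,
                             "best_Kcd_unweighted": [0.1] * 5})
        pre = pd.DataFrame({"animal_id": list("abcde"), "pv_flow": y})
        hand = (np.sum((x - x.mean()) * (y - y.mean()))
                / np.sqrt(np.sum((x - x.mean())**2)
                          * np.sum((y - y.mean())**2)))
        table = correlate_params(fits, pre)
        r = table[table.parameter == "best_M_unweighted"]["R"].iloc[0]
        assert r == pytest.approx(hand, rel=1e-12)

    def test_independent_data_has_small_r(self):
        rng = np.random.default_rng(31)
        n = 1000
        ids = [f"a{i}" for i in range(n)]
        fits = pd.DataFrame({"animal_id": ids,
                             "best_M_unweighted": rng.normal(size=n),
                             "best_Kcd_unweighted": rng.normal(size=n)})
        pre = pd.DataFrame({"animal_id": ids,
                            "stiffness": rng.normal(size=n)})
        table = correlate_params(fits, pre)
        assert (table["R"].abs() < 0.1).all()

    def test_constant_vector_reported_missing_with_warning(self, caplog):
        fits = pd.DataFrame({"animal_id": list("abc"),
                             "best_M_unweighted": [9.0, 9.0, 9.0],
                             "best_Kcd_unweighted": [0.1, 0.2, 0.3]})
        pre = pd.DataFrame({"animal_id": list("abc"),
                            "spo2": [55.0, 57.0, 54.0]})
        with caplog.at_level(logging.WARNING):
            table = correlate_params(fits, pre)
        row = table[table.parameter == "best_M_unweighted"].iloc[0]
        assert np.isnan(row["R"]) and "constant" in caplog.text

    def test_too_few_pairs_reported_missing(self, caplog):
        fits = pd.DataFrame({"animal_id": ["a", "b"],
                             "best_M_unweighted": [9.0, 12.0],
                             "best_Kcd_unweighted": [0.1, 0.2]})
        pre = pd.DataFrame({"animal_id": ["a", "b"], "spo2": [55.0, 57.0]})
        with caplog.at_level(logging.WARNING):
            table = correlate_params(fits, pre)
        assert table["R"].isna().all()
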