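import math
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from pvceval.cohort import CohortConfig, GroupConfig, generate_cohort, nhs_default_config
from pvceval.lmem import (
    LmemSpec,
    annualized_pct_from_slope,
    bootstrap_ci,
    evaluate_methods,
    fit_lmem,
    group_change_statistic,
    group_slope,
    group_slope_se,
    interaction_tscores,
    longitudinal_effect_size,
    residual_pct_cv,
    spearman_baseline_vs_change,
    subject_annualized_changes,
)


def two_group_config(seed=0, n=10, sd=1e-8, slopes=(0.02, 0.035), visits=(0.0, 26.0, 52.0)):
    groups = {
        "CU": GroupConfig(
            n=n, baseline_lnsuvr={"WCG": math.log(1.2)},
            slope_ln_per_year={"WCG": slopes[0]},
            sd_intercept=sd, sd_slope=sd, sd_residual=sd,
        ),
        "prodromal": GroupConfig(
            n=n, baseline_lnsuvr={"WCG": math.log(1.3)},
            slope_ln_per_year={"WCG": slopes[1]},
            sd_intercept=sd, sd_slope=sd, sd_residual=sd,
        ),
    }
    return CohortConfig(study="NHS", groups=groups, visit_weeks=visits,
                        jitter_sd_weeks=0.0, seed=seed)


@pytest.fixture(scope="module")
def nhs_fit():
    cohort = generate_cohort(nhs_default_config(seed=12).scaled(2))
    spec = LmemSpec(roi="WCG", group_vars=("group",), reference_group="CU")
    return cohort, fit_lmem(cohort.scans_frame(), cohort.subjects_frame(), spec)


class TestFitLmem:
    def test_noise_free_exact_recovery(self):
        cohort = generate_cohort(two_group_config())
        fit = fit_lmem(cohort.scans_frame(), cohort.subjects_frame(),
                       LmemSpec(roi="WCG", reference_group="CU"))
        assert group_slope(fit, "CU") == pytest.approx(0.02, abs=1e-6)
        assert group_slope(fit, "prodromal") == pytest.approx(0.035, abs=1e-6)

    def test_balanced_design_matches_gls_closed_form(self):
        """On a balanced orthogonal design the mixed-model fixed effects
        equal per-group OLS (the GLS closed form)."""
        config = two_group_config(seed=3, n=40, sd=0.02)
        cohort = generate_cohort(config)
        scans, subjects = cohort.scans_frame(), cohort.subjects_frame()
        fit = fit_lmem(scans, subjects, LmemSpec(roi="WCG", reference_group="CU"))
        merged = scans.merge(subjects[["subject_id", "group"]].drop_duplicates(),
                             on="subject_id", suffixes=("", "_s"))
        for g in ("CU", "prodromal"):
            sub = merged[merged["group"] == g]
            slope_ols = np.polyfit(sub["time_years"], np.log(sub["suvr"]), 1)[0]
            assert group_slope(fit, g) == pytest.approx(slope_ols, abs=1e-6)

    def test_recovered_variance_components(self):
        config = two_group_config(seed=4, n=300, sd=0.0)
        groups = {
            name: replace(g, sd_intercept=0.1, sd_slope=0.015, sd_residual=0.03)
            for name, g in config.groups.items()
        }
        config = replace(config, groups=groups, visit_weeks=(0.0, 26.0, 52.0, 78.0))
        cohort = generate_cohort(config)
        fit = fit_lmem(cohort.scans_frame(), cohort.subjects_frame(),
                       LmemSpec(roi="WCG", reference_group="CU"))
        assert fit.sigma == pytest.approx(0.03, rel=0.10)
        assert fit.sigma_u == pytest.approx(0.1, rel=0.10)
        assert fit.sigma_v == pytest.approx(0.015, rel=0.25)

    def test_unknown_apoe4_level_retained(self):
        cohort = generate_cohort(nhs_default_config(seed=5))
        scans, subjects = cohort.scans_frame(), cohort.subjects_frame()
        assert (subjects["apoe4"] == "unknown").any()
        fit = fit_lmem(scans, subjects,
                       LmemSpec(roi="WCG", covariates=("apoe4", "age", "sex"),
                                reference_group="CU"))
        assert fit.n_subjects == 63
        assert any("apoe4" in name.lower() for name in fit.params.index)

    def test_empty_interaction_cell_named(self):
        cohort = generate_cohort(nhs_default_config(seed=6))
        scans, subjects = cohort.scans_frame(), cohort.subjects_frame()
        # CU subjects all carry tau_level "CU", so diagnostic x tau crossing
        # leaves cells like prodromal:CU empty
        with pytest.raises(ValueError, match="empty interaction cells"):
            fit_lmem(scans, subjects,
                     LmemSpec(roi="WCG", group_vars=("group", "tau_level"),
                              reference_group="prodromal:low"))

    def test_nonpositive_suvr_rejected(self):
        cohort = generate_cohort(two_group_config())
        scans = cohort.scans_frame()
        scans.loc[scans.index[0], "suvr"] = -1.0
        with pytest.raises(ValueError, match="positive"):
            fit_lmem(scans, cohort.subjects_frame(), LmemSpec(roi="WCG"))

    def test_missing_reference_group(self):
        cohort = generate_cohort(two_group_config())
        with pytest.raises(ValueError, match="reference"):
            fit_lmem(cohort.scans_frame(), cohort.subjects_frame(),
                     LmemSpec(roi="WCG", reference_group="moderate"))

    def test_blups_centered_within_groups(self, nhs_fit):
        cohort, fit = nhs_fit
        subjects = cohort.subjects_frame()
        for g, ids in subjects.groupby("group")["subject_id"]:
            us = [fit.blups[s][0] for s in ids]
            vs = [fit.blups[s][1] for s in ids]
            assert abs(np.mean(us)) < 0.05
            assert abs(np.mean(vs)) < 0.01


class TestResidualPctCv:
    def test_zero(self):
        assert residual_pct_cv(0.0) == 0.0

    def test_closed_form_value(self):
        # 100*sqrt(exp(0.03^2) - 1)
        assert residual_pct_cv(0.03) == pytest.approx(3.000675, abs=1e-5)

    def test_matches_monte_carlo_cv(self):
        rng = np.random.default_rng(0)
        for sigma in (0.01, 0.03, 0.05):
            draws = np.exp(rng.normal(0.0, sigma, size=10**6))
            mc_cv = 100.0 * draws.std() / draws.mean()
            assert residual_pct_cv(sigma) == pytest.approx(mc_cv, rel=1e-3)

    def test_small_sigma_approximation(self):
        for sigma in (0.01, 0.03, 0.05):
            assert abs(residual_pct_cv(sigma) - 100.0 * sigma) < 0.05

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            residual_pct_cv(-0.01)


class TestInteractionTscores:
    def test_sign_convention(self):
        cohort = generate_cohort(two_group_config(slopes=(0.01, 0.04)))
        fit = fit_lmem(cohort.scans_frame(), cohort.subjects_frame(),
                       LmemSpec(roi="WCG", reference_group="CU"))
        assert interaction_tscores(fit)["prodromal"] > 0

    def test_power_with_injected_difference(self):
        hits = 0
        for rep in range(10):
            config = two_group_config(seed=100 + rep, n=50, sd=0.0,
                                      slopes=(0.0, 0.02),
                                      visits=(0.0, 26.0, 52.0, 78.0))
            groups = {n: replace(g, sd_residual=0.03) for n, g in config.groups.items()}
            cohort = generate_cohort(replace(config, groups=groups))
            fit = fit_lmem(cohort.scans_frame(), cohort.subjects_frame(),
                           LmemSpec(roi="WCG", reference_group="CU"))
            if interaction_tscores(fit)["prodromal"] > 1.96:
                hits += 1
        assert hits >= 6  # injected 2 percent/yr difference is detectable

    def test_null_mostly_insignificant(self):
        hits = 0
        for rep in range(10):
            config = two_group_config(seed=200 + rep, n=50, sd=0.0, slopes=(0.02, 0.02),
                                      visits=(0.0, 26.0, 52.0, 78.0))
            groups = {n: replace(g, sd_residual=0.03) for n, g in config.groups.items()}
            cohort = generate_cohort(replace(config, groups=groups))
            fit = fit_lmem(cohort.scans_frame(), cohort.subjects_frame(),
                           LmemSpec(roi="WCG", reference_group="CU"))
            if abs(interaction_tscores(fit)["prodromal"]) < 1.96:
                hits += 1
        assert hits >= 8


class TestAnnualizedPctFromSlope:
    def test_zero(self):
        assert annualized_pct_from_slope(0.0) == 0.0

    def test_five_percent(self):
        assert annualized_pct_from_slope(math.log(1.05)) == pytest.approx(5.0)

    def test_closed_form(self):
        assert annualized_pct_from_slope(0.0296) == pytest.approx(3.0042, abs=1e-4)


class TestSubjectChanges:
    def test_zero_random_slope_gives_group_value(self):
        cohort = generate_cohort(two_group_config(n=20, sd=1e-8))
        fit = fit_lmem(cohort.scans_frame(), cohort.subjects_frame(),
                       LmemSpec(roi="WCG", reference_group="CU"))
        changes = subject_annualized_changes(fit)
        subjects = cohort.subjects_frame()
        for g, expected in (("CU", 0.02), ("prodromal", 0.035)):
            ids = subjects.loc[subjects.group == g, "subject_id"]
            vals = {changes[s] for s in ids}
            for v in vals:
                assert v == pytest.approx(100 * math.expm1(expected), abs=1e-3)

    def test_noise_free_matches_generator_truth(self):
        config = two_group_config(seed=9, n=40)
        groups = {n: replace(g, sd_slope=0.02, sd_residual=1e-8, sd_intercept=1e-8)
                  for n, g in config.groups.items()}
        config = replace(config, groups=groups, visit_weeks=(0.0, 26.0, 52.0, 78.0))
        cohort = generate_cohort(config)
        fit = fit_lmem(cohort.scans_frame(), cohort.subjects_frame(),
                       LmemSpec(roi="WCG", reference_group="CU"))
        changes = subject_annualized_changes(fit)
        for sid, info in cohort.truth["subjects"].items():
            true_slope = config.groups[info["group"]].slope_ln_per_year["WCG"] + info["v"]
            assert changes[sid] == pytest.approx(100 * math.expm1(true_slope), abs=1e-3)

    def test_mean_close_to_group_value(self, nhs_fit):
        cohort, fit = nhs_fit
        changes = subject_annualized_changes(fit)
        subjects = cohort.subjects_frame()
        ids = subjects.loc[subjects.group == "prodromal", "subject_id"]
        group_val = annualized_pct_from_slope(group_slope(fit, "prodromal"))
        assert np.mean([changes[s] for s in ids]) == pytest.approx(group_val, abs=0.5)

    def test_unknown_subject_raises(self, nhs_fit):
        _, fit = nhs_fit
        with pytest.raises(KeyError):
            subject_annualized_changes(fit, ["not-a-subject"])


class TestEffectSize:
    def test_simple_value(self):
        assert longitudinal_effect_size([1.0, 2.0, 3.0]) == pytest.approx(2.0)

    def test_scale_invariance(self):
        values = [0.5, 1.5, 2.5, 4.0]
        assert longitudinal_effect_size([3 * v for v in values]) == pytest.approx(
            longitudinal_effect_size(values)
        )

    def test_zero_sd_rejected(self):
        with pytest.raises(ValueError):
            longitudinal_effect_size([1.0, 1.0, 1.0])


class TestBootstrap:
    def test_determinism(self, nhs_fit):
        _, fit = nhs_fit
        stat = group_change_statistic(fit, "prodromal")
        a = bootstrap_ci(stat, fit, n_draws=200, seed=33)
        b = bootstrap_ci(stat, fit, n_draws=200, seed=33)
        assert a == b

    def test_degenerate_zero_variance(self, nhs_fit):
        _, fit = nhs_fit
        degenerate = replace(fit, cov_beta=fit.cov_beta * 0.0)
        stat = group_change_statistic(degenerate, "prodromal")
        mean, lo, hi = bootstrap_ci(stat, degenerate, n_draws=100, seed=0)
        assert lo == pytest.approx(hi)

    def test_interval_contains_estimate(self, nhs_fit):
        _, fit = nhs_fit
        stat = group_change_statistic(fit, "prodromal")
        point = stat(fit.params)
        mean, lo, hi = bootstrap_ci(stat, fit, n_draws=500, seed=1)
        assert lo < point < hi
        assert mean == pytest.approx(point, abs=0.5)


class TestSpearman:
    def test_perfect_increasing(self):
        base = {f"s{i}": float(i) for i in range(5)}
        change = {f"s{i}": float(i * 2) for i in range(5)}
        rho, _, _ = spearman_baseline_vs_change(base, change, n_boot=10)
        assert rho == pytest.approx(1.0)

    def test_perfect_decreasing(self):
        base = {f"s{i}": float(i) for i in range(5)}
        change = {f"s{i}": float(-i) for i in range(5)}
        rho, _, _ = spearman_baseline_vs_change(base, change, n_boot=10)
        assert rho == pytest.approx(-1.0)

    def test_rank_formula_oracle(self):
        base = {"a": 1.0, "b": 2.0, "c": 3.0, "d": 4.0}
        change = {"a": 2.0, "b": 1.0, "c": 4.0, "d": 3.0}
        rho, _, _ = spearman_baseline_vs_change(base, change, n_boot=10)
        assert rho == pytest.approx(0.6)

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            spearman_baseline_vs_change({"a": 1.0}, {"a": 2.0})


class TestEvaluateMethods:
    def test_identical_tables_identical_rows(self):
        cohort = generate_cohort(two_group_config(seed=7, n=30, sd=0.02))
        scans, subjects = cohort.scans_frame(), cohort.subjects_frame()
        a = scans.copy()
        b = scans.copy()
        b["method"] = "vc"
        evaluation = evaluate_methods({"none": a, "vc": b}, subjects, ["WCG"],
                                      reference_group="CU")
        rows = evaluation.table.set_index("method")
        assert rows.loc["none", "residual_pct_cv"] == pytest.approx(
            rows.loc["vc", "residual_pct_cv"]
        )
        assert rows.loc["none", "t_score"] == pytest.approx(rows.loc["vc", "t_score"])

    def test_inflated_sigma_increases_cv(self):
        config = two_group_config(seed=8, n=60, sd=0.0)
        low = replace(config, groups={n: replace(g, sd_residual=0.03)
                                      for n, g in config.groups.items()})
        high = replace(config, groups={n: replace(g, sd_residual=0.06)
                                       for n, g in config.groups.items()})
        scans_a = generate_cohort(low).scans_frame()
        scans_b = generate_cohort(high).scans_frame()
        scans_b["method"] = "rbv"
        subjects = generate_cohort(low).subjects_frame()
        evaluation = evaluate_methods({"none": scans_a, "rbv": scans_b}, subjects,
                                      ["WCG"], reference_group="CU")
        rows = evaluation.table.set_index("method")
        assert rows.loc["rbv", "residual_pct_cv"] > rows.loc["none", "residual_pct_cv"]
        dom = evaluation.dominance
        won = dom[(dom.method == "none") & dom.dominates]
        assert len(won) == 1  # lower CV and higher t-score

    def test_significance_flag_matches_threshold(self):
        cohort = generate_cohort(two_group_config(seed=10, n=40, sd=0.02))
        evaluation = evaluate_methods({"none": cohort.scans_frame()},
                                      cohort.subjects_frame(), ["WCG"],
                                      reference_group="CU")
        for _, row in evaluation.table.iterrows():
            assert row["significant"] == (row["t_score"] > 1.96)

    def test_failures_recorded_not_raised(self):
        cohort = generate_cohort(two_group_config(seed=11, n=10, sd=0.02))
        evaluation = evaluate_methods({"none": cohort.scans_frame()},
                                      cohort.subjects_frame(),
                                      ["WCG", "missing_roi"], reference_group="CU")
        assert ("none", "missing_roi") in {(m, r) for m, r, _ in evaluation.failures}
        assert set(evaluation.table["roi"]) == {"WCG"}
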