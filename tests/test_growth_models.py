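"""Multilevel growth models: age centring, fits, LRTs, ICC, the ladder."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from popigt.growth_models import (
    GrowthSpec,
    center_age,
    compare_nested,
    compute_icc,
    fit_growth,
    fit_means_model,
    ladder_table,
    run_trajectory_ladder,
)
from popigt.synthetic_cohort import (
    CohortConfig,
    EffectMap,
    default_effect_maps,
    generate_cohort,
    truth_long_metrics,
)


@pytest.mark.parametrize("age, expected", [
    (10.98, 0.0),
    (17.0, 6.02),
    (9.0, -1.98),
])
def test_center_age(age, expected):
    assert center_age(age) == pytest.approx(expected)


def panel(n_sub=100, waves=5, seed=0, slope=0.2, intercept=0.5,
          subj_sd=0.0, slope_sd=0.0, resid_sd=0.0):
    rng = np.random.default_rng(seed)
    rows = []
    b0 = rng.normal(0, subj_sd, n_sub)
    b1 = rng.normal(0, slope_sd, n_sub)
    for i in range(n_sub):
        base = rng.uniform(-2, 2)
        for w in range(waves):
            age_c = base + 0.75 * w
            y = intercept + slope * age_c + b0[i] + b1[i] * age_c \
                + rng.normal(0, resid_sd)
            rows.append({"subject_id": f"s{i}", "wave": w + 1,
                         "age_c": age_c, "value": y,
                         "maternal_hx": i % 2, "sex": 0, "iq": 100.0,
                         "onsite": 1})
    return pd.DataFrame(rows)


class TestFitGrowth:
    def test_noise_free_linear_data_recovered_exactly(self):
        data = panel(n_sub=40, resid_sd=0.0)
        fit = fit_growth(data, GrowthSpec("linear"))
        assert fit.fixed.loc["const", "coef"] == pytest.approx(0.5, abs=1e-6)
        assert fit.fixed.loc["age", "coef"] == pytest.approx(0.2, abs=1e-6)
        assert fit.tau00 < 1e-6 and fit.tau11 < 1e-6

    def test_variance_components_match_generating_ratio(self):
        # constant value per subject + unit noise: ICC ~ 0.5
        data = panel(n_sub=200, slope=0.0, subj_sd=1.0, resid_sd=1.0, seed=3)
        means = fit_means_model(data)
        icc = compute_icc(means.tau00, means.sigma2)
        assert abs(icc - 0.5) < 0.1

    def test_single_wave_refused(self):
        data = panel(waves=1)
        with pytest.raises(ValueError):
            fit_growth(data, GrowthSpec("linear"))

    def test_slope_ci_covers_truth_at_nominal_rate(self):
        """95% CI coverage of a known age slope across 60 replications."""
        hits = 0
        for rep in range(60):
            data = panel(n_sub=80, slope=0.31, subj_sd=0.5, slope_sd=0.1,
                         resid_sd=0.8, seed=100 + rep)
            fit = fit_growth(data, GrowthSpec("linear"))
            lo, hi = fit.fixed.loc["age", ["ci_lo", "ci_hi"]]
            hits += lo <= 0.31 <= hi
        assert 0.85 <= hits / 60 <= 1.0

    def test_matches_reference_mixed_model_package(self):
        """Dual route: the internal profiled-ML engine must agree with
        statsmodels MixedLM on log-likelihood and coefficients."""
        import warnings

        from statsmodels.regression.mixed_linear_model import MixedLM

        data = panel(n_sub=60, slope=0.3, subj_sd=0.7, slope_sd=0.25,
                     resid_sd=0.6, seed=9)
        fit = fit_growth(data, GrowthSpec("linear"))
        X = np.column_stack((np.ones(len(data)), data["age_c"]))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sm_fit = MixedLM(
                data["value"].to_numpy(), X, groups=data["subject_id"].to_numpy(),
                exog_re=X,
            ).fit(reml=False, method="lbfgs", maxiter=500)
        assert fit.llf == pytest.approx(float(sm_fit.llf), abs=1e-3)
        assert fit.fixed["coef"].to_numpy() == pytest.approx(
            np.asarray(sm_fit.fe_params), abs=1e-4)
        assert fit.sigma2 == pytest.approx(float(sm_fit.scale), rel=1e-3)


class TestCompareNested:
    def test_self_comparison_is_null(self):
        data = panel(n_sub=40, subj_sd=0.5, resid_sd=0.5, seed=1)
        fit = fit_growth(data, GrowthSpec("linear"))
        chi2, df, p = compare_nested(fit, fit)
        assert chi2 == 0.0 and df == 0 and p == 1.0

    def test_printed_worked_example(self):
        assert stats.chi2.sf(38.99, 5) < 0.001

    def test_chi2_equals_bruteforce_refit_difference(self):
        rng = np.random.default_rng(7)
        for rep in range(20):
            data = panel(n_sub=30, slope=float(rng.normal(0, 0.2)),
                         subj_sd=0.5, resid_sd=0.7, seed=200 + rep)
            r = fit_growth(data, GrowthSpec("linear"))
            f = fit_growth(data, GrowthSpec("quadratic"),
                           structure=r.structure, warm_from=r)
            chi2, df, p = compare_nested(r, f)
            assert chi2 == pytest.approx(
                max(0.0, 2.0 * (f.llf - r.llf)), abs=1e-9)
            assert df == 1

    def test_null_rejection_rate_near_alpha(self):
        """With the reduced model true, the quadratic LRT should reject at
        roughly the nominal 5% rate."""
        rejections = 0
        n_reps = 120
        for rep in range(n_reps):
            data = panel(n_sub=40, slope=0.1, subj_sd=0.4, resid_sd=0.6,
                         seed=500 + rep)
            r = fit_growth(data, GrowthSpec("linear"))
            f = fit_growth(data, GrowthSpec("quadratic"),
                           structure=r.structure, warm_from=r)
            _, _, p = compare_nested(r, f)
            rejections += p < 0.05
        assert 0.01 <= rejections / n_reps <= 0.12


class TestICC:
    def test_symmetric_case(self):
        assert compute_icc(1.0, 1.0) == 0.5

    def test_printed_variance_components(self):
        assert compute_icc(1.21, 8.15) == pytest.approx(0.129, abs=5e-4)
        assert round(compute_icc(1.21, 8.15), 2) == 0.13

    def test_zero_between_subject_variance(self):
        assert compute_icc(0.0, 2.0) == 0.0

    def test_degenerate_refused(self):
        with pytest.raises(ValueError):
            compute_icc(0.0, 0.0)


def ladder_input(effect_maps, n=150, seed=0):
    cfg = CohortConfig(n_baseline=n, effect_maps=effect_maps)
    truth = generate_cohort(cfg, seed=seed)
    return truth_long_metrics(truth)


class TestTrajectoryLadder:
    def test_quadratic_curvature_detected_where_generated(self):
        """A cohort generated with clear curvature in the go bias only should
        select quadratic for beta_b in most replications and keep the other
        parameters linear."""
        maps = dict(default_effect_maps())
        maps["beta_b"] = EffectMap(intercept=1.25, age_slope=0.04, quad=0.06,
                                   hx_offset=0.0, subject_sd=0.45, wave_sd=0.4)
        wins = 0
        for rep in range(10):
            ladders = run_trajectory_ladder(ladder_input(maps, seed=rep))
            wins += ladders["beta_b"].winner == "quadratic"
        assert wins >= 8

    def test_linear_truth_mostly_keeps_linear(self):
        # all-linear trajectories: no quadratic terms, and constant
        # administration modality (the waves-4/5 remote shift would
        # otherwise bend the unconditional age profiles)
        maps = {k: EffectMap(**{**v.__dict__, "quad": 0.0})
                for k, v in default_effect_maps().items()}
        linear_counts = []
        for rep in range(5):
            cfg = CohortConfig(n_baseline=150, effect_maps=maps,
                               onsite_probs=(1.0,) * 5)
            truth = generate_cohort(cfg, seed=50 + rep)
            ladders = run_trajectory_ladder(truth_long_metrics(truth))
            linear_counts.append(
                sum(lad.winner == "linear" for lad in ladders.values()))
        # the truth table carries the four computational metrics; nearly all
        # selections should stay linear on average
        assert np.mean(linear_counts) >= 3.5

    def test_report_table_schema(self):
        ladders = run_trajectory_ladder(ladder_input(default_effect_maps(),
                                                     n=80, seed=3))
        table = ladder_table(ladders)
        fixed = table[table["row_type"] == "fixed"]
        for metric, lad in ladders.items():
            terms = fixed.loc[fixed["metric"] == metric, "term"].tolist()
            assert terms == list(lad.model4.fixed.index)
            for col in ("estimate", "se", "t", "p", "ci_lo", "ci_hi"):
                assert col in fixed.columns
        summary_terms = set(table.loc[table["row_type"] == "summary", "term"])
        assert {"sigma2", "tau00", "tau11", "icc", "pseudo_r2_total",
                "lrt_chi2"} <= summary_terms

    def test_missing_metric_skipped(self):
        long_df = ladder_input(default_effect_maps(), n=60, seed=1)
        long_df = long_df[long_df["metric_name"] != "beta_b"]
        ladders = run_trajectory_ladder(long_df)
        assert "beta_b" not in ladders
        assert "beta_f" in ladders

    def test_fdr_family_is_the_four_parameters(self):
        ladders = run_trajectory_ladder(ladder_input(default_effect_maps(),
                                                     n=80, seed=2))
        comp = [m for m in ("A_rew_z", "A_pun_z", "beta_f", "beta_b")
                if m in ladders]
        for m in comp:
            assert ladders[m].age_fdr >= ladders[m].age_p - 1e-12


class TestAttritionRobustness:
    def test_missing_at_random_leaves_slope_unbiased(self):
        ests = []
        for rep in range(40):
            data = panel(n_sub=60, slope=0.2, subj_sd=0.5, resid_sd=0.6,
                         seed=900 + rep)
            rng = np.random.default_rng(rep)
            keep = rng.random(len(data)) < 0.7
            fit = fit_growth(data[keep], GrowthSpec("linear"))
            ests.append(fit.fixed.loc["age", "coef"])
        bias = np.mean(ests) - 0.2
        mc_se = np.std(ests) / np.sqrt(len(ests))
        assert abs(bias) < 3 * mc_se + 1e-3
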