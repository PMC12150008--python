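import logging

import numpy as np
import pandas as pd
import pytest

from ncctrials.design import analysis_window, build_design, plan_recruitment
from ncctrials.models import (
    ModelSpec,
    build_spline_basis,
    fit_fixed,
    fit_mixed,
    fit_mixed_interaction,
    fit_model,
    fit_spline,
    interaction_columns,
    parse_model_spec,
    t_test,
)
from ncctrials.simulate import GenerativeParams, TimeTrendSpec, simulate_trial
from ncctrials.study import run_scenario, Scenario

from conftest import make_window


def _design_matrix_oracle(window, adjustment="period"):
    """Independent indicator-matrix construction (normal-equations route)."""
    df = window.df
    arms = [k for k in sorted(df["arm"].unique()) if k != 0]
    cols = {"intercept": np.ones(len(df))}
    for k in arms:
        cols[f"theta_{k}"] = (df["arm"] == k).astype(float).to_numpy()
    lab = df[adjustment].to_numpy()
    for lv in range(2, lab.max() + 1):
        cols[f"tau_{lv}"] = (lab == lv).astype(float)
    return np.column_stack(list(cols.values())), list(cols)


class TestFitFixed:
    def test_matches_normal_equations_oracle(self, window_k4):
        w = window_k4(seed=21)
        for adjustment in ("period", "calendar"):
            res = fit_fixed(w, adjustment)
            X, names = _design_matrix_oracle(w, adjustment)
            beta = np.linalg.pinv(X.T @ X) @ X.T @ w.df["y"].to_numpy()
            oracle = dict(zip(names, beta))
            assert set(res.coefficients) == set(oracle)
            for nm, v in oracle.items():
                assert res.coefficients[nm] == pytest.approx(v, abs=1e-8)

    def test_single_period_equals_raw_mean_difference(self):
        design = build_design(3, 0, 80)
        plan = plan_recruitment(design)
        data = simulate_trial(design, GenerativeParams.null(3), None, 2, plan)
        w = analysis_window(data, plan, 2)
        res = fit_fixed(w, "period")
        df = w.df
        raw = df.loc[df["arm"] == 2, "y"].mean() - df.loc[df["arm"] == 0, "y"].mean()
        assert res.theta_hat_M == pytest.approx(raw, abs=1e-10)

    def test_rejection_consistent_with_alpha(self, window_k4):
        res = fit_fixed(window_k4(seed=3, theta=(0, 0, 0.6, 0)))
        assert res.reject == (res.p_one_sided <= res.alpha)
        assert res.se > 0
        assert res.n_used == 1389

    def test_aliased_time_column_dropped_and_flagged(self, caplog):
        # period 2 contains only arm-2 patients: tau_2 is aliased with theta_2
        df = pd.DataFrame(
            {
                "j": range(1, 9),
                "t": range(1, 9),
                "arm": [0, 1, 0, 1, 2, 2, 2, 2],
                "y": [0.1, 1.2, -0.3, 0.9, 2.0, 2.2, 1.8, 2.1],
                "period": [1, 1, 1, 1, 2, 2, 2, 2],
                "calendar": [1] * 8,
            }
        )
        w = make_window(df, M=1, t_entry=1, t_exit=8)
        with caplog.at_level(logging.WARNING):
            res = fit_fixed(w, "period")
        assert res.dropped_columns == ("tau_2",)
        assert "tau_2" in caplog.text


def test_calendar_equals_period_when_grids_align(design_k10, plan_k10):
    # every period has length 500, so clength=500 reproduces the period cut
    data = simulate_trial(
        design_k10,
        GenerativeParams.null(10),
        TimeTrendSpec.equal("seasonal", 0.4, 10, plan_k10.N),
        seed=17,
        plan=plan_k10,
    )
    w = analysis_window(data, plan_k10, 5)
    by_period = fit_fixed(w, "period")
    by_calendar = fit_fixed(w, "calendar", clength=500)
    assert by_calendar.theta_hat_M == pytest.approx(by_period.theta_hat_M, abs=1e-10)
    assert by_calendar.se == pytest.approx(by_period.se, abs=1e-10)


class TestSplineBasis:
    def test_partition_of_unity(self, window_k4):
        w = window_k4(seed=2)
        t = w.df["t"].to_numpy()
        for q in (1, 2, 3):
            basis = build_spline_basis(t, "equidistant_calendar", q, clength=100)
            np.testing.assert_allclose(basis.matrix.sum(axis=1), 1.0, atol=1e-12)

    def test_no_inner_knots_degree1_is_affine(self):
        t = np.arange(1.0, 51.0)
        basis = build_spline_basis(t, "period_starts", 1, period_map=[])
        assert basis.matrix.shape[1] == 2
        # spans {1, t}: both columns affine in t
        for col in basis.matrix.T:
            slope = np.diff(col)
            np.testing.assert_allclose(slope, slope[0], atol=1e-12)

    def test_k10_window_knots_truncated(self, plan_k10, design_k10):
        data = simulate_trial(
            design_k10, GenerativeParams.null(10), None, 1, plan_k10
        )
        w = analysis_window(data, plan_k10, 5)
        t = w.df["t"].to_numpy()
        basis = build_spline_basis(
            t, "period_starts", 3, period_map=plan_k10.boundaries
        )
        assert basis.inner_knots == (500.0, 1000.0, 1500.0, 2000.0)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="distinct time values"):
            build_spline_basis([1.0, 2.0, 3.0], "period_starts", 3, period_map=[])

    def test_out_of_range_knots_dropped(self, caplog):
        t = np.arange(1.0, 21.0)
        with caplog.at_level(logging.WARNING):
            basis = build_spline_basis(t, "period_starts", 2, period_map=[5, 40])
        assert basis.inner_knots == (5.0,)
        assert "dropped 1 inner knots" in caplog.text


class TestFitSpline:
    def test_degree1_period_knots_recover_effect_exactly(self, design_k4, plan_k4):
        # piecewise-linear trend with breaks at period starts lies in the
        # q=1 span, so at sigma -> 0 the effect is recovered exactly
        trend = TimeTrendSpec.equal("linear", 0.5, 4, plan_k4.N)
        data = simulate_trial(
            design_k4,
            GenerativeParams(theta=(0, 0, 0.25, 0), sigma=1e-8),
            trend,
            seed=31,
            plan=plan_k4,
        )
        w = analysis_window(data, plan_k4, 3)
        res = fit_spline(w, "period_starts", q=1)
        assert res.theta_hat_M == pytest.approx(0.25, abs=1e-6)

    def test_matches_least_squares_oracle(self, window_k4):
        w = window_k4(seed=13)
        res = fit_spline(w, "period_starts", q=3)
        # oracle: rebuild the same matrix independently and solve
        t = w.df["t"].to_numpy()
        per = w.df["period"].to_numpy()
        starts = [t[per == s].min() - 1 for s in range(2, per.max() + 1)]
        basis = build_spline_basis(t, "period_starts", 3, period_map=starts)
        Xa, names = _design_matrix_oracle(w)
        X = np.column_stack([Xa[:, :5], basis.matrix[:, 1:]])
        beta = np.linalg.pinv(X.T @ X) @ X.T @ w.df["y"].to_numpy()
        assert res.theta_hat_M == pytest.approx(beta[3], abs=1e-8)

    def test_label_and_dispatch(self, window_k4):
        w = window_k4(seed=1)
        spec = parse_model_spec("spline-calendar-q2")
        res = fit_model(w, spec)
        assert res.model == "spline-calendar-q2"


class TestFitMixed:
    def test_ar1_fixed_at_zero_matches_iid(self, window_k4):
        w = window_k4(seed=7)
        iid = fit_mixed(w, "period", "iid")
        ar0 = fit_mixed(w, "period", "ar1", fix_rho=0.0)
        assert ar0.variance_components["neg2_reml"] == pytest.approx(
            iid.variance_components["neg2_reml"], abs=1e-6
        )

    def test_boundary_variance_matches_pooled_estimate(self, window_k4):
        # pick a seed whose REML variance lands on the zero boundary
        for seed in range(40):
            w = window_k4(seed=seed, lam=0.0)
            res = fit_mixed(w, "period", "iid")
            if res.variance_components["sigma2_period"] < 1e-8:
                pooled = t_test(w, "pooled")
                assert res.theta_hat_M == pytest.approx(
                    pooled.theta_hat_M, abs=1e-4
                )
                return
        pytest.fail("no boundary fit found in 40 seeds")

    def test_single_time_level_rejected(self):
        design = build_design(2, 0, 60)
        plan = plan_recruitment(design)
        data = simulate_trial(design, GenerativeParams.null(2), None, 3, plan)
        w = analysis_window(data, plan, 2)
        with pytest.raises(ValueError, match="fit_fixed"):
            fit_mixed(w, "period", "iid")

    def test_reports_variance_components(self, window_k4):
        res = fit_mixed(window_k4(seed=4), "calendar", "ar1")
        vc = res.variance_components
        assert vc["sigma2"] > 0
        assert vc["sigma2_calendar"] >= 0
        assert abs(vc["rho"]) < 1


class TestFitMixedInteraction:
    def test_no_interaction_column_for_evaluated_arm(self, window_k4):
        w = window_k4(seed=5)
        labels = w.df["period"].to_numpy()
        _, names = interaction_columns(w, labels)
        assert names  # arms 1, 2, 4 are present
        assert not any(nm.startswith(f"u_{w.M}_") for nm in names)

    def test_fallback_without_other_arms(self, caplog):
        design = build_design(1, 0, 60)
        plan = plan_recruitment(design)
        data = simulate_trial(design, GenerativeParams.null(1), None, 3, plan)
        w = analysis_window(data, plan, 1)
        with caplog.at_level(logging.WARNING):
            res = fit_mixed_interaction(w, "period")
        assert res.model == "fixed-period"
        assert "falling back" in caplog.text

    def test_shrunk_to_zero_recovers_fixed_fit(self, window_k4):
        for seed in range(40):
            w = window_k4(seed=seed, lam=0.0)
            res = fit_mixed_interaction(w, "period")
            if res.variance_components["sigma2_arm_period"] < 1e-8:
                fixed = fit_fixed(w, "period")
                assert res.theta_hat_M == pytest.approx(
                    fixed.theta_hat_M, abs=1e-4
                )
                return
        pytest.fail("no boundary fit found in 40 seeds")


class TestTTest:
    def test_identical_groups_give_half(self):
        df = pd.DataFrame(
            {
                "j": range(1, 9),
                "t": range(1, 9),
                "arm": [0, 1, 0, 1, 0, 1, 0, 1],
                "y": [1.0, 1.0, 2.0, 2.0, 3.0, 3.0, 4.0, 4.0],
                "period": [1] * 8,
                "calendar": [1] * 8,
            }
        )
        w = make_window(df, M=1, t_entry=1, t_exit=8)
        res = t_test(w, "separate")
        assert res.theta_hat_M == pytest.approx(0.0)
        assert res.p_one_sided == pytest.approx(0.5)

    def test_pooled_uses_all_controls_separate_only_concurrent(self, window_k4):
        w = window_k4(seed=9)
        pooled = t_test(w, "pooled")
        separate = t_test(w, "separate")
        n_ctrl_all = (w.df["arm"] == 0).sum()
        conc = w.df[(w.df["arm"] == 0) & (w.df["t"] >= w.t_entry)]
        n_M = (w.df["arm"] == w.M).sum()
        assert pooled.n_used == n_ctrl_all + n_M
        assert separate.n_used == len(conc) + n_M
        assert separate.n_used < pooled.n_used

    def test_matches_scipy(self, window_k4):
        from scipy import stats

        w = window_k4(seed=10)
        res = t_test(w, "pooled")
        xm = w.df.loc[w.df["arm"] == w.M, "y"]
        xc = w.df.loc[w.df["arm"] == 0, "y"]
        ref = stats.ttest_ind(xm, xc, equal_var=True, alternative="greater")
        assert res.p_one_sided == pytest.approx(ref.pvalue, abs=1e-12)

    def test_tiny_group_rejected(self):
        df = pd.DataFrame(
            {
                "j": [1, 2, 3],
                "t": [1, 2, 3],
                "arm": [0, 0, 1],
                "y": [0.0, 1.0, 2.0],
                "period": [1] * 3,
                "calendar": [1] * 3,
            }
        )
        w = make_window(df, M=1, t_entry=1, t_exit=3)
        with pytest.raises(ValueError, match=">= 2 observations"):
            t_test(w, "pooled")

    def test_unknown_mode(self, window_k4):
        with pytest.raises(ValueError, match="mode"):
            t_test(window_k4(seed=1), "welter")


def test_fixed_model_unbiased_pooled_ttest_biased_under_stepwise_trend(
    design_k4,
):
    """Under a strong stepwise trend the period-adjusted model is unbiased
    while naive pooling of non-concurrent controls is not."""
    res = {
        oc.model: oc
        for oc in run_scenario(
            Scenario(
                name="bias",
                design=design_k4,
                M=3,
                theta=(0.0,) * 4,
                pattern="stepwise",
                lam=(0.5,) * 5,
            ),
            [parse_model_spec("fixed-period"), parse_model_spec("ttest-pooled")],
            n_reps=300,
            master_seed=77,
        )
    }
    fixed = res["fixed-period"]
    pooled = res["ttest-pooled"]
    mc_se = fixed.empirical_se / np.sqrt(fixed.n_used)
    assert abs(fixed.mean_bias) < 3 * mc_se
    assert abs(pooled.mean_bias) > 10 * mc_se


class TestModelSpec:
    @pytest.mark.parametrize(
        "label",
        [
            "fixed-period",
            "fixed-calendar",
            "spline-period-q1",
            "spline-calendar-q3",
            "mixed-period-iid",
            "mixed-calendar-ar1",
            "interaction-period",
            "ttest-pooled",
            "ttest-separate",
        ],
    )
    def test_parse_round_trip(self, label):
        assert parse_model_spec(label).label == label

    @pytest.mark.parametrize(
        "bad", ["fixed", "spline-period-q4", "mixed-period", "ttest-both", "xyz"]
    )
    def test_bad_labels_rejected(self, bad):
        with pytest.raises(ValueError):
            parse_model_spec(bad)

    def test_validation(self):
        with pytest.raises(ValueError, match="alpha"):
            ModelSpec(family="fixed", alpha=1.5)
        with pytest.raises(ValueError, match="degree"):
            ModelSpec(family="spline", degree=4)
        with pytest.raises(ValueError, match="family"):
            ModelSpec(family="anova")
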