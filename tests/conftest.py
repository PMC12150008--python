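import numpy as np
import pandas as pd
import pytest

from ncctrials import (
    GenerativeParams,
    Scenario,
    TimeTrendSpec,
    analysis_window,
    build_design,
    plan_recruitment,
    simulate_trial,
)
from ncctrials.design import AnalysisWindow
from ncctrials.models import parse_model_spec
from ncctrials.study import run_scenario


@pytest.fixture(scope="session")
def design_k4():
    return build_design(4, 250, 250, clength=100)


@pytest.fixture(scope="session")
def plan_k4(design_k4):
    return plan_recruitment(design_k4)


@pytest.fixture(scope="session")
def design_k10():
    return build_design(10, 500, 250, clength=450)


@pytest.fixture(scope="session")
def plan_k10(design_k10):
    return plan_recruitment(design_k10)


@pytest.fixture(scope="session")
def small_design():
    # compact trial used for Monte-Carlo property tests
    return build_design(3, 100, 100, clength=50)


@pytest.fixture(scope="session")
def small_plan(small_design):
    return plan_recruitment(small_design)


@pytest.fixture
def window_k4(design_k4, plan_k4):
    """Factory: analysis window for arm 3 of the K=4 trial."""

    def make(seed=11, lam=0.5, pattern="linear", theta=(0.0, 0.0, 0.0, 0.0), sigma=1.0):
        trend = (
            TimeTrendSpec.equal(pattern, lam, 4, plan_k4.N)
            if pattern is not None
            else None
        )
        data = simulate_trial(
            design_k4,
            GenerativeParams(theta=tuple(theta), sigma=sigma),
            trend,
            seed,
            plan=plan_k4,
        )
        return analysis_window(data, plan_k4, 3)

    return make


def make_window(df: pd.DataFrame, M: int, t_entry: int, t_exit: int) -> AnalysisWindow:
    """Hand-built window for unit tests on small explicit datasets."""
    K_M = tuple(sorted(df["arm"].unique()))
    return AnalysisWindow(
        df=df.reset_index(drop=True),
        M=M,
        t_entry=t_entry,
        t_exit=t_exit,
        K_M=K_M,
        S_M=int(df["period"].max()),
        C_M=int(df["calendar"].max()),
        clength=100,
    )


# --- session-scoped Monte-Carlo runs shared by acceptance and property tests

NULL_CALIBRATION_MODELS = (
    "fixed-period",
    "fixed-calendar",
    "spline-period-q3",
    "spline-calendar-q1",
    "mixed-period-iid",
    "mixed-period-ar1",
    "interaction-period",
    "ttest-pooled",
    "ttest-separate",
)


@pytest.fixture(scope="session")
def null_calibration(small_design):
    """Rejection rates of one representative per model family under
    lambda = 0, theta = 0 (correctly specified null), R = 4000."""
    scenario = Scenario(
        name="null-calibration",
        design=small_design,
        M=2,
        theta=(0.0, 0.0, 0.0),
        pattern="linear",
        lam=(0.0, 0.0, 0.0, 0.0),
    )
    models = [parse_model_spec(lbl) for lbl in NULL_CALIBRATION_MODELS]
    results = run_scenario(scenario, models, n_reps=4000, master_seed=20260903)
    return {oc.model: oc for oc in results}


def rejection_rate(design, M, pattern, lam_vec, theta, n_reps, seed, labels, **kw):
    """Convenience wrapper returning {model label: OperatingCharacteristics}."""
    scenario = Scenario(
        name="prop",
        design=design,
        M=M,
        theta=theta,
        pattern=pattern,
        lam=lam_vec,
        **kw,
    )
    models = [parse_model_spec(lbl) for lbl in labels]
    return {oc.model: oc for oc in run_scenario(scenario, models, n_reps, seed)}
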