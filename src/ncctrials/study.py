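"""Monte-Carlo operating characteristics: type I error, power, bias and
Monte-Carlo error of the analysis models over replicated simulated trials.

Every replicate draws its generator from ``SeedSequence(master, spawn_key=(r,))``,
so results are independent of evaluation order and any single replicate can
be reproduced in isolation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .design import PlatformDesign, analysis_window, plan_recruitment
from .models import FitResult, ModelSpec
from .simulate import (
    GenerativeParams,
    TimeTrendSpec,
    replicate_seed,
    simulate_trial,
)

__all__ = ["Scenario", "OperatingCharacteristics", "run_scenario", "summarize"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Scenario:
    """One fully specified cell of a simulation grid."""

    name: str
    design: PlatformDesign
    M: int
    theta: tuple[float, ...]  # true effects theta_1..theta_K
    pattern: str | None = None  # None -> no time trend
    lam: tuple[float, ...] = ()  # strengths lambda_0..lambda_K
    Np: int | None = None
    psi: float = 1.0
    eta0: float = 0.0
    sigma: float = 1.0
    alpha: float = 0.025

    def __post_init__(self) -> None:
        K = self.design.K
        if not 1 <= self.M <= K:
            raise ValueError(f"evaluated arm M={self.M} outside 1..{K}")
        if len(self.theta) != K:
            raise ValueError(f"theta needs K={K} entries, got {len(self.theta)}")
        if self.pattern is not None and len(self.lam) != K + 1:
            raise ValueError(f"lam needs K+1={K + 1} entries, got {len(self.lam)}")

    @property
    def theta_M(self) -> float:
        return self.theta[self.M - 1]

    def under_null(self) -> "Scenario":
        """Same scenario with every treatment effect set to zero."""
        return replace(self, theta=(0.0,) * self.design.K)


@dataclass(frozen=True)
class OperatingCharacteristics:
    """Aggregated per-model results over the replicates of one scenario."""

    scenario: str
    model: str
    n_reps: int
    n_used: int  # converged, error-free replicates
    rejection_rate: float
    mc_se: float  # binomial sqrt(p(1-p)/n_used)
    mean_bias: float  # mean(theta_hat) - true theta_M
    empirical_se: float  # sd of theta_hat over replicates
    mean_model_se: float
    convergence_rate: float

    def to_row(self) -> dict[str, object]:
        return {
            "scenario": self.scenario,
            "model": self.model,
            "n_reps": self.n_reps,
            "n_used": self.n_used,
            "rejection_rate": self.rejection_rate,
            "mc_se": self.mc_se,
            "mean_bias": self.mean_bias,
            "empirical_se": self.empirical_se,
            "mean_model_se": self.mean_model_se,
            "convergence_rate": self.convergence_rate,
        }


def _replicate(scenario: Scenario, models: Sequence[ModelSpec], plan, trend, seed):
    data = simulate_trial(scenario.design, _params(scenario), trend, seed, plan=plan)
    window = analysis_window(data, plan, scenario.M)
    out = []
    for spec in models:
        try:
            fit: FitResult = spec.fit(window)
            out.append((fit.reject, fit.theta_hat_M, fit.se, fit.converged))
        except Exception as exc:  # noqa: BLE001 - a failed fit is a recorded outcome
            log.warning("model %s failed in a replicate: %s", spec.label, exc)
            out.append((False, np.nan, np.nan, False))
    return out


def _params(scenario: Scenario) -> GenerativeParams:
    return GenerativeParams(
        eta0=scenario.eta0, theta=scenario.theta, sigma=scenario.sigma
    )


def _trend(scenario: Scenario, N: int) -> TimeTrendSpec | None:
    if scenario.pattern is None:
        return None
    return TimeTrendSpec(
        pattern=scenario.pattern,
        lam=scenario.lam,
        N=N,
        Np=scenario.Np,
        psi=scenario.psi,
    )


def run_scenario(
    scenario: Scenario,
    models: Sequence[ModelSpec],
    n_reps: int,
    master_seed: int,
    n_jobs: int = 1,
) -> list[OperatingCharacteristics]:
    """Simulate ``n_reps`` trials and fit every model to each.

    Replicates failing to fit (or flagged non-converged) are excluded from
    both numerator and denominator of the rejection rate and show up in the
    convergence rate instead.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    models = [replace(m, alpha=scenario.alpha) for m in models]
    plan = plan_recruitment(scenario.design)
    trend = _trend(scenario, plan.N)
    seeds = [replicate_seed(master_seed, r) for r in range(n_reps)]
    if n_jobs > 1:
        from joblib import Parallel, delayed

        rows = Parallel(n_jobs=n_jobs, batch_size="auto")(
            delayed(_replicate)(scenario, models, plan, trend, s) for s in seeds
        )
    else:
        rows = [_replicate(scenario, models, plan, trend, s) for s in seeds]

    out = []
    for i, spec in enumerate(models):
        rec = np.array([r[i] for r in rows], dtype=float)  # reject, theta, se, conv
        ok = rec[:, 3] > 0.5
        n_used = int(ok.sum())
        if n_used == 0:
            raise RuntimeError(f"model {spec.label} failed in every replicate")
        rate = float(rec[ok, 0].mean())
        out.append(
            OperatingCharacteristics(
                scenario=scenario.name,
                model=spec.label,
                n_reps=n_reps,
                n_used=n_used,
                rejection_rate=rate,
                mc_se=float(np.sqrt(rate * (1.0 - rate) / n_used)),
                mean_bias=float(rec[ok, 1].mean() - scenario.theta_M),
                empirical_se=float(rec[ok, 1].std(ddof=1)) if n_used > 1 else np.nan,
                mean_model_se=float(rec[ok, 2].mean()),
                convergence_rate=n_used / n_reps,
            )
        )
    return out


def summarize(results: Iterable[OperatingCharacteristics]) -> pd.DataFrame:
    """Long-format study table, one row per (scenario, model)."""
    rows = [oc.to_row() for oc in results]
    if not rows:
        raise ValueError("no results to summarize")
    return pd.DataFrame(rows)


def plot_summary(table: pd.DataFrame, path: str, alpha: float = 0.025) -> None:
    """Rejection rate per scenario, one line per model, with the nominal
    level as reference (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(1.2 + 1.1 * table["scenario"].nunique(), 4.5))
    for model, sub in table.groupby("model"):
        ax.errorbar(
            sub["scenario"],
            sub["rejection_rate"],
            yerr=sub["mc_se"],
            marker="o",
            capsize=3,
            label=model,
        )
    ax.axhline(alpha, ls="--", c="gray", lw=1)
    ax.set_ylabel("rejection rate")
    ax.tick_params(axis="x", rotation=45)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
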