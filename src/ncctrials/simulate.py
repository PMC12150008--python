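"""Patient-level data generation: block randomization and time-trend injection.

Outcomes are Gaussian, ``y_j = eta0 + theta_k + f(j) + eps_j`` with
``eps_j ~ N(0, sigma^2)``; the drift ``f(j)`` follows one of four patterns
(linear, stepwise, inverted-U, seasonal) with a per-arm strength ``lambda_k``.
Allocation uses permuted blocks of size ``2 * (n_active_arms + 1)`` within
each period of the recruitment plan.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .design import (
    PlatformDesign,
    RecruitmentPlan,
    assign_calendar,
    assign_periods,
    plan_recruitment,
)

__all__ = [
    "TREND_PATTERNS",
    "TimeTrendSpec",
    "GenerativeParams",
    "TrialData",
    "trend_value",
    "trend_profile",
    "block_randomize",
    "simulate_trial",
    "replicate_seed",
]

TREND_PATTERNS = ("linear", "stepwise", "inverted_u", "seasonal")

#: column order of the on-disk TrialData format
TRIAL_COLUMNS = ("j", "t", "arm", "y", "period", "calendar")


@dataclass(frozen=True)
class TimeTrendSpec:
    """Pattern and per-arm strengths of the mean drift over recruitment time.

    ``lam[k]`` is the strength for arm ``k`` (index 0 = control).  ``N`` is
    the total trial size the drift is scaled to; ``Np`` the turning point of
    the inverted-U pattern; ``psi`` the number of seasonal cycles.
    """

    pattern: str
    lam: tuple[float, ...]
    N: int
    Np: int | None = None
    psi: float = 1.0

    def __post_init__(self) -> None:
        if self.pattern not in TREND_PATTERNS:
            raise ValueError(
                f"unknown trend pattern {self.pattern!r}; expected one of {TREND_PATTERNS}"
            )
        if not all(np.isfinite(self.lam)):
            raise ValueError("trend strengths must be finite")
        if self.psi <= 0:
            raise ValueError(f"psi must be > 0, got {self.psi}")
        if self.pattern == "inverted_u":
            if self.Np is None:
                object.__setattr__(self, "Np", self.N // 2)
            if not 1 <= self.Np <= self.N:
                raise ValueError(f"Np={self.Np} outside 1..N={self.N}")

    @classmethod
    def equal(
        cls, pattern: str, lam: float, K: int, N: int, Np: int | None = None, psi: float = 1.0
    ) -> "TimeTrendSpec":
        """Equal strength ``lam`` in the control and all ``K`` experimental arms."""
        return cls(pattern=pattern, lam=(lam,) * (K + 1), N=N, Np=Np, psi=psi)


@dataclass(frozen=True)
class GenerativeParams:
    """Control mean, treatment effects and residual scale of the outcome model."""

    eta0: float = 0.0
    theta: tuple[float, ...] = ()
    sigma: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")

    @classmethod
    def null(cls, K: int, eta0: float = 0.0, sigma: float = 1.0) -> "GenerativeParams":
        return cls(eta0=eta0, theta=(0.0,) * K, sigma=sigma)

    @classmethod
    def single_effect(
        cls, K: int, M: int, theta_M: float, eta0: float = 0.0, sigma: float = 1.0
    ) -> "GenerativeParams":
        """All effects zero except ``theta_M`` for arm ``M``."""
        theta = [0.0] * K
        theta[M - 1] = theta_M
        return cls(eta0=eta0, theta=tuple(theta), sigma=sigma)


def trend_profile(
    spec: TimeTrendSpec, t: np.ndarray, lam: np.ndarray, entered: np.ndarray | None = None
) -> np.ndarray:
    """Vectorized drift ``f(t)`` for recruitment times ``t`` with per-patient
    strengths ``lam``; ``entered`` counts arms already entered (stepwise only)."""
    t = np.asarray(t, dtype=float)
    N = spec.N
    if spec.pattern == "linear":
        return lam * (t - 1.0) / (N - 1.0)
    if spec.pattern == "inverted_u":
        Np = spec.Np
        rising = lam * (t - 1.0) / (N - 1.0)
        falling = -lam * (t - Np) / (N - 1.0) + lam * (Np - 1.0) / (N - 1.0)
        return np.where(t <= Np, rising, falling)
    if spec.pattern == "seasonal":
        return lam * np.sin(spec.psi * 2.0 * np.pi * (t - 1.0) / (N - 1.0))
    # stepwise
    if entered is None:
        raise ValueError("stepwise trend requires the entered-arm counts")
    return lam * (np.asarray(entered) - 1.0)


def trend_value(spec: TimeTrendSpec, j: int, arm: int, i_j: int | None = None) -> float:
    """Drift ``f(j)`` for a single patient on ``arm``.

    ``i_j`` — the number of experimental arms that had entered the trial by
    the time patient ``j`` was enrolled — is only required for the stepwise
    pattern.
    """
    if not 1 <= j <= spec.N:
        raise ValueError(f"patient index {j} outside 1..{spec.N}")
    lam = np.asarray([spec.lam[arm]])
    entered = None if i_j is None else np.asarray([i_j])
    return float(trend_profile(spec, np.asarray([j]), lam, entered)[0])


def block_randomize(
    active_arms: Sequence[int], n_patients: int, rng: np.random.Generator
) -> np.ndarray:
    """Permuted-block assignment sequence over ``active_arms`` (control included).

    Each complete block is a uniform random permutation of two copies of every
    active arm; a trailing incomplete block draws without replacement from one
    fresh permuted block.
    """
    arms = np.asarray(sorted(set(active_arms)), dtype=int)
    if arms.size == 0:
        raise ValueError("active arm set is empty")
    base = np.repeat(arms, 2)
    bsize = base.size
    n_complete, rem = divmod(n_patients, bsize)
    n_blocks = n_complete + (1 if rem else 0)
    if n_blocks == 0:
        return np.empty(0, dtype=int)
    blocks = rng.permuted(np.tile(base, (n_blocks, 1)), axis=1)
    seq = blocks[:n_complete].ravel()
    if rem:
        seq = np.concatenate([seq, blocks[n_complete, :rem]])
    return seq


@dataclass(frozen=True)
class TrialData:
    """Patient-level trial records with period and calendar labels attached."""

    df: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in TRIAL_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"TrialData missing columns {missing}")

    @property
    def N(self) -> int:
        return len(self.df)

    def write_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False, columns=list(TRIAL_COLUMNS))

    @classmethod
    def read_csv(cls, path: str | Path) -> "TrialData":
        df = pd.read_csv(path)
        if "j" not in df.columns and "t" in df.columns:
            df["j"] = df["t"]
        return cls(df=df[list(TRIAL_COLUMNS)])


def entered_counts(design: PlatformDesign, t: np.ndarray) -> np.ndarray:
    """Number of experimental arms entered strictly before time ``t`` elapsed
    (i.e. with ``d_k < t``), for each recruitment time in ``t``."""
    sched = np.sort(np.asarray(design.entry_schedule))
    return np.searchsorted(sched, np.asarray(t), side="left")


def simulate_trial(
    design: PlatformDesign,
    params: GenerativeParams,
    trend: TimeTrendSpec | None,
    seed: int | np.random.SeedSequence | np.random.Generator,
    plan: RecruitmentPlan | None = None,
) -> TrialData:
    """Simulate one platform trial.

    One patient is recruited per time unit; within each plan period patients
    are assigned by permuted blocks over the open arms plus control.  Passing
    ``trend=None`` disables the drift.
    """
    if plan is None:
        plan = plan_recruitment(design)
    if len(params.theta) != design.K:
        raise ValueError(
            f"theta has {len(params.theta)} entries, expected K={design.K}"
        )
    if trend is not None:
        if len(trend.lam) != design.K + 1:
            raise ValueError(
                f"trend.lam has {len(trend.lam)} entries, expected K+1={design.K + 1}"
            )
        if trend.N != plan.N:
            raise ValueError(f"trend.N={trend.N} does not match planned N={plan.N}")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    arm = np.concatenate(
        [
            block_randomize((0, *p.active_arms), p.length, rng)
            for p in plan.periods
        ]
    )
    N = plan.N
    t = np.arange(1, N + 1)
    theta = np.concatenate([[0.0], np.asarray(params.theta, dtype=float)])
    mu = params.eta0 + theta[arm]
    if trend is not None:
        lam = np.asarray(trend.lam, dtype=float)[arm]
        mu = mu + trend_profile(trend, t, lam, entered_counts(design, t))
    y = mu + rng.normal(0.0, params.sigma, size=N)
    df = pd.DataFrame(
        {
            "j": t,
            "t": t,
            "arm": arm,
            "y": y,
            "period": assign_periods(plan).labels(t),
            "calendar": assign_calendar(N, design.clength).labels(t),
        }
    )
    return TrialData(df=df)


def replicate_seed(master_seed: int, replicate: int) -> np.random.SeedSequence:
    """Independent, order-free seed stream for one replicate of a study."""
    return np.random.SeedSequence(master_seed, spawn_key=(replicate,))
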