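"""Analysis models for an evaluated arm: fixed-effect time adjustment
(period or calendar), B-spline time adjustment, mixed models with iid or
AR(1) random time effects, mixed models with a random treatment-by-time
interaction, and pooled/separate t-test comparators.

All models test the one-sided null ``H0: theta_M <= 0`` and reject when the
upper-tail p-value is at most ``alpha``.  Ordinary-least-squares models use
the t distribution with residual degrees of freedom; mixed models use the
normal approximation to the Wald statistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.interpolate import BSpline

from .design import AnalysisWindow
from .lmm import reml_fit

__all__ = [
    "FAMILIES",
    "ADJUSTMENTS",
    "ModelSpec",
    "FitResult",
    "SplineBasis",
    "build_spline_basis",
    "fit_fixed",
    "fit_spline",
    "fit_mixed",
    "fit_mixed_interaction",
    "t_test",
    "fit_model",
    "parse_model_spec",
]

log = logging.getLogger(__name__)

FAMILIES = (
    "fixed",
    "spline",
    "mixed",
    "mixed_interaction",
    "ttest_pooled",
    "ttest_separate",
)
ADJUSTMENTS = ("period", "calendar")
KNOT_STRATEGIES = ("period_starts", "equidistant_calendar")

_RANK_TOL = 1e-8


@dataclass(frozen=True)
class FitResult:
    """One-sided inference on ``theta_M`` plus the full coefficient set."""

    model: str
    M: int
    theta_hat_M: float
    se: float
    p_one_sided: float
    reject: bool
    alpha: float
    coefficients: dict[str, float]
    variance_components: dict[str, float]
    converged: bool
    n_used: int
    dropped_columns: tuple[str, ...] = ()
    df_resid: float | None = None

    def to_row(self) -> dict[str, object]:
        row: dict[str, object] = {
            "model": self.model,
            "arm": self.M,
            "theta_hat": self.theta_hat_M,
            "se": self.se,
            "p_one_sided": self.p_one_sided,
            "reject": self.reject,
            "converged": self.converged,
            "n_used": self.n_used,
        }
        for k, v in self.variance_components.items():
            row[k] = v
        return row


@dataclass(frozen=True)
class ModelSpec:
    """Which analysis to run on an :class:`~ncctrials.design.AnalysisWindow`."""

    family: str
    adjustment: str = "period"
    covariance: str = "iid"  # mixed only
    degree: int = 3  # spline only
    knot_strategy: str = "period_starts"  # spline only
    clength: int | None = None  # None -> the window's design value
    alpha: float = 0.025

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown model family {self.family!r}")
        if self.adjustment not in ADJUSTMENTS:
            raise ValueError(f"unknown adjustment {self.adjustment!r}")
        if self.covariance not in ("iid", "ar1"):
            raise ValueError(f"unknown covariance {self.covariance!r}")
        if self.degree not in (1, 2, 3):
            raise ValueError(f"spline degree must be 1, 2 or 3, got {self.degree}")
        if self.knot_strategy not in KNOT_STRATEGIES:
            raise ValueError(f"unknown knot strategy {self.knot_strategy!r}")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")

    @property
    def label(self) -> str:
        if self.family == "fixed":
            return f"fixed-{self.adjustment}"
        if self.family == "spline":
            strat = "period" if self.knot_strategy == "period_starts" else "calendar"
            return f"spline-{strat}-q{self.degree}"
        if self.family == "mixed":
            return f"mixed-{self.adjustment}-{self.covariance}"
        if self.family == "mixed_interaction":
            return f"interaction-{self.adjustment}"
        return self.family.replace("_", "-")

    def fit(self, window: AnalysisWindow) -> FitResult:
        return fit_model(window, self)


def parse_model_spec(label: str, clength: int | None = None, alpha: float = 0.025) -> ModelSpec:
    """Parse a compact model label such as ``fixed-period``, ``spline-period-q3``,
    ``mixed-calendar-ar1``, ``interaction-period`` or ``ttest-pooled``."""
    parts = label.strip().lower().split("-")
    kw: dict[str, object] = {"clength": clength, "alpha": alpha}
    if parts[0] == "ttest":
        if len(parts) != 2 or parts[1] not in ("pooled", "separate"):
            raise ValueError(f"bad t-test label {label!r}")
        return ModelSpec(family=f"ttest_{parts[1]}", **kw)
    if parts[0] == "fixed" and len(parts) == 2:
        return ModelSpec(family="fixed", adjustment=parts[1], **kw)
    if parts[0] == "spline" and len(parts) == 3:
        strat = {"period": "period_starts", "calendar": "equidistant_calendar"}.get(parts[1])
        if strat is None or not parts[2].startswith("q"):
            raise ValueError(f"bad spline label {label!r}")
        return ModelSpec(
            family="spline", knot_strategy=strat, degree=int(parts[2][1:]), **kw
        )
    if parts[0] == "mixed" and len(parts) == 3:
        return ModelSpec(family="mixed", adjustment=parts[1], covariance=parts[2], **kw)
    if parts[0] == "interaction" and len(parts) == 2:
        return ModelSpec(family="mixed_interaction", adjustment=parts[1], **kw)
    raise ValueError(f"unrecognized model label {label!r}")


# ---------------------------------------------------------------------------
# design-matrix building blocks


def _time_labels(window: AnalysisWindow, adjustment: str, clength: int | None) -> np.ndarray:
    """1-based time-interval label per patient under the requested adjustment."""
    if adjustment == "period":
        return window.df["period"].to_numpy()
    cl = clength or window.clength
    t = window.df["t"].to_numpy()
    return -(-t // cl)

def _arm_design(window: AnalysisWindow) -> tuple[np.ndarray, list[str], list[int]]:
    arms = [int(k) for k in window.K_M if k != 0]
    a = window.df["arm"].to_numpy()
    cols = [(a == k).astype(float) for k in arms]
    X = np.column_stack([np.ones(len(a)), *cols]) if cols else np.ones((len(a), 1))
    names = ["intercept"] + [f"theta_{k}" for k in arms]
    return X, names, arms


def _time_design(labels: np.ndarray, prefix: str) -> tuple[np.ndarray, list[str]]:
    levels = np.arange(2, labels.max() + 1)
    cols = [(labels == lv).astype(float) for lv in levels]
    names = [f"{prefix}_{lv}" for lv in levels]
    if cols:
        return np.column_stack(cols), names
    return np.empty((labels.size, 0)), names


def _resolve_rank(
    X: np.ndarray, names: list[str], protect: Sequence[str]
) -> tuple[np.ndarray, list[str], tuple[str, ...]]:
    """Drop linearly dependent columns, later columns first; refuse to drop
    any protected (arm) column."""
    R = np.linalg.qr(X, mode="r")
    d = np.abs(np.diag(R))
    if d.min() > _RANK_TOL * max(d.max(), 1.0):
        return X, names, ()
    keep: list[int] = []
    dropped: list[str] = []
    for i, nm in enumerate(names):
        cand = X[:, keep + [i]]
        r = np.abs(np.diag(np.linalg.qr(cand, mode="r")))
        if r.min() > _RANK_TOL * max(r.max(), 1.0):
            keep.append(i)
        elif nm in protect:
            raise ValueError(
                f"column {nm!r} is aliased with the remaining design; "
                f"the treatment effect is not estimable in this window"
            )
        else:
            dropped.append(nm)
    log.warning("dropped aliased design columns: %s", ", ".join(dropped))
    return X[:, keep], [names[i] for i in keep], tuple(dropped)


def _ols(
    window: AnalysisWindow,
    X: np.ndarray,
    names: list[str],
    label: str,
    alpha: float,
    extra_vc: dict[str, float] | None = None,
) -> FitResult:
    M = window.M
    X, names, dropped = _resolve_rank(X, names, protect=(f"theta_{M}",))
    y = window.df["y"].to_numpy()
    n, p = X.shape
    Q, R = np.linalg.qr(X)
    beta = np.linalg.solve(R, Q.T @ y)
    resid = y - X @ beta
    df_resid = n - p
    if df_resid < 1:
        raise ValueError(f"no residual degrees of freedom (n={n}, p={p})")
    sigma2 = float(resid @ resid) / df_resid
    Rinv = np.linalg.inv(R)
    cov = sigma2 * (Rinv @ Rinv.T)
    i = names.index(f"theta_{M}")
    theta, se = float(beta[i]), float(np.sqrt(cov[i, i]))
    p_one = float(stats.t.sf(theta / se, df_resid))
    vc = {"sigma2": sigma2}
    if extra_vc:
        vc.update(extra_vc)
    return FitResult(
        model=label,
        M=M,
        theta_hat_M=theta,
        se=se,
        p_one_sided=p_one,
        reject=p_one <= alpha,
        alpha=alpha,
        coefficients=dict(zip(names, map(float, beta))),
        variance_components=vc,
        converged=True,
        n_used=n,
        dropped_columns=dropped,
        df_resid=df_resid,
    )


# ---------------------------------------------------------------------------
# fixed-effect models


def fit_fixed(
    window: AnalysisWindow,
    adjustment: str = "period",
    clength: int | None = None,
    alpha: float = 0.025,
) -> FitResult:
    """OLS with arm indicators plus categorical time effects (levels >= 2)."""
    labels = _time_labels(window, adjustment, clength)
    Xa, names, _ = _arm_design(window)
    Xt, tnames = _time_design(labels, "tau")
    X = np.column_stack([Xa, Xt])
    return _ols(window, X, names + tnames, f"fixed-{adjustment}", alpha)


# ---------------------------------------------------------------------------
# spline regression


@dataclass(frozen=True)
class SplineBasis:
    """Clamped B-spline basis over a window's recruitment times."""

    degree: int
    inner_knots: tuple[float, ...]
    boundary: tuple[float, float]
    matrix: np.ndarray = field(repr=False)

    @property
    def knot_vector(self) -> np.ndarray:
        lo, hi = self.boundary
        return np.r_[[lo] * (self.degree + 1), self.inner_knots, [hi] * (self.degree + 1)]


def build_spline_basis(
    t_values: np.ndarray | Sequence[float],
    knot_strategy: str = "period_starts",
    q: int = 3,
    clength: int | None = None,
    period_map=None,
) -> SplineBasis:
    """B-spline basis of degree ``q`` with inner knots at period boundaries
    (``period_starts``) or at multiples of ``clength``
    (``equidistant_calendar``); boundary knots clamp the window's min/max time.

    ``period_map`` supplies the period boundaries: a
    :class:`~ncctrials.design.PeriodMap`, or any sequence of boundary times.
    """
    t = np.asarray(t_values, dtype=float)
    if np.unique(t).size < q + 2:
        raise ValueError(
            f"need at least {q + 2} distinct time values for a degree-{q} basis"
        )
    lo, hi = float(t.min()), float(t.max())
    if knot_strategy == "period_starts":
        if period_map is None:
            raise ValueError("period_starts strategy requires period boundaries")
        raw = np.asarray(getattr(period_map, "boundaries", period_map), dtype=float)
    elif knot_strategy == "equidistant_calendar":
        if not clength or clength < 1:
            raise ValueError("equidistant_calendar strategy requires clength >= 1")
        raw = np.arange(clength, hi, clength, dtype=float)
    else:
        raise ValueError(f"unknown knot strategy {knot_strategy!r}")
    inner = raw[(raw > lo) & (raw < hi)]
    if inner.size < raw.size:
        log.warning(
            "dropped %d inner knots outside (%s, %s)", raw.size - inner.size, lo, hi
        )
    knots = np.r_[[lo] * (q + 1), np.sort(inner), [hi] * (q + 1)]
    B = BSpline.design_matrix(t, knots, q).toarray()
    return SplineBasis(
        degree=q, inner_knots=tuple(np.sort(inner)), boundary=(lo, hi), matrix=B
    )


def fit_spline(
    window: AnalysisWindow,
    knot_strategy: str = "period_starts",
    q: int = 3,
    clength: int | None = None,
    alpha: float = 0.025,
) -> FitResult:
    """OLS with arm indicators plus a continuous B-spline drift in time.

    The model keeps an explicit intercept and drops the first basis column
    for identifiability (the clamped basis sums to one at every ``t``).
    """
    t = window.df["t"].to_numpy()
    if knot_strategy == "period_starts":
        per = window.df["period"].to_numpy()
        starts = [int(t[per == s].min()) - 1 for s in range(2, int(per.max()) + 1)]
        basis = build_spline_basis(t, knot_strategy, q, period_map=starts)
    else:
        basis = build_spline_basis(
            t, knot_strategy, q, clength=clength or window.clength
        )
    Xa, names, _ = _arm_design(window)
    Xs = basis.matrix[:, 1:]
    snames = [f"spline_{i}" for i in range(1, basis.matrix.shape[1])]
    strat = "period" if knot_strategy == "period_starts" else "calendar"
    X = np.column_stack([Xa, Xs])
    return _ols(window, X, names + snames, f"spline-{strat}-q{q}", alpha)


# ---------------------------------------------------------------------------
# mixed models


def _mixed_common(
    window: AnalysisWindow, adjustment: str, clength: int | None
) -> np.ndarray:
    labels = _time_labels(window, adjustment, clength)
    if np.unique(labels).size < 2:
        raise ValueError(
            "only one time-interval level in the window; use fit_fixed instead"
        )
    return labels


def fit_mixed(
    window: AnalysisWindow,
    adjustment: str = "period",
    covariance: str = "iid",
    clength: int | None = None,
    alpha: float = 0.025,
    fix_rho: float | None = None,
) -> FitResult:
    """Mixed model: fixed arm effects, random intercept per time interval.

    Random effects are iid or share an AR(1) correlation across consecutive
    intervals; estimation is REML, inference on ``theta_M`` a Wald z test.
    """
    labels = _mixed_common(window, adjustment, clength)
    Xa, names, _ = _arm_design(window)
    levels = np.arange(1, labels.max() + 1)
    Z = np.column_stack([(labels == lv).astype(float) for lv in levels])
    y = window.df["y"].to_numpy()
    fit = reml_fit(y, Xa, Z, covariance=covariance, fix_rho=fix_rho)
    i = names.index(f"theta_{window.M}")
    theta, se = float(fit.beta[i]), float(np.sqrt(fit.cov_beta[i, i]))
    p_one = float(stats.norm.sf(theta / se))
    vc = {"sigma2": fit.sigma2, f"sigma2_{adjustment}": fit.sigma2_u}
    if covariance == "ar1":
        vc["rho"] = fit.rho
    vc["neg2_reml"] = fit.neg2_reml
    return FitResult(
        model=f"mixed-{adjustment}-{covariance}",
        M=window.M,
        theta_hat_M=theta,
        se=se,
        p_one_sided=p_one,
        reject=p_one <= alpha,
        alpha=alpha,
        coefficients=dict(zip(names, map(float, fit.beta))),
        variance_components=vc,
        converged=fit.converged,
        n_used=len(y),
    )


def interaction_columns(
    window: AnalysisWindow, labels: np.ndarray
) -> tuple[list[np.ndarray], list[str]]:
    """Random-interaction indicator columns ``u_{k,level}`` for every
    experimental arm except the evaluated one, crossed with time levels >= 2;
    empty crossings are omitted."""
    a = window.df["arm"].to_numpy()
    other = [int(k) for k in window.K_M if k not in (0, window.M)]
    zcols, znames = [], []
    for k in other:
        for lv in range(2, int(labels.max()) + 1):
            col = ((a == k) & (labels == lv)).astype(float)
            if col.any():
                zcols.append(col)
                znames.append(f"u_{k}_{lv}")
    return zcols, znames


def fit_mixed_interaction(
    window: AnalysisWindow,
    adjustment: str = "period",
    clength: int | None = None,
    alpha: float = 0.025,
) -> FitResult:
    """Fixed arm and time effects plus an iid random treatment-by-time
    interaction for every experimental arm except the evaluated one.

    The evaluated arm is excluded from the interaction, so its effect is
    compared to control under the equal-trend assumption while other arms'
    deviations are shrunk toward zero.
    """
    other = [int(k) for k in window.K_M if k not in (0, window.M)]
    if not other:
        log.warning(
            "no non-evaluated experimental arm in the window; "
            "falling back to the fixed-effect model"
        )
        return fit_fixed(window, adjustment, clength, alpha)
    labels = _mixed_common(window, adjustment, clength)
    Xa, names, _ = _arm_design(window)
    Xt, tnames = _time_design(labels, "tau")
    X = np.column_stack([Xa, Xt])
    X, names2, dropped = _resolve_rank(
        X, names + tnames, protect=(f"theta_{window.M}",)
    )
    zcols, znames = interaction_columns(window, labels)
    if not zcols:
        log.warning("interaction design is empty; falling back to the fixed model")
        return fit_fixed(window, adjustment, clength, alpha)
    Z = np.column_stack(zcols)
    y = window.df["y"].to_numpy()
    fit = reml_fit(y, X, Z, covariance="iid")
    i = names2.index(f"theta_{window.M}")
    theta, se = float(fit.beta[i]), float(np.sqrt(fit.cov_beta[i, i]))
    p_one = float(stats.norm.sf(theta / se))
    vc = {
        "sigma2": fit.sigma2,
        f"sigma2_arm_{adjustment}": fit.sigma2_u,
        "neg2_reml": fit.neg2_reml,
    }
    return FitResult(
        model=f"interaction-{adjustment}",
        M=window.M,
        theta_hat_M=theta,
        se=se,
        p_one_sided=p_one,
        reject=p_one <= alpha,
        alpha=alpha,
        coefficients=dict(zip(names2, map(float, fit.beta))),
        variance_components=vc,
        converged=fit.converged,
        n_used=len(y),
        dropped_columns=dropped,
    )


# ---------------------------------------------------------------------------
# t-test comparators


def t_test(
    window: AnalysisWindow,
    mode: str = "separate",
    alpha: float = 0.025,
    welch: bool = False,
) -> FitResult:
    """One-sided two-sample t-test of arm ``M`` against controls.

    ``pooled`` uses every control in the window (concurrent and
    non-concurrent); ``separate`` only controls recruited while arm ``M`` was
    open.  The variance is pooled unless ``welch=True``.
    """
    if mode not in ("pooled", "separate"):
        raise ValueError(f"unknown t-test mode {mode!r}")
    df = window.df
    xm = df.loc[df["arm"] == window.M, "y"].to_numpy()
    ctrl = df[df["arm"] == 0]
    if mode == "separate":
        ctrl = ctrl[(ctrl["t"] >= window.t_entry) & (ctrl["t"] <= window.t_exit)]
    xc = ctrl["y"].to_numpy()
    if len(xm) < 2 or len(xc) < 2:
        raise ValueError(
            f"t-test needs >= 2 observations per group (n_M={len(xm)}, n_ctrl={len(xc)})"
        )
    n1, n2 = len(xm), len(xc)
    theta = float(xm.mean() - xc.mean())
    if welch:
        res = stats.ttest_ind(xm, xc, equal_var=False, alternative="greater")
        se = theta / res.statistic if res.statistic != 0 else float("nan")
        p_one, dof = float(res.pvalue), float(res.df)
    else:
        v1, v2 = xm.var(ddof=1), xc.var(ddof=1)
        dof = n1 + n2 - 2
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / dof
        se = float(np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2)))
        p_one = float(stats.t.sf(theta / se, dof))
    return FitResult(
        model=f"ttest-{mode}",
        M=window.M,
        theta_hat_M=theta,
        se=float(se),
        p_one_sided=p_one,
        reject=p_one <= alpha,
        alpha=alpha,
        coefficients={f"theta_{window.M}": theta},
        variance_components={},
        converged=True,
        n_used=n1 + n2,
        df_resid=dof,
    )


def fit_model(window: AnalysisWindow, spec: ModelSpec) -> FitResult:
    """Dispatch a :class:`ModelSpec` to the matching fit function."""
    if spec.family == "fixed":
        return fit_fixed(window, spec.adjustment, spec.clength, spec.alpha)
    if spec.family == "spline":
        return fit_spline(
            window, spec.knot_strategy, spec.degree, spec.clength, spec.alpha
        )
    if spec.family == "mixed":
        return fit_mixed(
            window, spec.adjustment, spec.covariance, spec.clength, spec.alpha
        )
    if spec.family == "mixed_interaction":
        return fit_mixed_interaction(window, spec.adjustment, spec.clength, spec.alpha)
    mode = spec.family.split("_")[1]
    return t_test(window, mode, spec.alpha)
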