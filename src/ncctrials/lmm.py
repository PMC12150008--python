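"""Restricted-maximum-likelihood engine for linear mixed models with a single
random-effect block.

Model: ``y = X b + Z u + e`` with ``e ~ N(0, s2 I)`` and
``u ~ N(0, s2 * gamma * G(rho))`` where ``G`` is either the identity (iid
random effects) or an AR(1) correlation matrix ``G_ij = rho^|i-j|``.

The marginal covariance is ``V = s2 (I + gamma Z G Z')``; ``b`` and ``s2``
are profiled out of the REML criterion, leaving an optimization over
``log gamma`` (and ``atanh rho`` for AR(1)).  All linear algebra runs on the
``q x q`` scale via the Woodbury identity, so fits cost O(n p q) once the
cross-products are formed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve

__all__ = ["LMMFit", "reml_fit"]

_LOG_GAMMA_BOUNDS = (-25.0, 20.0)
_Z_RHO_BOUND = 5.0  # atanh(rho) bound -> |rho| < 0.9999


@dataclass(frozen=True)
class LMMFit:
    beta: np.ndarray
    cov_beta: np.ndarray
    sigma2: float  # residual variance
    sigma2_u: float  # random-effect variance (= gamma * sigma2)
    rho: float  # AR(1) correlation (0 for iid)
    neg2_reml: float
    converged: bool


def _ar1_inverse(q: int, rho: float) -> tuple[np.ndarray, float]:
    """Analytic inverse and log-determinant of the q x q AR(1) correlation."""
    if q == 1:
        return np.array([[1.0]]), 0.0
    Gi = np.zeros((q, q))
    f = 1.0 / (1.0 - rho * rho)
    d = np.full(q, (1.0 + rho * rho) * f)
    d[0] = d[-1] = f
    np.fill_diagonal(Gi, d)
    off = -rho * f
    idx = np.arange(q - 1)
    Gi[idx, idx + 1] = off
    Gi[idx + 1, idx] = off
    logdet = (q - 1) * np.log(1.0 - rho * rho)
    return Gi, logdet


class _REMLProblem:
    def __init__(self, y: np.ndarray, X: np.ndarray, Z: np.ndarray):
        self.n, self.p = X.shape
        self.q = Z.shape[1]
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)
        self.ZtZ = Z.T @ Z
        self.ZtX = Z.T @ X
        self.Zty = Z.T @ y

    def criterion(self, log_gamma: float, rho: float, want_fit: bool = False):
        gamma = np.exp(log_gamma)
        if abs(rho) > 0:
            Gi, logdetG = _ar1_inverse(self.q, rho)
        else:
            Gi, logdetG = np.eye(self.q), 0.0
        A = Gi / gamma + self.ZtZ
        try:
            cA = cho_factor(A, lower=True)
        except np.linalg.LinAlgError:
            return (np.inf, None) if want_fit else np.inf
        AiZtX = cho_solve(cA, self.ZtX)
        AiZty = cho_solve(cA, self.Zty)
        XtWX = self.XtX - self.ZtX.T @ AiZtX
        XtWy = self.Xty - self.ZtX.T @ AiZty
        ytWy = self.yty - self.Zty @ AiZty
        try:
            cX = cho_factor(XtWX, lower=True)
        except np.linalg.LinAlgError:
            return (np.inf, None) if want_fit else np.inf
        beta = cho_solve(cX, XtWy)
        rss = max(ytWy - beta @ XtWy, 1e-12)
        logdetA = 2.0 * np.sum(np.log(np.diag(cA[0])))
        logdetH = logdetA + self.q * np.log(gamma) + logdetG
        logdetXtWX = 2.0 * np.sum(np.log(np.diag(cX[0])))
        crit = (self.n - self.p) * np.log(rss) + logdetH + logdetXtWX
        if not want_fit:
            return crit
        sigma2 = rss / (self.n - self.p)
        cov_beta = sigma2 * cho_solve(cX, np.eye(self.p))
        return crit, (beta, cov_beta, sigma2, gamma * sigma2)


def reml_fit(
    y: np.ndarray,
    X: np.ndarray,
    Z: np.ndarray,
    covariance: str = "iid",
    fix_rho: float | None = None,
    n_restarts: int = 2,
) -> LMMFit:
    """REML fit of the single-block mixed model.

    Parameters
    ----------
    covariance : {"iid", "ar1"}
        Correlation structure of the random effects across the columns of
        ``Z`` (whose order defines AR(1) adjacency).
    fix_rho : float, optional
        Hold the AR(1) correlation fixed instead of estimating it.
    """
    if covariance not in ("iid", "ar1"):
        raise ValueError(f"unknown covariance {covariance!r}")
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    Z = np.asarray(Z, dtype=float)
    if Z.ndim != 2 or Z.shape[1] < 1:
        raise ValueError("Z must have at least one random-effect column")
    prob = _REMLProblem(y, X, Z)

    def profile_gamma(rho: float, xatol: float = 1e-8) -> tuple[float, float, bool]:
        """Minimize the criterion over log gamma at fixed rho."""
        res = optimize.minimize_scalar(
            lambda lg: prob.criterion(lg, rho),
            bounds=_LOG_GAMMA_BOUNDS,
            method="bounded",
            options={"xatol": xatol},
        )
        return float(res.fun), float(res.x), bool(res.success)

    estimate_rho = covariance == "ar1" and fix_rho is None and prob.q > 1
    rho0 = 0.0 if covariance == "iid" else (fix_rho or 0.0)

    if not estimate_rho:
        f0, lg0, ok = profile_gamma(rho0)
        best_x, best_f = (lg0, rho0), f0
    elif (lg_at_zero := profile_gamma(0.0))[1] <= _LOG_GAMMA_BOUNDS[0] + 0.5:
        # random-effect variance at the zero boundary: rho is unidentified,
        # report the iid-degenerate fit
        f0, lg0, ok = lg_at_zero
        best_x, best_f = (lg0, 0.0), f0
    else:
        # multi-start coarse scan over atanh(rho), then a bounded refine
        # around the best bracket; rho = 0 (the nested iid model) is always
        # a scan candidate.
        zgrid = np.unique(
            np.append(np.linspace(-_Z_RHO_BOUND, _Z_RHO_BOUND, 2 * n_restarts + 1), 0.0)
        )
        scans = [(profile_gamma(np.tanh(z), xatol=2e-1)[0], z) for z in zgrid]
        _, z_best = min(scans)
        i = list(zgrid).index(z_best)
        lo = zgrid[max(i - 1, 0)]
        hi = zgrid[min(i + 1, len(zgrid) - 1)]
        res = optimize.minimize_scalar(
            lambda z: profile_gamma(np.tanh(z), xatol=1e-3)[0],
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-3},
        )
        z_opt = float(res.x) if res.fun <= min(scans)[0] else z_best
        rho_opt = float(np.tanh(z_opt))
        best_f, lg_opt, ok = profile_gamma(rho_opt)
        best_x = (lg_opt, rho_opt)

    crit, fit = prob.criterion(best_x[0], best_x[1], want_fit=True)
    if fit is None:
        raise np.linalg.LinAlgError("REML criterion not evaluable at the optimum")
    beta, cov_beta, sigma2, sigma2_u = fit
    return LMMFit(
        beta=beta,
        cov_beta=cov_beta,
        sigma2=sigma2,
        sigma2_u=sigma2_u,
        rho=float(best_x[1]),
        neg2_reml=float(crit),
        converged=ok and np.isfinite(crit),
    )
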