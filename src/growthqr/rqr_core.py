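"""L1-penalized quantile regression of marker effects (step two).

For a corrected trait y, genotype matrix X (0/1/2 dosages, uncentered)
and quantile tau in (0, 1), the estimator solves

    min_{mu, beta}  sum_i rho_tau(y_i - mu - x_i . beta) + lam * sum_k |beta_k|

where rho_tau(u) = tau*u for u > 0 and -(1-tau)*u otherwise (the check,
or pinball, loss).  The intercept mu is unpenalized.  The problem is a
linear program: splitting residuals and coefficients into positive and
negative parts gives

    min  tau * 1'u+ + (1-tau) * 1'u- + lam * 1'(b+ + b-)
    s.t. mu + X(b+ - b-) + u+ - u- = y,   u+, u-, b+, b- >= 0

solved exactly with the HiGHS backend of scipy.optimize.linprog.  The
penalty lam is chosen on a grid by maximizing predictive capacity (the
Pearson correlation between fitted and observed trait values), and
marker-effect uncertainty comes from a case (row) bootstrap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linprog
from scipy.stats import norm, pearsonr

logger = logging.getLogger(__name__)

_COEF_TOL = 1e-9  # below this a coefficient counts as zero


class UndefinedCapacityError(ValueError):
    """Predictive capacity is undefined (constant fitted values)."""


def check_loss(u, tau: float):
    """Check (pinball) loss rho_tau(u): tau*u if u > 0, else -(1-tau)*u.

    Vectorized over ``u``; non-negative, zero iff u == 0.
    """
    if not 0.0 < tau < 1.0:
        raise ValueError(f"tau must be in (0, 1), got {tau}")
    u = np.asarray(u, dtype=float)
    out = np.where(u > 0, tau * u, -(1.0 - tau) * u)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class RQRProblem:
    """One penalized quantile-regression instance."""

    y: np.ndarray
    X: np.ndarray
    tau: float
    lam: float
    marker_ids: Optional[tuple[str, ...]] = None

    def __post_init__(self) -> None:
        y = np.asarray(self.y, dtype=float)
        X = np.asarray(self.X, dtype=float)
        if y.ndim != 1 or X.ndim != 2 or X.shape[0] != y.size:
            raise ValueError(f"incompatible shapes y{y.shape}, X{X.shape}")
        if y.size == 0:
            raise ValueError("empty problem")
        if not (np.isfinite(y).all() and np.isfinite(X).all()):
            raise ValueError("y and X must be finite (no missing entries)")
        if not 0.0 < self.tau < 1.0:
            raise ValueError(f"tau must be in (0, 1), got {self.tau}")
        if self.lam < 0:
            raise ValueError("lam must be non-negative")
        if self.marker_ids is not None and len(self.marker_ids) != X.shape[1]:
            raise ValueError("marker_ids length != number of columns of X")
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "X", X)


@dataclass(frozen=True)
class RQRFit:
    """Solution of one RQRProblem."""

    tau: float
    lam: float
    mu_hat: float
    beta_hat: np.ndarray
    objective: float
    fitted: np.ndarray
    pseudo_r1: float
    n_nonzero: int
    marker_ids: Optional[tuple[str, ...]] = None

    def residuals(self, y: np.ndarray) -> np.ndarray:
        return np.asarray(y, float) - self.fitted


def solve_rqr(problem: RQRProblem) -> RQRFit:
    """Exact LP solution of the penalized check-loss problem.

    Returns a global minimizer (any optimal vertex when the optimum is not
    unique).  The reported objective is recomputed from the returned
    coefficients, so it is self-consistent by construction.
    """
    y, X, tau, lam = problem.y, problem.X, problem.tau, problem.lam
    n, p = X.shape
    # variable order: mu+, mu-, b+ (p), b- (p), u+ (n), u- (n)
    c = np.concatenate([[0.0, 0.0], np.full(2 * p, lam),
                        np.full(n, tau), np.full(n, 1.0 - tau)])
    A_eq = np.hstack([np.ones((n, 1)), -np.ones((n, 1)), X, -X, np.eye(n), -np.eye(n)])
    res = linprog(c, A_eq=A_eq, b_eq=y, bounds=(0, None), method="highs",
                  options={"presolve": True, "primal_feasibility_tolerance": 1e-9,
                           "dual_feasibility_tolerance": 1e-9})
    if res.status != 0:
        raise RuntimeError(f"LP solver failed (status {res.status}): {res.message}")
    x = res.x
    mu = float(x[0] - x[1])
    beta = x[2:2 + p] - x[2 + p:2 + 2 * p]
    beta[np.abs(beta) < _COEF_TOL] = 0.0
    fitted = mu + X @ beta
    objective = float(np.sum(check_loss(y - fitted, tau)) + lam * np.sum(np.abs(beta)))
    try:
        r1 = _pseudo_r1_from_fitted(fitted, y, tau)
    except ValueError:
        r1 = float("nan")
    return RQRFit(tau=tau, lam=lam, mu_hat=mu, beta_hat=beta, objective=objective,
                  fitted=fitted, pseudo_r1=r1,
                  n_nonzero=int(np.count_nonzero(beta)), marker_ids=problem.marker_ids)


def predictive_capacity(fit: RQRFit, y: np.ndarray) -> float:
    """Pearson correlation between fitted and observed trait values.

    This in-sample correlation is the criterion used to pick the penalty.
    Raises :class:`UndefinedCapacityError` when the fitted vector is
    constant (correlation undefined; the caller treats that lam as
    rejected).
    """
    y = np.asarray(y, dtype=float)
    if y.size < 3:
        raise ValueError("need at least 3 observations for a correlation")
    if np.ptp(fit.fitted) == 0 or np.allclose(fit.fitted, fit.fitted[0]):
        raise UndefinedCapacityError("fitted values are constant; capacity undefined")
    return float(pearsonr(fit.fitted, y).statistic)


def select_lambda(
    y: np.ndarray,
    X: np.ndarray,
    tau: float,
    grid: Sequence[float],
    marker_ids: Optional[tuple[str, ...]] = None,
) -> tuple[float, pd.DataFrame, RQRFit]:
    """Fit every lam in ``grid`` and keep the capacity maximizer.

    Ties are broken toward the largest lam (the sparser model).  Returns
    the winning lam, the per-lam capacity table (NaN where capacity was
    undefined) and the winning fit.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("empty lambda grid")
    if any(b < a for a, b in zip(grid, grid[1:])):
        raise ValueError("lambda grid must be sorted ascending")
    rows = []
    best = None  # (capacity, lam, fit)
    for lam in grid:
        fit = solve_rqr(RQRProblem(y=y, X=X, tau=tau, lam=float(lam), marker_ids=marker_ids))
        try:
            cap = predictive_capacity(fit, y)
        except UndefinedCapacityError:
            rows.append({"lambda": lam, "capacity": np.nan, "n_nonzero": fit.n_nonzero})
            continue
        rows.append({"lambda": lam, "capacity": cap, "n_nonzero": fit.n_nonzero})
        if best is None or cap >= best[0]:  # >= : ties go to the larger lam
            best = (cap, float(lam), fit)
    table = pd.DataFrame(rows, columns=["lambda", "capacity", "n_nonzero"])
    if best is None:
        raise UndefinedCapacityError("every lambda in the grid yielded undefined capacity")
    logger.info("selected lambda=%g (capacity %.4f) at tau=%.2f", best[1], best[0], tau)
    return best[1], table, best[2]


def _tau_quantile(y: np.ndarray, tau: float) -> float:
    # check-loss-minimizing sample quantile (lower end of the optimal set)
    return float(np.quantile(y, tau, method="inverted_cdf"))


def _pseudo_r1_from_fitted(fitted: np.ndarray, y: np.ndarray, tau: float) -> float:
    y = np.asarray(y, dtype=float)
    v_full = float(np.sum(check_loss(y - fitted, tau)))
    v_null = float(np.sum(check_loss(y - _tau_quantile(y, tau), tau)))
    if v_null == 0.0:
        raise ValueError("constant response: null check loss is zero, pseudo-R1 undefined")
    return 1.0 - v_full / v_null


def pseudo_r1(fit: RQRFit, y: np.ndarray, tau: float) -> float:
    """Goodness of fit 1 - V_full/V_null for quantile models.

    V_full is the check loss of the fitted model; V_null that of the
    intercept-only model at the sample tau-quantile.  Equals 1 for a
    perfect fit, 0 when the model does no better than the quantile.
    """
    return _pseudo_r1_from_fitted(fit.fitted, y, tau)


@dataclass(frozen=True)
class BootstrapSummary:
    """Case-bootstrap uncertainty for marker effects at one (trait, tau)."""

    se: np.ndarray
    p_value: np.ndarray
    reps_used: int
    seed: int
    beta_hat: np.ndarray
    replicates: np.ndarray = field(repr=False)  # reps x p matrix of bootstrap beta


def bootstrap_effects(
    y: np.ndarray,
    X: np.ndarray,
    tau: float,
    lam: float,
    reps: int = 200,
    seed: int = 0,
) -> BootstrapSummary:
    """Case (paired-row) bootstrap of the penalized quantile fit.

    Resamples (y_i, x_i.) rows with replacement ``reps`` times, refits,
    and reports per-marker standard errors (SD over replicates) and
    two-sided normal-approximation p-values 2*(1 - Phi(|beta_hat|/se)).
    A marker with se = 0 gets p = 1 if its point estimate is zero.
    Deterministic for a given seed.
    """
    if reps < 2:
        raise ValueError("bootstrap requires reps >= 2")
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    base = solve_rqr(RQRProblem(y=y, X=X, tau=tau, lam=lam))
    rng = np.random.default_rng(seed)
    betas = np.empty((reps, p))
    for r in range(reps):
        idx = rng.integers(0, n, size=n)
        betas[r] = solve_rqr(RQRProblem(y=y[idx], X=X[idx], tau=tau, lam=lam)).beta_hat
    se = betas.std(axis=0, ddof=1)
    pv = np.ones(p)
    pos = se > 0
    pv[pos] = 2.0 * norm.sf(np.abs(base.beta_hat[pos]) / se[pos])
    pv[pos] = np.maximum(pv[pos], np.finfo(float).tiny)  # keep p in (0, 1]
    degenerate = (~pos) & (base.beta_hat != 0)
    pv[degenerate] = np.finfo(float).tiny
    return BootstrapSummary(se=se, p_value=pv, reps_used=reps, seed=seed,
                            beta_hat=base.beta_hat.copy(), replicates=betas)
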