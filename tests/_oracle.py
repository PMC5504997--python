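"""Independent brute-force oracles for the penalized quantile LP.

The penalized check-loss objective is piecewise linear in (mu, beta), so
its minimum is attained at a vertex of the arrangement formed by the n
residual-zero hyperplanes and the p coefficient-zero hyperplanes.  The
oracle enumerates every such vertex — choose a zero set Z of
coefficients and an interpolation set S of data points with
|S| = 1 + p - |Z|, solve the linear system, evaluate the objective — and
returns the minimum.  Exhaustive for the tiny instances used in tests
(n <= 8, p <= 2) and entirely independent of the LP solver under test.
"""

from __future__ import annotations

import itertools

import numpy as np


def check_loss_ref(u, tau: float) -> np.ndarray:
    u = np.asarray(u, dtype=float)
    return np.where(u > 0, tau * u, (tau - 1.0) * u)


def objective_ref(y, X, tau, lam, mu, beta) -> float:
    resid = y - mu - X @ beta
    return float(check_loss_ref(resid, tau).sum() + lam * np.abs(beta).sum())


def bruteforce_optimum(y: np.ndarray, X: np.ndarray, tau: float, lam: float) -> float:
    """Minimum objective over all vertices of the piecewise-linear arrangement."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    best = np.inf
    for z_size in range(p + 1):
        for zeros in itertools.combinations(range(p), z_size):
            free = [k for k in range(p) if k not in zeros]
            n_par = 1 + len(free)
            if n_par > n:
                continue
            for S in itertools.combinations(range(n), n_par):
                rows = np.array(S)
                A = np.column_stack([np.ones(n_par), X[rows][:, free]])
                try:
                    theta = np.linalg.solve(A, y[rows])
                except np.linalg.LinAlgError:
                    continue
                if not np.all(np.isfinite(theta)):
                    continue
                beta = np.zeros(p)
                beta[free] = theta[1:]
                best = min(best, objective_ref(y, X, tau, lam, theta[0], beta))
    return best


def lad_optimum(y: np.ndarray, X: np.ndarray) -> float:
    """Minimum sum of absolute residuals over the same vertex enumeration."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    best = np.inf
    for S in itertools.combinations(range(n), p + 1):
        rows = np.array(S)
        A = np.column_stack([np.ones(p + 1), X[rows]])
        try:
            theta = np.linalg.solve(A, y[rows])
        except np.linalg.LinAlgError:
            continue
        if not np.all(np.isfinite(theta)):
            continue
        resid = y - theta[0] - X @ theta[1:]
        best = min(best, float(np.abs(resid).sum()))
    return best


def random_tiny_instance(rng: np.random.Generator):
    """One random (y, X, tau, lam) instance in the oracle's regime."""
    p = int(rng.integers(0, 3))
    n = int(rng.integers(max(4, p + 2), 9))
    X = rng.integers(0, 3, size=(n, p)).astype(float)
    beta = rng.normal(0, 2, size=p)
    y = 1.0 + X @ beta + rng.normal(0, 1, size=n)
    tau = float(rng.choice([0.2, 0.5, 0.8]))
    lam = float(rng.choice([0.0, 0.5, 2.0]))
    return y, X, tau, lam
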