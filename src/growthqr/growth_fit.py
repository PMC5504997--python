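"""Step one of the two-step approach: per-animal logistic growth curves.

The three-parameter logistic model for weight w at age t is

    w(t) = alpha1 / (1 + exp((alpha2 - t) / alpha3))

with alpha1 the mature weight (horizontal asymptote, kg), alpha2 the
inflection age (days, where w = alpha1/2) and alpha3 the growth scale
(days; the distance on the age axis between the inflection point and the
age where w = alpha1/(1+e^-1) ~= 0.73*alpha1; the reciprocal of the
growth rate in the rate parameterization).  After fitting, the parameter
estimates are corrected for fixed effects (sex, lot, halothane genotype)
by an ordinary least-squares model; the corrected trait is the OLS
residual plus the overall mean, so trait means are preserved exactly.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import least_squares

from .data_io import Covariates, GrowthRecords

logger = logging.getLogger(__name__)

TRAITS = ("alpha1", "alpha2", "alpha3")


class InsufficientDataError(ValueError):
    """Fewer observations than parameters allow a meaningful fit."""


@dataclass(frozen=True)
class CurveParams:
    """Fitted logistic parameters and diagnostics for one animal."""

    animal_id: str
    alpha1: float  # mature weight, kg
    alpha2: float  # inflection age, days
    alpha3: float  # growth scale, days
    rss: float     # residual sum of squares, kg^2
    converged: bool
    n_iter: int


@dataclass(frozen=True)
class AdjustedPhenotypes:
    """Fixed-effect-corrected curve parameters (residual + grand mean)."""

    table: pd.DataFrame  # index animal_id; columns alpha1_star, alpha2_star, alpha3_star
    grand_means: dict[str, float]

    @property
    def animal_ids(self) -> tuple[str, ...]:
        return tuple(self.table.index)

    def trait_vector(self, trait: str) -> np.ndarray:
        return self.table[f"{trait}_star"].to_numpy(float)


def logistic_predict(params, age) -> np.ndarray | float:
    """Predicted weight at ``age`` for logistic parameters.

    ``params`` is a CurveParams or an (alpha1, alpha2, alpha3) triple;
    ``age`` may be a scalar or array of days.  Raises on alpha3 == 0.
    """
    if isinstance(params, CurveParams):
        a1, a2, a3 = params.alpha1, params.alpha2, params.alpha3
    else:
        a1, a2, a3 = params
    if a3 == 0:
        raise ValueError("alpha3 must be nonzero")
    age = np.asarray(age, dtype=float)
    out = a1 / (1.0 + np.exp((a2 - age) / a3))
    return float(out) if out.ndim == 0 else out


def _self_start(ages: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Initial (alpha1, alpha2, alpha3) from the data.

    alpha1: 1.05 x max weight; alpha2: linearly interpolated age at which
    weight crosses alpha1/2; alpha3: reciprocal slope of logit(w/alpha1)
    regressed on age, with a span-based fallback if the slope degenerates.
    """
    a1 = 1.05 * float(np.max(weights))
    half = a1 / 2.0
    above = np.nonzero(weights >= half)[0]
    if above.size == 0:
        a2 = float(ages[-1])
    elif above[0] == 0:
        a2 = float(ages[0])
    else:
        j = above[0]
        t0, t1 = ages[j - 1], ages[j]
        w0, w1 = weights[j - 1], weights[j]
        a2 = float(t0 + (half - w0) * (t1 - t0) / (w1 - w0))
    frac = np.clip(weights / a1, 1e-6, 1 - 1e-6)
    z = np.log(frac / (1.0 - frac))  # (t - alpha2)/alpha3 on the true curve
    span = float(ages[-1] - ages[0]) or 1.0
    denom = np.sum((ages - ages.mean()) ** 2)
    slope = float(np.sum((ages - ages.mean()) * (z - z.mean())) / denom) if denom > 0 else 0.0
    a3 = 1.0 / slope if slope > 1e-8 else span / 5.0
    a3 = float(np.clip(a3, 1e-3, 10.0 * span))
    return np.array([a1, a2, a3])


def fit_logistic(
    records: GrowthRecords,
    init: str | np.ndarray = "self_start",
    tol: float = 1e-8,
    max_iter: int = 200,
) -> CurveParams:
    """Least-squares fit of the logistic model to one animal's weights.

    Uses Levenberg-Marquardt damped Gauss-Newton with relative tolerance
    ``tol`` on the residual sum of squares.  Never raises on divergence:
    a failed or implausible fit (fitted mature weight outside
    [max weight, 10 x max weight]) is returned with ``converged=False``.
    Requires at least 4 observations.
    """
    if records.n_obs < 4:
        raise InsufficientDataError(
            f"{records.animal_id}: {records.n_obs} observations, need >= 4 for a 3-parameter fit"
        )
    ages, weights = records.ages, records.weights
    if np.ptp(weights) == 0:
        # no curvature to fit: report the flat self-start, unconverged
        x0 = _self_start(ages, weights)
        rss = float(np.sum((x0[0] / (1.0 + np.exp((x0[1] - ages) / x0[2])) - weights) ** 2))
        return CurveParams(records.animal_id, *x0.tolist(), rss=rss,
                           converged=False, n_iter=0)
    if isinstance(init, str):
        if init != "self_start":
            raise ValueError(f"unknown init {init!r}")
        x0 = _self_start(ages, weights)
    else:
        x0 = np.asarray(init, dtype=float)
        if x0.shape != (3,):
            raise ValueError("explicit init must be (alpha1, alpha2, alpha3)")

    def resid(theta: np.ndarray) -> np.ndarray:
        a1, a2, a3 = theta
        return a1 / (1.0 + np.exp((a2 - ages) / a3)) - weights

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sol = least_squares(resid, x0, method="lm", ftol=tol, xtol=1e-12,
                                gtol=1e-12, max_nfev=max_iter * 10)
    except Exception:
        return CurveParams(records.animal_id, *x0.tolist(), rss=float(np.sum(resid(x0) ** 2)),
                           converged=False, n_iter=0)

    a1, a2, a3 = sol.x
    rss = float(2.0 * sol.cost)
    w_max = float(np.max(weights))
    plausible = (
        np.all(np.isfinite(sol.x))
        and a1 > 0
        and a3 > 0
        # exact/near-exact fits are accepted regardless of the asymptote band
        and (w_max <= a1 <= 10.0 * w_max or rss <= 1e-10 * max(1.0, np.sum(weights**2)))
    )
    converged = bool(sol.success) and bool(plausible)
    return CurveParams(records.animal_id, float(a1), float(a2), float(a3),
                       rss=rss, converged=converged, n_iter=int(sol.nfev))


def fit_all(records: list[GrowthRecords], **kwargs) -> list[CurveParams]:
    """Fit every animal; logs the converged/failed counts."""
    fits = [fit_logistic(r, **kwargs) for r in records]
    n_ok = sum(f.converged for f in fits)
    logger.info("fitted %d animals: %d converged, %d failed", len(fits), n_ok, len(fits) - n_ok)
    return fits


def adjust_fixed_effects(estimates: list[CurveParams], covariates: Covariates) -> AdjustedPhenotypes:
    """Correct curve parameters for sex, lot and halothane fixed effects.

    For each trait an OLS model with the three categorical main effects is
    fitted; the corrected value is the OLS residual plus the grand mean of
    the (converged-animal) raw estimates, so the corrected trait mean
    equals the raw mean.  Non-converged animals are dropped with a logged
    count.  A rank-deficient (confounded) design triggers a warning and
    the minimum-norm least-squares solution.
    """
    kept = [f for f in estimates if f.converged]
    n_drop = len(estimates) - len(kept)
    if n_drop:
        logger.warning("excluding %d non-converged animals from fixed-effect correction", n_drop)
    if not kept:
        raise InsufficientDataError("no converged curve fits to adjust")

    ids = [f.animal_id for f in kept]
    raw = pd.DataFrame({t: [getattr(f, t) for f in kept] for t in TRAITS}, index=ids)
    cov = covariates.for_animals(ids)

    design = pd.get_dummies(cov[["sex", "lot", "halothane"]].astype(str),
                            drop_first=True, dtype=float)
    design.insert(0, "const", 1.0)
    X = design.to_numpy(float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        warnings.warn("rank-deficient fixed-effect design (confounded factors); "
                      "using minimum-norm least squares", UserWarning, stacklevel=2)

    out = {}
    means = {}
    for trait in TRAITS:
        y = raw[trait].to_numpy(float)
        fit = sm.OLS(y, X).fit()  # pinv -> minimum-norm under rank deficiency
        means[trait] = float(y.mean())
        out[f"{trait}_star"] = fit.resid + means[trait]
    return AdjustedPhenotypes(pd.DataFrame(out, index=ids), means)
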