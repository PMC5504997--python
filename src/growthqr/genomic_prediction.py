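"""GEBVs, quantile-specific genomic growth curves and marker ranking.

The genomic estimated breeding value of animal i at quantile tau is the
dosage-weighted sum of estimated marker effects, GEBV_i(tau) = x_i . beta_hat(tau),
computed per curve-parameter trait.  A genomic growth curve plugs the
GEBV-shifted parameters into the logistic model:

    y_hat_i(t) = (mu1 + u1_i) / (1 + exp(((mu2 + u2_i) - t) / (mu3 + u3_i)))

with mu_s the grand means of the corrected traits and u_si the GEBVs.
Confidence bands come from recomputing the mean curve over bootstrap
replicates of the marker effects and taking pointwise percentiles.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .data_io import GenotypePanel
from .growth_fit import TRAITS
from .rqr_core import BootstrapSummary, RQRFit

logger = logging.getLogger(__name__)

_SCALE_EPS = 1e-9  # |alpha3 + u3| below this is treated as a degenerate curve


class AlignmentError(ValueError):
    """Panel markers and fit coefficients do not line up."""


@dataclass(frozen=True)
class GEBVSet:
    """Per-animal genomic values for the three curve traits at one tau."""

    tau: float
    animal_ids: tuple[str, ...]
    values: pd.DataFrame  # index animal_id; columns u_alpha1, u_alpha2, u_alpha3

    def trait_vector(self, trait: str) -> np.ndarray:
        return self.values[f"u_{trait}"].to_numpy(float)


@dataclass(frozen=True)
class GenomicCurve:
    """Predicted weight trajectory at one tau, with optional bands."""

    tau: float
    ages: np.ndarray
    mean_curve: np.ndarray
    band_low: Optional[np.ndarray] = None
    band_high: Optional[np.ndarray] = None
    per_animal: Optional[np.ndarray] = None  # n_animals x n_ages


@dataclass(frozen=True)
class RankedMarkers:
    """Top markers by absolute effect for one (trait, tau)."""

    trait: str
    tau: float
    table: pd.DataFrame  # marker_id, effect_abs, se, p_value, chromosome, position_cM


def compute_gebv(panel: GenotypePanel, fits: Mapping[str, RQRFit]) -> GEBVSet:
    """GEBV_i = x_i . beta_hat per trait, for the fits of one quantile.

    ``fits`` maps trait name ("alpha1", "alpha2", "alpha3") to its RQRFit;
    all fits must share tau and align with the panel's marker order.
    """
    taus = {round(f.tau, 12) for f in fits.values()}
    if len(taus) != 1:
        raise ValueError(f"fits mix quantiles: {sorted(taus)}")
    X = panel.dosage_matrix()
    cols = {}
    for trait, fit in fits.items():
        if fit.beta_hat.size != panel.n_markers:
            raise AlignmentError(
                f"{trait}: fit has {fit.beta_hat.size} coefficients, panel has {panel.n_markers} markers"
            )
        if fit.marker_ids is not None and tuple(fit.marker_ids) != tuple(panel.marker_ids):
            raise AlignmentError(f"{trait}: marker order differs between fit and panel")
        cols[f"u_{trait}"] = X @ fit.beta_hat
    values = pd.DataFrame(cols, index=list(panel.animal_ids))
    return GEBVSet(tau=next(iter(fits.values())).tau, animal_ids=panel.animal_ids, values=values)


def genomic_curve(
    means: Mapping[str, float],
    gebvs: GEBVSet,
    ages: np.ndarray,
    keep_per_animal: bool = True,
) -> GenomicCurve:
    """Mean genomic growth curve from GEBV-shifted logistic parameters.

    ``means`` holds the grand means of the corrected traits.  Animals
    whose effective growth scale (mean + GEBV) is zero are excluded from
    the mean with a warning.
    """
    ages = np.asarray(ages, dtype=float)
    a1 = means["alpha1"] + gebvs.trait_vector("alpha1")
    a2 = means["alpha2"] + gebvs.trait_vector("alpha2")
    a3 = means["alpha3"] + gebvs.trait_vector("alpha3")
    ok = np.abs(a3) > _SCALE_EPS
    if not ok.all():
        logger.warning("excluding %d animals with zero effective growth scale", int((~ok).sum()))
    if not ok.any():
        raise ValueError("no animal has a nonzero effective growth scale")
    curves = a1[ok, None] / (1.0 + np.exp((a2[ok, None] - ages[None, :]) / a3[ok, None]))
    return GenomicCurve(
        tau=gebvs.tau,
        ages=ages,
        mean_curve=curves.mean(axis=0),
        per_animal=curves if keep_per_animal else None,
    )


def rank_markers(
    fit: RQRFit,
    boot: Optional[BootstrapSummary],
    marker_map: pd.DataFrame,
    fraction: float = 0.025,
    trait: str = "",
) -> RankedMarkers:
    """Top ceil(fraction * p) markers by |effect|, with map annotation.

    Ties in |effect| are broken toward the lower marker index.  The
    default fraction 0.025 yields 6 markers on a 237-marker panel.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    p = fit.beta_hat.size
    if p < 1:
        raise ValueError("fit has no markers to rank")
    ids = list(fit.marker_ids) if fit.marker_ids is not None else [f"m{k}" for k in range(p)]
    k_top = math.ceil(fraction * p)
    eff = np.abs(fit.beta_hat)
    order = np.lexsort((np.arange(p), -eff))  # by |effect| desc, index asc on ties
    top = order[:k_top]
    se = boot.se if boot is not None else np.full(p, np.nan)
    pv = boot.p_value if boot is not None else np.full(p, np.nan)
    rows = []
    for k in top:
        mid = ids[k]
        in_map = mid in marker_map.index
        rows.append({
            "marker_id": mid,
            "effect_abs": float(eff[k]),
            "se": float(se[k]),
            "p_value": float(pv[k]),
            "chromosome": marker_map.loc[mid, "chromosome"] if in_map else "",
            "position_cM": float(marker_map.loc[mid, "position_cM"]) if in_map else float("nan"),
        })
    table = pd.DataFrame(rows, columns=["marker_id", "effect_abs", "se", "p_value",
                                        "chromosome", "position_cM"])
    return RankedMarkers(trait=trait, tau=fit.tau, table=table)


def curve_confidence_band(
    boot_effects: Mapping[str, np.ndarray],
    panel: GenotypePanel,
    means: Mapping[str, float],
    ages: np.ndarray,
    level: float = 0.95,
    tau: float = 0.5,
) -> GenomicCurve:
    """Percentile bootstrap band for the mean genomic growth curve.

    ``boot_effects`` maps trait -> (reps x p) matrix of bootstrap effect
    replicates.  For each replicate the mean curve is recomputed; the band
    is the pointwise percentile interval over replicate mean curves at the
    given coverage (default 95%, i.e. the 2.5th and 97.5th percentiles).
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    reps = {t: np.atleast_2d(np.asarray(m, float)) for t, m in boot_effects.items()}
    n_rep = min(m.shape[0] for m in reps.values())
    if n_rep < 2:
        raise ValueError("need at least 2 bootstrap replicates per trait")
    ages = np.asarray(ages, dtype=float)
    X = panel.dosage_matrix()
    curves = np.empty((n_rep, ages.size))
    for r in range(n_rep):
        a1 = means["alpha1"] + X @ reps["alpha1"][r]
        a2 = means["alpha2"] + X @ reps["alpha2"][r]
        a3 = means["alpha3"] + X @ reps["alpha3"][r]
        ok = np.abs(a3) > _SCALE_EPS
        per = a1[ok, None] / (1.0 + np.exp((a2[ok, None] - ages[None, :]) / a3[ok, None]))
        curves[r] = per.mean(axis=0)
    lo_q, hi_q = 100.0 * (1.0 - level) / 2.0, 100.0 * (1.0 + level) / 2.0
    return GenomicCurve(
        tau=tau,
        ages=ages,
        mean_curve=curves.mean(axis=0),
        band_low=np.percentile(curves, lo_q, axis=0),
        band_high=np.percentile(curves, hi_q, axis=0),
    )


def traits() -> tuple[str, ...]:
    return TRAITS
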