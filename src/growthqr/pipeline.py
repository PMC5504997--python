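"""End-to-end orchestration: curves -> correction -> RQR -> prediction."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import genomic_prediction as gp
from . import growth_fit, rqr_core
from .data_io import Covariates, GenotypePanel, GrowthRecords, PipelineConfig

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    """Everything a full run produces, keyed by (trait, tau) where relevant."""

    adjusted: growth_fit.AdjustedPhenotypes
    curve_fits: list[growth_fit.CurveParams]
    fits: dict[tuple[str, float], rqr_core.RQRFit]
    lambdas: dict[tuple[str, float], float]
    capacity_tables: dict[tuple[str, float], object]
    boots: dict[tuple[str, float], rqr_core.BootstrapSummary] = field(default_factory=dict)
    ranked: dict[tuple[str, float], gp.RankedMarkers] = field(default_factory=dict)
    gebvs: dict[float, gp.GEBVSet] = field(default_factory=dict)
    curves: dict[float, gp.GenomicCurve] = field(default_factory=dict)
    bands: dict[float, gp.GenomicCurve] = field(default_factory=dict)


def run_pipeline(
    records: list[GrowthRecords],
    panel: GenotypePanel,
    covariates: Covariates,
    config: PipelineConfig,
    bootstrap: bool = True,
    bands: bool = False,
) -> PipelineResult:
    """Run the full two-step analysis under one configuration.

    Step one fits per-animal logistic curves and corrects the parameter
    estimates for fixed effects; step two selects the penalty and fits
    the regularized quantile regression per (trait, quantile), then
    computes bootstrap inference, marker rankings, GEBVs and genomic
    growth curves (with percentile bands when ``bands`` is set).
    """
    logger.info("pipeline seed=%d, %d animals, %d markers",
                config.seed, len(records), panel.n_markers)
    curve_fits = growth_fit.fit_all(records)
    adjusted = growth_fit.adjust_fixed_effects(curve_fits, covariates)

    # align the genotype matrix with the adjusted (converged) animals
    pos = {a: i for i, a in enumerate(panel.animal_ids)}
    rows = [pos[a] for a in adjusted.animal_ids]
    X = panel.dosage_matrix()[rows]

    result = PipelineResult(adjusted=adjusted, curve_fits=curve_fits,
                            fits={}, lambdas={}, capacity_tables={})
    for tau in config.quantiles:
        trait_fits = {}
        for s, trait in enumerate(growth_fit.TRAITS):
            y = adjusted.trait_vector(trait)
            lam, table, fit = rqr_core.select_lambda(
                y, X, tau, config.lambda_grid, marker_ids=panel.marker_ids)
            logger.info("trait=%s tau=%.2f: lambda=%g, pseudo-R1=%.3f",
                        trait, tau, lam, fit.pseudo_r1)
            key = (trait, tau)
            result.fits[key] = fit
            result.lambdas[key] = lam
            result.capacity_tables[key] = table
            trait_fits[trait] = fit
            if bootstrap:
                boot_seed = (config.seed * 1000 + s * 10 + int(round(tau * 10))) % (2**31)
                boot = rqr_core.bootstrap_effects(
                    y, X, tau, lam, reps=config.bootstrap_reps, seed=boot_seed)
                result.boots[key] = boot
                result.ranked[key] = gp.rank_markers(
                    fit, boot, panel.marker_map, config.top_fraction, trait=trait)
            else:
                result.ranked[key] = gp.rank_markers(
                    fit, None, panel.marker_map, config.top_fraction, trait=trait)
        gebvs = gp.compute_gebv(panel, trait_fits)
        result.gebvs[tau] = gebvs
        result.curves[tau] = gp.genomic_curve(adjusted.grand_means, gebvs, config.age_grid)
        if bands and bootstrap:
            reps = {t: result.boots[(t, tau)].replicates for t in growth_fit.TRAITS}
            result.bands[tau] = gp.curve_confidence_band(
                reps, panel, adjusted.grand_means, config.age_grid, tau=tau)
    return result
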