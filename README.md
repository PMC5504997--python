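# growthqr

Quantile-specific genomic analysis of animal growth curves.

Genomic growth curves are usually defined only at the population mean: a
nonlinear growth model is fitted per animal, and marker effects are then
estimated for the conditional *mean* of each curve parameter. `growthqr`
implements the quantile alternative for SNP panels on F2 livestock
populations: marker effects are estimated at chosen quantiles (say
τ = 0.2, 0.5, 0.8) of each growth-curve parameter, so low-, average- and
high-growth animals each get their own genomic growth curve, and the
markers that matter can differ between levels.

## The model

**Step 1 — growth curves.** For each animal *i*, weight at age *t* follows
the three-parameter logistic

    w_i(t) = α₁ᵢ / (1 + exp((α₂ᵢ − t) / α₃ᵢ)) + e_i(t)

with α₁ the mature weight (kg), α₂ the inflection age in days (where
w = α₁/2) and α₃ the growth scale in days (the distance on the age axis
between the inflection point and the age where w = α₁/(1+e⁻¹) ≈ 0.73·α₁).
The per-animal estimates are corrected for fixed effects (sex, lot,
halothane genotype) by OLS; the corrected trait is the residual plus the
overall mean.

**Step 2 — regularized quantile regression (RQR).** Each corrected trait
y is regressed on the SNP dosage matrix X (coded 2/1/0 for AA/Aa/aa) at
quantile τ by solving

    min over (μ, β) of  Σᵢ ρ_τ(yᵢ − μ − xᵢ·β) + λ Σₖ |βₖ|

where ρ_τ(u) = τu for u > 0 and −(1−τ)u otherwise (the check loss) and
the intercept μ is unpenalized. The problem is a linear program solved
exactly (HiGHS). λ is picked on a grid (default 0–50 by 0.5) by maximizing
predictive capacity, the Pearson correlation between fitted and observed
trait values. Goodness of fit is the quantile pseudo-R¹ = 1 − V_full/V_null,
and marker-effect uncertainty comes from a case bootstrap.

**Prediction.** GEBV_i(τ) = xᵢ·β̂(τ) per trait; a genomic growth curve
plugs the GEBV-shifted parameters into the logistic, and the top markers
by |effect| (default top 2.5%, i.e. 6 of a 237-SNP panel) are reported
with bootstrap p-values and map positions.

A built-in simulator generates F2-cross panels (founder lines fixed for
alternate alleles, Haldane recombination along six chromosomes with the
56/54/59/31/25/12 marker layout, 237 SNPs total) and logistic weight
trajectories at ages 0/21/42/63/77/105/150 d with age-increasing residual
spread, so the whole pipeline is testable without external data.

## Worked example

```sh
growthqr simulate --n-animals 345 --seed 1 --out data/
growthqr run \
  --phenotypes data/phenotypes.csv --genotypes data/genotypes.csv \
  --map data/map.csv --covariates data/covariates.csv \
  --tau 0.2 --tau 0.5 --tau 0.8 --lambda-grid 0:2:0.5 \
  --bootstrap 50 --top-fraction 0.025 --seed 1 --out report/
```

The same run from Python, on a small strong-signal simulation:

```python
import numpy as np, growthqr as gq

cfg = gq.default_strong_signal_config(n_animals=300, n_markers=100, seed=1)
panel = gq.simulate_genotypes(cfg)
records, cov, truth = gq.simulate_phenotypes(panel, cfg)
pc = gq.PipelineConfig(quantiles=(0.5,), lambda_grid=np.array([0.0, 0.5, 1.0, 2.0]),
                       top_fraction=0.06, seed=1)
res = gq.run_pipeline(records, panel, cov, pc, bootstrap=False)
print(res.lambdas[("alpha1", 0.5)])
print(res.fits[("alpha1", 0.5)].pseudo_r1)
print(res.ranked[("alpha1", 0.5)].table[["marker_id", "effect_abs"]].head(6))
```

prints

```
0.5
0.8963289265050737
  marker_id  effect_abs
0   C1_M061   16.041640
1   C1_M081   15.753459
2   C1_M041   12.962319
3   C1_M001   12.363997
4   C1_M021   11.450076
5   C1_M002    4.947929
```

λ = 0.5 was selected by predictive capacity; the pseudo-R¹ of 0.90 says
the penalized quantile fit removes ~90% of the check loss of the
intercept-only median; and the five simulated causal markers (effects of
15 kg/allele on mature weight at C1_M001/021/041/061/081) head the
ranking, well clear of the first null marker.

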