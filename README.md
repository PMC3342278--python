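# saltssd

Censored-data **species sensitivity distributions (SSDs)** for the salinity
tolerance of riverine macroinvertebrates.

Acute salinity tolerance is usually measured as a 72-h LC50 in electrical
conductivity (mS/cm).  Because species are exposed to a finite ladder of test
concentrations, many LC50 values are only known as an interval ("35–40") or a
right-censored bound (">30").  `saltssd` provides the full analysis chain for
such data:

- **`data_model`** — parse the three LC50 notations, convert µS/cm tables to
  mS/cm, map orders/classes to seven quasi-taxonomic groups, and merge
  duplicate taxa by censoring informativeness.
- **`km_ssd`** — Kaplan-Meier SSDs (interval values mid-point imputed, right
  values censored), restricted means with Greenwood-based 95% CIs, medians,
  and hazardous-concentration percentiles HC1/HC5/HC10/HC20 with the bound
  forms (`<x`, `a-b`, `>x`) a step estimator requires.
- **`comparisons`** — Mantel-Cox / Breslow / Tarone-Ware log-rank tests
  between regions or taxa, two-way ANOVA on √LC50 (Type-II SS, right-censored
  records excluded), CI-overlap letter displays, family/genus summaries.
- **`bayes_ssd`** — a hierarchical Bayesian model with *exact* censored
  likelihood: group means `μ_g ~ N(µ_hyper, τ²)` on the log10 scale, a shared
  within-group variance `σ²`, priors Inv-Gamma(0.001, 0.001) on `σ²`,
  N(0, 10⁶) on `µ_hyper`, Uniform(0, 10) on `τ`.  The ecologically weighted
  assemblage SSD is the richness-weighted mixture
  `F(x) = Σ_g w_g Φ((log₁₀x − μ_g)/σ)` per posterior draw, from which HCp
  medians and 95% credible intervals follow.
- **`representativeness`** — tested vs regional order-richness proportions:
  Pearson r, least-squares line, residuals from the identity line y = x.
- **`synthetic_data`** — a generator that mirrors the hierarchical model
  (hyper-population of group means, shared variance, richness-weighted group
  membership, ladder-induced censoring) plus parameter-recovery/coverage
  experiments.

## Worked example

Generate a synthetic 92-species assemblage under the default study
conditions, summarize its Kaplan-Meier SSD, and fit the weighted Bayesian
SSD:

```python
from saltssd import (AssemblageConfig, ModelSpec, WeightedSSD,
                     fit_hierarchical, generate_assemblage, km_table)

cfg = AssemblageConfig(seed=11)
records, truth = generate_assemblage(cfg)
print(km_table(records, hc=[5, 10, 20]).to_string(index=False))

spec = ModelSpec(seed=11, n_chains=4, n_iter=6000, n_burnin=3000)
post = fit_hierarchical(records, spec, groups=list(cfg.weights.weights))
print(WeightedSSD(post, cfg.weights).hc_table([1, 5, 50]).to_string(index=False))
```

prints

```
stratum  range_lo  range_hi      mean  mean_ci_lo  mean_ci_hi      median  ...  n_right_censored  n_total  HC5     HC10     HC20
Overall       7.5      55.0 32.078804   28.792993   35.364615 23.75-31.25  ...                16       92 <7.5 7.5-12.5 7.5-12.5

 p  hc_median     hc_lo     hc_hi
 1   5.419370  3.982286  6.912266
 5   8.450710  6.709860 10.255558
50  31.420094 28.085588 35.172037
```

Reading this: the nonparametric restricted mean of the tested sample is
32.1 mS/cm (95% CI 28.8–35.4); the KM median and low percentiles can only be
bracketed (`23.75-31.25`, `<7.5`) because the ladder of test concentrations
ties many species to the same interval.  The Bayesian model, which uses the
interval and right-censored records exactly and reweights the seven
quasi-taxonomic groups by regional species richness, estimates that 5% of the
assemblage would have its LC50 exceeded at 8.5 mS/cm (95% credible interval
6.7–10.3) — the HC5 used in salinity risk screening.

The same operations are exposed on the command line:

```sh
saltssd simulate --seed 11 --out synth.csv
saltssd km synth.csv --hc 5,10,20
saltssd logrank records.csv --by region --pairwise
saltssd bayes records.csv --weights richness.csv --seed 17 --out draws.csv
```

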