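# Methods

This note documents the statistical machinery in `saltssd`: the models and
their assumptions, the conventions adopted where several were defensible, the
numerical choices, and what the synthetic-data experiments do and do not
demonstrate.

## Data model

A toxicity record is one species' 72-h LC50 as electrical conductivity in
mS/cm, in one of three censoring states: a point value, an interval
`(lo, hi]` bracketed by two tested concentrations, or a right-censored bound
(the species survived the highest concentration tested).  Tables recorded in
µS/cm at 25 °C are divided by 1000 exactly once at load time; the unit is a
property of the table, so double conversion cannot occur downstream.

Orders and classes are pooled into seven quasi-taxonomic groups —
Coleoptera & Odonata, Crustaceans, Diptera & Hemiptera, Ephemeroptera,
Hydracarina, Non-arthropods, Trichoptera & Plecoptera — chosen because
tolerance distributions within each pool are broadly similar.  The bundled
lookup covers the orders and non-arthropod classes that occur in riverine
macroinvertebrate test data (including unambiguous subgroups such as
Gastropoda → Non-arthropods).  Lepidoptera and Megaloptera, each represented
by a single tested species in the source assemblages and never pooled into a
group, are loaded with `group=None` and excluded from group-level analyses
rather than assigned by us.

Duplicate (region, taxon) rows are merged to the most informative record:
narrower censoring wins (so `35–40` beats `>30`), ties keep the smaller
midpoint, and between two right-censored bounds the larger bound is kept.

## Kaplan-Meier SSDs

With right-censoring present, the empirical CDF is biased; the product-limit
estimator on the concentration axis is the standard nonparametric SSD.
Interval records are mid-point imputed *only* in this module and in the
frequentist comparisons (the Bayesian model uses the exact censored
likelihood).  Ties between an event and a censoring at the same value follow
the usual convention that the event occurs first.  The fit itself is
delegated to `lifelines`; Greenwood variances, the restricted mean, and the
quantile bound logic are computed in-module.

**Restricted mean.** The mean is the area under the survivor curve from 0 to
the largest observed or censoring value, whether or not that value is
censored; this is what standard survival packages report and it yields finite
means even under heavy right-censoring.  Its sampling variance is the
Greenwood-type formula `Σ_j A_j² d_j / (n_j (n_j − d_j))` with
`A_j = ∫_{t_j}^{τ} S`, and the CI is a normal approximation at a fixed 95%
level.  (The plug-in variance `2∫ t S dt − μ²` that some libraries return is
the population variance of the tolerance itself, not the sampling variance of
the mean, and is not used.)

**HCp percentiles.** The point estimate of HCp is the smallest support value
whose CDF reaches p/100.  Three bound forms handle what a step function
cannot localize: `<x` when even the first step exceeds p/100, `>x` when the
CDF never reaches p/100 (heavy censoring), and the interval form `a-b` when
the crossing jump carries two or more tied events — the situation ladder
testing produces constantly, since every species in one rung shares the same
imputed midpoint.  Published tables of this kind mix exact and bracketed
entries without stating a rule; the convention here (exact infimum unless the
crossing jump is a multi-event tie) reproduces both styles and is
deterministic.  The median CI is obtained by inverting the survivor
confidence band (log(−log) Greenwood bands), a choice flagged in output
metadata since other inversions exist.

## Frequentist comparisons

The Mantel-Cox log-rank statistic (all weights one) is the default
between-sample test because it carries the fewest assumptions; Breslow
(weight = number at risk) and Tarone-Ware (√at-risk) variants are available
and generally give different statistics on the same data.  The k-sample
statistic is referred to χ² with k − 1 df.  Degenerate inputs where every
value is tied across samples yield χ² = 0, p = 1.  No multiplicity correction
is applied to pairwise tables.

The parametric route is a fixed-effects ANOVA on √LC50 (the transform
improves normality/homoscedasticity for these data), with right-censored
records excluded and intervals mid-point imputed.  Because tested-species
layouts are unbalanced, Type-II sums of squares are used (reported in table
metadata).  Levels of the first factor with fewer than two usable values in
some crossing cell are dropped with a warning — mirroring the practice of
analysing sparse groups (e.g. crustaceans, water mites) separately with a
single-factor model.

Letter displays are computed from CI overlap: letters correspond to maximal
cliques of the interval-overlap graph (intervals have the Helly property, so
maximal cliques are exactly the sets of CIs sharing a point, found by a sweep
over left endpoints in ascending mean order).  Two estimates share a letter
iff their CIs overlap.

## Hierarchical Bayesian SSD

On the log10 scale each quasi-taxonomic group g has mean `μ_g` and the seven
means are exchangeable draws from a normal hyper-population
`N(µ_hyper, τ²)`; all groups share one within-group variance `σ²`.  Priors:
`σ² ~ Inv-Gamma(0.001, 0.001)`, `µ_hyper ~ N(0, 10⁶)`, `τ ~ Uniform(0, 10)`
(on the SD scale; τ² is derived).  No expert-elicited information enters the
priors.

The sampler is written in-repo because the censored hierarchical likelihood
is the heart of the method and must be testable against closed forms:

- **Data augmentation.** Each interval record's latent log10 LC50 is drawn
  from a normal truncated to `[log₁₀ lo, log₁₀ hi]`; each right-censored
  record from a normal truncated below at the bound (scipy's truncated
  normal, which is tail-stable).
- **Conjugate Gibbs updates** for `μ_g`, `µ_hyper`, `σ²`.
- **Slice sampling** (stepping-out with shrinkage) for τ under the bounded
  uniform prior; under the alternative Gamma-on-precision prior used for
  sensitivity checks the update is conjugate.
- **Empty groups.** A group present in the richness weights but absent from
  the data receives predictive draws `μ_g ~ N(µ_hyper, τ²)` — the direct
  consequence of exchangeability, and the mechanism that lets the weighted
  SSD cover untested groups.

Defaults are 4 chains of 20,000 iterations with 10,000 burn-in and no
thinning; a seed is mandatory and fixes all randomness (chains receive
independent streams and overdispersed starts spawned from it).
Initialization: group means at mid-point-imputed group averages, σ² at the
pooled variance, µ_hyper at the grand mean, τ at 1.  Split-R̂ and bulk ESS
(via ArviZ) are attached to every fit; `summary()` refuses to report when any
split-R̂ exceeds 1.05 unless forced.

**Weighted SSD and HCp.** Per draw, the assemblage SSD is
`F(x) = Σ_g w_g Φ((log₁₀x − μ_g)/σ)` with `w` the normalized regional
richness fractions.  HCp solves `F(x) = p/100` by vectorized bisection on the
log10 axis to 1e-10 (the mixture CDF is strictly increasing, so the root is
unique and monotone in p draw by draw); draws are summarized by the median
and central 95% credible interval.  Note that the posterior mean of τ² is
much larger than its median with only seven groups — the uniform prior on τ
leaves a heavy right tail that a point summary of τ² inherits; HCp summaries
are unaffected since they integrate over draws.

## Representativeness

If q% of a region's species belong to an order, a representative testing
program draws ≈ q% of tested species from it.  Regional and tested count
tables are aligned by case-folded order name, percentages are normalized
after any exclusions (so excluding an order equals recomputing on the reduced
table), and the module reports Pearson r (p-value via the t transform with
n − 2 df, the method not being stated in the published analyses), the
least-squares line on both the percentage and the raw-count scales (r is
scale-invariant, the slope is not), and per-order residuals from y = x.

## Synthetic data and what the experiments show

The generator is the model's own generative process: group means from
`N(µ_hyper, τ²)`, multinomial group membership by richness weights, latent
log10 LC50 `N(μ_g, σ²)`, and censoring by the fixed ladder
{2.5, 5, 10, 15, 20, 27.5, 35, 45, 55} mS/cm, which spans the observed
tolerance range (~2–78 mS/cm).  Latent values inside the ladder become
interval records, values above the top rung right-censored records, and —
because the data model has no left-censored kind — values below the lowest
rung (≲1% under defaults) a wide bottom interval `(0.025, 2.5]`.  Defaults
are the French study conditions: 92 species, `µ_hyper = 1.26`,
`τ² = 0.0868`, `σ² = 0.0517` (log10 mS/cm), and a Diptera-rich weight vector
(Diptera & Hemiptera 52%, Non-arthropods 6%, remaining fractions fixed
plausible values); an arid-zone weight set with the complementary profile is
provided for two-region comparisons.

Because the generator and the model share their structure, recovery and
coverage experiments validate *inference* (the sampler, the censored
likelihood, the interval calibration), not the model's adequacy for real
assemblages: real data add taxonomic misassignment, non-normal group
distributions, unequal group variances, and between-region heterogeneity
that the generator deliberately omits.  Passing coverage tests therefore
shows the machinery is correct under its own assumptions, nothing more.

Two subtleties the experiments respect: the mean of the latent values
converges to `µ_hyper` only at the rate `√(τ²Σw_g² + σ²/n)` — the group
means are drawn once per assemblage — and doubling σ widens the posterior
for data-rich group means but can *tighten* sparsely tested groups, whose
posteriors are dominated by pooling through a τ estimate that shrinks when
more spread is attributed to σ.

## Problem sizes

Test-suite fits use 2 chains × 1000–4000 iterations on assemblages of
80–200 species, sizes at which the conjugate/grid/permutation oracles have
Monte-Carlo error well below the asserted tolerances; the coverage check runs
100 replicates at 2 × 1000 iterations.  `scripts/acceptance.py` uses
4 chains × 6000 iterations for the headline fit and 40 replicates at
2 × 1000 for coverage.  All are the package's own desk-scale choices; the
model defaults (4 × 20,000) remain what production analyses should use.

## Known limitations

- No Turnbull NPMLE for interval censoring in the nonparametric module: the
  mid-point rule is deliberate there, the Bayesian module being the exact
  treatment.
- The KM median CI method (inverted survivor band) is one of several
  reasonable inversions.
- Group lookup is a fixed table; no taxonomic name resolution or synonymy.
- One shared σ² across groups and no covariates, by design.
- The τ² posterior is prior-sensitive in its upper tail with only seven
  exchangeable groups; sensitivity of HC5 to the τ prior is tested and small,
  but τ² point summaries should be read with care.
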