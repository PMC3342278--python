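"""Hierarchical Bayesian SSD with exact censored likelihood and ecological
weighting.

The model treats the seven quasi-taxonomic groups as exchangeable: on the
log10 conductivity scale each group g has its own mean LC50 mu_g drawn from
a normal hyper-population N(mu_hyper, tau^2), species within every group
share a single variance sigma^2, and each observed LC50 enters the
likelihood exactly as recorded — a point value, an interval, or a
right-censored bound — with no mid-point imputation.  Priors are
non-informative: Inverse-Gamma(0.001, 0.001) on sigma^2, N(0, 1e6) on
mu_hyper, and Uniform(0, 10) on the hyper-population SD tau.

Posterior sampling is a purpose-built MCMC: censored observations are
data-augmented with truncated-normal draws, mu_g / mu_hyper / sigma^2 have
conjugate Gibbs updates, and tau is updated by slice sampling under its
bounded uniform prior.  Exchangeability makes groups with no tested species
predictive: their mu_g is drawn from the hyper-population, which is what
lets the ecologically weighted assemblage SSD

    F(x) = sum_g w_g * Phi((log10 x - mu_g) / sigma)

cover every group in a region's richness table.  HCp values solve
F(x) = p/100 per posterior draw (bisection on the log10 axis), summarized
by the median and central 95% credible interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import arviz as az
from scipy import stats
from scipy.special import ndtr

from .data_model import GROUPS, RegionalWeights, ToxicityRecord

__all__ = [
    "ModelSpec",
    "HierarchicalPosterior",
    "WeightedSSD",
    "ConvergenceError",
    "fit_hierarchical",
    "weighted_hc",
    "hc_draws",
]


class ConvergenceError(RuntimeError):
    """Raised when chains have not mixed (split-R-hat above threshold)."""


@dataclass(frozen=True)
class ModelSpec:
    """Sampler configuration and prior choices.

    The prior defaults are the standard non-informative set described in the
    module docstring; ``hyper_sd_prior`` may be swapped for
    ``("gamma-precision", shape, rate)`` (a Gamma prior on 1/tau^2, giving a
    conjugate update) for prior-sensitivity checks.  ``fix_sigma2`` /
    ``fix_tau`` clamp a variance component to a constant, which reduces the
    model to closed-form conjugate cases used in validation.
    """

    seed: int
    n_chains: int = 4
    n_iter: int = 20_000
    n_burnin: int = 10_000
    thin: int = 1
    sigma2_prior: tuple[float, float] = (0.001, 0.001)  # inv-gamma shape, rate
    hyper_mean_prior: tuple[float, float] = (0.0, 1e6)  # mean, variance
    hyper_sd_prior: tuple = ("uniform", 0.0, 10.0)
    fix_sigma2: float | None = None
    fix_tau: float | None = None
    store_latent: bool = True

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is required")
        if self.n_iter <= self.n_burnin:
            raise ValueError("n_iter must exceed n_burnin")
        if self.thin < 1 or self.n_chains < 1:
            raise ValueError("thin and n_chains must be >= 1")
        if self.hyper_sd_prior[0] not in ("uniform", "gamma-precision"):
            raise ValueError(f"unknown hyper_sd_prior {self.hyper_sd_prior[0]!r}")


@dataclass
class HierarchicalPosterior:
    """MCMC draws from the hierarchical censored SSD model.

    Arrays are shaped (chains, draws[, groups]); ``latent`` holds the
    augmented log10 LC50 values of censored records (chains, draws,
    n_censored) when stored.
    """

    group_names: tuple[str, ...]
    mu: np.ndarray
    sigma2: np.ndarray
    mu_hyper: np.ndarray
    tau: np.ndarray
    spec: ModelSpec
    latent: np.ndarray | None = None
    censored_taxa: tuple[str, ...] = ()
    _diagnostics: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def tau2(self) -> np.ndarray:
        return self.tau**2

    @property
    def n_draws_total(self) -> int:
        return self.mu.shape[0] * self.mu.shape[1]

    def flat(self, name: str) -> np.ndarray:
        arr = getattr(self, name)
        return arr.reshape(-1, *arr.shape[2:])

    def diagnostics(self) -> pd.DataFrame:
        """Split-R-hat and bulk ESS per free parameter."""
        if self._diagnostics is not None:
            return self._diagnostics
        post: dict[str, np.ndarray] = {"mu": self.mu, "mu_hyper": self.mu_hyper}
        if self.spec.fix_sigma2 is None:
            post["sigma2"] = self.sigma2
        if self.spec.fix_tau is None:
            post["tau"] = self.tau
        idata = az.from_dict(posterior=post)
        rhat = az.rhat(idata)
        ess = az.ess(idata)
        rows = []
        for name in post:
            r = np.atleast_1d(rhat[name].values)
            e = np.atleast_1d(ess[name].values)
            labels = (
                [f"mu[{g}]" for g in self.group_names] if name == "mu" else [name]
            )
            for lbl, rv, ev in zip(labels, r, e):
                rows.append({"parameter": lbl, "rhat": float(rv), "ess_bulk": float(ev)})
        self._diagnostics = pd.DataFrame(rows)
        return self._diagnostics

    @property
    def max_rhat(self) -> float:
        return float(np.nanmax(self.diagnostics()["rhat"]))

    def summary(self, force: bool = False, rhat_threshold: float = 1.05) -> pd.DataFrame:
        """Posterior mean, SD and central 95% interval per parameter.

        Refuses to summarize unconverged chains unless ``force=True``.
        """
        if not force and self.max_rhat > rhat_threshold:
            raise ConvergenceError(
                f"split-R-hat {self.max_rhat:.3f} exceeds {rhat_threshold}; "
                "run longer chains or pass force=True"
            )
        rows = []
        named = {f"mu[{g}]": self.flat("mu")[:, i] for i, g in enumerate(self.group_names)}
        named["mu_hyper"] = self.flat("mu_hyper")
        named["sigma2"] = self.flat("sigma2")
        named["tau2"] = self.flat("tau2")
        for name, draws in named.items():
            lo, hi = np.percentile(draws, [2.5, 97.5])
            rows.append(
                {
                    "parameter": name,
                    "mean": float(draws.mean()),
                    "sd": float(draws.std(ddof=1)),
                    "ci_2.5%": float(lo),
                    "ci_97.5%": float(hi),
                }
            )
        return pd.DataFrame(rows)

    def to_dataframe(self) -> pd.DataFrame:
        """One row per draw, one column per parameter (audit-friendly CSV)."""
        cols = {f"mu[{g}]": self.flat("mu")[:, i] for i, g in enumerate(self.group_names)}
        cols["sigma2"] = self.flat("sigma2")
        cols["mu_hyper"] = self.flat("mu_hyper")
        cols["tau"] = self.flat("tau")
        n_per_chain = self.mu.shape[1]
        cols["chain"] = np.repeat(np.arange(self.mu.shape[0]), n_per_chain)
        cols["draw"] = np.tile(np.arange(n_per_chain), self.mu.shape[0])
        return pd.DataFrame(cols)


def _slice_sample_tau(tau: float, log_post, lo: float, hi: float, rng, w: float = 0.5) -> float:
    """One stepping-out + shrinkage slice-sampling update on (lo, hi)."""
    log_y = log_post(tau) - rng.exponential()
    left = max(lo, tau - w * rng.uniform())
    right = min(hi, left + w)
    while left > lo + 1e-12 and log_post(left) > log_y:
        left = max(lo, left - w)
    while right < hi - 1e-12 and log_post(right) > log_y:
        right = min(hi, right + w)
    for _ in range(1000):
        x = rng.uniform(left, right)
        if log_post(x) > log_y:
            return x
        if x < tau:
            left = x
        else:
            right = x
    return tau  # pathological shrinkage; keep current value


def fit_hierarchical(
    records: Sequence[ToxicityRecord],
    spec: ModelSpec,
    groups: Sequence[str] | None = None,
) -> HierarchicalPosterior:
    """Sample the posterior of the hierarchical censored SSD model.

    Parameters
    ----------
    records
        Censored LC50 records; those with ``group=None`` are skipped.  All
        values are converted to log10(mS/cm) internally.
    spec
        Sampler settings and priors.
    groups
        Group universe for the fit.  Defaults to the groups present in the
        data; pass the full list from a richness table to obtain predictive
        hyper-population draws for groups with no tested species.
    """
    usable = [r for r in records if r.group is not None]
    if not usable:
        raise ValueError("no records with an assigned quasi-group")
    if groups is None:
        group_names = tuple(g for g in GROUPS if any(r.group == g for r in usable))
    else:
        group_names = tuple(groups)
        for g in group_names:
            if g not in GROUPS:
                raise ValueError(f"unknown group {g!r}")
        dropped = {r.group for r in usable} - set(group_names)
        if dropped:
            raise ValueError(f"records present for groups outside the fit: {sorted(dropped)}")

    g_index = {g: i for i, g in enumerate(group_names)}
    G = len(group_names)
    N = len(usable)

    gi = np.array([g_index[r.group] for r in usable])
    lo = np.log10([r.lo for r in usable])
    hi = np.array([math.log10(r.hi) if math.isfinite(r.hi) else math.inf for r in usable])
    if not np.all(np.isfinite(lo)):
        raise ValueError("non-finite censoring bound")
    kinds = np.array([r.censor_kind for r in usable])
    cens = kinds != "point"
    cens_idx = np.nonzero(cens)[0]
    censored_taxa = tuple(usable[i].taxon for i in cens_idx)

    # counts per group (point and censored together)
    n_g = np.bincount(gi, minlength=G).astype(float)
    group_sum = np.zeros(G)

    m0, v0 = spec.hyper_mean_prior
    a0, b0 = spec.sigma2_prior
    sd_prior = spec.hyper_sd_prior

    n_keep = (spec.n_iter - spec.n_burnin) // spec.thin
    mu_out = np.empty((spec.n_chains, n_keep, G))
    sigma2_out = np.empty((spec.n_chains, n_keep))
    mu_hyper_out = np.empty((spec.n_chains, n_keep))
    tau_out = np.empty((spec.n_chains, n_keep))
    latent_out = (
        np.empty((spec.n_chains, n_keep, cens_idx.size)) if spec.store_latent else None
    )

    # mid-point initialization values (imputation is for initialization only;
    # the likelihood itself is exactly censored)
    y_init = np.where(cens, np.where(np.isfinite(hi), 0.5 * (lo + hi), lo + 0.3), lo)

    seed_seq = np.random.SeedSequence(spec.seed)
    chain_seeds = seed_seq.spawn(spec.n_chains)

    for c in range(spec.n_chains):
        rng = np.random.default_rng(chain_seeds[c])
        y = y_init.copy()
        mu = np.zeros(G)
        for g in range(G):
            mu[g] = y[gi == g].mean() if n_g[g] > 0 else y.mean()
        pooled = y.var() if N > 1 else 0.04
        sigma2 = spec.fix_sigma2 if spec.fix_sigma2 is not None else max(pooled, 1e-4)
        mu_hyper = y.mean()
        tau = spec.fix_tau if spec.fix_tau is not None else 1.0
        # overdispersed starts: jitter scales with chain index
        if c > 0:
            mu = mu + rng.normal(0, 0.1 * c, size=G)
            mu_hyper = mu_hyper + rng.normal(0, 0.1 * c)
            if spec.fix_tau is None:
                tau = min(9.0, tau * math.exp(rng.normal(0, 0.3)))

        keep = 0
        for it in range(spec.n_iter):
            sigma = math.sqrt(sigma2)
            # --- data augmentation: censored records -> truncated normals
            if cens_idx.size:
                loc = mu[gi[cens_idx]]
                a = (lo[cens_idx] - loc) / sigma
                b = np.where(
                    np.isfinite(hi[cens_idx]), (hi[cens_idx] - loc) / sigma, np.inf
                )
                y[cens_idx] = stats.truncnorm.rvs(
                    a, b, loc=loc, scale=sigma, random_state=rng
                )
            # --- group means (conjugate); empty groups are predictive
            group_sum[:] = np.bincount(gi, weights=y, minlength=G)
            tau2 = tau * tau
            prec = n_g / sigma2 + 1.0 / tau2
            mean = (group_sum / sigma2 + mu_hyper / tau2) / prec
            mu = mean + rng.standard_normal(G) / np.sqrt(prec)
            empty = n_g == 0
            if empty.any():
                mu[empty] = mu_hyper + tau * rng.standard_normal(int(empty.sum()))
            # --- hyper-mean (conjugate)
            prec_h = G / tau2 + 1.0 / v0
            mean_h = (mu.sum() / tau2 + m0 / v0) / prec_h
            mu_hyper = mean_h + rng.standard_normal() / math.sqrt(prec_h)
            # --- shared within-group variance (conjugate inverse-gamma)
            if spec.fix_sigma2 is None:
                ss = float(np.sum((y - mu[gi]) ** 2))
                sigma2 = 1.0 / rng.gamma(a0 + 0.5 * N, 1.0 / (b0 + 0.5 * ss))
            # --- hyper-population SD
            if spec.fix_tau is None:
                s_mu = float(np.sum((mu - mu_hyper) ** 2))
                if sd_prior[0] == "uniform":
                    t_lo, t_hi = sd_prior[1], sd_prior[2]

                    def log_post(t: float) -> float:
                        if not t_lo < t < t_hi:
                            return -math.inf
                        return -G * math.log(t) - s_mu / (2.0 * t * t)

                    tau = _slice_sample_tau(tau, log_post, max(t_lo, 1e-6), t_hi, rng)
                else:  # gamma prior on the precision 1/tau^2 -> conjugate
                    shape, rate = sd_prior[1], sd_prior[2]
                    tau2_new = 1.0 / rng.gamma(
                        shape + 0.5 * G, 1.0 / (rate + 0.5 * s_mu)
                    )
                    tau = math.sqrt(tau2_new)

            if it >= spec.n_burnin and (it - spec.n_burnin) % spec.thin == 0:
                mu_out[c, keep] = mu
                sigma2_out[c, keep] = sigma2
                mu_hyper_out[c, keep] = mu_hyper
                tau_out[c, keep] = tau
                if latent_out is not None:
                    latent_out[c, keep] = y[cens_idx]
                keep += 1

    return HierarchicalPosterior(
        group_names=group_names,
        mu=mu_out,
        sigma2=sigma2_out,
        mu_hyper=mu_hyper_out,
        tau=tau_out,
        spec=spec,
        latent=latent_out,
        censored_taxa=censored_taxa,
    )


def _aligned_weights(posterior: HierarchicalPosterior, weights: RegionalWeights) -> np.ndarray:
    missing = [g for g in posterior.group_names if g not in weights.weights]
    if missing:
        raise ValueError(f"weights missing groups in the posterior: {missing}")
    extra = [g for g in weights.weights if g not in posterior.group_names and weights.weights[g] > 0]
    if extra:
        raise ValueError(
            f"weights include groups absent from the posterior: {extra}; "
            "refit with groups=list(weights.weights) to obtain predictive draws"
        )
    w = np.array([weights.weights[g] for g in posterior.group_names])
    return w / w.sum()


def _mixture_cdf(z: np.ndarray, mu: np.ndarray, sigma: np.ndarray, w: np.ndarray) -> np.ndarray:
    # z: (draws,), mu: (draws, G), sigma: (draws,), w: (G,)
    return ndtr((z[:, None] - mu) / sigma[:, None]) @ w


def hc_draws(
    posterior: HierarchicalPosterior,
    weights: RegionalWeights,
    p: float,
    tol: float = 1e-10,
) -> np.ndarray:
    """Per-draw HCp (mS/cm) of the weighted mixture SSD.

    Solves sum_g w_g Phi((z - mu_g)/sigma) = p/100 for z = log10 x by
    vectorized bisection to ``tol`` on the log10 axis.
    """
    if not 0 < p < 100:
        raise ValueError("p must be in (0, 100)")
    w = _aligned_weights(posterior, weights)
    mu = posterior.flat("mu")
    sigma = np.sqrt(posterior.flat("sigma2"))
    q = p / 100.0
    z_lo = (mu.min(axis=1) - 12.0 * sigma) - 1.0
    z_hi = (mu.max(axis=1) + 12.0 * sigma) + 1.0
    n_iter = int(np.ceil(np.log2((z_hi - z_lo).max() / tol))) + 1
    for _ in range(n_iter):
        z_mid = 0.5 * (z_lo + z_hi)
        below = _mixture_cdf(z_mid, mu, sigma, w) < q
        z_lo = np.where(below, z_mid, z_lo)
        z_hi = np.where(below, z_hi, z_mid)
    return 10.0 ** (0.5 * (z_lo + z_hi))


def weighted_hc(
    posterior: HierarchicalPosterior,
    weights: RegionalWeights,
    p: float,
    level: float = 0.95,
) -> tuple[float, float, float]:
    """Posterior median and central credible interval of HCp (mS/cm)."""
    draws = hc_draws(posterior, weights, p)
    alpha = 100 * (1 - level) / 2
    lo, med, hi = np.percentile(draws, [alpha, 50, 100 - alpha])
    return float(med), float(lo), float(hi)


@dataclass(frozen=True)
class WeightedSSD:
    """Ecologically weighted assemblage SSD over posterior draws.

    The CDF at concentration x is the potentially affected fraction (PAF):
    the richness-weighted mixture of group-level log10-normal CDFs, one
    value per posterior draw.
    """

    posterior: HierarchicalPosterior
    weights: RegionalWeights

    def cdf(self, x: float) -> np.ndarray:
        """Per-draw PAF at concentration x (mS/cm)."""
        if x <= 0:
            raise ValueError("concentration must be positive")
        w = _aligned_weights(self.posterior, self.weights)
        mu = self.posterior.flat("mu")
        sigma = np.sqrt(self.posterior.flat("sigma2"))
        z = np.full(mu.shape[0], math.log10(x))
        return _mixture_cdf(z, mu, sigma, w)

    def paf_band(self, xs: Sequence[float], level: float = 0.95) -> pd.DataFrame:
        """Median PAF curve with a pointwise credible band."""
        alpha = 100 * (1 - level) / 2
        rows = []
        for x in xs:
            draws = self.cdf(float(x))
            lo, med, hi = np.percentile(draws, [alpha, 50, 100 - alpha])
            rows.append({"x": float(x), "paf_lo": lo, "paf_median": med, "paf_hi": hi})
        return pd.DataFrame(rows)

    def hc(self, p: float, level: float = 0.95) -> tuple[float, float, float]:
        return weighted_hc(self.posterior, self.weights, p, level=level)

    def hc_table(self, ps: Sequence[float] = (1, 5, 10, 20, 50), level: float = 0.95) -> pd.DataFrame:
        rows = []
        for p in ps:
            med, lo, hi = self.hc(p, level=level)
            rows.append({"p": p, "hc_median": med, "hc_lo": lo, "hc_hi": hi})
        return pd.DataFrame(rows)
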