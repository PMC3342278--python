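"""Kaplan-Meier species sensitivity distributions and HCp percentiles.

With right-censored LC50 values present (species that survived the highest
test concentration), the empirical CDF is biased; the product-limit
(Kaplan-Meier) estimator is the standard nonparametric fix.  Here the "time"
axis is conductivity (mS/cm) and the "event" is a species' LC50 being
reached, so the KM CDF is the species sensitivity distribution and its p-th
percentile is the hazardous concentration HCp.

Interval-censored values are mid-point imputed before estimation (the
mid-point rule); the hierarchical Bayesian module handles them exactly
instead.  Means are restricted means: the area under the survivor curve up
to the largest observed or censored value, with a Greenwood-based normal
confidence interval.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats

from .data_model import ToxicityRecord

__all__ = ["KMCurve", "HCEstimate", "MeanCI", "km_fit", "km_mean_ci", "km_quantile", "km_table"]


@dataclass(frozen=True)
class HCEstimate:
    """A hazardous-concentration percentile, possibly only bounded.

    ``bound_kind``:

    - ``exact`` — the percentile is a support value,
    - ``below_min`` — the first KM step already exceeds p/100 (``"<x"``),
    - ``interval`` — the crossing step carries tied events, so the percentile
      is only located within a jump (``"a-b"``),
    - ``above_max`` — the KM CDF never reaches p/100 (``">x"``).
    """

    p: float
    value: float
    bound_kind: str = "exact"
    lo: float = math.nan
    hi: float = math.nan
    ci_lo: float = math.nan
    ci_hi: float = math.nan

    def __str__(self) -> str:
        if self.bound_kind == "below_min":
            return f"<{self.value:g}"
        if self.bound_kind == "above_max":
            return f">{self.value:g}"
        if self.bound_kind == "interval":
            return f"{self.lo:g}-{self.hi:g}"
        return f"{self.value:g}"


@dataclass(frozen=True)
class MeanCI:
    """Restricted mean with a normal-approximation confidence interval."""

    mean: float
    ci_lo: float
    ci_hi: float
    level: float = 0.95
    is_lower_bound: bool = False


@dataclass
class KMCurve:
    """Stepwise SSD (CDF form) from the product-limit estimator.

    ``support`` holds the distinct event values; ``cdf`` the estimated
    fraction of species with LC50 ≤ value; ``greenwood_var`` the Greenwood
    variance of the survivor estimate at each support point.
    """

    support: np.ndarray
    cdf: np.ndarray
    greenwood_var: np.ndarray
    n_event: np.ndarray
    n_censored: np.ndarray
    n_at_risk: np.ndarray
    largest_obs: float
    largest_is_censored: bool
    n_total: int
    all_censored: bool = False
    _durations: np.ndarray = field(repr=False, default=None)
    _events: np.ndarray = field(repr=False, default=None)
    _kmf: KaplanMeierFitter = field(repr=False, default=None)

    @property
    def survival(self) -> np.ndarray:
        return 1.0 - self.cdf


def _to_durations(records: Sequence[ToxicityRecord]) -> tuple[np.ndarray, np.ndarray]:
    # mid-point rule for intervals; right records enter censored at the bound
    durations = np.array([r.midpoint for r in records], dtype=float)
    events = np.array([0 if r.is_right_censored else 1 for r in records], dtype=int)
    return durations, events


def km_fit(records: Sequence[ToxicityRecord]) -> KMCurve:
    """Fit the product-limit SSD to censored records.

    Ties between an event and a censoring at the same value follow the
    standard convention: the event happens first, so the censored record is
    still at risk at that value.
    """
    records = list(records)
    if not records:
        raise ValueError("km_fit requires at least one record")
    durations, events = _to_durations(records)

    if events.sum() == 0:
        warnings.warn("all records are right-censored; KM CDF is identically 0")
        largest = float(durations.max())
        return KMCurve(
            support=np.array([]),
            cdf=np.array([]),
            greenwood_var=np.array([]),
            n_event=np.array([], dtype=int),
            n_censored=np.array([], dtype=int),
            n_at_risk=np.array([], dtype=int),
            largest_obs=largest,
            largest_is_censored=True,
            n_total=len(records),
            all_censored=True,
            _durations=durations,
            _events=events,
        )

    kmf = KaplanMeierFitter()
    kmf.fit(durations, event_observed=events)
    table = kmf.event_table  # indexed by value: removed, observed, censored, at_risk
    ev = table[table["observed"] > 0]
    support = ev.index.to_numpy(dtype=float)
    surv = kmf.survival_function_.loc[support, "KM_estimate"].to_numpy(dtype=float)

    # Greenwood: Var[S(t)] = S(t)^2 * sum_{t_i<=t} d_i / (n_i (n_i - d_i))
    d = ev["observed"].to_numpy(dtype=float)
    n = ev["at_risk"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(n > d, d / (n * (n - d)), np.inf)
    gw = surv**2 * np.cumsum(terms)
    gw = np.where(np.isfinite(gw), gw, 0.0)  # S=0 at the last event => variance 0

    cens_at = table["censored"].reindex(ev.index).to_numpy(dtype=float)
    largest = float(durations.max())
    largest_censored = bool((events[durations == durations.max()] == 0).all())
    return KMCurve(
        support=support,
        cdf=1.0 - surv,
        greenwood_var=gw,
        n_event=d.astype(int),
        n_censored=cens_at.astype(int),
        n_at_risk=n.astype(int),
        largest_obs=largest,
        largest_is_censored=largest_censored,
        n_total=len(records),
        _durations=durations,
        _events=events,
        _kmf=kmf,
    )


def km_mean_ci(curve: KMCurve, level: float = 0.95) -> MeanCI:
    """Restricted mean of the SSD with a normal-approximation CI.

    The mean is the area under the survivor function from 0 to the largest
    observed or censoring value tau; its sampling variance is the
    Greenwood-type restricted-mean formula

        Var = sum_j A_j^2 * d_j / (n_j (n_j - d_j)),   A_j = int_{t_j}^{tau} S,

    summed over event values.  For an all-censored curve the mean can only
    be bounded below by that largest value.
    """
    if curve.all_censored:
        return MeanCI(
            mean=curve.largest_obs,
            ci_lo=curve.largest_obs,
            ci_hi=math.inf,
            level=level,
            is_lower_bound=True,
        )
    t = curve.support
    s = curve.survival
    tau = curve.largest_obs
    # step areas: S is 1 on [0, t_1), s[j] on [t_{j+1}, t_{j+2}) ... up to tau
    edges = np.concatenate([[0.0], t, [tau]])
    s_steps = np.concatenate([[1.0], s])
    widths = np.diff(edges)
    areas = s_steps * widths  # area of each step piece
    rmst = float(areas.sum())
    # A_j: remaining area strictly after event value t_j
    tail_after = np.concatenate([np.cumsum(areas[::-1])[::-1], [0.0]])[1:]
    d = curve.n_event.astype(float)
    n = curve.n_at_risk.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(n > d, d / (n * (n - d)), 0.0)
    var = float(np.sum(tail_after[: len(d)] ** 2 * terms))
    z = stats.norm.ppf(0.5 + level / 2)
    se = math.sqrt(max(var, 0.0))
    return MeanCI(mean=rmst, ci_lo=rmst - z * se, ci_hi=rmst + z * se, level=level)


def _invert_cdf_band(curve: KMCurve, band_cdf: np.ndarray, q: float) -> float:
    idx = np.nonzero(band_cdf >= q - 1e-12)[0]
    return float(curve.support[idx[0]]) if idx.size else math.nan


def km_quantile(curve: KMCurve, p: float, level: float = 0.95) -> HCEstimate:
    """HCp: the p-th percentile of the KM species sensitivity distribution.

    The point estimate is the smallest support value whose CDF reaches
    p/100.  Bound forms are returned when the step function cannot locate
    the percentile: ``"<x"`` when even the first step exceeds p/100,
    ``"a-b"`` when the crossing jump carries two or more tied events, and
    ``">x"`` when the CDF never reaches p/100 (heavy right-censoring).  For
    the median, a CI is attached by inverting the survivor confidence band.
    """
    if not 0 < p < 100:
        raise ValueError("p must be in (0, 100)")
    q = p / 100.0
    if curve.all_censored or curve.cdf.size == 0 or curve.cdf[-1] < q - 1e-12:
        return HCEstimate(p=p, value=curve.largest_obs, bound_kind="above_max")
    if curve.cdf[0] > q + 1e-12:
        return HCEstimate(p=p, value=float(curve.support[0]), bound_kind="below_min")

    k = int(np.nonzero(curve.cdf >= q - 1e-12)[0][0])
    value = float(curve.support[k])

    ci_lo = ci_hi = math.nan
    if abs(p - 50.0) < 1e-9 and curve._kmf is not None:
        ci = curve._kmf.confidence_interval_survival_function_
        band = ci.loc[ci.index.isin(curve.support)]
        upper_cdf = 1.0 - band.iloc[:, 0].to_numpy(dtype=float)  # from lower survivor
        lower_cdf = 1.0 - band.iloc[:, 1].to_numpy(dtype=float)
        hi_cdf = np.maximum(upper_cdf, lower_cdf)
        lo_cdf = np.minimum(upper_cdf, lower_cdf)
        ci_lo = _invert_cdf_band(curve, hi_cdf, q)
        ci_hi = _invert_cdf_band(curve, lo_cdf, q)

    # interval form only when the crossing jump is a multi-event tie and the
    # target quantile falls strictly inside it
    prev_cdf = curve.cdf[k - 1] if k > 0 else 0.0
    strictly_inside = prev_cdf < q - 1e-12 and curve.cdf[k] > q + 1e-12
    if strictly_inside and curve.n_event[k] >= 2 and k > 0:
        return HCEstimate(
            p=p,
            value=value,
            bound_kind="interval",
            lo=float(curve.support[k - 1]),
            hi=value,
            ci_lo=ci_lo,
            ci_hi=ci_hi,
        )
    return HCEstimate(p=p, value=value, bound_kind="exact", ci_lo=ci_lo, ci_hi=ci_hi)


def km_table(
    records: Sequence[ToxicityRecord],
    by: str | None = None,
    hc: Iterable[float] = (1, 5, 10, 20),
    level: float = 0.95,
) -> pd.DataFrame:
    """Summary table of KM SSDs: range, restricted mean and median with CIs,
    HCp columns and censoring counts, optionally stratified by a record field
    (``"region"``, ``"group"``, ``"abundance"`` or ``"order_or_class"``).
    """
    records = list(records)
    if by is None:
        strata = {"Overall": records}
    else:
        strata = {}
        for r in records:
            key = getattr(r, by)
            if key is None:
                continue
            strata.setdefault(key, []).append(r)
    rows = []
    hc = list(hc)
    for label in sorted(strata):
        recs = strata[label]
        curve = km_fit(recs)
        mean = km_mean_ci(curve, level=level)
        median = km_quantile(curve, 50, level=level)
        mids = [r.midpoint for r in recs]
        n_right = sum(r.is_right_censored for r in recs)
        row = {
            by or "stratum": label,
            "range_lo": min(mids),
            "range_hi": max(mids),
            "mean": mean.mean,
            "mean_ci_lo": mean.ci_lo,
            "mean_ci_hi": mean.ci_hi,
            "median": str(median),
            "median_ci_lo": median.ci_lo,
            "median_ci_hi": median.ci_hi,
            "n_point_interval": len(recs) - n_right,
            "n_right_censored": n_right,
            "n_total": len(recs),
        }
        for p in hc:
            row[f"HC{p:g}"] = str(km_quantile(curve, p))
        rows.append(row)
    return pd.DataFrame(rows)
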