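"""Group comparisons between SSDs: weighted log-rank tests, square-root
transformed ANOVA, confidence-interval letter displays and per-rank summary
tables.

The log-rank family compares product-limit SSDs between regions or taxa
without distributional assumptions; the Mantel-Cox weighting (all weights 1)
is the default, with Breslow (generalized Wilcoxon, weight = number at risk)
and Tarone-Ware (weight = sqrt of number at risk) variants.  The parametric
route is a fixed-effects ANOVA on sqrt-transformed LC50 values with
right-censored records excluded.
"""

from __future__ import annotations

import itertools
import math
import string
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from lifelines.statistics import multivariate_logrank_test

from .data_model import ToxicityRecord
from .km_ssd import _to_durations

__all__ = [
    "LogRankResult",
    "logrank_test",
    "pairwise_logrank",
    "anova_sqrt",
    "ci_letter_groups",
    "summarize_by_rank",
]

_WEIGHT_SCHEMES = {
    "mantel-cox": None,
    "breslow": "wilcoxon",  # Gehan-Breslow generalized Wilcoxon
    "tarone-ware": "tarone-ware",
}


@dataclass(frozen=True)
class LogRankResult:
    chi2: float
    df: int
    p_value: float
    weight_scheme: str = "mantel-cox"

    def __post_init__(self) -> None:
        assert self.chi2 >= 0 and 0 <= self.p_value <= 1


def logrank_test(
    samples: Sequence[Sequence[ToxicityRecord]],
    weight_scheme: str = "mantel-cox",
) -> LogRankResult:
    """k-sample weighted log-rank test between censored SSD samples.

    Interval records are mid-point imputed and right records enter censored,
    exactly as in the KM fits being compared.  The statistic is referred to
    a chi-square distribution with k-1 degrees of freedom.
    """
    if weight_scheme not in _WEIGHT_SCHEMES:
        raise ValueError(f"unknown weight_scheme {weight_scheme!r}")
    if len(samples) < 2:
        raise ValueError("need at least two samples")
    for i, s in enumerate(samples):
        if len(s) == 0:
            raise ValueError(f"sample {i} has zero records")

    durations, events, groups = [], [], []
    for i, s in enumerate(samples):
        d, e = _to_durations(s)
        durations.append(d)
        events.append(e)
        groups.append(np.full(len(s), i))
    durations = np.concatenate(durations)
    events = np.concatenate(events)
    groups = np.concatenate(groups)
    df = len(samples) - 1

    res = multivariate_logrank_test(
        durations, groups, events, weightings=_WEIGHT_SCHEMES[weight_scheme]
    )
    chi2 = float(res.test_statistic)
    p = float(res.p_value)
    if not math.isfinite(chi2):
        # degenerate case: no between-sample variance (e.g. all values tied)
        chi2, p = 0.0, 1.0
    return LogRankResult(chi2=chi2, df=df, p_value=p, weight_scheme=weight_scheme)


def pairwise_logrank(
    samples: Mapping[str, Sequence[ToxicityRecord]],
    weight_scheme: str = "mantel-cox",
) -> pd.DataFrame:
    """All pairwise two-sample log-rank tests; no multiplicity correction."""
    rows = []
    for a, b in itertools.combinations(sorted(samples), 2):
        res = logrank_test([samples[a], samples[b]], weight_scheme=weight_scheme)
        rows.append({"sample_a": a, "sample_b": b, "chi2": res.chi2, "df": res.df, "p_value": res.p_value})
    return pd.DataFrame(rows)


def _usable_frame(records: Iterable[ToxicityRecord]) -> pd.DataFrame:
    rows = [
        {"value": r.midpoint, "group": r.group, "region": r.region}
        for r in records
        if not r.is_right_censored
    ]
    df = pd.DataFrame(rows)
    if not df.empty:
        df["sqrt_value"] = np.sqrt(df["value"])
    return df


def anova_sqrt(
    records: Sequence[ToxicityRecord],
    factors: Sequence[str] = ("group", "region"),
    min_per_cell: int = 2,
) -> pd.DataFrame:
    """Fixed-effects ANOVA on sqrt(LC50), right-censored records excluded.

    Two factors give the full factorial with interaction; Type-II sums of
    squares are used because the tested-species layouts are unbalanced.
    Levels of the first factor with fewer than ``min_per_cell`` usable values
    in any crossing cell are dropped with a warning (single-factor: levels
    with fewer than ``min_per_cell`` values overall).  Returns the ANOVA
    table with sum_sq, df, F and PR(>F) per term.
    """
    factors = list(factors)
    if not 1 <= len(factors) <= 2 or any(f not in ("group", "region") for f in factors):
        raise ValueError("factors must be one or two of: group, region")
    df = _usable_frame(records)
    df = df.dropna(subset=factors)
    if df.empty:
        raise ValueError("no usable (non-right-censored) records")

    if len(factors) == 1:
        f0 = factors[0]
        counts = df.groupby(f0)["value"].count()
        bad = counts[counts < min_per_cell].index.tolist()
    else:
        f0, f1 = factors
        cell = df.groupby([f0, f1])["value"].count().unstack(fill_value=0)
        bad = cell.index[(cell < min_per_cell).any(axis=1)].tolist()
    if bad:
        warnings.warn(f"dropping {factors[0]} levels with <{min_per_cell} usable values: {sorted(bad)}")
        df = df[~df[factors[0]].isin(bad)]
    if df[factors[0]].nunique() < 2:
        raise ValueError("fewer than two usable factor levels remain")

    if len(factors) == 1:
        formula = f"sqrt_value ~ C({factors[0]})"
    else:
        formula = f"sqrt_value ~ C({factors[0]}) * C({factors[1]})"
    model = smf.ols(formula, data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    table.attrs["ss_type"] = 2
    table.attrs["transform"] = "sqrt"
    table.attrs["dropped_levels"] = sorted(bad)
    return table


def ci_letter_groups(
    estimates: Sequence[tuple[str, float, float, float]],
) -> dict[str, set[str]]:
    """Compact letter display from confidence-interval overlap.

    Two estimates share at least one letter iff their CIs overlap; letters
    are assigned to maximal cliques of the interval-overlap graph, swept in
    ascending order of mean.  Input rows are (label, mean, ci_lo, ci_hi).
    """
    if not estimates:
        return {}
    for label, mean, lo, hi in estimates:
        if not (math.isfinite(lo) and math.isfinite(hi)):
            raise ValueError(f"non-finite CI for {label!r}")
        if lo > hi:
            raise ValueError(f"inverted CI for {label!r}")
    order = sorted(range(len(estimates)), key=lambda i: estimates[i][1])
    # intervals have the Helly property: every maximal clique is the set of
    # intervals containing some point, and each clique is witnessed at the
    # left endpoint of one of its members
    cliques: list[frozenset[int]] = []
    for i in order:
        x = estimates[i][2]
        clique = frozenset(
            j for j, (_, _, lo, hi) in enumerate(estimates) if lo <= x <= hi
        )
        if not any(clique <= c for c in cliques):
            cliques = [c for c in cliques if not c <= clique] + [clique]
    cliques.sort(key=lambda c: min(estimates[j][1] for j in c))
    letters = list(string.ascii_lowercase) + [
        a + b for a, b in itertools.product(string.ascii_lowercase, repeat=2)
    ]
    out: dict[str, set[str]] = {label: set() for label, *_ in estimates}
    for letter, clique in zip(letters, cliques):
        for j in clique:
            out[estimates[j][0]].add(letter)
    return out


def summarize_by_rank(
    records: Sequence[ToxicityRecord],
    rank_labels: Mapping[str, str],
    by_region: bool = True,
) -> pd.DataFrame:
    """Mean/SD/count of non-right-censored LC50 values per rank label.

    ``rank_labels`` maps taxon name to a family or genus label (a formatting
    pass over loaded records; taxa without a label are skipped).  Interval
    records contribute their mid-points; right-censored records are
    excluded, as in the family/genus summary tables.
    """
    rows = []
    for r in records:
        if r.is_right_censored:
            continue
        label = rank_labels.get(r.taxon)
        if label is None:
            continue
        rows.append({"rank": label, "region": r.region, "value": r.midpoint})
    if not rows:
        return pd.DataFrame(columns=["rank", "region", "mean", "sd", "n"])
    df = pd.DataFrame(rows)
    keys = ["rank", "region"] if by_region else ["rank"]
    out = (
        df.groupby(keys)["value"]
        .agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count")
        .reset_index()
    )
    return out
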