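"""Is the tested species pool representative of regional order richness?

If q% of a region's species belong to an order, a representative testing
program would draw ≈ q% of its tested species from that order, so the
(regional %, tested %) pairs should scatter around the identity line y = x.
This module aligns a regional richness table with a tested-species table,
computes the Pearson correlation, the least-squares line, and each order's
residual from the identity line.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["RepresentativenessResult", "representativeness_fit"]


@dataclass(frozen=True)
class RepresentativenessResult:
    """Correlation and regression of tested vs regional order proportions.

    ``slope``/``intercept`` are fitted on the percentage pairs; the
    counts-scale fit is also reported since r is identical on either scale
    but the line is not.  ``table`` carries per-order counts, percentages
    and residuals from the identity line (tested% - regional%).
    """

    r: float
    p_value: float
    slope: float
    intercept: float
    slope_counts: float
    intercept_counts: float
    table: pd.DataFrame
    n_orders: int


def _align(
    regional: Mapping[str, float],
    tested: Mapping[str, float],
    exclude: Iterable[str] | None,
) -> pd.DataFrame:
    def fold(m: Mapping[str, float]) -> dict[str, tuple[str, float]]:
        out: dict[str, tuple[str, float]] = {}
        for k, v in m.items():
            key = str(k).strip().casefold()
            if v < 0:
                raise ValueError(f"negative count for order {k!r}")
            if key in out:
                out[key] = (out[key][0], out[key][1] + float(v))
            else:
                out[key] = (str(k).strip(), float(v))
        return out

    reg = fold(regional)
    tst = fold(tested)
    excl = {str(e).strip().casefold() for e in (exclude or ())}
    rows = []
    for key in sorted(set(reg) | set(tst)):
        if key in excl:
            continue
        name = (reg.get(key) or tst.get(key))[0]
        rows.append(
            {
                "order": name,
                "regional_species_count": reg.get(key, (None, 0.0))[1],
                "tested_species_count": tst.get(key, (None, 0.0))[1],
            }
        )
    return pd.DataFrame(rows)


def representativeness_fit(
    regional_counts: Mapping[str, float],
    tested_counts: Mapping[str, float],
    exclude: Iterable[str] | None = None,
) -> RepresentativenessResult:
    """Fit tested vs regional order proportions.

    Orders are matched by case-folded exact name; excluded orders are
    removed before percentages are (re)normalized, so excluding an order is
    identical to computing on the reduced table.  The p-value for r uses the
    t transform with n-2 degrees of freedom.  Requires >= 3 orders.
    """
    table = _align(regional_counts, tested_counts, exclude)
    if len(table) < 3:
        raise ValueError(f"need >=3 orders after exclusions, got {len(table)}")
    for col in ("regional_species_count", "tested_species_count"):
        total = table[col].sum()
        if total <= 0:
            raise ValueError(f"{col} sums to zero")
        table[col.replace("_species_count", "_pct")] = 100.0 * table[col] / total
    table["residual_from_identity"] = table["tested_pct"] - table["regional_pct"]

    x = table["regional_pct"].to_numpy()
    y = table["tested_pct"].to_numpy()
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        warnings.warn("zero variance on one axis; r undefined")
        r = p = slope = intercept = math.nan
        slope_c = intercept_c = math.nan
    else:
        r, p = stats.pearsonr(x, y)
        fit = stats.linregress(x, y)
        slope, intercept = fit.slope, fit.intercept
        fit_c = stats.linregress(
            table["regional_species_count"], table["tested_species_count"]
        )
        slope_c, intercept_c = fit_c.slope, fit_c.intercept
    return RepresentativenessResult(
        r=float(r),
        p_value=float(p),
        slope=float(slope),
        intercept=float(intercept),
        slope_counts=float(slope_c),
        intercept_counts=float(intercept_c),
        table=table,
        n_orders=len(table),
    )
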