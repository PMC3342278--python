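"""Censored salinity-tolerance records and their tabular I/O.

A toxicity record is one species' 72-h LC50 expressed as electrical
conductivity (mS/cm).  Because species are exposed to a finite ladder of
test concentrations, an LC50 is reported in one of three notations:

``"12.6"``
    a point estimate,
``"35-40"`` (hyphen, en-dash or minus sign)
    an interval-censored value known only to lie between two tested
    concentrations,
``">30"``
    a right-censored value exceeding the highest concentration tested.

All downstream analyses consume :class:`ToxicityRecord` lists produced by
:func:`load_toxicity_table`; values are stored in mS/cm (tables recorded in
µS/cm at 25 °C are divided by 1000 on load).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "CENSOR_KINDS",
    "GROUPS",
    "ORDER_TO_GROUP",
    "UNMAPPED_ORDERS",
    "ToxicityRecord",
    "RegionalWeights",
    "LC50ParseError",
    "parse_lc50_value",
    "format_lc50_value",
    "load_toxicity_table",
    "write_toxicity_table",
    "merge_duplicates",
]

CENSOR_KINDS = ("point", "interval", "right")

#: The seven quasi-taxonomic groups used as exchangeable units in the
#: hierarchical model.  Orders/classes pooled into one group showed broadly
#: similar tolerance distributions.
GROUPS = (
    "Coleoptera & Odonata",
    "Crustaceans",
    "Diptera & Hemiptera",
    "Ephemeroptera",
    "Hydracarina",
    "Non-arthropods",
    "Trichoptera & Plecoptera",
)

# Keys are case-folded order/class names as they appear in input tables.
ORDER_TO_GROUP: dict[str, str] = {
    "coleoptera": "Coleoptera & Odonata",
    "odonata": "Coleoptera & Odonata",
    "amphipoda": "Crustaceans",
    "decapoda": "Crustaceans",
    "isopoda": "Crustaceans",
    "crustacea": "Crustaceans",
    "diptera": "Diptera & Hemiptera",
    "hemiptera": "Diptera & Hemiptera",
    "ephemeroptera": "Ephemeroptera",
    "hydracarina": "Hydracarina",
    "acarina": "Hydracarina",
    # non-arthropod classes/phyla and their common subgroups
    "annelida": "Non-arthropods",
    "oligochaeta": "Non-arthropods",
    "hirudinea": "Non-arthropods",
    "mollusca": "Non-arthropods",
    "gastropoda": "Non-arthropods",
    "bivalvia": "Non-arthropods",
    "turbellaria": "Non-arthropods",
    "tricladida": "Non-arthropods",
    "platyhelminthes": "Non-arthropods",
    "trichoptera": "Trichoptera & Plecoptera",
    "plecoptera": "Trichoptera & Plecoptera",
}

#: Orders with a single tested species that were never assigned to any of the
#: seven groups; they are kept in the record list with ``group=None`` and
#: excluded from group-level analyses.
UNMAPPED_ORDERS = frozenset({"lepidoptera", "megaloptera"})

_ABUNDANCE = ("rare", "abundant", "unknown")


class LC50ParseError(ValueError):
    """Raised when an LC50 value string cannot be interpreted."""


@dataclass(frozen=True)
class ToxicityRecord:
    """One species' censored 72-h LC50 observation (conductivity, mS/cm)."""

    taxon: str
    region: str
    order_or_class: str
    censor_kind: str
    lo: float
    hi: float
    group: str | None = None
    abundance: str = "unknown"

    def __post_init__(self) -> None:
        if self.censor_kind not in CENSOR_KINDS:
            raise ValueError(f"unknown censor_kind {self.censor_kind!r}")
        if not (self.lo > 0):
            raise ValueError(f"lo must be positive, got {self.lo}")
        if self.censor_kind == "point" and self.hi != self.lo:
            raise ValueError("point record requires hi == lo")
        if self.censor_kind == "interval" and not self.hi > self.lo:
            raise ValueError("interval record requires hi > lo")
        if self.censor_kind == "right" and not math.isinf(self.hi):
            raise ValueError("right-censored record requires hi = +inf")
        if self.abundance not in _ABUNDANCE:
            raise ValueError(f"unknown abundance {self.abundance!r}")
        if self.group is not None and self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")

    @property
    def midpoint(self) -> float:
        """Mid-point imputation of an interval; the bound for a right record."""
        if self.censor_kind == "right":
            return self.lo
        return 0.5 * (self.lo + self.hi)

    @property
    def is_right_censored(self) -> bool:
        return self.censor_kind == "right"


@dataclass(frozen=True)
class RegionalWeights:
    """Species-richness fractions per quasi-taxonomic group for one region.

    Weights are the ecological importance of each group in the regional
    assemblage; they are normalized to sum to one.
    """

    region: str
    weights: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        w = dict(self.weights)
        if not w:
            raise ValueError("weights must be non-empty")
        for g, v in w.items():
            if g not in GROUPS:
                raise ValueError(f"unknown group {g!r}")
            if v < 0:
                raise ValueError(f"negative weight for {g}: {v}")
        total = sum(w.values())
        if total <= 0:
            raise ValueError("weights sum to zero")
        object.__setattr__(
            self, "weights", {g: v / total for g, v in w.items()}
        )
        assert abs(sum(self.weights.values()) - 1.0) < 1e-9

    @classmethod
    def from_counts(cls, region: str, counts: Mapping[str, float]) -> "RegionalWeights":
        """Normalize raw per-group species counts into weights."""
        return cls(region=region, weights=dict(counts))

    @classmethod
    def from_richness_csv(cls, path: str | Path, region: str) -> "RegionalWeights":
        """Aggregate an (order, count) richness table into group weights.

        Orders without a group mapping raise; unmapped single-species orders
        (e.g. Lepidoptera) are dropped with a warning.
        """
        df = pd.read_csv(path)
        df.columns = [c.strip().lower() for c in df.columns]
        if not {"order", "count"}.issubset(df.columns):
            raise ValueError("richness CSV requires columns: order, count")
        counts: dict[str, float] = {}
        unknown: list[str] = []
        for _, row in df.iterrows():
            name = str(row["order"]).strip()
            key = name.casefold()
            if key in UNMAPPED_ORDERS:
                warnings.warn(f"order {name!r} has no quasi-group; dropped")
                continue
            group = ORDER_TO_GROUP.get(key)
            if group is None:
                unknown.append(name)
                continue
            counts[group] = counts.get(group, 0.0) + float(row["count"])
        if unknown:
            raise ValueError(f"no quasi-group mapping for orders: {sorted(set(unknown))}")
        return cls.from_counts(region, counts)


def _normalize_number_token(token: str) -> float:
    token = token.strip().replace(",", ".")
    try:
        value = float(token)
    except ValueError:
        raise LC50ParseError(f"cannot parse number {token!r}") from None
    if not value > 0:
        raise LC50ParseError(f"non-positive bound {token!r}")
    return value


# en-dash, em-dash, minus sign, figure dash -> plain hyphen
_DASHES = str.maketrans({"–": "-", "—": "-", "−": "-", "‒": "-"})


def parse_lc50_value(text: str) -> tuple[str, float, float]:
    """Parse the three LC50 notations into a censoring triple.

    Returns ``(censor_kind, lo, hi)`` with ``hi = +inf`` for right-censored
    values.  Decimal commas are tolerated; interval separators may be a
    hyphen, en-dash or minus sign.
    """
    if text is None or not str(text).strip():
        raise LC50ParseError("empty LC50 value")
    s = str(text).strip().translate(_DASHES)
    if s.startswith(">"):
        lo = _normalize_number_token(s[1:])
        return ("right", lo, math.inf)
    if "-" in s:
        parts = [p for p in s.split("-") if p.strip()]
        if len(parts) != 2:
            raise LC50ParseError(f"cannot parse interval {text!r}")
        lo = _normalize_number_token(parts[0])
        hi = _normalize_number_token(parts[1])
        if not hi > lo:
            raise LC50ParseError(f"inverted interval {text!r}")
        return ("interval", lo, hi)
    v = _normalize_number_token(s)
    return ("point", v, v)


def format_lc50_value(censor_kind: str, lo: float, hi: float) -> str:
    """Inverse of :func:`parse_lc50_value` (hyphen separator, repr floats)."""
    if censor_kind == "right":
        return f">{lo:g}"
    if censor_kind == "interval":
        return f"{lo:g}-{hi:g}"
    return f"{lo:g}"


def _informativeness_key(rec: ToxicityRecord) -> tuple:
    # Narrower censoring wins; a right-censored value is treated as infinitely
    # wide.  Ties broken by smaller midpoint; among right-censored duplicates
    # the larger bound carries more information.
    if rec.censor_kind == "right":
        return (math.inf, -rec.lo)
    return (rec.hi - rec.lo, rec.midpoint)


def merge_duplicates(records: Sequence[ToxicityRecord]) -> list[ToxicityRecord]:
    """Collapse duplicate (region, taxon) entries to one record each.

    The more informative (narrower) censoring is kept — e.g. a taxon recorded
    as both ``>30`` and ``35-40`` keeps ``35-40``; ties keep the smaller
    midpoint.  A warning lists the collapsed taxa.
    """
    best: dict[tuple[str, str], ToxicityRecord] = {}
    order: list[tuple[str, str]] = []
    dupes: list[str] = []
    for rec in records:
        key = (rec.region, rec.taxon.casefold())
        if key not in best:
            best[key] = rec
            order.append(key)
        else:
            dupes.append(f"{rec.taxon} ({rec.region})")
            if _informativeness_key(rec) < _informativeness_key(best[key]):
                best[key] = rec
    if dupes:
        warnings.warn(
            "duplicate taxa merged to the most informative record: "
            + ", ".join(sorted(set(dupes)))
        )
    return [best[k] for k in order]


_REQUIRED_COLUMNS = ("taxon", "region", "order_or_class", "lc50")
_UNIT_ALIASES = {"ms/cm": 1.0, "us/cm": 1e-3, "µs/cm": 1e-3, "μs/cm": 1e-3}


def load_toxicity_table(
    path: str | Path,
    unit: str = "mS/cm",
    merge: bool = True,
) -> list[ToxicityRecord]:
    """Read a toxicity CSV into :class:`ToxicityRecord` objects.

    Parameters
    ----------
    path
        CSV with header columns ``taxon, region, order_or_class, lc50`` and
        optionally ``abundance``.  The ``lc50`` column accepts the three
        censoring notations.
    unit
        ``"mS/cm"`` or ``"µS/cm"``; µS/cm values are divided by 1000 exactly
        once, so every in-memory value is mS/cm.  The unit is a property of
        the table, supplied here, never re-applied downstream.
    merge
        Collapse duplicate (region, taxon) rows via :func:`merge_duplicates`.
    """
    factor = _UNIT_ALIASES.get(str(unit).casefold())
    if factor is None:
        raise ValueError(f"unknown unit {unit!r}; expected mS/cm or µS/cm")
    df = pd.read_csv(path, dtype=str)
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")

    records: list[ToxicityRecord] = []
    unknown_orders: list[str] = []
    for idx, row in df.iterrows():
        kind, lo, hi = parse_lc50_value(row["lc50"])
        lo *= factor
        hi = hi * factor if math.isfinite(hi) else hi
        name = str(row["order_or_class"]).strip()
        key = name.casefold()
        if key in UNMAPPED_ORDERS:
            group = None
        else:
            group = ORDER_TO_GROUP.get(key)
            if group is None:
                unknown_orders.append(name)
                continue
        abundance = str(row.get("abundance", "unknown") or "unknown").strip().lower()
        if abundance in ("", "nan"):
            abundance = "unknown"
        records.append(
            ToxicityRecord(
                taxon=str(row["taxon"]).strip(),
                region=str(row["region"]).strip(),
                order_or_class=name,
                censor_kind=kind,
                lo=lo,
                hi=hi,
                group=group,
                abundance=abundance,
            )
        )
    if unknown_orders:
        raise ValueError(
            f"no quasi-group mapping for order_or_class: {sorted(set(unknown_orders))}"
        )
    if merge:
        records = merge_duplicates(records)
    return records


def write_toxicity_table(records: Iterable[ToxicityRecord], path: str | Path) -> None:
    """Write records back to CSV (always mS/cm); round-trips with load."""
    rows = [
        {
            "taxon": r.taxon,
            "region": r.region,
            "order_or_class": r.order_or_class,
            "lc50": format_lc50_value(r.censor_kind, r.lo, r.hi),
            "abundance": r.abundance,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def records_to_frame(records: Iterable[ToxicityRecord]) -> pd.DataFrame:
    """Tidy DataFrame view of a record list (one row per record)."""
    return pd.DataFrame(
        {
            "taxon": r.taxon,
            "region": r.region,
            "order_or_class": r.order_or_class,
            "group": r.group,
            "censor_kind": r.censor_kind,
            "lo": r.lo,
            "hi": r.hi,
            "abundance": r.abundance,
            "midpoint": r.midpoint,
        }
        for r in records
    )
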