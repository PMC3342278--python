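import math

import pytest

from saltssd import ToxicityRecord


def point(value, taxon=None, region="R", group="Diptera & Hemiptera", order="Diptera", abundance="unknown"):
    return ToxicityRecord(
        taxon=taxon or f"sp-{value:g}",
        region=region,
        order_or_class=order,
        censor_kind="point",
        lo=float(value),
        hi=float(value),
        group=group,
        abundance=abundance,
    )


def right(bound, taxon=None, region="R", group="Diptera & Hemiptera", order="Diptera"):
    return ToxicityRecord(
        taxon=taxon or f"rc-{bound:g}",
        region=region,
        order_or_class=order,
        censor_kind="right",
        lo=float(bound),
        hi=math.inf,
        group=group,
    )


def interval(lo, hi, taxon=None, region="R", group="Diptera & Hemiptera", order="Diptera"):
    return ToxicityRecord(
        taxon=taxon or f"iv-{lo:g}-{hi:g}",
        region=region,
        order_or_class=order,
        censor_kind="interval",
        lo=float(lo),
        hi=float(hi),
        group=group,
    )


@pytest.fixture
def make_point():
    return point


@pytest.fixture
def make_right():
    return right


@pytest.fixture
def make_interval():
    return interval
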