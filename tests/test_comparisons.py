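import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from saltssd import anova_sqrt, ci_letter_groups, logrank_test, pairwise_logrank, summarize_by_rank

from conftest import interval, point, right


def two_sample_logrank_oracle(values_a, values_b):
    """Direct score-test computation of the Mantel-Cox statistic for two
    uncensored samples: chi2 = (O - E)^2 / V with hypergeometric variance."""
    events = sorted(set(values_a) | set(values_b))
    O = E = V = 0.0
    for t in events:
        d1 = sum(1 for v in values_a if v == t)
        d = d1 + sum(1 for v in values_b if v == t)
        n1 = sum(1 for v in values_a if v >= t)
        n = n1 + sum(1 for v in values_b if v >= t)
        O += d1
        E += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return (O - E) ** 2 / V


def test_identical_samples_give_zero_statistic(make_point):
    a = [point(v, taxon=f"a{v}") for v in (5, 10, 20)]
    b = [point(v, taxon=f"b{v}") for v in (5, 10, 20)]
    res = logrank_test([a, b])
    assert res.chi2 == pytest.approx(0.0, abs=1e-9)
    assert res.p_value == pytest.approx(1.0)
    assert res.df == 1


def test_all_values_tied_across_samples(make_point):
    res = logrank_test([[point(7, taxon=f"a{i}") for i in range(3)],
                        [point(7, taxon=f"b{i}") for i in range(3)]])
    assert res.chi2 == 0.0 and res.p_value == 1.0


def test_empty_sample_rejected(make_point):
    with pytest.raises(ValueError):
        logrank_test([[point(5)], []])


def test_mantel_cox_agrees_with_direct_score_oracle():
    a = [1.0, 2.0, 5.0, 7.0]
    b = [3.0, 4.0, 6.0, 8.0, 9.0]
    res = logrank_test(
        [[point(v, taxon=f"a{v}") for v in a], [point(v, taxon=f"b{v}") for v in b]]
    )
    assert res.chi2 == pytest.approx(two_sample_logrank_oracle(a, b), abs=1e-8)


def test_chi_square_tail_matches_exhaustive_permutation_null():
    """The chi-square reference tail probability is cross-checked against an
    exhaustive label-permutation null on a small uncensored sample."""
    pooled = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
    obs_a = [1.0, 2.0, 5.0]
    obs = two_sample_logrank_oracle(obs_a, sorted(set(pooled) - set(obs_a)))
    stats_null = []
    for combo in itertools.combinations(pooled, 3):
        rest = [v for v in pooled if v not in combo]
        stats_null.append(two_sample_logrank_oracle(list(combo), rest))
    p_perm = np.mean([s >= obs - 1e-12 for s in stats_null])
    res = logrank_test(
        [
            [point(v, taxon=f"a{v}") for v in obs_a],
            [point(v, taxon=f"b{v}") for v in pooled if v not in obs_a],
        ]
    )
    assert res.chi2 == pytest.approx(obs, abs=1e-8)
    # with only C(6,3)=20 labelings the permutation p is coarse; the
    # asymptotic p must sit within one atom (1/20) of it
    assert abs(res.p_value - p_perm) <= 0.2


def test_logrank_handles_censoring_and_midpoints(make_interval, make_right):
    a = [interval(10, 20, taxon="a1"), right(30, taxon="a2"), point(25, taxon="a3")]
    b = [point(5, taxon="b1"), point(8, taxon="b2"), point(12, taxon="b3")]
    res = logrank_test([a, b])
    assert res.chi2 > 0 and 0 <= res.p_value <= 1


@settings(derandomize=True, max_examples=30, deadline=None)
@given(
    seed=st.integers(0, 10_000),
    scheme=st.sampled_from(["mantel-cox", "breslow", "tarone-ware"]),
)
def test_logrank_invariances(seed, scheme):
    """The statistic is unchanged by sample order and by any strictly
    increasing transform of the concentration axis."""
    rng = np.random.default_rng(seed)
    a = [point(v, taxon=f"a{i}") for i, v in enumerate(rng.lognormal(2.5, 0.5, 6))]
    b = [point(v, taxon=f"b{i}") for i, v in enumerate(rng.lognormal(2.9, 0.5, 7))]
    res = logrank_test([a, b], weight_scheme=scheme)
    swapped = logrank_test([b, a], weight_scheme=scheme)
    assert swapped.chi2 == pytest.approx(res.chi2, rel=1e-9)

    def transform(r):
        v = math.exp(math.sqrt(r.lo))  # strictly increasing on (0, inf)
        return point(v, taxon=r.taxon)

    trans = logrank_test([[transform(r) for r in a], [transform(r) for r in b]],
                         weight_scheme=scheme)
    assert trans.chi2 == pytest.approx(res.chi2, rel=1e-6)


def test_weight_schemes_differ_in_general(make_point):
    rng = np.random.default_rng(11)
    a = [point(v, taxon=f"a{i}") for i, v in enumerate(rng.lognormal(2.3, 0.4, 10))]
    b = [point(v, taxon=f"b{i}") for i, v in enumerate(rng.lognormal(2.8, 0.4, 10))]
    chis = {s: logrank_test([a, b], weight_scheme=s).chi2 for s in
            ("mantel-cox", "breslow", "tarone-ware")}
    assert len({round(c, 6) for c in chis.values()}) == 3


# --- ANOVA ---------------------------------------------------------------


def balanced_two_way_oracle(values):
    """Direct sums-of-squares decomposition for a balanced two-way layout.

    values[(i, j)] is the list of responses in cell (i, j); returns the F
    statistics for factor A, factor B and the interaction.
    """
    cells = sorted(values)
    a_levels = sorted({i for i, _ in cells})
    b_levels = sorted({j for _, j in cells})
    r = len(values[cells[0]])
    allv = [v for cell in values.values() for v in cell]
    grand = np.mean(allv)
    a_means = {i: np.mean([v for (ii, j) in cells if ii == i for v in values[(ii, j)]]) for i in a_levels}
    b_means = {j: np.mean([v for (i, jj) in cells if jj == j for v in values[(i, jj)]]) for j in b_levels}
    cell_means = {c: np.mean(values[c]) for c in cells}
    ss_a = r * len(b_levels) * sum((a_means[i] - grand) ** 2 for i in a_levels)
    ss_b = r * len(a_levels) * sum((b_means[j] - grand) ** 2 for j in b_levels)
    ss_ab = r * sum(
        (cell_means[(i, j)] - a_means[i] - b_means[j] + grand) ** 2
        for (i, j) in cells
    )
    ss_e = sum((v - cell_means[c]) ** 2 for c in cells for v in values[c])
    df_a = len(a_levels) - 1
    df_b = len(b_levels) - 1
    df_ab = df_a * df_b
    df_e = len(allv) - len(cells)
    ms_e = ss_e / df_e
    return (ss_a / df_a / ms_e, ss_b / df_b / ms_e, ss_ab / df_ab / ms_e)


def test_anova_balanced_layout_matches_ss_oracle():
    raw = {
        ("Ephemeroptera", "FRA"): [4.1, 5.2, 6.3],
        ("Ephemeroptera", "EAUS"): [7.4, 8.1, 9.3],
        ("Crustaceans", "FRA"): [20.5, 22.1, 24.4],
        ("Crustaceans", "EAUS"): [30.2, 33.8, 35.1],
    }
    records = [
        point(v, taxon=f"{g[:3]}{r}{k}", region=r, group=g,
              order="Ephemeroptera" if g == "Ephemeroptera" else "Amphipoda")
        for (g, r), vals in raw.items()
        for k, v in enumerate(vals)
    ]
    table = anova_sqrt(records, factors=("group", "region"))
    sqrt_cells = {c: [math.sqrt(v) for v in vals] for c, vals in raw.items()}
    f_a, f_b, f_ab = balanced_two_way_oracle(sqrt_cells)
    assert table.loc["C(group)", "F"] == pytest.approx(f_a, rel=1e-8)
    assert table.loc["C(region)", "F"] == pytest.approx(f_b, rel=1e-8)
    assert table.loc["C(group):C(region)", "F"] == pytest.approx(f_ab, rel=1e-8)


def test_anova_identical_region_multisets_give_zero_f():
    vals = [5.0, 9.0, 13.0, 17.0]
    records = [point(v, taxon=f"a{v}", region="A") for v in vals] + [
        point(v, taxon=f"b{v}", region="B") for v in vals
    ]
    table = anova_sqrt(records, factors=("region",))
    assert table.loc["C(region)", "F"] == pytest.approx(0.0, abs=1e-12)


def test_anova_excludes_right_censored_and_drops_sparse_levels(make_right):
    records = (
        [point(v, taxon=f"e{v}", region="A", group="Ephemeroptera") for v in (4, 6, 8)]
        + [point(v, taxon=f"f{v}", region="B", group="Ephemeroptera") for v in (5, 7, 9)]
        + [point(v, taxon=f"g{v}", region="A", group="Crustaceans", order="Amphipoda") for v in (20, 30)]
        + [point(v, taxon=f"h{v}", region="B", group="Crustaceans", order="Amphipoda") for v in (25, 35)]
        # Hydracarina has a single usable value in region A -> dropped
        + [point(19.3, taxon="mite", region="A", group="Hydracarina", order="Hydracarina")]
        + [right(30, taxon="rc", region="A", group="Ephemeroptera")]
    )
    with pytest.warns(UserWarning, match="Hydracarina"):
        table = anova_sqrt(records, factors=("group", "region"))
    # dropped level and censored record leave 10 usable observations
    assert table["df"].sum() == 10 - 1
    assert table.attrs["dropped_levels"] == ["Hydracarina"]


def test_anova_single_level_errors(make_point):
    records = [point(v, taxon=f"a{v}", region="A") for v in (1, 2, 3)]
    with pytest.raises(ValueError):
        anova_sqrt(records, factors=("region",))


# --- CI letter groups ----------------------------------------------------


def test_letters_disjoint_cis_distinct():
    letters = ci_letter_groups([("x", 1.5, 1.0, 2.0), ("y", 3.5, 3.0, 4.0)])
    assert letters["x"] and letters["y"]
    assert letters["x"] != letters["y"]
    assert not (letters["x"] & letters["y"])


def test_letters_overlapping_cis_share():
    letters = ci_letter_groups([("x", 2.0, 1.0, 3.0), ("y", 3.0, 2.0, 4.0)])
    assert letters["x"] & letters["y"]


def test_letters_chain_overlap():
    # A-B overlap and B-C overlap but A-C do not: B bridges both letters
    letters = ci_letter_groups(
        [("A", 1.0, 0.0, 2.0), ("B", 3.0, 1.5, 4.5), ("C", 5.0, 4.0, 6.0)]
    )
    assert letters["A"] & letters["B"]
    assert letters["B"] & letters["C"]
    assert not (letters["A"] & letters["C"])


def test_letters_regional_pattern():
    # two low-mean overlapping regions vs one separate high-mean region
    letters = ci_letter_groups(
        [
            ("E Australia", 33.3, 30.1, 36.6),
            ("France", 22.3, 19.5, 25.0),
            ("Israel", 24.9, 19.5, 26.6),
        ]
    )
    assert letters["France"] & letters["Israel"]
    assert not (letters["E Australia"] & letters["France"])
    assert not (letters["E Australia"] & letters["Israel"])


def test_letters_empty_input():
    assert ci_letter_groups([]) == {}


@settings(derandomize=True, max_examples=50)
@given(st.lists(st.tuples(st.floats(0, 50), st.floats(0.1, 10)), min_size=1, max_size=8))
def test_letters_overlap_iff_shared(intervals):
    """Pairwise: overlapping CIs share a letter, disjoint CIs never do."""
    ests = [
        (f"g{i}", c, c - w, c + w) for i, (c, w) in enumerate(intervals)
    ]
    letters = ci_letter_groups(ests)
    for (la, _, lo_a, hi_a), (lb, _, lo_b, hi_b) in itertools.combinations(ests, 2):
        overlap = max(lo_a, lo_b) <= min(hi_a, hi_b)
        assert bool(letters[la] & letters[lb]) == overlap


# --- rank summaries -------------------------------------------------------


def test_summarize_by_rank_moments(make_point, make_right, make_interval):
    records = [
        point(22.0, taxon="Gammarus a", region="FRA", group="Crustaceans", order="Amphipoda"),
        point(24.0, taxon="Gammarus b", region="FRA", group="Crustaceans", order="Amphipoda"),
        interval(30, 40, taxon="Gammarus c", region="FRA", group="Crustaceans", order="Amphipoda"),
        right(30, taxon="Gammarus d", region="FRA", group="Crustaceans", order="Amphipoda"),
        point(12.0, taxon="Dugesia a", region="FRA", group="Non-arthropods", order="Turbellaria"),
    ]
    labels = {r.taxon: ("Gammaridae" if "Gammarus" in r.taxon else "Dugesiidae") for r in records}
    out = summarize_by_rank(records, labels)
    gam = out[out["rank"] == "Gammaridae"].iloc[0]
    # right-censored record excluded; interval contributes its midpoint 35
    assert gam["n"] == 3
    assert gam["mean"] == pytest.approx(np.mean([22, 24, 35]))
    assert gam["sd"] == pytest.approx(np.std([22, 24, 35], ddof=1))
    dug = out[out["rank"] == "Dugesiidae"].iloc[0]
    assert dug["n"] == 1 and math.isnan(dug["sd"])


def test_pairwise_logrank_table(make_point):
    samples = {
        "A": [point(v, taxon=f"a{v}", region="A") for v in (1, 2, 3)],
        "B": [point(v, taxon=f"b{v}", region="B") for v in (4, 5, 6)],
        "C": [point(v, taxon=f"c{v}", region="C") for v in (1.5, 2.5, 3.5)],
    }
    table = pairwise_logrank(samples)
    assert len(table) == 3
    assert set(table.columns) == {"sample_a", "sample_b", "chi2", "df", "p_value"}
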