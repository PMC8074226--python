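"""Cohort-level statistics: counts, Fisher tests, distributions, resampling."""

import math

import numpy as np
import pytest

from posel.cohort import (
    cohort_quality_summary,
    compare_distributions,
    count_selected_by_category,
    fisher_pairwise,
    resample_equalized,
    selected_counts_table,
)
from posel.inference import GeneRecord


def _records(counts: dict[str, tuple[int, int]]):
    """counts: category -> (n_selected, n_total)."""
    out = []
    for cat, (k, n) in counts.items():
        for i in range(n):
            out.append(
                GeneRecord(
                    gene_id=f"{cat}_{i}",
                    category=cat,
                    p_value=0.001 if i < k else 0.9,
                    bh_significant=i < k,
                    complete=True,
                    two_delta_lnl=1.0,
                    tree_length_m0=1.0,
                )
            )
    return out


def fisher_two_tailed_by_enumeration(table):
    """Exact two-tailed Fisher p by summing hypergeometric probabilities of
    all tables with the observed margins that are no more probable."""
    (a, b), (c, d) = table
    row1, row2 = a + b, c + d
    col1 = a + c
    n = row1 + row2

    def prob(x):
        return (
            math.comb(row1, x) * math.comb(row2, col1 - x) / math.comb(n, col1)
        )

    p_obs = prob(a)
    total = 0.0
    for x in range(max(0, col1 - row2), min(row1, col1) + 1):
        px = prob(x)
        if px <= p_obs * (1 + 1e-12):
            total += px
    return total


def test_counts_and_proportions():
    table = count_selected_by_category(_records({"isg": (33, 100), "random": (18, 100)}))
    assert table.counts["isg"].n_genes == 100
    assert table.counts["isg"].n_selected == 33
    assert np.isclose(table.counts["isg"].proportion, 0.33)


def test_counts_invariant_to_order():
    recs = _records({"isg": (5, 20), "random": (2, 20), "induction": (3, 25)})
    t1 = count_selected_by_category(recs)
    t2 = count_selected_by_category(list(reversed(recs)))
    assert t1.counts.keys() == t2.counts.keys()
    for c in t1.counts:
        assert t1.counts[c].n_selected == t2.counts[c].n_selected


def test_incomplete_records_excluded():
    recs = _records({"isg": (5, 20)})
    recs.append(GeneRecord(gene_id="x", category="isg", complete=False))
    table = count_selected_by_category(recs)
    assert table.counts["isg"].n_genes == 20


@pytest.mark.parametrize(
    "table",
    [
        ((33, 67), (18, 82)),
        ((20, 80), (20, 80)),
        ((5, 5), (1, 9)),
        ((0, 10), (10, 0)),
        ((7, 13), (2, 18)),
    ],
)
def test_fisher_matches_enumeration_oracle(table):
    from scipy.stats import fisher_exact

    _, p = fisher_exact(table, alternative="two-sided")
    assert np.isclose(p, fisher_two_tailed_by_enumeration(table), atol=1e-10)


def test_fisher_pairwise_on_headline_counts():
    t = selected_counts_table(_records({"isg": (33, 100), "random": (18, 100)}))
    (cmp,) = t.comparisons
    assert cmp.p_value < 0.05
    assert cmp.higher_category() == "isg"


def test_fisher_identical_proportions_p1():
    t = selected_counts_table(_records({"isg": (20, 100), "random": (20, 100)}))
    (cmp,) = t.comparisons
    assert cmp.p_value == pytest.approx(1.0)


def test_compare_distributions_identical_samples():
    vals = {"a": np.arange(10.0), "b": np.arange(10.0)}
    (cmp,) = compare_distributions(vals, test="ks")
    assert cmp.statistic == 0.0 and cmp.p_value == pytest.approx(1.0)


def test_compare_distributions_disjoint_supports():
    vals = {"a": np.arange(10.0), "b": np.arange(10.0) + 100}
    (cmp,) = compare_distributions(vals, test="ks")
    assert cmp.statistic == 1.0
    assert cmp.p_value < 1e-4


def test_compare_distributions_shifted_by_two_sd():
    rng = np.random.default_rng(0)
    a = rng.normal(0, 1, 100)
    b = rng.normal(2, 1, 100)
    for test in ("ks", "mann_whitney"):
        (cmp,) = compare_distributions({"a": a, "b": b}, test=test)
        assert cmp.p_value < 0.001


def test_compare_distributions_requires_two_observations():
    with pytest.raises(ValueError):
        compare_distributions({"a": np.array([1.0]), "b": np.arange(5.0)})


# ---------------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------------


def test_resampling_deterministic_and_counts_sum():
    recs = _records({"induction": (30, 120), "isg": (40, 100), "random": (15, 100)})
    r1 = resample_equalized(recs, subsample_size=100, n_replicates=20, seed=9)
    r2 = resample_equalized(recs, subsample_size=100, n_replicates=20, seed=9)
    assert r1.patterns == r2.patterns
    assert sum(r1.pattern_counts.values()) == 20


def test_resampling_full_size_reproduces_full_data_result():
    recs = _records({"induction": (30, 100), "isg": (40, 100), "random": (15, 100)})
    full = selected_counts_table(recs)
    sig_full = frozenset(c.pair for c in full.comparisons if c.bh_significant)
    res = resample_equalized(recs, subsample_size=100, n_replicates=5, seed=1)
    assert all(p == sig_full for p in res.patterns)


def test_resampling_no_effect_yields_no_significance():
    recs = _records({"induction": (20, 150), "isg": (20, 100), "random": (20, 100)})
    res = resample_equalized(recs, subsample_size=100, n_replicates=20, seed=2)
    assert res.pattern_counts.get("none_significant", 0) == 20


def test_resampling_size_exceeds_category_raises():
    recs = _records({"induction": (5, 20), "isg": (5, 20), "random": (5, 20)})
    with pytest.raises(ValueError):
        resample_equalized(recs, subsample_size=50, n_replicates=2, seed=0)


# ---------------------------------------------------------------------------
# quality summaries
# ---------------------------------------------------------------------------


def test_quality_summary_presence_percentages():
    gene_taxa = {
        "g1": ("h", "c", "m"),
        "g2": ("h", "c"),
        "g3": ("h", "m"),
        "g4": ("h", "c", "m"),
    }
    cats = {"g1": "isg", "g2": "isg", "g3": "random", "g4": "random"}
    tls = {"g1": 1.0, "g2": 2.0, "g3": 3.0, "g4": 5.0}
    q = cohort_quality_summary(gene_taxa, cats, tls)
    assert q.species_presence_pct["h"] == 100.0
    assert q.species_presence_pct["c"] == 75.0
    assert q.taxon_counts["isg"] == [3, 2]
    assert np.isclose(q.mean_tree_length["random"], 4.0)
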