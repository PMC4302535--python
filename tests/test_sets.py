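"""Exact set statistics against enumeration oracles."""

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from riploop.io import CovariateTable, GeneSetCollection, ValidationError
from riploop.sets import (
    chisq_across_clusters,
    fisher_cluster_vs_genome,
    hypergeometric_enrichment,
    summarize_groups,
    wilcoxon_compare,
)


# ---------------------------------------------------------------------------
# hypergeometric
# ---------------------------------------------------------------------------


def hypergeom_tails_by_enumeration(M, K, n, k):
    """P(X >= k) and P(X <= k) by summing the exact pmf."""
    denom = comb(M, n)
    pmf = {
        x: comb(K, x) * comb(M - K, n - x) / denom
        for x in range(max(0, n - (M - K)), min(K, n) + 1)
    }
    p_over = sum(p for x, p in pmf.items() if x >= k)
    p_under = sum(p for x, p in pmf.items() if x <= k)
    return p_over, p_under


def _collection(term_members):
    return GeneSetCollection({"T": ("term", frozenset(term_members))})


def test_perfect_overlap_exact_value():
    """Universe 10, term 5, set 5, overlap 5: exactly one of C(10,5)=252 draws."""
    universe = [f"g{i}" for i in range(10)]
    term = universe[:5]
    out = hypergeometric_enrichment(term, _collection(term), universe)
    assert out.loc["T", "p_over"] == pytest.approx(1 / 252)


def test_term_equal_universe_certain():
    universe = [f"g{i}" for i in range(8)]
    out = hypergeometric_enrichment(universe[:3], _collection(universe), universe)
    assert out.loc["T", "p_over"] == pytest.approx(1.0)


def test_empty_gene_set_and_stray_genes_rejected():
    universe = ["a", "b", "c"]
    with pytest.raises(ValidationError):
        hypergeometric_enrichment([], _collection(["a"]), universe)
    with pytest.raises(ValidationError, match="zzz"):
        hypergeometric_enrichment(["zzz"], _collection(["a"]), universe)


def test_empty_intersection_reported_not_skipped():
    universe = ["a", "b", "c", "d"]
    out = hypergeometric_enrichment(["a"], _collection(["zzz"]), universe)
    assert out.loc["T", "overlap"] == 0
    assert out.loc["T", "p_over"] == pytest.approx(1.0)


@given(st.integers(0, 10_000))
@settings(max_examples=500, deadline=None)
def test_hypergeometric_matches_enumeration(seed):
    rng = np.random.default_rng(seed)
    M = int(rng.integers(2, 16))
    K = int(rng.integers(1, M + 1))
    n = int(rng.integers(1, M + 1))
    universe = [f"g{i}" for i in range(M)]
    term = list(rng.choice(universe, size=K, replace=False))
    query = list(rng.choice(universe, size=n, replace=False))
    out = hypergeometric_enrichment(query, _collection(term), universe)
    k = len(set(term) & set(query))
    p_over, p_under = hypergeom_tails_by_enumeration(M, K, n, k)
    assert out.loc["T", "p_over"] == pytest.approx(p_over, abs=1e-12)
    assert out.loc["T", "p_under"] == pytest.approx(p_under, abs=1e-12)


def test_directions_not_both_significant_on_null():
    rng = np.random.default_rng(0)
    universe = [f"g{i}" for i in range(200)]
    terms = {
        f"T{j}": ("t", frozenset(rng.choice(universe, 30, replace=False)))
        for j in range(25)
    }
    query = list(rng.choice(universe, 50, replace=False))
    out = hypergeometric_enrichment(query, GeneSetCollection(terms), universe)
    both = (out["fdr_over"] < 0.5) & (out["fdr_under"] < 0.5)
    assert not both.any()


# ---------------------------------------------------------------------------
# Fisher exact
# ---------------------------------------------------------------------------


def fisher_two_sided_by_enumeration(a, b, c, d):
    """Sum P(table) over all tables with the same margins and prob <= observed."""
    from scipy.stats import hypergeom

    r1, r2 = a + b, c + d
    c1 = a + c
    M = r1 + r2
    p_obs = hypergeom.pmf(a, M, r1, c1)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = hypergeom.pmf(x, M, r1, c1)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return total


def test_no_association_table_p_one():
    universe = [f"g{i}" for i in range(20)]
    cluster = universe[:10]
    term = universe[:2] + universe[10:12]  # 2/10 in each group
    res = fisher_cluster_vs_genome(cluster, term, universe)
    assert res["p_two_sided"] == pytest.approx(1.0, abs=1e-9)


@given(st.integers(0, 10_000))
@settings(max_examples=200, deadline=None)
def test_fisher_matches_fixed_margin_enumeration(seed):
    rng = np.random.default_rng(seed)
    a, b, c, d = (int(x) for x in rng.integers(1, 13, size=4))
    universe = [f"g{i}" for i in range(a + b + c + d)]
    cluster = universe[: a + b]
    term = universe[:a] + universe[a + b : a + b + c]
    res = fisher_cluster_vs_genome(cluster, term, universe)
    expected = fisher_two_sided_by_enumeration(a, b, c, d)
    assert res["p_two_sided"] == pytest.approx(expected, abs=1e-12)


def test_one_sided_fisher_equals_hypergeometric_tail():
    universe = [f"g{i}" for i in range(30)]
    cluster = universe[:12]
    term = universe[6:16]
    res = fisher_cluster_vs_genome(cluster, term, universe)
    hyp = hypergeometric_enrichment(cluster, _collection(term), universe)
    assert res["p_over"] == pytest.approx(hyp.loc["T", "p_over"], abs=1e-12)


def test_zero_margin_degenerate():
    universe = ["a", "b", "c", "d"]
    res = fisher_cluster_vs_genome(["a", "b"], [], universe)
    assert res["p_two_sided"] == 1.0
    assert np.isnan(res["odds_ratio"])


# ---------------------------------------------------------------------------
# chi-square across clusters
# ---------------------------------------------------------------------------


def test_identical_proportions_give_zero_statistic():
    clusters = pd.Series(
        ["A"] * 10 + ["B"] * 20, index=[f"g{i}" for i in range(30)]
    )
    term = [f"g{i}" for i in range(5)] + [f"g{i}" for i in range(10, 20)]
    res = chisq_across_clusters(clusters, term)
    assert res["statistic"] == pytest.approx(0.0, abs=1e-12)
    assert res["p_value"] == pytest.approx(1.0)


def test_hand_computed_two_by_two():
    """Table (10,10 / 20,0): statistic equals sum (O-E)^2/E computed by hand.

    Margins: rows 20,20; cols 30,10; E = [[15,5],[15,5]];
    chi2 = 25/15 + 25/5 + 25/15 + 25/5 = 40/3.
    """
    clusters = pd.Series(["A"] * 20 + ["B"] * 20, index=[f"g{i}" for i in range(40)])
    term = [f"g{i}" for i in range(10)] + [f"g{i}" for i in range(20, 40)]
    res = chisq_across_clusters(clusters, term)
    assert res["statistic"] == pytest.approx(40.0 / 3.0, abs=1e-9)


def test_merging_identical_groups_leaves_statistic_unchanged():
    """Two groups with identical observed in-term proportions contribute the
    same Pearson statistic merged or split (the p-value shifts only through
    the degrees of freedom)."""
    idx = [f"g{i}" for i in range(120)]
    clusters = pd.Series(["A"] * 40 + ["B"] * 40 + ["C"] * 40, index=idx)
    # A and B share a 25% in-term proportion; C differs
    term = idx[:10] + idx[40:50] + idx[80:110]
    merged = clusters.replace({"B": "A"})
    r1 = chisq_across_clusters(clusters, term)
    r2 = chisq_across_clusters(merged, term)
    assert r1["statistic"] == pytest.approx(r2["statistic"], abs=1e-9)
    assert r1["df"] == r2["df"] + 1


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum
# ---------------------------------------------------------------------------


def wilcoxon_exact_by_enumeration(a, b):
    """Two-sided p by enumerating all C(n_a+n_b, n_a) rank assignments."""
    pooled = np.concatenate([a, b])
    n = len(pooled)
    ranks = np.argsort(np.argsort(pooled)) + 1
    obs = ranks[: len(a)].sum()
    sums = [sum(cmb) for cmb in combinations(ranks, len(a))]
    mean = len(a) * (n + 1) / 2
    extreme = sum(1 for s in sums if abs(s - mean) >= abs(obs - mean) - 1e-9)
    return extreme / len(sums)


def test_separated_samples_exact_value():
    """A=(1,2,3) vs B=(4,5,6): U=0 and exact two-sided p = 2/20 = 0.1."""
    res = wilcoxon_compare([1, 2, 3], [4, 5, 6])
    assert res.statistic == 0.0
    assert res.p_value == pytest.approx(0.1)
    assert res.method == "exact"


def test_identical_multisets_p_one():
    res = wilcoxon_compare([1.5, 2.5, 3.5], [2.5, 1.5, 3.5])
    assert res.p_value == pytest.approx(1.0)


def test_swap_symmetry():
    a, b = [1.0, 4.0, 2.5], [3.0, 5.0, 0.5, 6.0]
    r1 = wilcoxon_compare(a, b)
    r2 = wilcoxon_compare(b, a)
    assert r1.p_value == pytest.approx(r2.p_value)
    assert r1.statistic == pytest.approx(r1.n_a * r1.n_b - r2.statistic)


@given(st.integers(0, 10_000))
@settings(max_examples=150, deadline=None)
def test_exact_p_matches_rank_enumeration(seed):
    rng = np.random.default_rng(seed)
    n_a = int(rng.integers(2, 6))
    n_b = int(rng.integers(2, 6))
    vals = rng.choice(np.arange(100), size=n_a + n_b, replace=False).astype(float)
    a, b = vals[:n_a], vals[n_a:]
    res = wilcoxon_compare(a, b)
    assert res.p_value == pytest.approx(wilcoxon_exact_by_enumeration(a, b), abs=1e-12)


def test_all_missing_set_rejected():
    with pytest.raises(ValidationError):
        wilcoxon_compare([np.nan, np.nan], [1.0, 2.0])


# ---------------------------------------------------------------------------
# group summaries
# ---------------------------------------------------------------------------


class TestSummarizeGroups:
    def test_quartile_convention_type7(self):
        idx = [f"g{i}" for i in range(9)]
        clusters = pd.Series(["A"] * 9, index=idx)
        cov = CovariateTable(pd.DataFrame({"x": np.arange(1.0, 10.0)}, index=idx))
        summary, _ = summarize_groups(clusters, cov)
        row = summary.iloc[0]
        assert (row["q1"], row["median"], row["q3"]) == (3.0, 5.0, 7.0)

    def test_single_value_group(self):
        idx = ["g0", "g1", "g2"]
        clusters = pd.Series(["A", "B", "B"], index=idx)
        cov = CovariateTable(pd.DataFrame({"x": [4.2, 1.0, 2.0]}, index=idx))
        summary, _ = summarize_groups(clusters, cov)
        row = summary[summary["group"] == "A"].iloc[0]
        assert row["min"] == row["median"] == row["max"] == 4.2

    def test_missing_covariate_named_in_error(self):
        idx = ["g0", "g1"]
        clusters = pd.Series(["A", "B"], index=idx)
        cov = CovariateTable(pd.DataFrame({"x": [1.0, 2.0]}, index=idx))
        with pytest.raises(KeyError, match="nope"):
            summarize_groups(clusters, cov, covariate_names=["nope"])

    def test_pairwise_comparisons_bh_corrected(self):
        rng = np.random.default_rng(2)
        idx = [f"g{i}" for i in range(90)]
        clusters = pd.Series(["A"] * 30 + ["B"] * 30 + ["C"] * 30, index=idx)
        x = np.concatenate([rng.normal(0, 1, 30), rng.normal(3, 1, 30), rng.normal(0, 1, 30)])
        cov = CovariateTable(pd.DataFrame({"x": x}, index=idx))
        _, comparisons = summarize_groups(clusters, cov)
        assert len(comparisons) == 3
        ab = comparisons[(comparisons["set_a"] == "A") & (comparisons["set_b"] == "B")]
        assert ab["fdr"].iloc[0] < 0.01
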