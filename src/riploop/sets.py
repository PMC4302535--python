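"""Statistics over transcript groups: set over/under-representation,
cross-cluster heterogeneity and covariate comparisons.

Over- and under-representation of annotation terms within a transcript set
is scored with hypergeometric tail probabilities (equivalently, one-sided
Fisher exact tests) against a user-supplied universe, with
Benjamini-Hochberg FDR within each direction.  A two-sided Fisher exact
variant compares a cluster against the rest of the universe, and a Pearson
chi-square test asks whether a term's prevalence differs across clusters.
Continuous per-gene covariates (ribosome occupancy, poly(A) tail length,
protein abundance, ...) are compared between transcript sets with the
two-sided Wilcoxon rank-sum (Mann-Whitney) test, exact for small untied
samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import bh_fdr
from .io import CovariateTable, GeneSetCollection, ValidationError

logger = logging.getLogger(__name__)

EXACT_WILCOXON_MAX_N = 20


def hypergeometric_enrichment(
    gene_set: Iterable[str],
    term_sets: GeneSetCollection,
    universe: Iterable[str],
) -> pd.DataFrame:
    """Hypergeometric over/under-representation of every term in a gene set.

    For a term with K members in a universe of M genes and a query set of n
    genes overlapping the term in k genes, ``p_over = P(X >= k)`` and
    ``p_under = P(X <= k)`` under Hypergeometric(M, K, n).  Terms are
    intersected with the universe before testing; terms with an empty
    intersection are reported with overlap 0, not skipped.  BH FDR is applied
    within each direction across terms.
    """
    universe = set(universe)
    gene_set = set(gene_set)
    if not gene_set:
        raise ValidationError("empty gene set")
    stray = gene_set - universe
    if stray:
        raise ValidationError(f"gene set not contained in universe: {sorted(stray)[:5]}")
    M = len(universe)
    n = len(gene_set)
    rows = []
    for term_id in term_sets.term_ids:
        members = term_sets.members(term_id) & universe
        K = len(members)
        k = len(gene_set & members)
        p_over = float(stats.hypergeom.sf(k - 1, M, K, n))
        p_under = float(stats.hypergeom.cdf(k, M, K, n))
        expected = n * K / M if M else 0.0
        rows.append(
            {
                "term_id": term_id,
                "term_name": term_sets.name(term_id),
                "overlap": k,
                "set_size": n,
                "term_size": K,
                "universe_size": M,
                "expected": expected,
                "p_over": p_over,
                "p_under": p_under,
                "direction": "over" if k >= expected else "under",
            }
        )
    out = pd.DataFrame(rows).set_index("term_id")
    out["fdr_over"] = bh_fdr(out["p_over"].to_numpy())
    out["fdr_under"] = bh_fdr(out["p_under"].to_numpy())
    return out


def fisher_cluster_vs_genome(
    cluster_genes: Iterable[str],
    term_genes: Iterable[str],
    universe: Iterable[str],
) -> dict:
    """Fisher exact test of a 2x2 table: cluster membership x term membership.

    Two-sided p sums all tables (at fixed margins) with probability <= the
    observed table; the one-sided ``p_over`` equals the hypergeometric upper
    tail.  With any zero margin the test is degenerate: p = 1 and the odds
    ratio is reported missing.
    """
    universe = set(universe)
    cluster = set(cluster_genes) & universe
    term = set(term_genes) & universe
    a = len(cluster & term)
    b = len(cluster - term)
    c = len(term - cluster)
    d = len(universe) - a - b - c
    table = np.array([[a, b], [c, d]])
    if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
        return {"odds_ratio": float("nan"), "p_two_sided": 1.0, "p_over": 1.0, "table": table}
    odds, p_two = stats.fisher_exact(table, alternative="two-sided")
    _, p_over = stats.fisher_exact(table, alternative="greater")
    return {
        "odds_ratio": float(odds),
        "p_two_sided": float(p_two),
        "p_over": float(p_over),
        "table": table,
    }


def chisq_across_clusters(
    clusters: pd.Series,
    term_genes: Iterable[str],
) -> dict:
    """Pearson chi-square for heterogeneity of a term's prevalence across groups.

    The contingency table is groups x (in-term, not-in-term); groups of size
    zero are dropped with a warning, and a warning is logged when any expected
    cell count falls below 5.
    """
    term = set(term_genes)
    counts = []
    labels = []
    for group, members in clusters.groupby(clusters):
        size = len(members)
        if size == 0:
            logger.warning("group %r is empty; dropped from chi-square", group)
            continue
        in_term = sum(1 for g in members.index if g in term)
        counts.append([in_term, size - in_term])
        labels.append(group)
    if len(counts) < 2:
        raise ValidationError("need at least 2 non-empty groups")
    table = np.array(counts)
    if table.sum(axis=0).min() == 0:
        # all genes in (or out of) the term: no heterogeneity to test
        return {
            "statistic": 0.0,
            "p_value": 1.0,
            "df": len(labels) - 1,
            "expected": table.astype(float),
            "groups": labels,
        }
    stat, p, df, expected = stats.chi2_contingency(table, correction=False)
    if (expected < 5).any():
        logger.warning("chi-square expected counts below 5; p-value is approximate")
    return {
        "statistic": float(stat),
        "p_value": float(p),
        "df": int(df),
        "expected": expected,
        "groups": labels,
    }


@dataclass
class CovariateComparison:
    """Two-sided rank-sum comparison of one covariate between two transcript sets."""

    set_a: str
    set_b: str
    covariate: str
    n_a: int
    n_b: int
    statistic: float  # Mann-Whitney U for set_a
    p_value: float
    median_a: float
    median_b: float
    method: str

    def as_row(self) -> dict:
        return {
            "set_a": self.set_a,
            "set_b": self.set_b,
            "covariate": self.covariate,
            "n_a": self.n_a,
            "n_b": self.n_b,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "median_a": self.median_a,
            "median_b": self.median_b,
            "method": self.method,
        }


def wilcoxon_compare(
    values_a: Sequence[float] | pd.Series,
    values_b: Sequence[float] | pd.Series,
    set_a: str = "A",
    set_b: str = "B",
    covariate: str = "",
) -> CovariateComparison:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact enumeration is used when the combined sample size is at most
    ``EXACT_WILCOXON_MAX_N`` and there are no ties; otherwise the normal
    approximation with tie and continuity corrections.
    """
    a = pd.Series(values_a, dtype=float).dropna().to_numpy()
    b = pd.Series(values_b, dtype=float).dropna().to_numpy()
    if a.size == 0 or b.size == 0:
        raise ValidationError("a transcript set has no non-missing covariate values")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < pooled.size
    if a.size + b.size <= EXACT_WILCOXON_MAX_N and not has_ties:
        method = "exact"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    else:
        method = "asymptotic"
        res = stats.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=True
        )
    return CovariateComparison(
        set_a=set_a,
        set_b=set_b,
        covariate=covariate,
        n_a=int(a.size),
        n_b=int(b.size),
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        median_a=float(np.median(a)),
        median_b=float(np.median(b)),
        method=method,
    )


def summarize_groups(
    clusters: pd.Series,
    covariates: CovariateTable,
    covariate_names: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Box-plot style summaries per group plus all pairwise rank-sum tests.

    Quartiles use linear interpolation (type 7); whiskers extend to the most
    extreme value within 1.5 x IQR of the quartiles.  Pairwise Wilcoxon
    p-values are BH-corrected across group pairs within each covariate.
    Returns (summary table, comparison table).
    """
    if covariate_names is None:
        covariate_names = covariates.covariate_names
    shared = clusters.index.intersection(covariates.values.index)
    if shared.empty:
        raise ValidationError("clusters and covariates share no genes")
    clusters = clusters.loc[shared]
    summaries = []
    comparisons = []
    for name in covariate_names:
        col = covariates.column(name).loc[shared]
        by_group = {g: col[clusters == g].dropna() for g in sorted(clusters.unique())}
        for group, vals in by_group.items():
            if vals.empty:
                continue
            q1, med, q3 = np.percentile(vals, [25, 50, 75])
            iqr = q3 - q1
            lo = vals[vals >= q1 - 1.5 * iqr].min()
            hi = vals[vals <= q3 + 1.5 * iqr].max()
            outliers = vals[(vals < lo) | (vals > hi)]
            summaries.append(
                {
                    "covariate": name,
                    "group": group,
                    "n": int(vals.size),
                    "min": float(vals.min()),
                    "q1": float(q1),
                    "median": float(med),
                    "q3": float(q3),
                    "max": float(vals.max()),
                    "whisker_low": float(lo),
                    "whisker_high": float(hi),
                    "n_outliers": int(outliers.size),
                }
            )
        pair_rows = []
        for g1, g2 in combinations(sorted(by_group), 2):
            if by_group[g1].empty or by_group[g2].empty:
                continue
            cmp = wilcoxon_compare(by_group[g1], by_group[g2], g1, g2, name)
            pair_rows.append(cmp.as_row())
        if pair_rows:
            pairs = pd.DataFrame(pair_rows)
            pairs["fdr"] = bh_fdr(pairs["p_value"].to_numpy())
            comparisons.append(pairs)
    summary_df = pd.DataFrame(summaries)
    comparison_df = (
        pd.concat(comparisons, ignore_index=True) if comparisons else pd.DataFrame()
    )
    return summary_df, comparison_df
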