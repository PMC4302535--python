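"""Clustering: uncentered Pearson, average-linkage oracle equivalence, cuts,
archetype matching and heatmap export."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from riploop.clustering import (
    ClusterResult,
    build_profile_matrix,
    cut_groups,
    export_heatmap,
    hierarchical_cluster,
    match_groups_to_archetypes,
    select_cluster_genes,
    uncentered_pearson,
)
from riploop.enrichment import enrich_all_baits
from riploop.io import ValidationError
from riploop.simulate import generate_dataset

from conftest import small_config


# ---------------------------------------------------------------------------
# uncentered Pearson
# ---------------------------------------------------------------------------


class TestUncenteredPearson:
    def test_self_similarity_is_one(self):
        x = np.array([1.0, -2.0, 3.0])
        assert uncentered_pearson(x, x) == pytest.approx(1.0)

    def test_orthogonal_vectors(self):
        assert uncentered_pearson(np.array([1.0, 0.0]), np.array([0.0, 1.0])) == 0.0

    def test_differs_from_centered_pearson(self):
        # plain Pearson of (1,1) vs (1,-1) is -1; the uncentered form is 0
        assert uncentered_pearson(np.array([1.0, 1.0]), np.array([1.0, -1.0])) == 0.0

    def test_zero_vector_gives_nan_with_warning(self):
        with pytest.warns(UserWarning):
            out = uncentered_pearson(np.zeros(3), np.ones(3))
        assert np.isnan(out)

    @given(
        st.lists(st.floats(-50, 50), min_size=2, max_size=8),
        st.floats(0.01, 100.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_bounded_and_scale_invariant(self, values, scale):
        x = np.asarray(values)
        y = np.linspace(1, 2, len(values))
        if np.allclose(x, 0):
            return
        s = uncentered_pearson(x, y)
        assert -1.0 <= s <= 1.0
        assert uncentered_pearson(scale * x, y) == pytest.approx(s, abs=1e-9)


# ---------------------------------------------------------------------------
# brute-force average-linkage oracle
# ---------------------------------------------------------------------------


def brute_force_average_linkage(X):
    """O(n^3) agglomeration recomputing all average pairwise distances per step.

    Distances are 1 - uncentered Pearson.  Returns a list of
    (frozenset_a, frozenset_b, height) merges.
    """
    n = X.shape[0]

    def dist(i, j):
        return 1.0 - np.dot(X[i], X[j]) / (
            np.linalg.norm(X[i]) * np.linalg.norm(X[j])
        )

    clusters = {i: frozenset([i]) for i in range(n)}
    merges = []
    while len(clusters) > 1:
        best = None
        for a in sorted(clusters):
            for b in sorted(clusters):
                if a >= b:
                    continue
                d = np.mean(
                    [dist(i, j) for i in clusters[a] for j in clusters[b]]
                )
                if best is None or d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        merges.append((clusters[a], clusters[b], d))
        clusters[min(a, b)] = clusters[a] | clusters[b]
        del clusters[max(a, b)]
    return merges


def _tree_merges(result: ClusterResult, n: int):
    members = {i: frozenset([i]) for i in range(n)}
    merges = []
    for step, (a, b, h, _c) in enumerate(result.linkage):
        a, b = int(a), int(b)
        merged = members[a] | members[b]
        merges.append((members[a], members[b], h))
        members[n + step] = merged
    return merges


@pytest.mark.parametrize("seed", range(12))
def test_average_linkage_matches_bruteforce_oracle(seed):
    rng = np.random.default_rng(seed)
    n = 6
    X = rng.normal(size=(n, 4))
    profiles = pd.DataFrame(X, index=[f"g{i}" for i in range(n)])
    profiles.columns = pd.MultiIndex.from_product([["b"], range(4)], names=["bait", "replicate"])
    result = hierarchical_cluster(profiles)
    ours = _tree_merges(result, n)
    oracle = brute_force_average_linkage(X)
    for (a1, b1, h1), (a2, b2, h2) in zip(ours, oracle):
        assert {a1, b1} == {a2, b2}
        assert h1 == pytest.approx(h2, abs=1e-10)


@given(st.integers(0, 10_000))
@settings(max_examples=60, deadline=None)
def test_average_linkage_oracle_property(seed):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(6, 3))
    profiles = pd.DataFrame(X, index=[f"g{i}" for i in range(6)])
    profiles.columns = pd.MultiIndex.from_product([["b"], range(3)], names=["bait", "replicate"])
    ours = _tree_merges(hierarchical_cluster(profiles), 6)
    oracle = brute_force_average_linkage(X)
    for (a1, b1, h1), (a2, b2, h2) in zip(ours, oracle):
        assert {a1, b1} == {a2, b2}
        assert h1 == pytest.approx(h2, abs=1e-9)


class TestTreeBasics:
    def test_identical_rows_merge_at_height_zero(self):
        X = np.array([[1.0, 2.0], [1.0, 2.0], [5.0, -1.0]])
        profiles = pd.DataFrame(X, index=["a", "b", "c"])
        profiles.columns = pd.MultiIndex.from_product([["b"], range(2)], names=["bait", "replicate"])
        result = hierarchical_cluster(profiles)
        assert result.merge_heights[0] == pytest.approx(0.0, abs=1e-12)

    def test_row_permutation_gives_same_heights(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(8, 5))
        idx = [f"g{i}" for i in range(8)]
        cols = pd.MultiIndex.from_product([["b"], range(5)], names=["bait", "replicate"])
        p1 = pd.DataFrame(X, index=idx, columns=cols)
        perm = rng.permutation(8)
        p2 = p1.iloc[perm]
        h1 = np.sort(hierarchical_cluster(p1).merge_heights)
        h2 = np.sort(hierarchical_cluster(p2).merge_heights)
        np.testing.assert_allclose(h1, h2, atol=1e-12)

    def test_missing_values_rejected_naming_gene(self):
        profiles = pd.DataFrame(
            [[1.0, 2.0], [np.nan, 1.0]], index=["good", "bad"],
            columns=pd.MultiIndex.from_product([["b"], range(2)], names=["bait", "replicate"]),
        )
        with pytest.raises(ValidationError, match="bad"):
            hierarchical_cluster(profiles)


@pytest.fixture
def tree():
    rng = np.random.default_rng(8)
    X = rng.normal(size=(10, 4))
    profiles = pd.DataFrame(X, index=[f"g{i}" for i in range(10)])
    profiles.columns = pd.MultiIndex.from_product([["b"], range(4)], names=["bait", "replicate"])
    return hierarchical_cluster(profiles)


class TestCutGroups:
    def test_k_equals_n_gives_singletons(self, tree):
        labels = cut_groups(tree, k=10)
        assert labels.nunique() == 10

    def test_k_one_gives_single_group(self, tree):
        assert cut_groups(tree, k=1).nunique() == 1

    def test_k_above_n_rejected(self, tree):
        with pytest.raises(ValidationError):
            cut_groups(tree, k=11)


def test_within_group_similarity_exceeds_between(small_dataset):
    """Mean uncentered-Pearson similarity within a planted group exceeds
    similarity to every other group."""
    matrix, sheet, truth = small_dataset
    genes = truth.genes.index[truth.group_labels != "background"]
    profiles = build_profile_matrix(matrix, sheet, set(genes))
    X = profiles.to_numpy()
    X = X / np.linalg.norm(X, axis=1, keepdims=True)
    sim = X @ X.T
    labels = truth.group_labels.loc[profiles.index].to_numpy()
    groups = sorted(set(labels))
    for g1 in groups:
        within = sim[np.ix_(labels == g1, labels == g1)]
        mean_within = (within.sum() - len(within)) / max(len(within) ** 2 - len(within), 1)
        for g2 in groups:
            if g1 == g2:
                continue
            between = sim[np.ix_(labels == g1, labels == g2)].mean()
            assert mean_within > between


def test_selection_rules(small_dataset):
    """FDR-in-any-bait plus Total-count-in-all-baits selection logic."""
    matrix, sheet, _ = small_dataset
    tables = enrich_all_baits(matrix, sheet)
    selected = select_cluster_genes(tables, matrix, sheet, fdr_threshold=0.01)
    fdr = pd.DataFrame({b: t["fdr"] for b, t in tables.items()})
    from riploop.enrichment import filter_by_total_counts

    count_ok = filter_by_total_counts(matrix, sheet, sheet.proteins)
    for gene in list(selected)[:50]:
        assert (fdr.loc[gene] < 0.01).any() and gene in count_ok
    not_selected = set(matrix.gene_ids) - selected
    for gene in list(not_selected)[:50]:
        assert (fdr.loc[gene] >= 0.01).all() or np.isnan(fdr.loc[gene]).all() or gene not in count_ok


def test_archetype_matching_recovers_planted_groups(small_dataset):
    matrix, sheet, truth = small_dataset
    cfg = truth.config
    genes = truth.genes.index[truth.group_labels != "background"]
    profiles = build_profile_matrix(matrix, sheet, set(genes))
    tree = hierarchical_cluster(profiles)
    clusters = cut_groups(tree, k=7)
    groups = match_groups_to_archetypes(profiles, clusters, cfg.polya_binder, cfg.repressors)
    tl = truth.group_labels.loc[groups.index]
    agreement = (groups == tl).mean()
    assert agreement > 0.9


def test_heatmap_export_deterministic(small_dataset, tmp_path):
    matrix, sheet, truth = small_dataset
    genes = list(truth.genes.index[:40])
    profiles = build_profile_matrix(matrix, sheet, set(genes))
    tree = hierarchical_cluster(profiles)
    tsv1, png1 = export_heatmap(profiles, tree, tmp_path / "h1")
    tsv2, _ = export_heatmap(profiles, tree, tmp_path / "h2")
    ordered = pd.read_csv(tsv1, sep="\t", index_col=0)
    assert list(ordered.index) == tree.ordered_genes
    assert tsv1.read_bytes() == tsv2.read_bytes()
    assert png1.exists()


def test_adjusted_rand_index_matches_sklearn():
    from sklearn.metrics import adjusted_rand_score

    from riploop.evaluation import adjusted_rand_index

    rng = np.random.default_rng(13)
    for _ in range(20):
        a = rng.integers(0, 4, size=60)
        b = rng.integers(0, 5, size=60)
        assert adjusted_rand_index(a, b) == pytest.approx(
            adjusted_rand_score(a, b), abs=1e-12
        )
    assert adjusted_rand_index([1, 1, 2, 2], [3, 3, 4, 4]) == pytest.approx(1.0)
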