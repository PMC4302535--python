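"""Hierarchical clustering of per-bait enrichment profiles into binding groups.

Profiles are per-replicate log2(IP/Total) CPM ratios for the genes that show
significant enrichment or under-representation (FDR below a conservative
threshold) in at least one bait and pass the Total-library read-count filter
in every bait.  The similarity metric is the uncentered Pearson correlation
(cosine similarity, no mean-centering) and the linkage is average; the
distance transform is d = 1 - s.  Groups are extracted by cutting the tree
at a target count k and, optionally, merging the cut clusters into four named
binding groups by matching each cluster's mean per-bait profile against the
archetypal sign patterns:

* group I   — under-represented with every bait except the poly(A) binder;
* group II  — enriched with the two repressors only;
* group III — enriched with the closed-loop baits, depleted of repressors;
* group IV  — enriched with everything.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .enrichment import DEFAULT_PSEUDOCOUNT, cpm, filter_by_total_counts
from .io import FRACTION_IP, FRACTION_TOTAL, CountMatrix, SampleSheet, ValidationError

logger = logging.getLogger(__name__)


def uncentered_pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Cosine similarity sum(x*y) / sqrt(sum(x^2) sum(y^2)); no centering.

    Unlike the plain Pearson coefficient the means are not subtracted, so two
    vectors with proportional values but opposite deviations from their means
    can still score highly.  Returns NaN (with a warning) for a zero-norm
    argument.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 1:
        raise ValueError("inputs must be equal-length 1-d vectors")
    nx = np.sqrt((x**2).sum())
    ny = np.sqrt((y**2).sum())
    if nx == 0 or ny == 0:
        warnings.warn("uncentered Pearson undefined for a zero vector", stacklevel=2)
        return float("nan")
    return float(np.clip((x * y).sum() / (nx * ny), -1.0, 1.0))


def select_cluster_genes(
    enrichment_tables: Mapping[str, pd.DataFrame],
    matrix: CountMatrix,
    sheet: SampleSheet,
    fdr_threshold: float = 0.01,
    min_total_count: int = 20,
    baits: Sequence[str] | None = None,
) -> set[str]:
    """Differential transcript set for clustering.

    Genes significant (FDR < threshold) in at least one bait's paired
    enrichment test AND exceeding the Total-count filter in every bait.
    """
    baits = list(baits) if baits is not None else sheet.proteins
    significant: pd.Series | None = None
    for bait in baits:
        table = enrichment_tables[bait]
        hit = table["fdr"] < fdr_threshold
        significant = hit if significant is None else (significant | hit)
    assert significant is not None
    count_ok = filter_by_total_counts(matrix, sheet, baits, threshold=min_total_count)
    selected = set(significant.index[significant]) & count_ok
    if not selected:
        logger.warning("no genes pass the clustering selection filters")
    return selected


def build_profile_matrix(
    matrix: CountMatrix,
    sheet: SampleSheet,
    genes: Sequence[str] | set[str],
    baits: Sequence[str] | None = None,
    aggregate_replicates: bool = False,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Genes x (bait, replicate) matrix of per-replicate log2 CPM ratios.

    With ``aggregate_replicates`` the per-bait median over replicates is used
    instead, giving one column per bait.  Column metadata is encoded in the
    column MultiIndex (bait, replicate).
    """
    baits = list(baits) if baits is not None else sheet.proteins
    genes = sorted(genes)
    cpm_table = cpm(matrix).loc[genes]
    columns = {}
    for bait in baits:
        for rep in sheet.replicates(bait):
            ip = cpm_table[sheet.sample_id(bait, rep, FRACTION_IP)]
            total = cpm_table[sheet.sample_id(bait, rep, FRACTION_TOTAL)]
            columns[(bait, rep)] = np.log2((ip + pseudocount) / (total + pseudocount))
    profiles = pd.DataFrame(columns)
    profiles.columns = pd.MultiIndex.from_tuples(profiles.columns, names=["bait", "replicate"])
    if aggregate_replicates:
        profiles = profiles.T.groupby(level="bait", sort=False).median().T
        profiles.columns = pd.MultiIndex.from_product(
            [profiles.columns, [0]], names=["bait", "replicate"]
        )
    return profiles


@dataclass
class ClusterResult:
    """Average-linkage tree over genes with 1 - uncentered-Pearson distances."""

    linkage: np.ndarray  # scipy linkage matrix (n-1, 4)
    genes: list[str]
    leaf_order: list[int]
    metric: str = "uncentered_pearson"
    linkage_name: str = "average"

    @property
    def ordered_genes(self) -> list[str]:
        return [self.genes[i] for i in self.leaf_order]

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2]


def hierarchical_cluster(profiles: pd.DataFrame) -> ClusterResult:
    """Agglomerative average-linkage clustering of profile rows.

    Distances are 1 - uncentered Pearson similarity (the cosine distance).
    Leaf order follows the standard recursive rule: at each merge the subtree
    containing the smaller minimum original index is placed first.
    """
    if profiles.shape[0] < 2:
        raise ValidationError("need at least 2 profile rows to cluster")
    bad = profiles.index[~np.isfinite(profiles).all(axis=1)].tolist()
    if bad:
        raise ValidationError(f"profiles contain missing values for genes: {bad[:5]}")
    X = profiles.to_numpy(dtype=float)
    d = pdist(X, metric="cosine")  # == 1 - uncentered Pearson
    Z = hierarchy.linkage(d, method="average")
    leaf_order = _leaf_order(Z, X.shape[0])
    return ClusterResult(linkage=Z, genes=list(profiles.index), leaf_order=leaf_order)


def _leaf_order(Z: np.ndarray, n: int) -> list[int]:
    """Recursive leaf ordering: subtree with the smaller minimum index first."""
    min_leaf: dict[int, int] = {i: i for i in range(n)}
    children: dict[int, tuple[int, int]] = {}
    for step, (a, b, _h, _c) in enumerate(Z):
        a, b = int(a), int(b)
        node = n + step
        first, second = (a, b) if min_leaf[a] <= min_leaf[b] else (b, a)
        children[node] = (first, second)
        min_leaf[node] = min(min_leaf[a], min_leaf[b])
    order: list[int] = []
    stack = [n + len(Z) - 1] if len(Z) else [0]
    while stack:
        node = stack.pop()
        if node < n:
            order.append(node)
        else:
            first, second = children[node]
            stack.append(second)
            stack.append(first)
    return order


def cut_groups(
    tree: ClusterResult,
    k: int | None = None,
    height: float | None = None,
) -> pd.Series:
    """Cut the tree into flat clusters by target count k or merge height.

    Clusters are labelled ``C1, C2, ...`` in order of first appearance along
    the leaf ordering.
    """
    n = len(tree.genes)
    if k is not None:
        if not 1 <= k <= n:
            raise ValidationError(f"k must lie in [1, {n}]")
        flat = hierarchy.fcluster(tree.linkage, t=k, criterion="maxclust")
    elif height is not None:
        if height < 0:
            raise ValidationError("height must be >= 0")
        flat = hierarchy.fcluster(tree.linkage, t=height, criterion="distance")
    else:
        raise ValidationError("either k or height must be given")
    labels = pd.Series(flat, index=tree.genes)
    relabel: dict[int, str] = {}
    for gene in tree.ordered_genes:
        c = labels[gene]
        if c not in relabel:
            relabel[c] = f"C{len(relabel) + 1}"
    return labels.map(relabel)


def group_archetypes(
    baits: Sequence[str],
    polya_binder: str | None,
    repressors: Sequence[str],
) -> pd.DataFrame:
    """Sign-pattern archetypes of the four binding groups over the given baits."""
    rows = {}
    for group in ("I", "II", "III", "IV"):
        signs = []
        for bait in baits:
            is_rep = bait in repressors
            is_polya = bait == polya_binder
            if group == "I":
                signs.append(0.0 if is_polya else -1.0)
            elif group == "II":
                signs.append(1.0 if is_rep else 0.0)
            elif group == "III":
                signs.append(-1.0 if is_rep else 1.0)
            else:
                signs.append(1.0)
        rows[group] = signs
    return pd.DataFrame(rows, index=list(baits)).T


def match_groups_to_archetypes(
    profiles: pd.DataFrame,
    cluster_labels: pd.Series,
    polya_binder: str | None,
    repressors: Sequence[str],
    min_similarity: float = 0.0,
) -> pd.Series:
    """Merge flat clusters into the named binding groups I-IV.

    Each cluster's mean per-bait profile is compared (uncentered Pearson)
    against the four archetypal sign patterns; the cluster inherits the best
    matching group name, or ``unassigned`` when no archetype exceeds
    ``min_similarity``.
    """
    baits = list(profiles.columns.get_level_values("bait").unique())
    arch = group_archetypes(baits, polya_binder, repressors)
    per_bait = profiles.T.groupby(level="bait", sort=False).mean().T
    mapping: dict[str, str] = {}
    for cluster in cluster_labels.unique():
        members = cluster_labels.index[cluster_labels == cluster]
        mean_profile = per_bait.loc[members].mean(axis=0).reindex(baits).to_numpy()
        sims = {g: uncentered_pearson(mean_profile, arch.loc[g].to_numpy()) for g in arch.index}
        best = max(sims, key=lambda g: sims[g])
        mapping[cluster] = best if sims[best] >= min_similarity else "unassigned"
    return cluster_labels.map(mapping)


def export_heatmap(
    profiles: pd.DataFrame,
    tree: ClusterResult,
    path_prefix: str | Path,
    labels: pd.Series | None = None,
) -> tuple[Path, Path]:
    """Write the leaf-ordered profile TSV and a diverging heatmap PNG.

    The colour scale is centred at log2 enrichment 0 (red = enriched,
    blue = under-represented).  Returns (tsv_path, png_path).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import seaborn as sns

    path_prefix = Path(path_prefix)
    ordered = profiles.loc[tree.ordered_genes]
    tsv_path = path_prefix.with_suffix(".tsv")
    out = ordered.copy()
    out.columns = [f"{b}.rep{r}" for b, r in out.columns]
    if labels is not None:
        out.insert(0, "group", labels.reindex(ordered.index))
    out.index.name = "gene_id"
    out.to_csv(tsv_path, sep="\t")

    png_path = path_prefix.with_suffix(".png")
    vmax = float(np.nanpercentile(np.abs(ordered.to_numpy()), 99)) or 1.0
    fig, ax = plt.subplots(figsize=(8, 10))
    sns.heatmap(
        ordered,
        cmap="RdBu_r",
        center=0.0,
        vmin=-vmax,
        vmax=vmax,
        yticklabels=False,
        xticklabels=[f"{b}.{r}" for b, r in ordered.columns],
        cbar_kws={"label": "log2(IP/Total)"},
        ax=ax,
    )
    ax.set_ylabel(f"{ordered.shape[0]} transcripts (leaf order)")
    fig.tight_layout()
    fig.savefig(png_path, dpi=150)
    plt.close(fig)
    return tsv_path, png_path
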