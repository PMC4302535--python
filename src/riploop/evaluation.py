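"""Simulation-based evaluation scenarios for the pipeline.

Each function generates a synthetic experiment with known truth, runs the
relevant pipeline stage(s), and returns the recovery or calibration measure:
type-I error of the paired enrichment test, empirical FDR and sensitivity on
planted effects, the interaction-test null rate for an identical-profile bait
pair, clustering recovery of the planted binding groups, stoichiometric
coefficient / outlier recovery, and planted gene-set term recovery.  These
are the quantitative checks a user can run to convince themselves the
statistics behave as advertised at desk scale.
"""

from __future__ import annotations

from math import comb

import numpy as np
import pandas as pd

from . import clustering, enrichment, sets, stoichiometry
from .simulate import SimulationConfig, generate_dataset, generate_gene_sets


def _single_bait_config(**kwargs) -> SimulationConfig:
    defaults = dict(
        proteins=("bait1",),
        hub=None,
        polya_binder=None,
        repressors=(),
        partners=(),
        beta_true=(),
        group_proportions={},
        n_outliers=0,
    )
    defaults.update(kwargs)
    return SimulationConfig(**defaults)


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Adjusted Rand index between two partitions of the same items."""
    a = pd.Series(labels_a).astype(str).to_numpy()
    b = pd.Series(labels_b).astype(str).to_numpy()
    if a.shape != b.shape:
        raise ValueError("label vectors must have equal length")
    n = a.size
    table = pd.crosstab(a, b).to_numpy()
    sum_cells = sum(comb(int(x), 2) for x in table.ravel())
    sum_rows = sum(comb(int(x), 2) for x in table.sum(axis=1))
    sum_cols = sum(comb(int(x), 2) for x in table.sum(axis=0))
    total = comb(n, 2)
    expected = sum_rows * sum_cols / total if total else 0.0
    max_index = 0.5 * (sum_rows + sum_cols)
    if max_index == expected:
        return 1.0
    return (sum_cells - expected) / (max_index - expected)


# ---------------------------------------------------------------------------
# enrichment-test calibration
# ---------------------------------------------------------------------------


def null_type_i_error(seed: int, n_genes: int = 2000, alpha: float = 0.05) -> float:
    """Pure-null rejection rate of the paired enrichment test at p < alpha."""
    cfg = _single_bait_config(n_genes=n_genes, seed=seed)
    matrix, sheet, _ = generate_dataset(cfg)
    table = enrichment.test_enrichment(matrix, sheet, "bait1")
    p = table["p_value"].dropna()
    return float((p < alpha).mean())


def enrichment_recovery(seed: int, n_genes: int = 2000) -> tuple[float, float]:
    """(empirical FDR, sensitivity) at BH 0.05 for balanced +/-1.5 log2
    planting on 10% of genes."""
    cfg = _single_bait_config(
        n_genes=n_genes,
        group_proportions={"I": 0.05, "IV": 0.05},
        effect_jitter=0.0,
        seed=seed,
    )
    matrix, sheet, truth = generate_dataset(cfg)
    table = enrichment.test_enrichment(matrix, sheet, "bait1")
    differential = truth.group_labels != "background"
    sig = table["fdr"] < 0.05
    emp_fdr = float((sig & ~differential).sum() / max(int(sig.sum()), 1))
    sensitivity = float((sig & differential).sum() / differential.sum())
    return emp_fdr, sensitivity


def interaction_null_rate(seed: int, n_genes: int = 2000) -> float:
    """Fraction of genes called significant (FDR < 0.05) between two baits
    simulated with literally identical enrichment profiles."""
    cfg = SimulationConfig(
        n_genes=n_genes,
        proteins=("isoform1", "isoform2"),
        hub=None,
        polya_binder=None,
        repressors=(),
        partners=(),
        beta_true=(),
        group_proportions={"I": 0.10, "III": 0.10, "IV": 0.10},
        shared_profile_baits=(("isoform1", "isoform2"),),
        n_outliers=0,
        seed=seed,
    )
    matrix, sheet, truth = generate_dataset(cfg)
    assert (truth.enrichment("isoform1") == truth.enrichment("isoform2")).all()
    table = enrichment.test_interaction(matrix, sheet, "isoform1", "isoform2")
    return float((table["fdr"] < 0.05).mean())


# ---------------------------------------------------------------------------
# clustering recovery
# ---------------------------------------------------------------------------


def clustering_group_recovery(seed: int, n_genes: int = 2000) -> dict:
    """Cluster the selected transcripts of a default six-bait experiment.

    Returns the adjusted Rand index of the k=5 cut against the planted truth
    labels over all selected genes (``ari``), the same index restricted to
    genes from the four planted groups (``ari_planted``), and the number of
    selected genes.
    """
    cfg = SimulationConfig(n_genes=n_genes, seed=seed)
    matrix, sheet, truth = generate_dataset(cfg)
    tables = enrichment.enrich_all_baits(matrix, sheet)
    selected = clustering.select_cluster_genes(tables, matrix, sheet, fdr_threshold=0.01)
    profiles = clustering.build_profile_matrix(matrix, sheet, selected)
    tree = clustering.hierarchical_cluster(profiles)
    labels = clustering.cut_groups(tree, k=5)
    truth_labels = truth.group_labels.loc[labels.index]
    planted = truth_labels != "background"
    return {
        "ari": adjusted_rand_index(truth_labels, labels),
        "ari_planted": adjusted_rand_index(truth_labels[planted], labels[planted]),
        "n_selected": len(selected),
    }


# ---------------------------------------------------------------------------
# stoichiometric decomposition
# ---------------------------------------------------------------------------


def stoichiometry_beta_recovery(seed: int, n_genes: int = 3000) -> pd.Series:
    """Estimated partner coefficients from the true enrichment profiles of a
    default-configuration experiment (hub noise sd 0.3)."""
    cfg = SimulationConfig(n_genes=n_genes, n_outliers=0, seed=seed)
    _, _, truth = generate_dataset(cfg)
    em = truth.enrichment_matrix()
    fit = stoichiometry.fit_linear_decomposition(
        em[cfg.hub], em[list(cfg.partners)], target_name=cfg.hub
    )
    return fit.beta.drop("intercept")


def outlier_recovery(seed: int, n_genes: int = 3000) -> bool:
    """Two +3 log2 outliers planted on the hub relation (noise sd 0.3):
    do they occupy the top-2 |jackknife residual| ranks?"""
    cfg = SimulationConfig(n_genes=n_genes, n_outliers=2, outlier_shift=3.0, seed=seed)
    _, _, truth = generate_dataset(cfg)
    em = truth.enrichment_matrix()
    fit = stoichiometry.fit_linear_decomposition(
        em[cfg.hub], em[list(cfg.partners)], target_name=cfg.hub
    )
    ranked = stoichiometry.flag_outliers(fit)
    return set(ranked.index[:2]) == set(truth.outlier_genes)


def r_squared_at_signal_fraction(
    seed: int, signal_fraction: float = 0.75, n_genes: int = 3000
) -> float:
    """Fitted R^2 of the hub decomposition when the generator's hub noise is
    calibrated to the given signal fraction."""
    cfg = SimulationConfig(
        n_genes=n_genes, hub_signal_fraction=signal_fraction, seed=seed
    )
    _, _, truth = generate_dataset(cfg)
    em = truth.enrichment_matrix()
    fit = stoichiometry.fit_linear_decomposition(
        em[cfg.hub], em[list(cfg.partners)], target_name=cfg.hub
    )
    return float(fit.r_squared)


# ---------------------------------------------------------------------------
# gene-set term recovery (enrichment -> clustering -> hypergeometric chain)
# ---------------------------------------------------------------------------


def planted_term_recovery(seed: int, n_genes: int = 2000) -> dict:
    """Run enrichment, clustering and set statistics; report the planted
    group-III term's over-representation FDR within the recovered group III."""
    cfg = SimulationConfig(n_genes=n_genes, seed=seed)
    matrix, sheet, truth = generate_dataset(cfg)
    gene_sets = generate_gene_sets(truth, n_terms=20, planted_odds={"III": 5.0})
    tables = enrichment.enrich_all_baits(matrix, sheet)
    selected = clustering.select_cluster_genes(tables, matrix, sheet, fdr_threshold=0.01)
    profiles = clustering.build_profile_matrix(matrix, sheet, selected)
    tree = clustering.hierarchical_cluster(profiles)
    clusters = clustering.cut_groups(tree, k=7)
    groups = clustering.match_groups_to_archetypes(
        profiles, clusters, cfg.polya_binder, cfg.repressors
    )
    universe = enrichment.filter_by_total_counts(matrix, sheet, sheet.proteins)
    members = set(groups.index[groups == "III"]) & universe
    if not members:
        return {"term_fdr": float("nan"), "recovered": False, "n_group_iii": 0}
    stats_table = sets.hypergeometric_enrichment(members, gene_sets, universe)
    fdr = float(stats_table.loc["planted_III", "fdr_over"])
    top_term = stats_table["fdr_over"].idxmin()
    return {
        "term_fdr": fdr,
        "recovered": fdr < 0.01,
        "top_term_is_planted": top_term == "planted_III",
        "n_group_iii": len(members),
    }
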