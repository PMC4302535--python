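"""End-to-end orchestration: simulate -> enrich -> interact -> cluster ->
stoichiometry -> set analysis, with a run manifest and a markdown report.

Every stage writes plain TSV outputs into the results directory; the report
is regenerated from those persisted tables only, so it can be rebuilt without
recomputation.  A manifest records inputs, thresholds, seed, per-stage row
counts and content hashes of the central tables, making repeated runs
byte-comparable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clustering, enrichment, sets, stoichiometry
from .io import (
    CountMatrix,
    CovariateTable,
    GeneSetCollection,
    SampleSheet,
    read_counts,
    read_covariates,
    read_gene_sets,
    read_sample_sheet,
    write_counts,
    write_covariates,
    write_gene_sets,
    write_sample_sheet,
    write_table,
)
from .simulate import (
    ConfigError,
    SimulationConfig,
    generate_covariates,
    generate_dataset,
    generate_gene_sets,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Declarative configuration for the full pipeline run."""

    counts: str | None = None
    sample_sheet: str | None = None
    gene_sets: str | None = None
    covariates: str | None = None
    out_dir: str = "results"
    enrichment_fdr: float = 0.05
    cluster_fdr: float = 0.01
    min_total_count: int = 20
    k_groups: int = 7
    outlier_alpha: float = 0.05
    pseudocount: float = 0.5
    hub: str | None = "eIF4E"
    predictors: tuple[str, ...] = ("eIF4G1", "eIF4G2", "Caf20", "Eap1")
    polya_binder: str | None = "Pab1"
    repressors: tuple[str, ...] = ("Caf20", "Eap1")
    include_intercept: bool = True
    aggregate_replicates: bool = False
    simulation: SimulationConfig | None = None
    seed: int = 0

    def validate(self) -> None:
        for name, value in (
            ("enrichment_fdr", self.enrichment_fdr),
            ("cluster_fdr", self.cluster_fdr),
            ("outlier_alpha", self.outlier_alpha),
        ):
            if not 0 < value <= 1:
                raise ConfigError(f"{name} must lie in (0, 1], got {value}")
        if self.min_total_count < 0:
            raise ConfigError("min_total_count must be >= 0")
        if self.k_groups < 1:
            raise ConfigError("k_groups must be >= 1")
        if self.hub is not None and self.hub in self.predictors:
            raise ConfigError("hub must not appear among its predictors")
        if len(set(self.predictors)) != len(self.predictors):
            raise ConfigError("duplicate predictor baits")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as handle:
            raw = yaml.safe_load(handle) or {}
        sim = raw.pop("simulation", None)
        for key in ("predictors", "repressors"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        config = cls(**raw)
        if sim is not None:
            for key in ("proteins", "repressors", "partners", "beta_true"):
                if key in sim and sim[key] is not None:
                    sim[key] = tuple(sim[key])
            if "shared_profile_baits" in sim:
                sim["shared_profile_baits"] = tuple(
                    tuple(g) for g in sim["shared_profile_baits"]
                )
            config.simulation = SimulationConfig(**sim)
        return config


def _hash_frame(df: pd.DataFrame) -> str:
    payload = df.to_csv(sep="\t").encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def simulate_to_dir(
    config: PipelineConfig, out_dir: str | Path, force: bool = False
) -> dict[str, Path]:
    """Write a simulated dataset (counts, sheet, truth, covariates, gene sets)."""
    if config.simulation is None:
        raise ConfigError("no simulation block in the configuration")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": out / "counts.tsv",
        "sample_sheet": out / "sample_sheet.tsv",
        "truth": out / "truth.json",
        "covariates": out / "covariates.tsv",
        "gene_sets": out / "gene_sets.gmt",
    }
    existing = [p for p in paths.values() if p.exists()]
    if existing and not force:
        raise FileExistsError(
            f"outputs already exist (use force to overwrite): {existing[0]}"
        )
    sim = config.simulation.replace(seed=config.simulation.seed or config.seed)
    logger.info("simulate: seed=%d genes=%d baits=%d", sim.seed, sim.n_genes, len(sim.proteins))
    matrix, sheet, truth = generate_dataset(sim)
    write_counts(matrix, paths["counts"])
    write_sample_sheet(sheet, paths["sample_sheet"])
    truth.to_json(paths["truth"])
    write_covariates(generate_covariates(truth), paths["covariates"])
    write_gene_sets(generate_gene_sets(truth), paths["gene_sets"])
    return paths


@dataclass
class RunResult:
    """Handles to the tables a full pipeline run produced."""

    out_dir: Path
    enrichment_tables: dict[str, pd.DataFrame]
    interaction_tables: dict[tuple[str, str], pd.DataFrame]
    cluster_labels: pd.Series | None
    group_labels: pd.Series | None
    fit: stoichiometry.StoichiometricFit | None
    outliers: pd.DataFrame | None
    set_stats: dict[str, pd.DataFrame] = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)


def run_all(
    matrix: CountMatrix,
    sheet: SampleSheet,
    config: PipelineConfig,
    gene_sets: GeneSetCollection | None = None,
    covariates: CovariateTable | None = None,
    out_dir: str | Path | None = None,
) -> RunResult:
    """Execute the full analysis chain and persist per-stage TSV outputs."""
    config.validate()
    sheet.validate_against(matrix)
    out = Path(out_dir or config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "thresholds": {
            "enrichment_fdr": config.enrichment_fdr,
            "cluster_fdr": config.cluster_fdr,
            "min_total_count": config.min_total_count,
            "k_groups": config.k_groups,
            "outlier_alpha": config.outlier_alpha,
        },
        "n_genes": matrix.n_genes,
        "n_samples": len(matrix.sample_ids),
        "stages": {},
    }

    def _stage(name: str, rows: int, started: float, **extra) -> None:
        manifest["stages"][name] = {
            "rows": rows,
            "elapsed_s": round(time.monotonic() - started, 3),
            **extra,
        }
        logger.info("stage %s: %d rows (%.2fs)", name, rows, time.monotonic() - started)

    # --- enrichment per bait -------------------------------------------------
    t0 = time.monotonic()
    dispersions = enrichment.estimate_dispersions(matrix, sheet)
    write_table(dispersions.table.rename_axis("gene_id"), out / "dispersions.tsv")
    tables = enrichment.enrich_all_baits(
        matrix,
        sheet,
        dispersions=dispersions,
        pseudocount=config.pseudocount,
        min_total_count=config.min_total_count,
    )
    combined_hash = []
    for bait, table in tables.items():
        write_table(table.rename_axis("gene_id"), out / f"enrichment_{bait}.tsv")
        combined_hash.append(_hash_frame(table))
    _stage(
        "enrichment",
        sum(int(t["tested"].sum()) for t in tables.values()),
        t0,
        table_hash=hashlib.sha256("".join(combined_hash).encode()).hexdigest()[:16],
    )

    # --- pairwise interaction contrasts -------------------------------------
    t0 = time.monotonic()
    interactions: dict[tuple[str, str], pd.DataFrame] = {}
    summary_rows = []
    for bait_a, bait_b in combinations(sheet.proteins, 2):
        table = enrichment.test_interaction(
            matrix, sheet, bait_a, bait_b, dispersions=dispersions
        )
        interactions[(bait_a, bait_b)] = table
        write_table(
            table.rename_axis("gene_id"), out / f"interaction_{bait_a}_vs_{bait_b}.tsv"
        )
        sig = table["fdr"] < config.enrichment_fdr
        summary_rows.append(
            {
                "bait_a": bait_a,
                "bait_b": bait_b,
                "n_significant": int(sig.sum()),
                "n_over_in_a": int((sig & (table["delta_log2"] > 0)).sum()),
                "n_over_in_b": int((sig & (table["delta_log2"] < 0)).sum()),
            }
        )
    interaction_summary = pd.DataFrame(summary_rows)
    write_table(interaction_summary, out / "interaction_summary.tsv", index=False)
    _stage("interactions", len(interactions), t0)

    # --- clustering ----------------------------------------------------------
    t0 = time.monotonic()
    selected = clustering.select_cluster_genes(
        tables,
        matrix,
        sheet,
        fdr_threshold=config.cluster_fdr,
        min_total_count=config.min_total_count,
    )
    cluster_labels = group_labels = None
    if len(selected) >= 2:
        profiles = clustering.build_profile_matrix(
            matrix,
            sheet,
            selected,
            aggregate_replicates=config.aggregate_replicates,
            pseudocount=config.pseudocount,
        )
        tree = clustering.hierarchical_cluster(profiles)
        cluster_labels = clustering.cut_groups(tree, k=min(config.k_groups, len(selected)))
        group_labels = clustering.match_groups_to_archetypes(
            profiles, cluster_labels, config.polya_binder, config.repressors
        )
        assignment = pd.DataFrame(
            {
                "cluster": cluster_labels,
                "group": group_labels,
                "leaf_position": pd.Series(
                    np.arange(len(tree.ordered_genes)), index=tree.ordered_genes
                ),
            }
        ).rename_axis("gene_id")
        write_table(assignment.sort_values("leaf_position"), out / "cluster_assignments.tsv")
        merge_table = pd.DataFrame(
            tree.linkage, columns=["node_a", "node_b", "height", "n_leaves"]
        )
        write_table(merge_table, out / "cluster_tree.tsv", index=False)
        clustering.export_heatmap(profiles, tree, out / "heatmap", labels=group_labels)
    else:
        logger.warning("clustering skipped: %d gene(s) selected", len(selected))
    _stage("clustering", len(selected), t0)

    # --- stoichiometric decomposition ---------------------------------------
    t0 = time.monotonic()
    fit = outliers = None
    if config.hub is not None and config.hub in sheet.proteins:
        stoich_genes = enrichment.filter_by_total_counts(
            matrix, sheet, sheet.proteins, threshold=config.min_total_count
        )
        profile_frame = pd.DataFrame(
            {b: tables[b]["log2_enrichment"] for b in (config.hub, *config.predictors)}
        ).loc[sorted(stoich_genes)]
        fit = stoichiometry.fit_linear_decomposition(
            profile_frame[config.hub],
            profile_frame[list(config.predictors)],
            include_intercept=config.include_intercept,
            target_name=config.hub,
        )
        outliers = stoichiometry.flag_outliers(fit, alpha=config.outlier_alpha)
        write_table(
            stoichiometry.fit_summary_table(fit), out / "stoichiometry_coefficients.tsv"
        )
        write_table(
            outliers.rename_axis("gene_id"), out / "stoichiometry_outliers.tsv"
        )
        stoichiometry.plot_residuals(fit, out / "stoichiometry_residuals.png")
        manifest["stoichiometry"] = {
            "r_squared": fit.r_squared,
            "condition_number": fit.condition_number,
            "beta": {k: float(v) for k, v in fit.beta.items()},
        }
        _stage("stoichiometry", fit.n_genes, t0)
    else:
        logger.info("stoichiometry skipped: no hub bait configured")

    # --- set analysis --------------------------------------------------------
    set_stats: dict[str, pd.DataFrame] = {}
    if gene_sets is not None and group_labels is not None:
        t0 = time.monotonic()
        universe = enrichment.filter_by_total_counts(
            matrix, sheet, sheet.proteins, threshold=config.min_total_count
        )
        term_rows = []
        for group in sorted(g for g in group_labels.unique() if g != "unassigned"):
            members = set(group_labels.index[group_labels == group]) & universe
            if not members:
                continue
            table = sets.hypergeometric_enrichment(members, gene_sets, universe)
            table.insert(0, "group", group)
            set_stats[group] = table
            term_rows.append(table.reset_index())
        if term_rows:
            all_terms = pd.concat(term_rows, ignore_index=True)
            write_table(all_terms, out / "set_enrichment.tsv", index=False)
        chi_rows = []
        grouped = group_labels[group_labels != "unassigned"]
        if grouped.nunique() >= 2:
            for term_id in gene_sets.term_ids:
                res = sets.chisq_across_clusters(grouped, gene_sets.members(term_id))
                chi_rows.append(
                    {
                        "term_id": term_id,
                        "statistic": res["statistic"],
                        "p_value": res["p_value"],
                        "df": res["df"],
                    }
                )
            chi_table = pd.DataFrame(chi_rows)
            chi_table["fdr"] = enrichment.bh_fdr(chi_table["p_value"].to_numpy())
            write_table(chi_table, out / "set_chisq.tsv", index=False)
        _stage("set_enrichment", sum(len(t) for t in set_stats.values()), t0)
    if covariates is not None and group_labels is not None:
        t0 = time.monotonic()
        grouped = group_labels[group_labels != "unassigned"]
        summary, comparisons = sets.summarize_groups(grouped, covariates)
        write_table(summary, out / "covariate_summary.tsv", index=False)
        write_table(comparisons, out / "covariate_comparisons.tsv", index=False)
        _stage("covariates", len(summary), t0)

    manifest_path = out / "manifest.json"
    with open(manifest_path, "w", encoding="utf-8") as handle:
        json.dump(manifest, handle, indent=1, sort_keys=True)
        handle.write("\n")

    result = RunResult(
        out_dir=out,
        enrichment_tables=tables,
        interaction_tables=interactions,
        cluster_labels=cluster_labels,
        group_labels=group_labels,
        fit=fit,
        outliers=outliers,
        set_stats=set_stats,
        manifest=manifest,
    )
    write_report(out)
    return result


def _scatter_grid(out: Path) -> Path | None:
    """Pairwise scatter grid of per-bait median log2 fold changes."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    files = sorted(out.glob("enrichment_*.tsv"))
    if len(files) < 2:
        return None
    profiles = {}
    for f in files:
        bait = f.stem.removeprefix("enrichment_")
        profiles[bait] = pd.read_csv(f, sep="\t", index_col=0)["median_log2_fc"]
    baits = list(profiles)
    k = len(baits)
    fig, axes = plt.subplots(k, k, figsize=(2.0 * k, 2.0 * k), squeeze=False)
    for i, bi in enumerate(baits):
        for j, bj in enumerate(baits):
            ax = axes[i][j]
            if i == j:
                ax.annotate(bi, (0.5, 0.5), xycoords="axes fraction", ha="center")
                ax.set_xticks([])
                ax.set_yticks([])
                continue
            ax.scatter(profiles[bj], profiles[bi], s=2, alpha=0.2, color="steelblue")
            ax.tick_params(labelsize=6)
    fig.suptitle("pairwise median log2(IP/Total) profiles")
    fig.tight_layout()
    path = out / "pairwise_scatter.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def write_report(out_dir: str | Path) -> Path:
    """Regenerate the markdown report from persisted stage outputs only."""
    out = Path(out_dir)
    lines = ["# RIP-seq pipeline report", ""]
    missing = []

    manifest_path = out / "manifest.json"
    if manifest_path.exists():
        manifest = json.loads(manifest_path.read_text())
        lines += [
            f"Seed: {manifest.get('seed')}; genes: {manifest.get('n_genes')}; "
            f"samples: {manifest.get('n_samples')}",
            "",
        ]

    # enrichment section
    files = sorted(out.glob("enrichment_*.tsv"))
    if files:
        lines += ["## Per-bait enrichment", ""]
        lines += ["| bait | tested | significant (FDR<0.05) |", "| --- | --- | --- |"]
        for f in files:
            table = pd.read_csv(f, sep="\t", index_col=0)
            bait = f.stem.removeprefix("enrichment_")
            lines.append(
                f"| {bait} | {int(table['tested'].sum())} | {int((table['fdr'] < 0.05).sum())} |"
            )
        lines.append("")
        scatter = _scatter_grid(out)
        if scatter is not None:
            lines += [f"![pairwise profiles]({scatter.name})", ""]
    else:
        missing.append("enrichment")

    summary_path = out / "interaction_summary.tsv"
    if summary_path.exists():
        lines += ["## Pairwise interaction contrasts", ""]
        summary = pd.read_csv(summary_path, sep="\t")
        lines += ["| pair | significant | over in A | over in B |", "| --- | --- | --- | --- |"]
        for _, row in summary.iterrows():
            lines.append(
                f"| {row['bait_a']} vs {row['bait_b']} | {row['n_significant']} "
                f"| {row['n_over_in_a']} | {row['n_over_in_b']} |"
            )
        lines.append("")
    else:
        missing.append("interactions")

    assign_path = out / "cluster_assignments.tsv"
    if assign_path.exists():
        assign = pd.read_csv(assign_path, sep="\t", index_col=0)
        lines += ["## Binding groups", ""]
        counts = assign["group"].value_counts().sort_index()
        lines += ["| group | transcripts |", "| --- | --- |"]
        lines += [f"| {g} | {n} |" for g, n in counts.items()]
        lines += ["", "![heatmap](heatmap.png)", ""]
    else:
        missing.append("clustering")

    coef_path = out / "stoichiometry_coefficients.tsv"
    if coef_path.exists():
        coef = pd.read_csv(coef_path, sep="\t", index_col=0)
        lines += ["## Stoichiometric decomposition", ""]
        lines += ["| predictor | beta | se | p |", "| --- | --- | --- | --- |"]
        for name, row in coef.iterrows():
            lines.append(
                f"| {name} | {row['beta']:.3f} | {row['se']:.3f} | {row['p_value']:.2e} |"
            )
        out_path = out / "stoichiometry_outliers.tsv"
        if out_path.exists():
            ranked = pd.read_csv(out_path, sep="\t", index_col=0)
            top = ranked.head(10)
            lines += ["", "Top outlier transcripts by |jackknife residual|:", ""]
            lines += ["| gene | jackknife residual | flagged |", "| --- | --- | --- |"]
            lines += [
                f"| {g} | {row['jackknife_residual']:.2f} | {bool(row['outlier'])} |"
                for g, row in top.iterrows()
            ]
        lines += ["", "![residuals](stoichiometry_residuals.png)", ""]
    else:
        missing.append("stoichiometry")

    set_path = out / "set_enrichment.tsv"
    if set_path.exists():
        table = pd.read_csv(set_path, sep="\t")
        lines += ["## Gene-set over-representation (top terms per group)", ""]
        lines += ["| group | term | overlap | expected | FDR (over) |", "| --- | --- | --- | --- | --- |"]
        for group, sub in table.groupby("group"):
            best = sub.nsmallest(3, "fdr_over")
            for _, row in best.iterrows():
                lines.append(
                    f"| {group} | {row['term_id']} | {row['overlap']} "
                    f"| {row['expected']:.1f} | {row['fdr_over']:.2e} |"
                )
        lines.append("")
    else:
        missing.append("set analysis")

    if missing:
        lines += [f"_Sections absent (no persisted outputs): {', '.join(missing)}._", ""]
        logger.warning("report sections absent: %s", ", ".join(missing))

    report_path = out / "report.md"
    report_path.write_text("\n".join(lines), encoding="utf-8")
    return report_path


def load_inputs(
    config: PipelineConfig,
) -> tuple[CountMatrix, SampleSheet, GeneSetCollection | None, CovariateTable | None]:
    if config.counts is None or config.sample_sheet is None:
        raise ConfigError("counts and sample_sheet paths are required")
    matrix = read_counts(config.counts)
    sheet = read_sample_sheet(config.sample_sheet)
    gene_sets = read_gene_sets(config.gene_sets) if config.gene_sets else None
    covariates = read_covariates(config.covariates) if config.covariates else None
    return matrix, sheet, gene_sets, covariates
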