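"""Synthetic paired IP/Total RIP-seq data with known truth.

The generator emulates the structure of a six-bait closed-loop RIP-seq study:
six TAP-tagged baits (a cap-binding hub, two scaffold isoforms, a poly(A)
binder and two translational repressors), three biological replicates of
paired IP and Total libraries, library depths in the millions of reads, and
negative-binomial count noise (variance = mu + phi * mu^2).

Planted structure, recorded in a machine-readable :class:`SyntheticTruth`:

* four co-binding groups (I-IV) with fixed sign patterns of log2(IP/Total)
  enrichment across the baits, magnitudes jittered around ``effect_size``;
* a linear stoichiometric relation for the hub bait: its true enrichment is
  ``sum_f beta_f * e(g, f)`` over the four hub-partner baits plus Gaussian
  noise;
* autoregulatory outlier transcripts whose hub enrichment deviates from that
  relation by exactly ``outlier_shift``;
* optional covariates (ribosome occupancy, poly(A)-tail length) correlated
  with the poly(A) binder's enrichment, and gene-set terms preferentially
  drawn from one planted group each.

IP expected proportions are renormalized to sum to 1 by default, which
deliberately induces the composition ("real estate") bias that arises when
libraries are compared on the counts-per-million scale with no further
normalization.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import CountMatrix, CovariateTable, GeneSetCollection, SampleSheet

GROUPS = ("I", "II", "III", "IV")
BACKGROUND = "background"


class ConfigError(ValueError):
    """An infeasible or inconsistent simulation configuration."""


DEFAULT_PROTEINS = ("eIF4E", "eIF4G1", "eIF4G2", "Pab1", "Caf20", "Eap1")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic RIP-seq experiment.

    Defaults mirror the shape of the motivating study: 6,000 genes, six baits
    with the cap binder as hub, three replicates, ~5 million reads per library
    with a wide depth spread (CV 0.74), NB dispersion 0.1 and planted
    |log2 enrichment| of 1.5.
    """

    n_genes: int = 6000
    proteins: tuple[str, ...] = DEFAULT_PROTEINS
    hub: str | None = "eIF4E"
    polya_binder: str | None = "Pab1"
    repressors: tuple[str, ...] = ("Caf20", "Eap1")
    partners: tuple[str, ...] = ("eIF4G1", "eIF4G2", "Caf20", "Eap1")
    n_replicates: int = 3
    mean_library_size: float = 5e6
    library_size_cv: float = 0.74
    dispersion: float = 0.1
    group_proportions: Mapping[str, float] = field(
        default_factory=lambda: {"I": 0.10, "II": 0.08, "III": 0.10, "IV": 0.17}
    )
    effect_size: float = 1.5
    effect_jitter: float = 0.25
    beta_true: tuple[float, ...] = (1.0, 0.4, 0.2, -0.1)
    hub_noise_sd: float = 0.3
    hub_signal_fraction: float | None = None
    n_outliers: int = 2
    outlier_shift: float = 3.0
    replicate_effect_sd: float = 0.0
    renormalize_ip: bool = True
    shared_profile_baits: tuple[tuple[str, ...], ...] = ()
    abundance_sigma: float = 1.2
    covariate_strength: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 10:
            raise ConfigError("n_genes must be at least 10")
        if len(set(self.proteins)) != len(self.proteins):
            raise ConfigError("duplicate bait names")
        if self.hub is not None and self.hub not in self.proteins:
            raise ConfigError(f"hub {self.hub!r} not among proteins")
        if self.hub is not None:
            missing = [p for p in self.partners if p not in self.proteins]
            if missing:
                raise ConfigError(f"partner baits not among proteins: {missing}")
            if self.hub in self.partners:
                raise ConfigError("hub cannot be its own partner")
            if len(self.beta_true) != len(self.partners):
                raise ConfigError("beta_true length must match number of partners")
        if self.n_replicates < 2:
            raise ConfigError("need at least 2 replicates")
        if self.mean_library_size <= 0:
            raise ConfigError("mean_library_size must be positive")
        if self.library_size_cv < 0:
            raise ConfigError("library_size_cv must be >= 0")
        if self.dispersion < 0:
            raise ConfigError("dispersion must be >= 0")
        props = dict(self.group_proportions)
        if any(p < 0 or p > 1 for p in props.values()) or sum(props.values()) > 1:
            raise ConfigError("group proportions must lie in [0,1] and sum to <= 1")
        if self.effect_size <= 0:
            raise ConfigError("effect_size must be > 0")
        if not 0 <= self.effect_jitter < 1:
            raise ConfigError("effect_jitter must be in [0, 1)")
        if self.n_outliers >= self.n_genes:
            raise ConfigError("n_outliers must be smaller than n_genes")
        if self.hub_signal_fraction is not None and not 0 < self.hub_signal_fraction < 1:
            raise ConfigError("hub_signal_fraction must lie in (0, 1)")

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass
class SyntheticTruth:
    """Planted truth: per-gene group labels, true enrichments and outlier flags."""

    genes: pd.DataFrame  # columns: group, is_outlier, enrichment_<bait>...
    beta_true: tuple[float, ...]
    dispersion: float
    seed: int
    config: SimulationConfig

    @property
    def group_labels(self) -> pd.Series:
        return self.genes["group"]

    @property
    def outlier_genes(self) -> list[str]:
        return self.genes.index[self.genes["is_outlier"]].tolist()

    def enrichment(self, bait: str) -> pd.Series:
        return self.genes[f"enrichment_{bait}"]

    def enrichment_matrix(self, baits: Sequence[str] | None = None) -> pd.DataFrame:
        baits = list(baits) if baits is not None else list(self.config.proteins)
        out = self.genes[[f"enrichment_{b}" for b in baits]].copy()
        out.columns = baits
        return out

    def to_json(self, path: str | Path) -> None:
        cfg = dataclasses.asdict(self.config)
        cfg["group_proportions"] = dict(cfg["group_proportions"])
        payload = {
            "seed": self.seed,
            "dispersion": self.dispersion,
            "beta_true": list(self.beta_true),
            "config": cfg,
            "genes": {
                "gene_id": self.genes.index.tolist(),
                **{c: self.genes[c].tolist() for c in self.genes.columns},
            },
        }
        with open(path, "w", encoding="utf-8") as handle:
            json.dump(payload, handle, indent=1, sort_keys=True)
            handle.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        with open(path, encoding="utf-8") as handle:
            payload = json.load(handle)
        genes = pd.DataFrame(payload["genes"]).set_index("gene_id")
        cfg = payload["config"]
        ordered = ["group", "is_outlier"] + [f"enrichment_{b}" for b in cfg["proteins"]]
        genes = genes[ordered]
        for key in ("proteins", "repressors", "partners", "beta_true"):
            cfg[key] = tuple(cfg[key])
        cfg["shared_profile_baits"] = tuple(tuple(g) for g in cfg["shared_profile_baits"])
        config = SimulationConfig(**cfg)
        return cls(
            genes=genes,
            beta_true=tuple(payload["beta_true"]),
            dispersion=payload["dispersion"],
            seed=payload["seed"],
            config=config,
        )


# ---------------------------------------------------------------------------
# true enrichment profiles
# ---------------------------------------------------------------------------


def _group_sign(group: str, bait: str, config: SimulationConfig) -> int:
    """Sign of the planted enrichment for a (group, bait) cell.

    Baits with no designated role behave like closed-loop scaffold members.
    The hub's profile is never assigned a pattern directly; it is derived from
    the stoichiometric relation.
    """
    is_repressor = bait in config.repressors
    is_polya = bait == config.polya_binder
    if group == "I":
        return 0 if is_polya else -1
    if group == "II":
        return 1 if is_repressor else 0
    if group == "III":
        return -1 if is_repressor else 1
    if group == "IV":
        return 1
    return 0


def _planted_enrichments(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Per-gene true log2 enrichment for every bait, plus group labels."""
    n = config.n_genes
    props = dict(config.group_proportions)
    labels = list(GROUPS) + [BACKGROUND]
    p = [props.get(g, 0.0) for g in GROUPS]
    p.append(1.0 - sum(p))
    group = rng.choice(labels, size=n, p=p)

    non_hub = [b for b in config.proteins if b != config.hub]
    # shared-jitter groups: every bait maps to a jitter stream key
    stream_of = {b: b for b in non_hub}
    for tied in config.shared_profile_baits:
        for b in tied:
            stream_of[b] = tied[0]
    jitter: dict[str, np.ndarray] = {}
    for key in dict.fromkeys(stream_of.values()):
        jitter[key] = 1.0 + config.effect_jitter * rng.uniform(-1.0, 1.0, size=n)

    e = pd.DataFrame(0.0, index=_gene_ids(n), columns=list(config.proteins))
    for bait in non_hub:
        signs = np.array([_group_sign(g, bait, config) for g in group], dtype=float)
        e[bait] = signs * config.effect_size * jitter[stream_of[bait]]

    is_outlier = np.zeros(n, dtype=bool)
    if config.hub is not None:
        partner_e = e[list(config.partners)].to_numpy()
        signal = partner_e @ np.asarray(config.beta_true)
        if config.hub_signal_fraction is not None:
            var_signal = float(np.var(signal))
            noise_sd = float(np.sqrt(var_signal * (1.0 / config.hub_signal_fraction - 1.0)))
        else:
            noise_sd = config.hub_noise_sd
        hub_e = signal + rng.normal(0.0, noise_sd, size=n)
        if config.n_outliers > 0:
            group_ii = np.flatnonzero(group == "II")
            pool = group_ii if len(group_ii) >= config.n_outliers else np.arange(n)
            chosen = rng.choice(pool, size=config.n_outliers, replace=False)
            hub_e[chosen] += config.outlier_shift
            is_outlier[chosen] = True
        e[config.hub] = hub_e

    e["group"] = group
    e["is_outlier"] = is_outlier
    return e


def _gene_ids(n: int) -> list[str]:
    width = len(str(n - 1))
    return [f"G{i:0{width}d}" for i in range(n)]


# ---------------------------------------------------------------------------
# count sampling
# ---------------------------------------------------------------------------


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    mean = np.maximum(mean, 1e-12)
    if phi <= 0:
        return rng.poisson(mean)
    r = 1.0 / phi
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def generate_dataset(
    config: SimulationConfig,
) -> tuple[CountMatrix, SampleSheet, SyntheticTruth]:
    """Simulate paired IP/Total count libraries with planted truth.

    Total counts are NB(library_size x abundance, phi); IP counts are
    NB(library_size x abundance x 2^e / renormalizer, phi) where the
    renormalizer rescales the IP expected proportions to sum to 1 (inducing
    the composition bias) unless ``renormalize_ip`` is off.  Identical seeds
    give byte-identical outputs.
    """
    config.validate()
    master = np.random.SeedSequence(config.seed)
    rng_truth, rng_lib, rng_counts = (
        np.random.default_rng(s) for s in master.spawn(3)
    )

    truth_frame = _planted_enrichments(config, rng_truth)
    genes = truth_frame.index
    abundance = rng_truth.lognormal(0.0, config.abundance_sigma, size=config.n_genes)
    abundance /= abundance.sum()

    # library sizes: lognormal with the configured mean and CV
    cv = config.library_size_cv
    sigma2 = np.log1p(cv**2)
    mu_log = np.log(config.mean_library_size) - sigma2 / 2.0

    columns: dict[str, np.ndarray] = {}
    rows = []
    for protein in config.proteins:
        ip_weight = abundance * np.exp2(truth_frame[protein].to_numpy())
        for rep in range(1, config.n_replicates + 1):
            if config.replicate_effect_sd > 0:
                rep_factor = np.exp(
                    rng_counts.normal(0.0, config.replicate_effect_sd, size=config.n_genes)
                )
            else:
                rep_factor = 1.0
            total_prop = abundance * rep_factor
            total_prop = total_prop / total_prop.sum()
            ip_prop = ip_weight * rep_factor
            if config.renormalize_ip:
                ip_prop = ip_prop / ip_prop.sum()
            for fraction, prop in ((("Total"), total_prop), (("IP"), ip_prop)):
                lib = float(rng_lib.lognormal(mu_log, np.sqrt(sigma2)))
                sample_id = f"{protein}.rep{rep}.{fraction}"
                counts = _nb_sample(rng_counts, lib * prop, config.dispersion)
                columns[sample_id] = counts
                rows.append(
                    {
                        "sample_id": sample_id,
                        "protein": protein,
                        "replicate": rep,
                        "fraction": fraction,
                    }
                )

    counts_df = pd.DataFrame(columns, index=genes)
    counts_df.index.name = "gene_id"
    matrix = CountMatrix(counts_df)
    sheet = SampleSheet(pd.DataFrame(rows))

    enrichment_cols = {f"enrichment_{b}": truth_frame[b] for b in config.proteins}
    truth_genes = pd.DataFrame(
        {"group": truth_frame["group"], "is_outlier": truth_frame["is_outlier"], **enrichment_cols}
    )
    truth = SyntheticTruth(
        genes=truth_genes,
        beta_true=tuple(config.beta_true),
        dispersion=config.dispersion,
        seed=config.seed,
        config=config,
    )
    return matrix, sheet, truth


# ---------------------------------------------------------------------------
# covariates and gene sets
# ---------------------------------------------------------------------------


def generate_covariates(
    truth: SyntheticTruth,
    strength: float | None = None,
    rng: np.random.Generator | None = None,
) -> CovariateTable:
    """Per-gene covariates correlated with the poly(A) binder's enrichment.

    ``ribosome_occupancy`` (a 0-1 fraction) and ``polyA_length`` (nucleotides)
    are strictly monotone functions of ``strength * z + sqrt(1-strength^2) * eps``
    where z is the standardized poly(A)-binder true enrichment.  strength = 0
    gives independent covariates; strength = 1 a noise-free monotone map.
    """
    config = truth.config
    if strength is None:
        strength = config.covariate_strength
    if not 0 <= strength <= 1:
        raise ConfigError("covariate strength must lie in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(truth.seed).spawn(4)[3])
    bait = config.polya_binder or config.proteins[0]
    e = truth.enrichment(bait).to_numpy()
    sd = e.std()
    z = (e - e.mean()) / sd if sd > 0 else np.zeros_like(e)
    noise = rng.normal(size=len(e))
    latent = strength * z + np.sqrt(max(0.0, 1.0 - strength**2)) * noise
    occupancy = 1.0 / (1.0 + np.exp(-latent))
    polya = 25.0 + 15.0 / (1.0 + np.exp(-0.8 * latent))
    df = pd.DataFrame(
        {"ribosome_occupancy": occupancy, "polyA_length": polya},
        index=truth.genes.index,
    )
    df.index.name = "gene_id"
    return CovariateTable(df)


def generate_gene_sets(
    truth: SyntheticTruth,
    n_terms: int = 40,
    term_size: int | None = None,
    planted_odds: Mapping[str, float] | None = None,
    rng: np.random.Generator | None = None,
) -> GeneSetCollection:
    """Gene-set terms, some drawn preferentially from one planted group each.

    ``planted_odds`` maps group label -> sampling odds; a term named
    ``planted_<group>`` draws members with weight ``odds`` for genes of that
    group and 1 elsewhere.  The remaining terms are uniform draws.  The
    default term size is 100 genes, capped at a fifth of the gene universe.
    """
    config = truth.config
    if term_size is None:
        term_size = min(100, max(5, config.n_genes // 5))
    if term_size > config.n_genes:
        raise ConfigError("term size exceeds number of genes")
    if planted_odds is None:
        planted_odds = {g: 5.0 for g in GROUPS}
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(truth.seed).spawn(5)[4])
    genes = np.asarray(truth.genes.index)
    group = truth.group_labels.to_numpy()
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    for label, odds in sorted(planted_odds.items()):
        weights = np.where(group == label, float(odds), 1.0)
        weights = weights / weights.sum()
        members = rng.choice(genes, size=term_size, replace=False, p=weights)
        terms[f"planted_{label}"] = (f"planted group {label} term", frozenset(members))
    n_random = max(0, n_terms - len(terms))
    for i in range(n_random):
        members = rng.choice(genes, size=term_size, replace=False)
        terms[f"random_{i:03d}"] = (f"uniform term {i}", frozenset(members))
    return GeneSetCollection(terms)
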