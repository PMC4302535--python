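"""Paired IP/Total enrichment tests, pairwise bait contrasts and FDR control.

Per bait, each gene's counts over the paired IP and Total libraries are
modelled with a negative-binomial log-linear model containing a log
library-size offset, replicate-pair block effects and an IP-vs-Total
(fraction) coefficient.  The fraction coefficient, reported on the log2
scale, is the IP/Total enrichment on the counts-per-million scale; its
significance comes from a 1-df likelihood-ratio test against the null model
without the fraction term.  No cross-library normalization beyond CPM is
applied, so fold changes of null genes are subject to composition ("real
estate") shifts when abundant transcripts are enriched — the statistical
test, which contrasts paired libraries gene-wise, is unaffected in its
calibration by balanced composition shifts.

The pairwise bait-vs-bait comparison fits a joint model over two baits'
libraries with fraction, replicate-pair block and fraction x bait interaction
terms; the interaction coefficient is the difference of the two baits'
enrichments and is tested by the same LRT machinery.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .glm import fit_nb_glm, lrt_pvalues
from .io import FRACTION_IP, FRACTION_TOTAL, CountMatrix, SampleSheet, ValidationError

logger = logging.getLogger(__name__)

DEFAULT_MIN_TOTAL_COUNT = 20
DEFAULT_PSEUDOCOUNT = 0.5
LOG2 = np.log(2.0)


# ---------------------------------------------------------------------------
# CPM and count filters
# ---------------------------------------------------------------------------


def cpm(matrix: CountMatrix) -> pd.DataFrame:
    """Counts per million: count / library size * 1e6, no other normalization."""
    lib = matrix.library_sizes
    return matrix.counts / lib * 1e6


def filter_by_total_counts(
    matrix: CountMatrix,
    sheet: SampleSheet,
    baits: list[str] | None = None,
    threshold: int = DEFAULT_MIN_TOTAL_COUNT,
    mode: str = "all_above",
) -> set[str]:
    """Genes passing the Total-library read-count filter.

    ``mode="all_above"`` (default, the strict reading): keep genes whose count
    is strictly greater than ``threshold`` in *every* Total sample of every
    listed bait.  ``mode="any_above"`` (the alternate reading, under which a
    gene is excluded only when it is below the threshold in each Total
    sample): keep genes exceeding the threshold in at least one Total sample.
    """
    if baits is None:
        baits = sheet.proteins
    if not baits:
        raise ValidationError("empty bait subset for the Total-count filter")
    unknown = [b for b in baits if b not in sheet.proteins]
    if unknown:
        raise ValidationError(f"baits not in sample sheet: {unknown}")
    total_samples = [s for b in baits for s in sheet.samples(b, FRACTION_TOTAL)]
    sub = matrix.counts[total_samples]
    if mode == "all_above":
        keep = (sub > threshold).all(axis=1)
    elif mode == "any_above":
        keep = (sub > threshold).any(axis=1)
    else:
        raise ValueError(f"unknown filter mode {mode!r}")
    return set(sub.index[keep])


# ---------------------------------------------------------------------------
# dispersion estimation
# ---------------------------------------------------------------------------


@dataclass
class DispersionEstimate:
    """Per-gene raw and empirical-Bayes shrunken NB dispersions."""

    table: pd.DataFrame  # columns: raw, shrunk, prior, prior_weight
    prior: float | pd.Series
    prior_weight: float
    residual_df: int

    def for_genes(self, genes: pd.Index) -> np.ndarray:
        return self.table.loc[genes, "shrunk"].to_numpy()


def estimate_dispersions(
    matrix: CountMatrix,
    sheet: SampleSheet,
    prior_weight: float = 25.0,
    trend: str = "global",
) -> DispersionEstimate:
    """Method-of-moments NB dispersion per gene, shrunk toward a prior.

    Within each (bait, fraction) replicate group, counts are rescaled to the
    group's mean library size; the excess of the sample variance over the
    (depth-corrected) mean estimates phi * mu^2.  Pooling over groups gives a
    raw per-gene moment estimate, which is shrunk toward a global prior (the
    mean of the raw estimates, ``trend="global"``) or toward a running-median
    trend over gene abundance (``trend="trended"``) with weight
    ``prior_weight`` against the pooled residual degrees of freedom.
    """
    numer = np.zeros(matrix.n_genes)
    denom = np.zeros(matrix.n_genes)
    mean_scaled = np.zeros(matrix.n_genes)
    df_total = 0
    lib = matrix.library_sizes
    for protein in sheet.proteins:
        for fraction in (FRACTION_IP, FRACTION_TOTAL):
            samples = sheet.samples(protein, fraction)
            if len(samples) < 2:
                continue
            sub = matrix.counts[samples].to_numpy(dtype=float)
            sizes = lib[samples].to_numpy(dtype=float)
            nbar = sizes.mean()
            scaled = sub * (nbar / sizes)[None, :]
            m = scaled.mean(axis=1)
            v = scaled.var(axis=1, ddof=1)
            c = nbar * np.mean(1.0 / sizes)  # depth-correction of the Poisson part
            numer += v - c * m
            # m^2 - v/n is the unbiased estimator of mu^2 (removes the
            # Var(mean)/n inflation that would bias phi downward)
            denom += m**2 - v / len(samples)
            mean_scaled += m
            df_total += len(samples) - 1
    if df_total == 0:
        raise ValidationError(
            "dispersion cannot be estimated: no replicate group has >= 2 samples"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(denom > 0, numer / np.where(denom > 0, denom, 1.0), 0.0)

    if trend == "global":
        prior = float(max(np.nanmean(raw), 0.0))
        prior_vec = np.full(matrix.n_genes, prior)
    elif trend == "trended":
        order = np.argsort(mean_scaled)
        window = max(101, matrix.n_genes // 20) | 1
        sorted_raw = pd.Series(raw[order])
        trend_sorted = (
            sorted_raw.rolling(window, center=True, min_periods=1).median().to_numpy()
        )
        prior_vec = np.empty(matrix.n_genes)
        prior_vec[order] = np.maximum(trend_sorted, 0.0)
        prior = pd.Series(prior_vec, index=matrix.counts.index)
    else:
        raise ValueError(f"unknown trend {trend!r}")

    shrunk = np.clip(
        (prior_weight * prior_vec + df_total * raw) / (prior_weight + df_total),
        0.0,
        None,
    )
    table = pd.DataFrame(
        {
            "raw": np.maximum(raw, 0.0),
            "shrunk": shrunk,
            "prior": prior_vec,
            "prior_weight": prior_weight,
        },
        index=matrix.counts.index,
    )
    return DispersionEstimate(
        table=table, prior=prior, prior_weight=prior_weight, residual_df=df_total
    )


# ---------------------------------------------------------------------------
# per-bait paired enrichment test
# ---------------------------------------------------------------------------


def _paired_design(n_reps: int) -> tuple[np.ndarray, np.ndarray]:
    """Design for one bait: intercept, replicate blocks, fraction (IP=1).

    Sample order is rep1.Total, rep1.IP, rep2.Total, rep2.IP, ...
    Returns (full design, null design without the fraction column).
    """
    n = 2 * n_reps
    X = np.zeros((n, n_reps + 1))
    X[:, 0] = 1.0
    for r in range(1, n_reps):
        X[2 * r, r] = 1.0
        X[2 * r + 1, r] = 1.0
    X[1::2, n_reps] = 1.0  # fraction indicator
    return X, X[:, :-1]


def test_enrichment(
    matrix: CountMatrix,
    sheet: SampleSheet,
    bait: str,
    dispersions: DispersionEstimate | None = None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    min_total_count: int = DEFAULT_MIN_TOTAL_COUNT,
) -> pd.DataFrame:
    """Paired IP-vs-Total NB GLM enrichment test for one bait.

    Returns a per-gene table with columns ``log2_enrichment`` (the fraction
    coefficient), ``median_log2_fc`` (median over replicates of the
    pseudocounted per-replicate log2 CPM ratio), ``p_value``, ``fdr``,
    ``tested``, ``n_reads_ok`` (Total-count filter flag) and ``converged``.
    Genes with zero counts in every library of the bait are not tested and
    carry missing p-values.
    """
    if bait not in sheet.proteins:
        raise ValidationError(f"bait {bait!r} not in sample sheet")
    if dispersions is None:
        dispersions = estimate_dispersions(matrix, sheet)
    reps = sheet.replicates(bait)
    samples = []
    for rep in reps:
        samples.append(sheet.sample_id(bait, rep, FRACTION_TOTAL))
        samples.append(sheet.sample_id(bait, rep, FRACTION_IP))
    counts = matrix.counts[samples]
    offset = np.log(matrix.library_sizes[samples].to_numpy(dtype=float))
    X_full, X_null = _paired_design(len(reps))

    y = counts.to_numpy(dtype=float)
    tested = y.sum(axis=1) > 0
    phi = dispersions.for_genes(counts.index)

    log2_enr = np.full(matrix.n_genes, np.nan)
    pvals = np.full(matrix.n_genes, np.nan)
    converged = np.zeros(matrix.n_genes, dtype=bool)
    if tested.any():
        fit_full = fit_nb_glm(y[tested], X_full, offset, phi[tested])
        fit_null = fit_nb_glm(y[tested], X_null, offset, phi[tested])
        ok = fit_full.converged & fit_null.converged
        p_sub = lrt_pvalues(fit_null.deviance, fit_full.deviance)
        p_sub[~ok] = np.nan
        log2_sub = fit_full.beta[:, -1] / LOG2
        idx = np.flatnonzero(tested)
        log2_enr[idx] = log2_sub
        pvals[idx] = p_sub
        converged[idx] = ok
        n_bad = int((~ok).sum())
        if n_bad:
            logger.warning("%s: %d gene(s) failed IRLS convergence", bait, n_bad)

    # descriptive per-replicate median log2 fold change on pseudocounted CPM
    cpm_table = cpm(matrix)
    ratios = []
    for rep in reps:
        ip = cpm_table[sheet.sample_id(bait, rep, FRACTION_IP)]
        total = cpm_table[sheet.sample_id(bait, rep, FRACTION_TOTAL)]
        ratios.append(np.log2((ip + pseudocount) / (total + pseudocount)))
    median_fc = pd.concat(ratios, axis=1).median(axis=1)

    n_reads_ok_genes = filter_by_total_counts(
        matrix, sheet, [bait], threshold=min_total_count
    )
    result = pd.DataFrame(
        {
            "log2_enrichment": log2_enr,
            "median_log2_fc": median_fc,
            "p_value": pvals,
            "fdr": bh_fdr(pvals),
            "tested": tested,
            "n_reads_ok": counts.index.isin(n_reads_ok_genes),
            "converged": converged,
        },
        index=counts.index,
    )
    return result


def enrich_all_baits(
    matrix: CountMatrix,
    sheet: SampleSheet,
    dispersions: DispersionEstimate | None = None,
    **kwargs,
) -> dict[str, pd.DataFrame]:
    """Run :func:`test_enrichment` for every bait; shared dispersion estimate."""
    if dispersions is None:
        dispersions = estimate_dispersions(matrix, sheet)
    return {
        bait: test_enrichment(matrix, sheet, bait, dispersions=dispersions, **kwargs)
        for bait in sheet.proteins
    }


# ---------------------------------------------------------------------------
# pairwise bait-vs-bait interaction contrast
# ---------------------------------------------------------------------------


def _interaction_design(n_pairs_a: int, n_pairs_b: int) -> tuple[np.ndarray, np.ndarray]:
    """Joint design over two baits: pair blocks + fraction + fraction x baitA.

    Sample order: for bait A then bait B, rep-wise (Total, IP).  The
    interaction column is the fraction indicator restricted to bait A, so its
    coefficient is enrichment(A) - enrichment(B).
    """
    pairs = n_pairs_a + n_pairs_b
    n = 2 * pairs
    p = pairs + 2  # intercept + (pairs-1) blocks + fraction + interaction
    X = np.zeros((n, p))
    X[:, 0] = 1.0
    for blk in range(1, pairs):
        X[2 * blk : 2 * blk + 2, blk] = 1.0
    X[1::2, pairs] = 1.0  # fraction (IP)
    X[1 : 2 * n_pairs_a : 2, pairs + 1] = 1.0  # fraction x baitA
    return X, X[:, :-1]


def test_interaction(
    matrix: CountMatrix,
    sheet: SampleSheet,
    bait_a: str,
    bait_b: str,
    dispersions: DispersionEstimate | None = None,
) -> pd.DataFrame:
    """Test whether IP/Total enrichment differs between two baits.

    Returns per-gene ``delta_log2`` (enrichment(A) - enrichment(B)),
    ``p_value``, ``fdr`` and ``direction`` (which bait over-represents the
    transcript).  Swapping the baits negates ``delta_log2`` and leaves the
    p-values unchanged.
    """
    if bait_a == bait_b:
        raise ValidationError("bait_a and bait_b must differ")
    for bait in (bait_a, bait_b):
        if bait not in sheet.proteins:
            raise ValidationError(f"bait {bait!r} not in sample sheet")
    if dispersions is None:
        dispersions = estimate_dispersions(matrix, sheet)

    samples: list[str] = []
    reps_a = sheet.replicates(bait_a)
    reps_b = sheet.replicates(bait_b)
    for bait, reps in ((bait_a, reps_a), (bait_b, reps_b)):
        for rep in reps:
            samples.append(sheet.sample_id(bait, rep, FRACTION_TOTAL))
            samples.append(sheet.sample_id(bait, rep, FRACTION_IP))
    counts = matrix.counts[samples]
    offset = np.log(matrix.library_sizes[samples].to_numpy(dtype=float))
    X_full, X_null = _interaction_design(len(reps_a), len(reps_b))

    y = counts.to_numpy(dtype=float)
    tested = y.sum(axis=1) > 0
    phi = dispersions.for_genes(counts.index)

    delta = np.full(matrix.n_genes, np.nan)
    pvals = np.full(matrix.n_genes, np.nan)
    if tested.any():
        fit_full = fit_nb_glm(y[tested], X_full, offset, phi[tested])
        fit_null = fit_nb_glm(y[tested], X_null, offset, phi[tested])
        ok = fit_full.converged & fit_null.converged
        p_sub = lrt_pvalues(fit_null.deviance, fit_full.deviance)
        p_sub[~ok] = np.nan
        idx = np.flatnonzero(tested)
        delta[idx] = fit_full.beta[:, -1] / LOG2
        pvals[idx] = p_sub

    direction = np.where(np.isnan(delta), "", np.where(delta >= 0, bait_a, bait_b))
    return pd.DataFrame(
        {
            "delta_log2": delta,
            "p_value": pvals,
            "fdr": bh_fdr(pvals),
            "direction": direction,
            "tested": tested,
        },
        index=counts.index,
    )


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------


def bh_fdr(p_values: np.ndarray | pd.Series) -> np.ndarray | pd.Series:
    """Benjamini-Hochberg step-up q-values; NaNs are passed through."""
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    pm = p[mask]
    if ((pm < 0) | (pm > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = pm.size
    if m:
        order = np.argsort(pm, kind="mergesort")
        ranked = pm[order] * m / np.arange(1, m + 1)
        q = np.minimum.accumulate(ranked[::-1])[::-1]
        q = np.minimum(q, 1.0)
        qs = np.empty(m)
        qs[order] = q
        out[mask] = qs
    if isinstance(p_values, pd.Series):
        return pd.Series(out, index=p_values.index)
    return out
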