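"""Stoichiometric linear decomposition of a hub bait's binding profile.

The hub protein (the cap binder) is bound by several partner proteins in a
competitive equilibrium, so its per-gene log2(IP/Total) enrichment profile is
modelled as a linear combination of the partner profiles,

    e_hub(g) = b0 + sum_f beta_f * e_f(g) + eps_g,

fitted by ordinary least squares via a QR decomposition.  The beta
coefficients measure each partner's contribution to the hub profile.
Transcripts that escape the model — in the motivating biology, the
repressor-encoding mRNAs themselves — are flagged by externally studentized
(jackknife) residuals, computed with the closed-form leave-one-out deletion
identity rather than n refits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import ValidationError


class CollinearityError(ValidationError):
    """Predictor profiles are linearly dependent; coefficients are not identifiable."""


@dataclass
class StoichiometricFit:
    """OLS decomposition of the hub profile with regression diagnostics."""

    target: str
    predictors: list[str]
    beta: pd.Series  # includes "intercept" when fitted
    beta_se: pd.Series
    beta_p: pd.Series
    r_squared: float
    fitted: pd.Series
    residual: pd.Series
    jackknife_residual: pd.Series
    leverage: pd.Series
    n_genes: int
    df_resid: int
    condition_number: float
    predictor_correlations: pd.DataFrame
    include_intercept: bool = True
    outlier_flags: pd.Series = field(default=None)  # filled by flag_outliers


def fit_linear_decomposition(
    target_profile: pd.Series,
    predictor_profiles: pd.DataFrame,
    include_intercept: bool = True,
    target_name: str | None = None,
) -> StoichiometricFit:
    """Fit the hub profile as an OLS linear combination of partner profiles.

    Genes are aligned by id; genes with a missing value in the target or any
    predictor are dropped.  Raises :class:`CollinearityError`, naming the
    dependent columns, when the predictor matrix is rank deficient.
    """
    predictors = list(predictor_profiles.columns)
    data = predictor_profiles.copy()
    data["__target__"] = target_profile
    data = data.dropna()
    n = len(data)
    p = len(predictors) + (1 if include_intercept else 0)
    if n < p + 2:
        raise ValidationError(
            f"need at least {p + 2} genes with complete profiles, have {n}"
        )
    y = data["__target__"].to_numpy(dtype=float)
    Xp = data[predictors].to_numpy(dtype=float)
    if include_intercept:
        X = np.column_stack([np.ones(n), Xp])
        names = ["intercept", *predictors]
    else:
        X = Xp
        names = list(predictors)

    Q, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    tol = max(X.shape) * np.finfo(float).eps * (diag.max() if diag.size else 0.0)
    if (diag <= tol).any():
        bad = [names[i] for i in np.flatnonzero(diag <= tol)]
        raise CollinearityError(
            f"predictor matrix is rank deficient; collinear columns involve {bad}"
        )
    beta = np.linalg.solve(R, Q.T @ y)
    fitted = X @ beta
    resid = y - fitted
    rss = float(resid @ resid)
    df_resid = n - p
    s2 = rss / df_resid

    Rinv = np.linalg.solve(R, np.eye(p))
    cov_unscaled = Rinv @ Rinv.T
    se = np.sqrt(np.diag(cov_unscaled) * s2)
    tvals = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df_resid)

    leverage = np.einsum("ij,ij->i", Q, Q)
    # externally studentized (jackknife) residuals via the deletion identity
    one_minus_h = np.clip(1.0 - leverage, 1e-12, None)
    if rss <= 1e-12 * max(float(y @ y), 1.0):
        # numerically exact fit: every jackknife residual is zero
        jackknife = np.zeros(n)
    else:
        s2_loo = (rss - resid**2 / one_minus_h) / (df_resid - 1)
        s2_loo = np.clip(s2_loo, 1e-300, None)
        jackknife = resid / np.sqrt(s2_loo * one_minus_h)

    if include_intercept:
        tss = float(((y - y.mean()) ** 2).sum())
    else:
        tss = float((y**2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else 0.0

    sv = np.linalg.svd(X, compute_uv=False)
    cond = float(sv.max() / sv.min())
    corr = data[predictors].corr() if len(predictors) > 1 else pd.DataFrame()

    genes = data.index
    return StoichiometricFit(
        target=target_name or str(target_profile.name or "target"),
        predictors=predictors,
        beta=pd.Series(beta, index=names),
        beta_se=pd.Series(se, index=names),
        beta_p=pd.Series(pvals, index=names),
        r_squared=r2,
        fitted=pd.Series(fitted, index=genes),
        residual=pd.Series(resid, index=genes),
        jackknife_residual=pd.Series(jackknife, index=genes),
        leverage=pd.Series(leverage, index=genes),
        n_genes=n,
        df_resid=df_resid,
        condition_number=cond,
        predictor_correlations=corr,
        include_intercept=include_intercept,
    )


def flag_outliers(
    fit: StoichiometricFit,
    alpha: float = 0.05,
    method: str = "bonferroni_t",
) -> pd.DataFrame:
    """Rank genes by |jackknife residual| and flag Bonferroni-significant outliers.

    A gene is flagged when its |externally studentized residual| exceeds the
    two-sided t quantile at level ``alpha / n_genes`` with ``n - p - 1``
    degrees of freedom.  The full ranking is always returned so callers can
    apply their own cutoff.
    """
    if method != "bonferroni_t":
        raise ValueError(f"unknown outlier method {method!r}")
    t = fit.jackknife_residual
    df = fit.df_resid - 1
    crit = stats.t.ppf(1.0 - alpha / (2.0 * fit.n_genes), df)
    abs_t = t.abs()
    ranked = pd.DataFrame(
        {
            "jackknife_residual": t,
            "abs_jackknife": abs_t,
            "fitted": fit.fitted,
            "leverage": fit.leverage,
            "outlier": abs_t > crit,
        }
    ).sort_values("abs_jackknife", ascending=False)
    ranked["rank"] = np.arange(1, len(ranked) + 1)
    fit.outlier_flags = ranked["outlier"].reindex(fit.fitted.index)
    return ranked


def fit_summary_table(fit: StoichiometricFit) -> pd.DataFrame:
    """Coefficient table (predictor, beta, se, p) for reporting."""
    return pd.DataFrame(
        {"beta": fit.beta, "se": fit.beta_se, "p_value": fit.beta_p}
    ).rename_axis("predictor")


def diagnostics_table(fit: StoichiometricFit) -> pd.DataFrame:
    """Per-gene diagnostics (fitted, residual, jackknife residual, leverage)."""
    table = pd.DataFrame(
        {
            "fitted": fit.fitted,
            "residual": fit.residual,
            "jackknife_residual": fit.jackknife_residual,
            "leverage": fit.leverage,
        }
    ).rename_axis("gene_id")
    if fit.outlier_flags is not None:
        table["outlier"] = fit.outlier_flags
    return table


def plot_residuals(
    fit: StoichiometricFit,
    path: str | Path,
    flagged: Sequence[str] | None = None,
) -> tuple[Path, Path]:
    """Jackknife residuals vs fitted values, flagged genes labelled.

    Writes the figure and a companion TSV of the plotted values; returns
    (figure_path, tsv_path).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    path = Path(path)
    tsv_path = path.with_suffix(".tsv")
    table = diagnostics_table(fit).sort_index()
    table.to_csv(tsv_path, sep="\t")

    if flagged is None:
        if fit.outlier_flags is None:
            flag_outliers(fit)
        flagged = fit.outlier_flags.index[fit.outlier_flags].tolist()
    fig, ax = plt.subplots(figsize=(7, 5))
    ax.scatter(fit.fitted, fit.jackknife_residual, s=6, alpha=0.4, color="grey")
    for gene in flagged:
        ax.scatter(fit.fitted[gene], fit.jackknife_residual[gene], s=25, color="crimson")
        ax.annotate(gene, (fit.fitted[gene], fit.jackknife_residual[gene]), fontsize=7)
    ax.axhline(0.0, lw=0.8, color="black")
    ax.set_xlabel(f"fitted {fit.target} log2 enrichment")
    ax.set_ylabel("jackknife residual")
    ax.set_title(f"R^2 = {fit.r_squared:.3f}, n = {fit.n_genes}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path, tsv_path
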