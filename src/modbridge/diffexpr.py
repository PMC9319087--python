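"""Per-gene differential expression with empirical-Bayes variance moderation.

Given covariate-adjusted expression and a binary phenotype, each gene g is
fit by OLS on intercept + phenotype; the phenotype coefficient is the
case-control effect and s2_g the residual variance on d_g degrees of
freedom.  The gene-wise variances are then shrunk toward a prior via the
scaled inverse-chi-square empirical-Bayes model

    s2_g | sigma2_g ~ sigma2_g * chi2_{d_g} / d_g,
    1/sigma2_g     ~ (1/s0^2) * chi2_{d0} / d0,

whose hyperparameters (d0, s0^2) are estimated by method-of-moments on
log s2_g through digamma/trigamma matching of the scaled-F marginal.  The
moderated statistic is

    t~_g = effect_g / (s~_g * u_g),   s~2_g = (d0*s0^2 + d_g*s2_g)/(d0 + d_g),

with u_g the unscaled standard error (sqrt(1/n_case + 1/n_control) for the
two-group design), referred to a t distribution on d0 + d_g df.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .io_formats import ExpressionMatrix, SampleTable

logger = logging.getLogger(__name__)

__all__ = [
    "EbayesParams",
    "fit_gene_models",
    "estimate_ebayes_params",
    "ebayes_moderate",
    "differential_expression",
    "trigamma_inverse",
]


@dataclass
class EbayesParams:
    """Empirical-Bayes hyperparameters: prior df d0 (may be inf), prior variance s0^2."""

    d0: float
    s0_2: float

    def __post_init__(self) -> None:
        if self.d0 < 0:
            raise ValueError("prior degrees of freedom must be >= 0")
        if not np.isfinite(self.s0_2) or self.s0_2 <= 0:
            raise ValueError("prior variance must be finite and > 0")


def fit_gene_models(adj: ExpressionMatrix, samples: SampleTable) -> pd.DataFrame:
    """Per-gene two-group OLS fits.

    Returns a DataFrame indexed by gene with columns ``effect`` (case mean
    minus control mean on the adjusted scale), ``sigma2`` (residual
    variance), ``df_resid`` and ``se_unit`` (unscaled standard error).
    """
    pheno = samples.phenotype(adj.sample_ids)
    n1 = int(pheno.sum())
    n0 = len(pheno) - n1
    for n, label in ((n0, "control"), (n1, "case")):
        if n < 2:
            raise ValueError(f"{label} class has {n} sample(s); >=2 required")
    Y = adj.values  # genes x samples
    case, ctrl = Y[:, pheno == 1], Y[:, pheno == 0]
    effect = case.mean(axis=1) - ctrl.mean(axis=1)
    rss = ((case - case.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    rss += ((ctrl - ctrl.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    df = n0 + n1 - 2
    return pd.DataFrame(
        {
            "effect": effect,
            "sigma2": rss / df,
            "df_resid": float(df),
            "se_unit": np.sqrt(1.0 / n0 + 1.0 / n1),
        },
        index=list(adj.gene_ids),
    )


def trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        raise ValueError("trigamma_inverse needs y > 0")
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if -dif / x < 1e-8:
            break
    return float(x)


def estimate_ebayes_params(sigma2: np.ndarray, df_resid: np.ndarray) -> EbayesParams:
    """Method-of-moments fit of the scaled-F model on log variances.

    Matches the mean and variance of log s2_g (corrected by digamma /
    trigamma terms of the chi-square sampling distribution) to the prior.
    Zero variances are floored at a tiny fraction of the median positive
    variance before taking logs (logged when it happens).
    """
    sigma2 = np.asarray(sigma2, dtype=float)
    df_resid = np.asarray(df_resid, dtype=float)
    pos = sigma2[sigma2 > 0]
    if pos.size == 0:
        raise ValueError("all gene variances are zero; cannot estimate prior")
    if pos.size < sigma2.size:
        floor = np.median(pos) * 1e-12
        logger.warning(
            "estimate_ebayes_params: flooring %d zero variance(s)",
            sigma2.size - pos.size,
        )
        sigma2 = np.maximum(sigma2, floor)
    z = np.log(sigma2)
    e = z - special.digamma(df_resid / 2.0) + np.log(df_resid / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - special.polygamma(1, df_resid / 2.0).mean()
    if evar > 0:
        d0 = 2.0 * trigamma_inverse(evar)
        s0_2 = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0_2 = float(np.exp(emean))
    return EbayesParams(d0=d0, s0_2=s0_2)


def ebayes_moderate(
    gene_fits: pd.DataFrame,
    params: EbayesParams | None = None,
    population: str = "",
    tissue: str = "",
) -> pd.DataFrame:
    """Moderated t-statistics and two-sided p-values.

    Shrinks each gene's variance toward the prior, forms
    t~ = effect / (posterior sd * unscaled se) and refers it to a t
    distribution on ``d0 + d_g`` df (capped at the total residual df, as
    no more information than the pooled residuals can exist).

    With fewer than 10 genes and no explicit *params*, hyperparameter
    estimation is unreliable; the function falls back to ordinary t
    (d0 = 0) with a logged warning.
    """
    sigma2 = gene_fits["sigma2"].to_numpy(dtype=float)
    df_resid = gene_fits["df_resid"].to_numpy(dtype=float)
    if params is None:
        if len(gene_fits) < 10:
            logger.warning(
                "ebayes_moderate: %d genes < 10; falling back to ordinary t",
                len(gene_fits),
            )
            params = None
        elif not np.any(sigma2 > 0):
            logger.warning(
                "ebayes_moderate: all variances zero; ordinary t on pseudo-variance floor"
            )
            sigma2 = np.full_like(sigma2, 1e-12)
            params = None
        else:
            params = estimate_ebayes_params(sigma2, df_resid)

    if params is None:
        d0, s2_post = 0.0, sigma2.copy()
    elif np.isinf(params.d0):
        d0, s2_post = params.d0, np.full_like(sigma2, params.s0_2)
    else:
        d0 = params.d0
        s2_post = (d0 * params.s0_2 + df_resid * sigma2) / (d0 + df_resid)

    if d0 == 0.0 and np.any(s2_post == 0):
        floor = np.median(s2_post[s2_post > 0]) * 1e-12 if np.any(s2_post > 0) else 1e-300
        logger.warning("ebayes_moderate: flooring zero posterior variance(s)")
        s2_post = np.maximum(s2_post, floor)

    se = np.sqrt(s2_post) * gene_fits["se_unit"].to_numpy(dtype=float)
    t = gene_fits["effect"].to_numpy(dtype=float) / se
    df_total = np.minimum(d0 + df_resid, df_resid.sum())
    if np.isinf(d0):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    out = gene_fits.copy()
    out["s2_post"] = s2_post
    out["moderated_t"] = t
    out["df_total"] = df_total
    out["p_value"] = p
    out["population"] = population
    out["tissue"] = tissue
    return out


def differential_expression(
    adj: ExpressionMatrix,
    samples: SampleTable,
    params: EbayesParams | None = None,
) -> pd.DataFrame:
    """Convenience: fit_gene_models then ebayes_moderate."""
    fits = fit_gene_models(adj, samples)
    return ebayes_moderate(fits, params, population=adj.population, tissue=adj.tissue)
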