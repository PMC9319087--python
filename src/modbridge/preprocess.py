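"""Covariate adjustment of imputed expression.

Two steps precede differential testing: (1) per-sample principal
components, computed from the expression matrix itself when genotype PCs
are not supplied (they proxy population structure); (2) per-gene OLS
residualization of expression on the demographic covariates (sex, age and
the top PCs by default).  The phenotype is deliberately NOT among the
regressors — it is the contrast tested downstream, and regressing it out
here would erase the case/control signal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import ExpressionMatrix, SampleTable

logger = logging.getLogger(__name__)

__all__ = ["AdjustedExpression", "compute_pcs", "adjust_covariates", "DEFAULT_COVARIATES"]

DEFAULT_COVARIATES = ("sex", "age", "pc_1", "pc_2", "pc_3", "pc_4")


@dataclass
class AdjustedExpression(ExpressionMatrix):
    """Expression residuals after covariate regression.

    Each gene's residual vector is orthogonal to every covariate column
    used (including the intercept, so residuals sum to ~0).
    """

    covariates_used: list[str] = field(default_factory=list)


def compute_pcs(expr: ExpressionMatrix, n_pcs: int = 4):
    """Principal components of the sample x gene matrix.

    Genes are centered and scaled to unit variance first; zero-variance
    genes are excluded (logged).  Returns a DataFrame of per-sample PC
    coordinates (columns ``pc_1..pc_K``) and the variance-explained
    fractions (non-increasing, each in [0, 1]).
    """
    n = expr.n_samples
    if n_pcs >= min(n, expr.n_genes):
        raise ValueError(
            f"n_pcs={n_pcs} must be < min(n_samples, n_genes)="
            f"{min(n, expr.n_genes)}"
        )
    X = expr.values.T  # samples x genes
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        logger.info("compute_pcs: excluded %d zero-variance gene(s)", (~keep).sum())
    X = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    # SVD of the centered/scaled matrix == eigendecomposition of sample covariance
    U, S, _ = np.linalg.svd(X, full_matrices=False)
    var = S**2
    frac = var / var.sum()
    coords = U[:, :n_pcs] * S[:n_pcs]
    # deterministic sign: largest-magnitude loading positive
    for j in range(n_pcs):
        i = np.argmax(np.abs(coords[:, j]))
        if coords[i, j] < 0:
            coords[:, j] = -coords[:, j]
    pcs = pd.DataFrame(
        coords, index=expr.sample_ids,
        columns=[f"pc_{j + 1}" for j in range(n_pcs)],
    )
    return pcs, frac[:n_pcs]


def _design_matrix(samples: SampleTable, ids: list[str], covariates) -> tuple[np.ndarray, list[str]]:
    frame = samples.frame.loc[ids]
    cols, names = [np.ones(len(ids))], ["intercept"]
    for cov in covariates:
        if cov not in frame.columns:
            raise ValueError(f"covariate {cov!r} missing from sample table")
        col = pd.to_numeric(frame[cov], errors="raise").to_numpy(dtype=float)
        if np.allclose(col, col[0]):
            logger.warning("adjust_covariates: dropping constant covariate %r", cov)
            continue
        cols.append(col)
        names.append(cov)
    X = np.column_stack(cols)
    # drop columns that are linearly dependent on earlier ones
    if np.linalg.matrix_rank(X) < X.shape[1]:
        keep = [0]
        for j in range(1, X.shape[1]):
            if np.linalg.matrix_rank(X[:, keep + [j]]) > len(keep):
                keep.append(j)
            else:
                logger.warning(
                    "adjust_covariates: dropping rank-deficient covariate %r", names[j]
                )
        names = [names[j] for j in keep]
        X = X[:, keep]
    return X, names


def adjust_covariates(
    expr: ExpressionMatrix,
    samples: SampleTable,
    covariates=DEFAULT_COVARIATES,
) -> AdjustedExpression:
    """Residualize each gene on intercept + covariates via OLS.

    Samples with any missing covariate are dropped (listwise, logged).
    Constant or linearly dependent covariate columns are dropped with a
    warning; if every non-intercept column is dropped the residuals reduce
    to centered expression.
    """
    missing = [s for s in expr.sample_ids if s not in samples.frame.index]
    if missing:
        raise ValueError(f"samples absent from sample table: {missing[:5]}")
    covariates = [c for c in covariates if c in samples.frame.columns]
    frame = samples.frame.loc[expr.sample_ids, covariates] if covariates else None
    ids = list(expr.sample_ids)
    if frame is not None and frame.isna().any().any():
        ok = ~frame.isna().any(axis=1)
        dropped = int((~ok).sum())
        logger.warning("adjust_covariates: dropped %d sample(s) with missing covariates", dropped)
        ids = [s for s, keep in zip(ids, ok) if keep]
    X, names = _design_matrix(samples, ids, covariates)
    sub = expr.subset_samples(ids)
    Y = sub.values.T  # samples x genes
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = (Y - X @ beta).T
    return AdjustedExpression(
        gene_ids=list(sub.gene_ids), sample_ids=ids, values=resid,
        population=expr.population, tissue=expr.tissue,
        covariates_used=names,
    )
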