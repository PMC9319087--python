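"""Linear genetically-regulated-expression (GReX) prediction.

Predicted expression of gene g in sample s is the dot product of the
gene's trained variant weights with the sample's allele dosages:
``GReX_gs = sum_k w_gk * dosage_ks``.  This is the PrediXcan prediction
rule; model training is out of scope and the weights are user input.
Variants present in the weight model but absent from the dosage matrix
contribute zero (they are counted and logged).
"""

from __future__ import annotations

import logging

import numpy as np

from .io_formats import DosageMatrix, ExpressionMatrix, WeightDB

logger = logging.getLogger(__name__)

__all__ = ["impute_grex"]


def impute_grex(
    dosages: DosageMatrix,
    weights: WeightDB,
    population: str = "",
    tissue: str = "",
    min_matched_fraction: float = 0.0,
) -> ExpressionMatrix:
    """Predict expression as the weight-dosage linear combination per gene.

    Parameters
    ----------
    dosages
        Variant x sample dosage matrix (values in [0, 2]).
    weights
        Per-gene variant weights.
    min_matched_fraction
        Genes whose fraction of weight variants found in the dosage matrix
        falls below this threshold are flagged in the log but kept.

    Returns
    -------
    ExpressionMatrix with one row per weight-model gene that matched at
    least one dosage variant.

    Raises
    ------
    ValueError
        If no gene shares any variant with the dosage matrix.
    """
    vidx = {v: i for i, v in enumerate(dosages.variant_ids)}
    gene_ids: list[str] = []
    rows: list[np.ndarray] = []
    n_missing_total = 0
    flagged: list[str] = []
    for gene, wlist in weights.weights.items():
        matched = [(vidx[v], w) for v, w in wlist if v in vidx]
        n_missing = len(wlist) - len(matched)
        n_missing_total += n_missing
        if not matched:
            continue
        if len(matched) / len(wlist) < min_matched_fraction:
            flagged.append(gene)
        idx = np.array([i for i, _ in matched], dtype=int)
        w = np.array([w for _, w in matched], dtype=float)
        rows.append(w @ dosages.values[idx, :])
        gene_ids.append(gene)
    if not gene_ids:
        raise ValueError("weights and dosages share no variants")
    if n_missing_total:
        logger.info(
            "impute_grex: %d weight variant(s) absent from dosages contributed 0",
            n_missing_total,
        )
    if flagged:
        logger.warning(
            "impute_grex: %d gene(s) below matched-variant fraction %g: %s",
            len(flagged), min_matched_fraction, flagged[:10],
        )
    return ExpressionMatrix(
        gene_ids, list(dosages.sample_ids), np.vstack(rows),
        population=population, tissue=tissue,
    )
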