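"""Tissue-specificity (Tau), tissue-specific gene selection, DE filtering.

Tau is the Yanai index: with x̂_i = x_i / max(x) over N tissues,

    tau = Σ_i (1 − x̂_i) / (N − 1)

so tau = 0 for perfectly uniform expression and tau = 1 for expression
confined to a single tissue.  By default it is computed on log2(x + 1)
transformed values, the convention for TPM-scale inputs.

Tissue-specific genes must meet two criteria in a tissue t: (1) t ranks in
the gene's top 5 tissues by expression (competition ranking, ties share the
best rank) and (2) the gene's expression in t is strictly above the 90th
percentile of all genes' expression within t.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import SchemaError

logger = logging.getLogger(__name__)


def tau(expression, log_transform: bool = True) -> float:
    """Tissue-specificity index of one gene's expression across tissues.

    Returns NaN for an all-zero vector (specificity undefined).
    """
    x = np.asarray(expression, dtype=np.float64)
    if x.ndim != 1 or x.size < 2:
        raise SchemaError("tau needs a 1-D vector over >= 2 tissues")
    if (x < 0).any():
        raise SchemaError("expression must be nonnegative")
    if log_transform:
        x = np.log2(x + 1.0)
    m = x.max()
    if m == 0:
        return float("nan")
    return float((1.0 - x / m).sum() / (x.size - 1))


def tau_table(matrix: pd.DataFrame, log_transform: bool = True) -> pd.Series:
    """Tau for every row of a genes x tissues matrix."""
    return pd.Series(
        {g: tau(row.to_numpy(), log_transform) for g, row in matrix.iterrows()},
        name="tau",
    )


def select_tissue_specific(
    matrix: pd.DataFrame, top_rank: int = 5, percentile: float = 90.0
) -> dict:
    """Per-tissue sets of tissue-specific genes under the two-criteria rule.

    ``matrix`` is genes x tissues (median expression, TPM-like).  Returns
    ``{tissue: set(gene_id)}``; a gene may be specific to several tissues.
    Use :func:`tissue_specific_evidence` for per-gene rank/percentile
    support.
    """
    ev = tissue_specific_evidence(matrix, top_rank, percentile)
    out = {t: set() for t in matrix.columns}
    for (gene, tissue), row in ev.iterrows():
        if row["selected"]:
            out[tissue].add(gene)
    return out


def tissue_specific_evidence(
    matrix: pd.DataFrame, top_rank: int = 5, percentile: float = 90.0
) -> pd.DataFrame:
    """Rank and percentile evidence for every (gene, tissue) pair.

    Competition ranking: a tissue's rank for a gene is 1 + the number of
    tissues with strictly greater expression, so ties share the best rank.
    The percentile cut is the linear-interpolation quantile of all genes'
    expression within the tissue, applied strictly (">").
    """
    if matrix.shape[1] < 2:
        raise SchemaError("need >= 2 tissues")
    if (matrix.to_numpy() < 0).any():
        raise SchemaError("expression must be nonnegative")
    if matrix.shape[0] < 10:
        logger.warning(
            "only %d genes: the within-tissue percentile is ill-conditioned",
            matrix.shape[0],
        )
    x = matrix.to_numpy(dtype=np.float64)
    # competition rank of each tissue within each gene's row
    rank = 1 + (x[:, :, None] > x[:, None, :]).sum(axis=1)  # genes x tissues
    cuts = np.percentile(x, percentile, axis=0)             # per tissue
    selected = (rank <= top_rank) & (x > cuts[None, :])
    idx = pd.MultiIndex.from_product(
        [matrix.index, matrix.columns], names=["gene", "tissue"]
    )
    return pd.DataFrame(
        {
            "expression": x.ravel(),
            "rank": rank.ravel(),
            "percentile_cut": np.repeat(cuts[None, :], len(matrix), axis=0).ravel(),
            "selected": selected.ravel(),
        },
        index=idx,
    )


def filter_de(
    de_table: pd.DataFrame, lfc_cut: float = 2.0, p_cut: float = 0.05
) -> dict:
    """Split a DE table into up/down gene sets at |log2FC| >= cut, p <= cut.

    Both thresholds are inclusive; a record at log2FC = 1.19 does not pass
    a 1.2 cut.  Returns ``{"up": set, "down": set}`` (disjoint).
    """
    if lfc_cut <= 0 or p_cut <= 0:
        raise SchemaError("thresholds must be positive")
    required = {"gene", "log2FoldChange", "pvalue"}
    missing = required - set(de_table.columns)
    if missing:
        raise SchemaError(f"DE table missing columns {sorted(missing)}")
    lfc = de_table["log2FoldChange"].to_numpy(dtype=np.float64)
    pv = de_table["pvalue"].to_numpy(dtype=np.float64)
    genes = de_table["gene"].astype(str).to_numpy()
    ok = pv <= p_cut
    return {
        "up": set(genes[ok & (lfc >= lfc_cut)]),
        "down": set(genes[ok & (lfc <= -lfc_cut)]),
    }
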