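"""H3K4me1 pattern classification and H3K27me3–H3K4me1 transition calling.

A promoter's H3K4me1 pattern is read from two one-dimensional 2-means
clusterings — one on CGI-body means, one on shore means — each labelled
high/low by cluster mean.  The 2x2 combination maps to three patterns:

====================  ===========  ============
body level            shore level  pattern
====================  ===========  ============
high                  high or low  untypical_unimodal
low                   high         typical_bimodal
low                   low          flat
====================  ===========  ============

Body elevation dominates because the trivalent (bivalent) state is defined
by H3K4me1 over the CGI itself.  Between two paired conditions, loss of
H3K27me3 (body-mean drop beyond a threshold) combined with a shore-level
flip defines the transition: shore high→low is *biloss* (bimodal loss),
low→high is *bigain*.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .errors import DegenerateDataError, SchemaError
from .signal import SignalMatrix, summarize_region

logger = logging.getLogger(__name__)


def _two_level(values: pd.Series, seed: int, what: str) -> pd.Series:
    """1-D 2-means; returns 'high'/'low' per row by cluster mean."""
    x = values.to_numpy(dtype=np.float64).reshape(-1, 1)
    if np.ptp(x) == 0:
        raise DegenerateDataError(
            f"{what} summaries are constant; 2-means cannot separate levels — "
            "supply explicit thresholds or add signal variation"
        )
    km = KMeans(n_clusters=2, n_init=10, random_state=seed)
    lab = km.fit_predict(x)
    high_cluster = int(np.argmax(km.cluster_centers_.ravel()))
    return pd.Series(
        np.where(lab == high_cluster, "high", "low"), index=values.index
    )


def classify_pattern(h3k4me1_matrix: SignalMatrix, seed: int = 0) -> pd.DataFrame:
    """Call the per-promoter H3K4me1 pattern for one condition.

    Returns a frame indexed by cgi_id with ``body_level``, ``shore_level``
    and ``pattern``.
    """
    if len(h3k4me1_matrix.row_ids) < 4:
        raise SchemaError("pattern classification needs at least 4 promoters")
    body = summarize_region(h3k4me1_matrix, "body")
    shores = summarize_region(h3k4me1_matrix, "shores")
    body_level = _two_level(body, seed, "body")
    shore_level = _two_level(shores, seed, "shore")
    pattern = np.where(
        body_level == "high", "untypical_unimodal",
        np.where(shore_level == "high", "typical_bimodal", "flat"),
    )
    return pd.DataFrame(
        {"body_level": body_level, "shore_level": shore_level, "pattern": pattern},
        index=h3k4me1_matrix.row_ids,
    )


def default_loss_threshold(
    k27_matrix_cond1: SignalMatrix, bivalent_ids
) -> float:
    """Half the condition-1 bivalent-cluster median body H3K27me3.

    A numeric stand-in for the visual heatmap criterion of "loss".
    """
    body = summarize_region(k27_matrix_cond1, "body")
    med = float(body.loc[body.index.intersection(pd.Index(list(bivalent_ids)))].median())
    return 0.5 * med


def call_transitions(
    calls_cond1: pd.DataFrame,
    calls_cond2: pd.DataFrame,
    k27_matrices: tuple,
    loss_threshold: float,
    k4me1_matrices: tuple | None = None,
) -> pd.DataFrame:
    """Call per-promoter H3K27me3–H3K4me1 transitions between two conditions.

    Parameters
    ----------
    calls_cond1, calls_cond2
        Pattern calls from :func:`classify_pattern` on the paired conditions.
    k27_matrices
        ``(cond1, cond2)`` H3K27me3 signal matrices.
    loss_threshold
        H3K27me3 body-mean drop (cond2 − cond1 <= −threshold) that counts
        as loss; see :func:`default_loss_threshold`.
    k4me1_matrices
        Optional ``(cond1, cond2)`` H3K4me1 matrices for delta reporting.

    Returns
    -------
    Frame indexed by cgi_id with ``h3k27me3_delta``, ``h3k4me1_shore_delta``,
    ``h3k4me1_body_delta``, ``k27_loss``, ``group`` in {biloss, bigain, none}
    and boolean ``transition`` (loss AND shore-level flip).
    """
    if not calls_cond1.index.equals(calls_cond2.index):
        raise SchemaError("pattern calls cover different promoter universes")
    k27_1, k27_2 = k27_matrices
    if not k27_1.row_ids.equals(calls_cond1.index) or not k27_2.row_ids.equals(
        calls_cond1.index
    ):
        raise SchemaError("H3K27me3 matrices do not match the pattern-call universe")
    delta27 = summarize_region(k27_2, "body") - summarize_region(k27_1, "body")
    loss = delta27 <= -loss_threshold

    s1 = calls_cond1["shore_level"]
    s2 = calls_cond2["shore_level"]
    group = np.where(
        (s1 == "high") & (s2 == "low"), "biloss",
        np.where((s1 == "low") & (s2 == "high"), "bigain", "none"),
    )
    out = pd.DataFrame(
        {
            "h3k27me3_delta": delta27,
            "k27_loss": loss,
            "group": group,
            "transition": loss.to_numpy() & (group != "none"),
        },
        index=calls_cond1.index,
    )
    if k4me1_matrices is not None:
        k4_1, k4_2 = k4me1_matrices
        out["h3k4me1_shore_delta"] = (
            summarize_region(k4_2, "shores") - summarize_region(k4_1, "shores")
        )
        out["h3k4me1_body_delta"] = (
            summarize_region(k4_2, "body") - summarize_region(k4_1, "body")
        )
    else:
        out["h3k4me1_shore_delta"] = np.nan
        out["h3k4me1_body_delta"] = np.nan
    return out


def group_expression_contrast(
    transitions: pd.DataFrame,
    gene_map: pd.Series,
    de_table: pd.DataFrame,
    lfc_cut: float = 1.2,
    p_cut: float = 0.1,
) -> dict:
    """Contrast KO-vs-WT expression change between biloss and bigain genes.

    ``gene_map`` maps cgi_id -> gene_id; ``de_table`` needs ``gene``,
    ``log2FoldChange`` and ``pvalue`` columns.  Reports per-group log2FC
    summaries, a two-sided Wilcoxon rank-sum p-value between the groups,
    and a chi-square test (no continuity correction) of up/down counts x
    group at the given DE thresholds.  Groups with fewer than 3 genes make
    the corresponding statistic undefined (NaN, with a warning).
    """
    de = de_table.set_index("gene")
    groups = {}
    for name in ("biloss", "bigain"):
        cgis = transitions.index[transitions["group"] == name]
        genes = gene_map.reindex(cgis).dropna()
        lfc = de["log2FoldChange"].reindex(genes).dropna()
        pv = de["pvalue"].reindex(genes).dropna()
        up = int(((lfc >= lfc_cut) & (pv <= p_cut)).sum())
        down = int(((lfc <= -lfc_cut) & (pv <= p_cut)).sum())
        groups[name] = {
            "n": int(len(lfc)),
            "median_lfc": float(lfc.median()) if len(lfc) else float("nan"),
            "mean_lfc": float(lfc.mean()) if len(lfc) else float("nan"),
            "n_up": up,
            "n_down": down,
            "_lfc": lfc,
        }
    small = [g for g, d in groups.items() if d["n"] < 3]
    if small:
        logger.warning("group(s) %s have < 3 genes; tests undefined", small)
        wilcoxon_p = float("nan")
        chi2_stat = chi2_p = float("nan")
    else:
        wilcoxon_p = float(
            stats.ranksums(groups["biloss"]["_lfc"], groups["bigain"]["_lfc"]).pvalue
        )
        table = np.array(
            [[groups["biloss"]["n_up"], groups["biloss"]["n_down"]],
             [groups["bigain"]["n_up"], groups["bigain"]["n_down"]]]
        )
        if (table.sum(axis=1) > 0).all() and (table.sum(axis=0) > 0).all():
            chi2 = stats.chi2_contingency(table, correction=False)
            chi2_stat, chi2_p = float(chi2.statistic), float(chi2.pvalue)
        else:
            chi2_stat = chi2_p = float("nan")
    lower = (
        "biloss"
        if groups["biloss"]["median_lfc"] <= groups["bigain"]["median_lfc"]
        else "bigain"
    )
    for d in groups.values():
        d.pop("_lfc")
    return {
        "groups": groups,
        "wilcoxon_p": wilcoxon_p,
        "chi2_stat": chi2_stat,
        "chi2_p": chi2_p,
        "lower_median_group": lower,
        "lfc_cut": lfc_cut,
        "p_cut": p_cut,
    }
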