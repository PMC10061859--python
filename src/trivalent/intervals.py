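"""Promoter-CGI definition, gene linking, and enhancer assignment.

A *promoter CGI* is a CpG island of 200–5000 bp overlapping a window of
±1 kb around some TSS; it is linked to the gene whose TSS lies nearest its
midpoint.  An *enhancer* is an H3K4me1 peak whose midpoint is more than
5 kb from every TSS; each gene keeps only its nearest enhancer.

Coordinates are BED-style 0-based half-open throughout; "TSS ± 1 kb" means
``[tss - 1000, tss + 1000)``.  CGIs are unstranded, so shores are genomic
left/right rather than transcription-oriented.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .config import CGI_MIN_BP, CGI_MAX_BP, ENHANCER_MIN_TSS_DISTANCE
from .errors import NotAPromoterError, SchemaError

logger = logging.getLogger(__name__)

TSS_WINDOW_BP = 1000


def _require_columns(df: pd.DataFrame, cols, what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} is missing columns {missing}")


def _tss_frame(tss_annotation: pd.DataFrame) -> pd.DataFrame:
    """Normalize a TSS annotation (BED6-like) to chrom/tss/gene columns."""
    _require_columns(tss_annotation, ["chrom", "start", "name"], "TSS annotation")
    out = pd.DataFrame(
        {
            "chrom": tss_annotation["chrom"].astype(str),
            "tss": tss_annotation["start"].astype(int),
            "gene_id": tss_annotation["name"].astype(str),
        }
    )
    if "strand" in tss_annotation.columns:
        # minus-strand BED6 intervals of length 1 still carry the TSS in
        # `start`; wider intervals use the strand-appropriate edge.
        wide = (tss_annotation["end"] - tss_annotation["start"]) > 1
        minus = (tss_annotation["strand"] == "-") & wide
        out.loc[minus.values, "tss"] = tss_annotation.loc[minus, "end"].astype(int) - 1
    return out


def define_promoter_cgis(cgis: pd.DataFrame, tss_annotation: pd.DataFrame) -> pd.DataFrame:
    """Select promoter CGIs and link each to its nearest overlapping gene.

    Parameters
    ----------
    cgis
        Interval frame with ``chrom``, ``start``, ``end`` and optionally
        ``name`` (a ``cgi_id`` is synthesized when absent).
    tss_annotation
        BED6-like frame with one TSS per row; ``name`` is the gene id.

    Returns
    -------
    DataFrame with columns ``cgi_id, chrom, start, end, gene_id, tss,
    tss_distance`` — exactly the CGIs of length 200–5000 bp with >= 1 bp
    overlap with some TSS ± 1 kb window.  Empty inputs yield an empty frame.
    """
    _require_columns(cgis, ["chrom", "start", "end"], "CGI set")
    tss = _tss_frame(tss_annotation)

    cgis = cgis.copy()
    if "name" not in cgis.columns:
        cgis["name"] = [f"cgi{i:06d}" for i in range(len(cgis))]
    cgis["chrom"] = cgis["chrom"].astype(str)

    known = set(tss["chrom"].unique())
    orphan = sorted(set(cgis["chrom"].unique()) - known)
    if orphan:
        logger.warning("skipping CGIs on chromosomes absent from annotation: %s", orphan)
        cgis = cgis[cgis["chrom"].isin(known)]

    rows = []
    for chrom, sub in cgis.groupby("chrom", sort=False):
        t = tss[tss["chrom"] == chrom]
        if t.empty:
            continue
        tpos = t["tss"].to_numpy()
        tgene = t["gene_id"].to_numpy()
        for start, end, name in zip(sub["start"], sub["end"], sub["name"]):
            length = end - start
            if length < CGI_MIN_BP or length > CGI_MAX_BP:
                continue
            # overlap with [tss-1000, tss+1000): start < tss+1000 and end > tss-1000
            hit = (start < tpos + TSS_WINDOW_BP) & (end > tpos - TSS_WINDOW_BP)
            if not hit.any():
                continue
            gene, tss_pos = _nearest_tss(start, end, tpos[hit], tgene[hit])
            rows.append(
                (name, chrom, int(start), int(end), gene, int(tss_pos),
                 abs((start + end) / 2.0 - tss_pos))
            )
    out = pd.DataFrame(
        rows,
        columns=["cgi_id", "chrom", "start", "end", "gene_id", "tss", "tss_distance"],
    )
    return out.reset_index(drop=True)


def _nearest_tss(start: int, end: int, tpos: np.ndarray, tgene: np.ndarray):
    """Nearest TSS to the CGI midpoint; ties broken by lexicographic gene id.

    Uses doubled integer coordinates so midpoint ties are detected exactly.
    """
    mid2 = start + end  # 2 * midpoint
    dist2 = np.abs(2 * tpos.astype(np.int64) - mid2)
    best = dist2.min()
    idx = np.flatnonzero(dist2 == best)
    if len(idx) > 1:
        idx = idx[np.argsort(tgene[idx], kind="stable")]
    return tgene[idx[0]], tpos[idx[0]]


def assign_gene(cgi, tss_annotation: pd.DataFrame) -> str:
    """Return the gene id for one CGI interval (``chrom, start, end``).

    Raises :class:`NotAPromoterError` when no TSS ± 1 kb window overlaps.
    """
    chrom, start, end = str(cgi[0]), int(cgi[1]), int(cgi[2])
    tss = _tss_frame(tss_annotation)
    t = tss[tss["chrom"] == chrom]
    tpos = t["tss"].to_numpy()
    hit = (start < tpos + TSS_WINDOW_BP) & (end > tpos - TSS_WINDOW_BP)
    if not hit.any():
        raise NotAPromoterError(
            f"no TSS within 1 kb of CGI {chrom}:{start}-{end}"
        )
    gene, _ = _nearest_tss(start, end, tpos[hit], t["gene_id"].to_numpy()[hit])
    return gene


def define_enhancers(h3k4me1_peaks: pd.DataFrame, tss_annotation: pd.DataFrame) -> pd.DataFrame:
    """Assign each gene its nearest H3K4me1 peak > 5 kb from every TSS.

    Peaks whose midpoint lies within 5 kb of *any* TSS are discarded as
    promoter-proximal.  Each gene then receives the surviving peak nearest
    its TSS (midpoint distance); ties go to the leftmost peak.  Genes with
    no surviving peak on their chromosome are omitted (logged).

    Returns columns ``gene_id, chrom, start, end, enhancer_id, distance``.
    """
    _require_columns(h3k4me1_peaks, ["chrom", "start", "end"], "peak set")
    if h3k4me1_peaks.empty:
        raise SchemaError("peak set is empty")
    tss = _tss_frame(tss_annotation)

    peaks = h3k4me1_peaks.copy()
    peaks["chrom"] = peaks["chrom"].astype(str)
    if "name" not in peaks.columns:
        peaks["name"] = [f"peak{i:06d}" for i in range(len(peaks))]

    rows = []
    for chrom, t in tss.groupby("chrom", sort=False):
        p = peaks[peaks["chrom"] == chrom]
        if p.empty:
            dropped = t["gene_id"].tolist()
            logger.info("no enhancer candidates on %s; dropping genes %s", chrom, dropped)
            continue
        pmid2 = (p["start"].to_numpy(np.int64) + p["end"].to_numpy(np.int64))
        tpos2 = 2 * t["tss"].to_numpy(np.int64)
        # distal filter: midpoint distance to every TSS must exceed 5 kb
        d2 = np.abs(pmid2[:, None] - tpos2[None, :])
        distal = d2.min(axis=1) > 2 * ENHANCER_MIN_TSS_DISTANCE
        if not distal.any():
            logger.info("no distal peaks on %s", chrom)
            continue
        p = p[distal]
        pmid2 = pmid2[distal]
        starts = p["start"].to_numpy(np.int64)
        for gene, tss_pos in zip(t["gene_id"], t["tss"]):
            dist2 = np.abs(pmid2 - 2 * tss_pos)
            best = dist2.min()
            idx = np.flatnonzero(dist2 == best)
            if len(idx) > 1:  # leftmost peak wins
                idx = idx[np.argsort(starts[idx], kind="stable")]
            i = idx[0]
            rows.append(
                (gene, chrom, int(p["start"].iloc[i]), int(p["end"].iloc[i]),
                 str(p["name"].iloc[i]), best / 2.0)
            )
    out = pd.DataFrame(
        rows, columns=["gene_id", "chrom", "start", "end", "enhancer_id", "distance"]
    )
    # multi-TSS genes: keep the assignment via the nearest TSS
    out = out.sort_values(["gene_id", "distance", "start"], kind="stable")
    out = out.drop_duplicates("gene_id", keep="first")
    return out.reset_index(drop=True)
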