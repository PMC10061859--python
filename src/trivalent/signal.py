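"""Signal matrices over promoter CGIs and their 1 kb shores.

Each promoter row is binned as ``n_flank`` equal-width bins over the left
shore, ``n_body`` bins over the variable-length CGI body (rescaled to a
common width by exact fractional-basepair averaging) and ``n_flank`` bins
over the right shore.  Bin values are mean input-adjusted coverage; missing
coverage (off-contig spans) counts as zero.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateDataError, SchemaError
from .io import CoverageTrack

logger = logging.getLogger(__name__)

REGIONS = ("left_shore", "body", "right_shore", "shores", "full")


@dataclass
class SignalMatrix:
    """Promoter x bin matrix for one histone mark in one condition."""

    values: pd.DataFrame          # index = cgi_id, columns = bin labels
    n_flank: int
    n_body: int
    flank_bp: int
    body_bp: pd.Series            # per-row CGI length (bp), same index
    mark: str = ""
    condition: str = ""
    scaling: str = "none"

    def __post_init__(self):
        expected = 2 * self.n_flank + self.n_body
        if self.values.shape[1] != expected:
            raise SchemaError(
                f"expected {expected} columns, got {self.values.shape[1]}"
            )

    @property
    def row_ids(self) -> pd.Index:
        return self.values.index

    def block(self, region: str) -> pd.DataFrame:
        nf, nb = self.n_flank, self.n_body
        if region == "left_shore":
            return self.values.iloc[:, :nf]
        if region == "body":
            return self.values.iloc[:, nf: nf + nb]
        if region == "right_shore":
            return self.values.iloc[:, nf + nb:]
        raise KeyError(region)

    def copy_with(self, values: pd.DataFrame, scaling: str | None = None) -> "SignalMatrix":
        return SignalMatrix(
            values=values, n_flank=self.n_flank, n_body=self.n_body,
            flank_bp=self.flank_bp, body_bp=self.body_bp, mark=self.mark,
            condition=self.condition,
            scaling=self.scaling if scaling is None else scaling,
        )

    # -- TSV round-trip ---------------------------------------------------
    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(
                f"# mark={self.mark}\tcondition={self.condition}\t"
                f"n_flank={self.n_flank}\tn_body={self.n_body}\t"
                f"flank_bp={self.flank_bp}\tscaling={self.scaling}\n"
            )
            out = self.values.copy()
            out.insert(0, "body_bp", self.body_bp)
            out.to_csv(fh, sep="\t", index_label="cgi_id", float_format="%.8g")

    @classmethod
    def from_tsv(cls, path) -> "SignalMatrix":
        with open(path) as fh:
            header = fh.readline()
            meta = dict(
                kv.split("=", 1) for kv in header.lstrip("# ").rstrip().split("\t")
            )
            df = pd.read_csv(fh, sep="\t", index_col="cgi_id")
        body_bp = df.pop("body_bp")
        return cls(
            values=df, n_flank=int(meta["n_flank"]), n_body=int(meta["n_body"]),
            flank_bp=int(meta["flank_bp"]), body_bp=body_bp,
            mark=meta.get("mark", ""), condition=meta.get("condition", ""),
            scaling=meta.get("scaling", "none"),
        )


def _bin_labels(n_flank: int, n_body: int) -> list:
    return (
        [f"L{i + 1:02d}" for i in range(n_flank)]
        + [f"B{i + 1:02d}" for i in range(n_body)]
        + [f"R{i + 1:02d}" for i in range(n_flank)]
    )


def _fractional_bin_means(window: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Mean coverage over each ``[edges[i], edges[i+1])`` span.

    ``window`` is per-bp coverage; edges may be fractional.  Exact under
    the piecewise-constant (per-bp) coverage model.
    """
    cum = np.concatenate(([0.0], np.cumsum(window, dtype=np.float64)))

    def integral(t: np.ndarray) -> np.ndarray:
        i = np.minimum(np.floor(t).astype(np.int64), len(window) - 1)
        i = np.maximum(i, 0)
        return cum[i] + (t - i) * window[i]

    upper = integral(edges[1:])
    upper[edges[1:] >= len(window)] = cum[-1]
    lower = integral(edges[:-1])
    return (upper - lower) / np.diff(edges)


def bin_signal(
    track: CoverageTrack,
    promoters: pd.DataFrame,
    n_flank: int = 20,
    n_body: int = 20,
    flank: int = 1000,
    mark: str = "",
    condition: str = "",
) -> SignalMatrix:
    """Bin a coverage track over promoter CGIs plus ``flank`` bp shores.

    ``promoters`` must carry ``cgi_id, chrom, start, end``.  Input-adjusted
    coverage can dip below zero upstream; negatives are clamped to 0 here.
    Shores running off a contig edge are filled with zero coverage and the
    affected promoters are logged.
    """
    if n_flank < 1 or n_body < 1:
        raise SchemaError("n_flank and n_body must be >= 1")
    labels = _bin_labels(n_flank, n_body)
    mat = np.empty((len(promoters), len(labels)), dtype=np.float64)
    truncated = []

    edges_flank = np.linspace(0, flank, n_flank + 1)
    for r, (cgi_id, chrom, start, end) in enumerate(
        zip(promoters["cgi_id"], promoters["chrom"], promoters["start"], promoters["end"])
    ):
        arr = track.get(str(chrom))
        length = end - start
        win_len = length + 2 * flank
        if arr is None:
            mat[r] = 0.0
            logger.warning("promoter %s on missing contig %s: zero row", cgi_id, chrom)
            continue
        ws, we = start - flank, end + flank
        window = np.zeros(win_len, dtype=np.float64)
        lo, hi = max(ws, 0), min(we, len(arr))
        if lo < hi:
            window[lo - ws: hi - ws] = arr[lo:hi]
        if ws < 0 or we > len(arr):
            truncated.append(cgi_id)
        np.maximum(window, 0.0, out=window)
        edges = np.concatenate(
            (
                edges_flank[:-1],
                flank + np.linspace(0, length, n_body + 1)[:-1],
                flank + length + edges_flank,
            )
        )
        mat[r] = _fractional_bin_means(window, edges)
    if truncated:
        logger.warning(
            "%d promoter shore(s) truncated at contig edges (zero-filled): %s%s",
            len(truncated), truncated[:5], "..." if len(truncated) > 5 else "",
        )
    values = pd.DataFrame(mat, index=pd.Index(promoters["cgi_id"], name="cgi_id"),
                          columns=labels)
    body_bp = pd.Series(
        (promoters["end"] - promoters["start"]).to_numpy(),
        index=values.index, name="body_bp",
    )
    return SignalMatrix(
        values=values, n_flank=n_flank, n_body=n_body, flank_bp=flank,
        body_bp=body_bp, mark=mark, condition=condition,
    )


def winsorize_scale(matrix: SignalMatrix, upper_pct: float = 99.0) -> SignalMatrix:
    """Clamp values above the matrix-wide ``upper_pct`` percentile.

    Robustness step before clustering/heatmaps; ``upper_pct=100`` is the
    identity.
    """
    if not 50 < upper_pct <= 100:
        raise SchemaError("upper_pct must be in (50, 100]")
    vals = matrix.values.to_numpy()
    if not np.all(np.isfinite(vals)):
        raise DegenerateDataError("matrix contains non-finite values")
    cap = np.percentile(vals, upper_pct)
    clipped = pd.DataFrame(
        np.minimum(vals, cap), index=matrix.values.index, columns=matrix.values.columns
    )
    return matrix.copy_with(clipped, scaling=f"winsorized@{upper_pct:g}")


def summarize_region(matrix: SignalMatrix, region: str) -> pd.Series:
    """Per-row mean coverage over one region.

    ``shores`` is the plain average of the two shore means; ``full`` is the
    bp-weighted mean over shores + body (equal to the per-basepair mean of
    the whole padded window).
    """
    if region not in REGIONS:
        raise KeyError(f"unknown region {region!r}; choose from {REGIONS}")
    if region in ("left_shore", "body", "right_shore"):
        return matrix.block(region).mean(axis=1).rename(region)
    left = matrix.block("left_shore").mean(axis=1)
    right = matrix.block("right_shore").mean(axis=1)
    if region == "shores":
        return ((left + right) / 2.0).rename("shores")
    body = matrix.block("body").mean(axis=1)
    fl = float(matrix.flank_bp)
    bw = matrix.body_bp.astype(float)
    total = 2 * fl + bw
    return ((fl * (left + right) + bw * body) / total).rename("full")
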