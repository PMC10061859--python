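"""Text-format IO: BED, chrom.sizes, bedGraph coverage tracks, TSV tables.

All genomic coordinates follow the BED convention (0-based, half-open).
Coverage is held in memory as one dense per-chromosome float array at
basepair resolution — toy genomes here are tens of megabases at most, so a
dense representation keeps binning exact and simple.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SchemaError

BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def read_chrom_sizes(path) -> dict:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "size"])
    return dict(zip(df["chrom"].astype(str), df["size"].astype(int)))


def write_chrom_sizes(sizes: dict, path) -> None:
    with open(path, "w") as fh:
        for chrom, size in sizes.items():
            fh.write(f"{chrom}\t{size}\n")


def read_bed(path) -> pd.DataFrame:
    """Read BED3/4/6 into a DataFrame with as many named columns as present."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 3:
        raise SchemaError(f"{path}: BED needs at least 3 columns")
    df = df.iloc[:, : min(df.shape[1], 6)]
    df.columns = BED6_COLUMNS[: df.shape[1]]
    df["chrom"] = df["chrom"].astype(str)
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    return df


def write_bed(df: pd.DataFrame, path, columns=None) -> None:
    cols = columns or [c for c in BED6_COLUMNS if c in df.columns]
    df.to_csv(path, sep="\t", header=False, index=False, columns=cols)


def extract_tss_from_gtf(path) -> pd.DataFrame:
    """Extract one TSS record per gene from a GTF (gene or transcript rows).

    Returns a BED6-like frame with ``start`` = TSS (0-based), ``end`` =
    TSS + 1 and ``name`` = gene_id.  For minus-strand features the TSS is
    the feature end.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] not in ("gene", "transcript"):
                continue
            attrs = f[8]
            gene = None
            for part in attrs.split(";"):
                part = part.strip()
                if part.startswith("gene_id"):
                    gene = part.split(None, 1)[1].strip('" ')
                    break
            if gene is None:
                continue
            start1, end1, strand = int(f[3]), int(f[4]), f[6]
            tss = start1 - 1 if strand != "-" else end1 - 1
            rows.append((f[0], tss, tss + 1, gene, 0, strand))
    df = pd.DataFrame(rows, columns=BED6_COLUMNS)
    # gene rows take precedence; otherwise keep the most upstream transcript TSS
    df = df.sort_values(["name", "start"]).drop_duplicates("name")
    return df.reset_index(drop=True)


class CoverageTrack:
    """Dense per-chromosome coverage at basepair resolution."""

    def __init__(self, values: dict):
        self.values = {str(c): np.asarray(v) for c, v in values.items()}

    @property
    def chrom_sizes(self) -> dict:
        return {c: len(v) for c, v in self.values.items()}

    def get(self, chrom: str) -> np.ndarray | None:
        return self.values.get(chrom)

    @classmethod
    def zeros(cls, chrom_sizes: dict, dtype=np.float32) -> "CoverageTrack":
        return cls({c: np.zeros(n, dtype=dtype) for c, n in chrom_sizes.items()})

    @classmethod
    def from_bedgraph(cls, path, chrom_sizes: dict) -> "CoverageTrack":
        track = cls.zeros(chrom_sizes)
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            names=["chrom", "start", "end", "value"],
            dtype={"chrom": str, "start": int, "end": int, "value": float},
        )
        for chrom, sub in df.groupby("chrom", sort=False):
            arr = track.values.get(str(chrom))
            if arr is None:
                continue
            for s, e, v in zip(sub["start"], sub["end"], sub["value"]):
                arr[max(s, 0): min(e, len(arr))] = v
        return track

    @classmethod
    def from_bigwig(cls, path) -> "CoverageTrack":
        import pyBigWig  # optional dependency, only needed for bigWig input

        bw = pyBigWig.open(str(path))
        values = {}
        for chrom, size in bw.chroms().items():
            arr = np.nan_to_num(
                np.asarray(bw.values(chrom, 0, size), dtype=np.float64)
            )
            values[chrom] = arr.astype(np.float32)
        bw.close()
        return cls(values)

    def to_bedgraph(self, path) -> None:
        """Write run-length-encoded bedGraph; zero runs are omitted."""
        with open(path, "w") as fh:
            for chrom in self.values:
                arr = np.asarray(self.values[chrom], dtype=np.float64)
                if arr.size == 0:
                    continue
                breaks = np.flatnonzero(np.diff(arr)) + 1
                starts = np.concatenate(([0], breaks))
                ends = np.concatenate((breaks, [arr.size]))
                vals = arr[starts]
                for s, e, v in zip(starts, ends, vals):
                    if v == 0:
                        continue
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:.6g}\n")


def read_track(path, chrom_sizes: dict | None = None) -> CoverageTrack:
    """Read a coverage track from bedGraph (or bigWig if pyBigWig imports)."""
    p = str(path)
    if p.endswith((".bw", ".bigwig", ".bigWig")):
        return CoverageTrack.from_bigwig(p)
    if chrom_sizes is None:
        raise SchemaError("bedGraph input requires chrom_sizes")
    return CoverageTrack.from_bedgraph(p, chrom_sizes)


def write_tsv(df: pd.DataFrame, path, index=False, float_format="%.6g") -> None:
    df.to_csv(path, sep="\t", index=index, float_format=float_format)


def read_expression_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] < 2:
        raise SchemaError(f"{path}: expression matrix needs >= 2 tissue columns")
    return df


def read_de_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"gene", "log2FoldChange", "pvalue"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: DE table missing columns {sorted(missing)}")
    return df
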