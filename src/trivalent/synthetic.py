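"""Synthetic genomes, coverage tracks and expression with planted truth.

The generator lays out non-overlapping promoter "slots" along toy
chromosomes.  Each slot holds one CpG island (its TSS inside the island),
1 kb shores, and one distal enhancer interval planted more than 5 kb from
every TSS.  Promoters are assigned one of three chromatin classes:

``low``
    flat, near-baseline coverage for every mark;
``bivalent``
    high H3K4me3 and H3K27me3 over the CGI with H3K4me1 elevated over the
    CGI body (the trivalent/untypical-unimodal state);
``active``
    high H3K4me3 with the typical bimodal H3K4me1 — high shoulders at the
    shores, low body — and no H3K27me3.

In the second (perturbed) condition every bivalent promoter loses its
H3K27me3 plateau, and planted subsets of bivalent promoters additionally
lose (``biloss``) or gain (``bigain``) the shore H3K4me1 shoulder.
Coverage noise is per-basepair negative binomial around the deterministic
shape.  All outputs are byte-deterministic given the config seed.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import CLASSES, MARKS, SyntheticConfig
from .errors import ConfigError, SizingError
from .io import CoverageTrack, write_bed, write_chrom_sizes, write_tsv

logger = logging.getLogger(__name__)

# stable per-mark / per-condition stream indices for seed derivation
_MARK_INDEX = {m: i for i, m in enumerate(MARKS)}


@dataclass
class GenomeBundle:
    """A simulated genome plus its planted truth tables."""

    chrom_sizes: dict
    promoters: pd.DataFrame   # cgi_id, gene_id, chrom, start, end, tss, strand,
                              # class, transition, pattern_wt, pattern_ko
    enhancers: pd.DataFrame   # enhancer_id, gene_id, chrom, start, end
    genes: pd.DataFrame       # gene_id, class, transition, tissue_specific,
                              # target_tissue
    config: SyntheticConfig

    @property
    def tss_annotation(self) -> pd.DataFrame:
        p = self.promoters
        return pd.DataFrame(
            {
                "chrom": p["chrom"], "start": p["tss"], "end": p["tss"] + 1,
                "name": p["gene_id"], "score": 0, "strand": p["strand"],
            }
        )

    @property
    def cgi_bed(self) -> pd.DataFrame:
        p = self.promoters
        return pd.DataFrame(
            {"chrom": p["chrom"], "start": p["start"], "end": p["end"],
             "name": p["cgi_id"]}
        )

    @property
    def peak_bed(self) -> pd.DataFrame:
        """H3K4me1 peak calls: promoter-proximal regions plus enhancers.

        Proximal peaks exercise the > 5 kb distal filter downstream.
        """
        p = self.promoters
        prox = pd.DataFrame(
            {
                "chrom": p["chrom"],
                "start": p["start"] - self.config.flank,
                "end": p["end"] + self.config.flank,
                "name": "prox_" + p["cgi_id"],
            }
        )
        e = self.enhancers
        dist = pd.DataFrame(
            {"chrom": e["chrom"], "start": e["start"], "end": e["end"],
             "name": e["enhancer_id"]}
        )
        return pd.concat([prox, dist], ignore_index=True)

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_chrom_sizes(self.chrom_sizes, outdir / "chrom.sizes")
        write_bed(self.tss_annotation, outdir / "tss.bed")
        write_bed(self.cgi_bed, outdir / "cgis.bed")
        write_bed(self.peak_bed, outdir / "h3k4me1_peaks.bed")
        write_tsv(self.promoters, outdir / "truth_promoters.tsv")
        write_tsv(self.genes, outdir / "truth_genes.tsv")


def _allocate_counts(n: int, weights: dict, keys) -> dict:
    """Largest-remainder apportionment of n items over weighted keys."""
    raw = np.array([weights.get(k, 0.0) for k in keys], dtype=float) * n
    base = np.floor(raw).astype(int)
    rem = n - base.sum()
    order = np.argsort(-(raw - base), kind="stable")
    for i in order[:rem]:
        base[i] += 1
    return dict(zip(keys, base))


def make_genome(config: SyntheticConfig) -> GenomeBundle:
    """Lay out promoters, enhancers and planted labels on toy chromosomes."""
    slot = config.slot_length
    cap = config.capacity_per_chrom()
    if cap * config.n_chroms < config.n_promoters:
        need = -(-config.n_promoters // config.n_chroms) * slot + 2 * config.flank
        raise SizingError(
            f"cannot place {config.n_promoters} promoters on {config.n_chroms} "
            f"chromosome(s) of {config.chrom_length} bp (slot={slot} bp); "
            f"chrom_length must be at least {need} bp"
        )
    rng = np.random.default_rng([config.seed, 101])
    n = config.n_promoters
    lo, hi = config.cgi_length_range

    # class labels: exact counts, shuffled
    counts = _allocate_counts(n, config.class_proportions, CLASSES)
    classes = np.repeat(list(counts), list(counts.values()))
    rng.shuffle(classes)

    # transition labels within the bivalent class
    transition = np.full(n, "none", dtype=object)
    biv_idx = np.flatnonzero(classes == "bivalent")
    perm = rng.permutation(biv_idx)
    nb = round(config.transition_fractions.get("biloss", 0.0) * len(biv_idx))
    ng = round(config.transition_fractions.get("bigain", 0.0) * len(biv_idx))
    transition[perm[:nb]] = "biloss"
    transition[perm[nb: nb + ng]] = "bigain"

    chroms = [f"chr{i + 1}" for i in range(config.n_chroms)]
    sizes = {c: config.chrom_length for c in chroms}
    per_chrom = np.array_split(np.arange(n), config.n_chroms)

    lengths = rng.integers(lo, hi + 1, size=n)
    rows = []
    enh_rows = []
    maxL = hi
    for ci, idx in enumerate(per_chrom):
        for j, i in enumerate(idx):
            s = config.flank + j * slot
            L = int(lengths[i])
            start, end = s, s + L
            jitter = int(rng.integers(-(L // 4), L // 4 + 1))
            tss = start + L // 2 + jitter
            # enhancer midpoint 6 kb downstream of its own TSS: > 5 kb from
            # every TSS, and nearer its own TSS than any neighbour's, so
            # nearest-enhancer assignment recovers the planted pairing
            e_mid = tss + 6000
            e_start = e_mid - config.enhancer_length // 2
            rows.append(
                (f"cgi{i:06d}", f"g{i:06d}", chroms[ci], start, end, tss,
                 "+" if i % 2 == 0 else "-", classes[i], transition[i])
            )
            if config.place_enhancers:
                enh_rows.append(
                    (f"enh{i:06d}", f"g{i:06d}", chroms[ci], e_start,
                     e_start + config.enhancer_length)
                )
    promoters = pd.DataFrame(
        rows, columns=["cgi_id", "gene_id", "chrom", "start", "end", "tss",
                       "strand", "class", "transition"],
    )
    # planted H3K4me1 pattern per condition (body stays elevated for
    # bivalent promoters in both conditions)
    pattern = {"low": "flat", "bivalent": "untypical_unimodal",
               "active": "typical_bimodal"}
    promoters["pattern_wt"] = promoters["class"].map(pattern)
    promoters["pattern_ko"] = promoters["class"].map(pattern)
    enhancers = pd.DataFrame(
        enh_rows, columns=["enhancer_id", "gene_id", "chrom", "start", "end"]
    )

    genes = promoters[["gene_id", "class", "transition"]].copy()
    genes["tissue_specific"] = False
    genes["target_tissue"] = ""
    n_spec = config.n_tissues * config.n_specific_per_tissue
    if n_spec > len(genes):
        raise SizingError(
            f"{n_spec} tissue-specific genes requested but only "
            f"{len(genes)} genes exist"
        )
    # tissue-specific genes drawn from the bivalent class first (they are
    # the poised, tissue-restricted ones), topped up from others if needed
    rng_spec = np.random.default_rng([config.seed, 102])
    biv = genes.index[genes["class"] == "bivalent"].to_numpy()
    other = genes.index[genes["class"] != "bivalent"].to_numpy()
    pool = np.concatenate([rng_spec.permutation(biv), rng_spec.permutation(other)])
    chosen = pool[:n_spec]
    tissues = [f"tissue{t + 1}" for t in range(config.n_tissues)]
    genes.loc[chosen, "tissue_specific"] = True
    genes.loc[chosen, "target_tissue"] = np.repeat(
        tissues, config.n_specific_per_tissue
    )
    return GenomeBundle(
        chrom_sizes=sizes, promoters=promoters, enhancers=enhancers,
        genes=genes, config=config,
    )


# ---------------------------------------------------------------------------
# coverage tracks


def _shape_amplitudes(genome: GenomeBundle, mark: str, condition: str):
    """Per-promoter (body, shore) shape amplitudes for one mark/condition."""
    cfg = genome.config
    p = genome.promoters
    try:
        table = {c: cfg.shape_params[c][mark] for c in CLASSES}
    except KeyError as exc:
        raise ConfigError(
            [f"shape_params has no entry for mark {mark!r} (class {exc})"]
        )
    body = p["class"].map({c: table[c][0] for c in CLASSES}).to_numpy(float)
    shore = p["class"].map({c: table[c][1] for c in CLASSES}).to_numpy(float)

    is_ko = condition == cfg.conditions[1]
    biv = (p["class"] == "bivalent").to_numpy()
    if mark == "H3K4me1":
        # bivalent shore shoulders: biloss promoters start high and drop in
        # the perturbed condition, bigain promoters start low and rise
        hi_amp, lo_amp = cfg.transition_shore
        tr = p["transition"].to_numpy()
        high_group = "bigain" if is_ko else "biloss"
        shore = np.where(biv, np.where(tr == high_group, hi_amp, lo_amp), shore)
    if mark == "H3K27me3" and is_ko:
        # the planted perturbation: PRC2 loss abolishes H3K27me3
        body = np.where(biv, cfg.baseline, body)
        shore = np.where(biv, cfg.baseline, shore)
    return body, shore


def _enhancer_amplitude(genome: GenomeBundle, mark: str, condition: str) -> np.ndarray:
    cfg = genome.config
    amps = cfg.enhancer_amps.get(mark)
    if amps is None:
        return np.array([])
    base, induced = amps
    spec = genome.genes.set_index("gene_id")["tissue_specific"]
    flags = spec.reindex(genome.enhancers["gene_id"]).fillna(False).to_numpy(bool)
    cond_idx = list(cfg.conditions).index(condition)
    if cond_idx == 1:
        amp = np.where(flags, induced, base).astype(float)
    else:
        amp = np.full(len(flags), base, dtype=float)
    if cfg.enhancer_amp_sd > 0:
        rng = np.random.default_rng(
            [cfg.seed, 9, _MARK_INDEX.get(mark, 99), cond_idx]
        )
        amp = np.maximum(amp + rng.normal(0.0, cfg.enhancer_amp_sd, amp.shape), 0.1)
    return amp


def simulate_track(genome: GenomeBundle, mark: str, condition: str) -> CoverageTrack:
    """Simulate one coverage track (deterministic shape + NB noise).

    The shape is ``baseline`` genome-wide, a flat plateau at the body
    amplitude over each CGI, Gaussian shoulders peaking mid-shore (500 bp
    from the CGI edge, sd ``shore_sigma``), and plateaus over enhancer
    intervals for enhancer marks.  Noise is per-basepair
    NB(mean = shape * mean_scale, size = dispersion); the noiseless limit
    (``dispersion=None``) returns the shape exactly.
    """
    cfg = genome.config
    if condition not in cfg.conditions:
        raise ConfigError([f"unknown condition {condition!r}; have {cfg.conditions}"])
    body_amp, shore_amp = _shape_amplitudes(genome, mark, condition)
    enh_amp = _enhancer_amplitude(genome, mark, condition)

    track = CoverageTrack(
        {c: np.full(nbp, cfg.baseline, dtype=np.float32)
         for c, nbp in genome.chrom_sizes.items()}
    )
    flank, sigma = cfg.flank, cfg.shore_sigma
    d = np.arange(1, flank + 1, dtype=np.float64)
    left_kernel = np.exp(-((d[::-1] - 500.0) ** 2) / (2 * sigma ** 2))
    right_kernel = np.exp(-((d - 500.0) ** 2) / (2 * sigma ** 2))

    p = genome.promoters
    for i, (chrom, start, end) in enumerate(zip(p["chrom"], p["start"], p["end"])):
        arr = track.values[chrom]
        b = cfg.baseline
        arr[start:end] = body_amp[i]
        arr[start - flank: start] = b + (shore_amp[i] - b) * left_kernel
        arr[end: end + flank] = b + (shore_amp[i] - b) * right_kernel
    if enh_amp.size:
        e = genome.enhancers
        for j, (chrom, start, end) in enumerate(zip(e["chrom"], e["start"], e["end"])):
            track.values[chrom][start:end] = enh_amp[j]

    if cfg.noise.dispersion is None:
        return track
    r = float(cfg.noise.dispersion)
    scale = float(cfg.noise.mean_scale)
    cond_idx = list(cfg.conditions).index(condition)
    rng = np.random.default_rng(
        [cfg.seed, 7, _MARK_INDEX.get(mark, hash(mark) % 1000), cond_idx]
    )
    for chrom, arr in track.values.items():
        mu = arr.astype(np.float64) * scale
        prob = r / (r + mu)
        draws = rng.negative_binomial(r, prob)
        track.values[chrom] = (draws / scale).astype(np.float32)
    return track


def make_tracks(genome: GenomeBundle, marks=None, conditions=None) -> dict:
    """Simulate tracks for each requested (mark, condition) pair.

    Returns ``{(mark, condition): CoverageTrack}``.  Large pipelines should
    prefer :func:`simulate_track` one at a time to bound memory.
    """
    marks = tuple(marks or MARKS)
    conditions = tuple(conditions or genome.config.conditions)
    return {
        (m, c): simulate_track(genome, m, c) for m in marks for c in conditions
    }


# ---------------------------------------------------------------------------
# expression and DE tables


def make_expression(genome: GenomeBundle) -> pd.DataFrame:
    """Gene-by-tissue median expression with planted tissue-specific genes.

    Noiseless construction: every gene of a class shares that class's
    constant level in every tissue; planted specific genes get
    ``specific_high`` in the target tissue and ``specific_off`` elsewhere,
    guaranteeing both the top-5 tissue rank and the within-tissue > 90th
    percentile criterion.  ``expression_noise_sd`` > 0 multiplies every cell
    by log-normal noise, so the criteria hold in expectation instead.
    """
    cfg = genome.config
    genes = genome.genes
    tissues = [f"tissue{t + 1}" for t in range(cfg.n_tissues)]
    base = genes["class"].map(cfg.expression_levels).to_numpy(float)
    mat = np.tile(base[:, None], (1, cfg.n_tissues))
    spec = genes["tissue_specific"].to_numpy(bool)
    # bivalent background genes: poised, expressed in a few tissues only
    k = min(cfg.n_expressed_tissues_bivalent, cfg.n_tissues)
    if k < cfg.n_tissues:
        rng_biv = np.random.default_rng([cfg.seed, 105])
        biv_bg = np.flatnonzero((genes["class"] == "bivalent").to_numpy() & ~spec)
        for i in biv_bg:
            off = rng_biv.choice(cfg.n_tissues, size=cfg.n_tissues - k, replace=False)
            mat[i, off] = cfg.specific_off
    mat[spec, :] = cfg.specific_off
    for t, tissue in enumerate(tissues):
        hit = spec & (genes["target_tissue"] == tissue).to_numpy()
        mat[hit, t] = cfg.specific_high
    if cfg.expression_noise_sd > 0:
        rng = np.random.default_rng([cfg.seed, 103])
        mat = mat * np.exp2(rng.normal(0.0, cfg.expression_noise_sd, mat.shape))
    return pd.DataFrame(mat, index=pd.Index(genes["gene_id"], name="gene"),
                        columns=tissues)


def make_de_table(genome: GenomeBundle) -> pd.DataFrame:
    """KO-vs-WT differential-expression table with planted group effects.

    log2 fold changes are drawn per transition group from the configured
    normal effects; transition-group genes get the configured small p-value,
    others a uniform null p-value.  Returns ``gene, log2FoldChange, pvalue,
    de_status`` where ``de_status`` in {up, down, ns} evaluates the drawn
    values at the config thresholds (truth column; drop it to get a plain
    DE input table).
    """
    cfg = genome.config
    genes = genome.genes
    rng = np.random.default_rng([cfg.seed, 104])
    lfc = np.empty(len(genes))
    pval = np.empty(len(genes))
    tr = genes["transition"].to_numpy()
    for group, (mu, sd) in cfg.de_effects.items():
        m = tr == group
        lfc[m] = rng.normal(mu, sd, m.sum())
        if group in ("biloss", "bigain"):
            pval[m] = cfg.de_p_transition
        else:
            pval[m] = rng.uniform(0.05, 1.0, m.sum())
    status = np.where(
        (np.abs(lfc) >= cfg.de_lfc_cut) & (pval <= cfg.de_p_cut),
        np.where(lfc > 0, "up", "down"), "ns",
    )
    return pd.DataFrame(
        {"gene": genes["gene_id"], "log2FoldChange": lfc, "pvalue": pval,
         "de_status": status}
    )


def simulate_all(config: SyntheticConfig, outdir=None) -> dict:
    """Generate genome, all tracks, expression and DE table; optionally write.

    Convenience wrapper used by the CLI ``simulate`` command; returns a dict
    with keys ``genome``, ``tracks``, ``expression``, ``de_table``.
    """
    genome = make_genome(config)
    tracks = make_tracks(genome)
    expression = make_expression(genome)
    de = make_de_table(genome)
    if outdir is not None:
        outdir = Path(outdir)
        genome.write(outdir)
        for (mark, cond), tr in tracks.items():
            tr.to_bedgraph(outdir / f"{mark}_{cond}.bedgraph")
        write_tsv(expression.reset_index(), outdir / "expression.tsv")
        write_tsv(de, outdir / "de_KO_vs_WT.tsv")
    return {"genome": genome, "tracks": tracks, "expression": expression,
            "de_table": de}
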