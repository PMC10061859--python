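"""End-to-end orchestration: simulate/load → promoters → matrices →
partition (+overlap) → patterns → transitions → expression → regression.

Every stage persists its outputs as TSV/JSON under the run's output
directory, and the machine-readable run report collects per-stage summary
statistics.  Runs are deterministic under the configured seed (byte-stable
TSV outputs).
"""
from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association, expression, intervals, partition, patterns, signal
from .config import SyntheticConfig
from .errors import ConfigError, TrivalentError
from .io import (
    read_bed, read_chrom_sizes, read_de_table, read_expression_matrix,
    read_track, write_tsv,
)
from .synthetic import (
    GenomeBundle, make_de_table, make_expression, make_genome, simulate_track,
)

logger = logging.getLogger(__name__)

PROMOTER_MARKS = ("H3K4me1", "H3K4me3", "H3K27me3")
ENHANCER_MARKS = ("H3K4me1", "H3K27ac")

DEFAULT_PARAMS = {
    "n_flank": 20,
    "n_body": 20,
    "flank": 1000,
    "k": 3,
    "winsor_pct": 99.0,
    "loss_threshold": None,   # None -> half the bivalent median body H3K27me3
    "lfc_cut": 1.2,
    "p_cut": 0.1,
    "focal_tissue": None,     # None -> first tissue column
    "pattern_seed": 0,
}


@dataclass
class RunConfig:
    """Validated pipeline configuration (YAML-friendly)."""

    outdir: str = "trivalent_out"
    seed: int = 0
    simulate: dict | None = None
    inputs: dict | None = None
    params: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def validate_config(config: RunConfig) -> RunConfig:
    """Fill defaults and reject contradictions, reporting all errors at once."""
    errs = []
    params = dict(DEFAULT_PARAMS)
    unknown = set(config.params) - set(DEFAULT_PARAMS)
    if unknown:
        errs.append(f"unknown params: {sorted(unknown)}")
    params.update({k: v for k, v in config.params.items() if k in DEFAULT_PARAMS})
    if params["k"] < 2:
        errs.append("k must be >= 2 (partitioning needs at least two clusters)")
    if params["flank"] <= 0:
        errs.append("flank must be positive")
    if params["n_flank"] < 1 or params["n_body"] < 1:
        errs.append("n_flank and n_body must be >= 1")
    if params["lfc_cut"] <= 0 or not (0 < params["p_cut"] <= 1):
        errs.append("DE thresholds must be positive (p_cut in (0, 1])")
    if config.simulate is None and config.inputs is None:
        errs.append("either a 'simulate' block or an 'inputs' block is required")
    if config.simulate is not None and config.inputs is not None:
        errs.append("'simulate' and 'inputs' blocks are mutually exclusive")
    syn = None
    if config.simulate is not None:
        sim = dict(config.simulate)
        sim.setdefault("seed", config.seed)
        if sim.get("flank", params["flank"]) != params["flank"]:
            errs.append("simulate.flank must equal params.flank")
        try:
            syn = SyntheticConfig.from_dict(sim)
        except ConfigError as exc:
            errs.extend(exc.errors)
    if config.inputs is not None:
        required = {"chrom_sizes", "cgis", "tss", "tracks", "conditions"}
        missing = required - set(config.inputs)
        if missing:
            errs.append(f"inputs block missing keys: {sorted(missing)}")
        else:
            for mark in PROMOTER_MARKS:
                if mark not in config.inputs["tracks"]:
                    errs.append(f"inputs.tracks missing mark {mark}")
    if errs:
        raise ConfigError(errs)
    out = RunConfig(
        outdir=config.outdir, seed=config.seed,
        simulate=syn.to_dict() if syn is not None else None,
        inputs=config.inputs, params=params,
    )
    return out


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(
        {"seed": config.seed, "simulate": config.simulate,
         "inputs": config.inputs, "params": config.params},
        sort_keys=True, default=str,
    )
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _enhancer_means(track, enhancers: pd.DataFrame) -> pd.Series:
    vals = np.empty(len(enhancers))
    for i, (chrom, s, e) in enumerate(
        zip(enhancers["chrom"], enhancers["start"], enhancers["end"])
    ):
        arr = track.get(str(chrom))
        vals[i] = max(float(arr[s:e].mean()), 0.0) if arr is not None else 0.0
    return pd.Series(vals, index=pd.Index(enhancers["gene_id"], name="gene_id"))


def run_all(config: RunConfig) -> dict:
    """Execute every stage; returns the run report (also written to disk)."""
    config = validate_config(config)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = {"config_hash": _config_hash(config), "seed": config.seed,
              "params": config.params, "stages": {}}
    t0 = time.time()
    stage = "simulate"
    try:
        bundle = _stage_inputs(config, outdir, report)
        stage = "promoters"
        promoters, enhancers = _stage_promoters(bundle, outdir, report)
        stage = "matrices"
        prom_mats, enh_signal = _stage_matrices(
            config, bundle, promoters, enhancers, outdir, report
        )
        stage = "partition"
        assign, overlap = _stage_partition(config, prom_mats, outdir, report)
        stage = "patterns"
        calls = _stage_patterns(config, prom_mats, outdir, report)
        stage = "transitions"
        trans = _stage_transitions(
            config, calls, prom_mats, assign, promoters, outdir, report
        )
        stage = "contrast"
        _stage_contrast(config, trans, promoters, bundle, outdir, report)
        stage = "expression"
        spec_sets = _stage_expression(bundle, outdir, report)
        stage = "regress"
        _stage_regress(
            config, bundle, spec_sets, prom_mats, enh_signal, promoters,
            outdir, report,
        )
    except TrivalentError as exc:
        report["failed_stage"] = stage
        report["error"] = str(exc)
        _write_report(report, outdir, t0)
        raise TrivalentError(f"stage {stage!r} failed: {exc}") from exc
    _write_report(report, outdir, t0)
    if config.simulate is not None:
        _truth_comparison(report, outdir)
    _write_report(report, outdir, t0)
    return report


def _write_report(report: dict, outdir: Path, t0: float) -> None:
    report["wall_time_s"] = round(time.time() - t0, 3)
    with open(outdir / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=str)
    # summary without wall time, for byte-stability checks
    stable = {k: v for k, v in report.items() if k != "wall_time_s"}
    with open(outdir / "run_summary.json", "w") as fh:
        json.dump(stable, fh, indent=2, sort_keys=True, default=str)


# ---------------------------------------------------------------------------
# stages


@dataclass
class _Inputs:
    chrom_sizes: dict
    cgis: pd.DataFrame
    tss: pd.DataFrame
    peaks: pd.DataFrame | None
    expression: pd.DataFrame | None
    de_table: pd.DataFrame | None
    conditions: tuple
    genome: GenomeBundle | None = None   # set in simulate mode

    def track(self, mark: str, condition: str):
        raise NotImplementedError


class _SimulatedInputs(_Inputs):
    def track(self, mark, condition):
        return simulate_track(self.genome, mark, condition)


class _FileInputs(_Inputs):
    def __init__(self, paths: dict, **kw):
        super().__init__(**kw)
        self._paths = paths

    def track(self, mark, condition):
        entry = self._paths["tracks"].get(mark, {})
        path = entry.get(condition)
        if path is None:
            raise ConfigError([f"no track file for {mark}/{condition}"])
        return read_track(path, self.chrom_sizes)


def _stage_inputs(config: RunConfig, outdir: Path, report: dict) -> _Inputs:
    if config.simulate is not None:
        syn = SyntheticConfig.from_dict(config.simulate)
        genome = make_genome(syn)
        genome.write(outdir / "simulated")
        expr = make_expression(genome)
        de = make_de_table(genome)
        write_tsv(expr.reset_index(), outdir / "simulated" / "expression.tsv")
        write_tsv(de, outdir / "simulated" / "de_KO_vs_WT.tsv")
        report["stages"]["simulate"] = {
            "n_promoters": len(genome.promoters),
            "n_genes": len(genome.genes),
            "class_counts": genome.promoters["class"].value_counts().to_dict(),
            "transition_counts": genome.promoters["transition"].value_counts().to_dict(),
        }
        return _SimulatedInputs(
            chrom_sizes=genome.chrom_sizes, cgis=genome.cgi_bed,
            tss=genome.tss_annotation, peaks=genome.peak_bed,
            expression=expr, de_table=de.drop(columns="de_status"),
            conditions=syn.conditions, genome=genome,
        )
    paths = config.inputs
    sizes = read_chrom_sizes(paths["chrom_sizes"])
    inputs = _FileInputs(
        paths,
        chrom_sizes=sizes,
        cgis=read_bed(paths["cgis"]),
        tss=read_bed(paths["tss"]),
        peaks=read_bed(paths["peaks"]) if paths.get("peaks") else None,
        expression=(
            read_expression_matrix(paths["expression"])
            if paths.get("expression") else None
        ),
        de_table=read_de_table(paths["de_table"]) if paths.get("de_table") else None,
        conditions=tuple(paths["conditions"]),
    )
    report["stages"]["inputs"] = {
        "n_cgis": len(inputs.cgis), "n_tss": len(inputs.tss),
        "conditions": list(inputs.conditions),
    }
    return inputs


def _stage_promoters(bundle: _Inputs, outdir: Path, report: dict):
    promoters = intervals.define_promoter_cgis(bundle.cgis, bundle.tss)
    write_tsv(promoters, outdir / "promoter_cgis.tsv")
    enhancers = None
    if bundle.peaks is not None:
        enhancers = intervals.define_enhancers(bundle.peaks, bundle.tss)
        write_tsv(enhancers, outdir / "enhancer_assignments.tsv")
    report["stages"]["promoters"] = {
        "n_promoter_cgis": len(promoters),
        "n_enhancer_assignments": len(enhancers) if enhancers is not None else 0,
    }
    return promoters, enhancers


def _stage_matrices(config, bundle, promoters, enhancers, outdir, report):
    p = config.params
    prom_mats = {}
    enh_signal = {}
    for mark in ("H3K4me1", "H3K4me3", "H3K27me3", "H3K27ac"):
        for cond in bundle.conditions:
            track = bundle.track(mark, cond)
            if mark in PROMOTER_MARKS:
                mat = signal.bin_signal(
                    track, promoters, n_flank=p["n_flank"], n_body=p["n_body"],
                    flank=p["flank"], mark=mark, condition=cond,
                )
                prom_mats[(mark, cond)] = mat
                mat.to_tsv(outdir / f"matrix_{mark}_{cond}.tsv")
            if mark in ENHANCER_MARKS and enhancers is not None:
                enh_signal[(mark, cond)] = _enhancer_means(track, enhancers)
            del track
    report["stages"]["matrices"] = {
        "n_rows": len(promoters),
        "n_columns": 2 * p["n_flank"] + p["n_body"],
        "promoter_matrices": [f"{m}/{c}" for m, c in prom_mats],
    }
    return prom_mats, enh_signal


def _stage_partition(config, prom_mats, outdir, report):
    p = config.params
    cond1 = next(c for m, c in prom_mats if m == "H3K4me3")
    mats1 = {m: prom_mats[(m, cond1)] for m in PROMOTER_MARKS}
    assign = partition.kmeans_partition(
        mats1, k=p["k"], seed=config.seed, winsor_pct=p["winsor_pct"]
    )
    assign = partition.label_cluster_roles(assign, mats1)
    write_tsv(assign.to_frame().reset_index(), outdir / "partition_trivalent.tsv")

    # traditional bivalent definition: H3K4me3 + H3K27me3 only
    trad = partition.kmeans_partition(
        {m: mats1[m] for m in ("H3K4me3", "H3K27me3")},
        k=p["k"], seed=config.seed, winsor_pct=p["winsor_pct"],
    )
    trad = partition.label_cluster_roles(trad, mats1)
    write_tsv(trad.to_frame().reset_index(), outdir / "partition_traditional.tsv")
    overlap = partition.overlap_comparison(assign, trad)
    with open(outdir / "overlap_report.json", "w") as fh:
        json.dump(overlap.to_dict(), fh, indent=2, sort_keys=True, default=str)
    report["stages"]["partition"] = {
        "condition": cond1,
        "cluster_sizes": assign.role_series().value_counts().to_dict(),
        "bivalent_overlap_pct_of_trivalent": overlap.directional.loc[
            "bivalent", "pct_of_A"
        ],
        "bivalent_overlap_pct_of_traditional": overlap.directional.loc[
            "bivalent", "pct_of_B"
        ],
    }
    return assign, overlap


def _stage_patterns(config, prom_mats, outdir, report):
    calls = {}
    stats = {}
    conditions = [c for (m, c) in prom_mats if m == "H3K4me1"]
    for cond in conditions:
        df = patterns.classify_pattern(
            prom_mats[("H3K4me1", cond)], seed=config.params["pattern_seed"]
        )
        calls[cond] = df
        write_tsv(df.reset_index(), outdir / f"patterns_{cond}.tsv")
        stats[cond] = df["pattern"].value_counts().to_dict()
    report["stages"]["patterns"] = stats
    return calls


def _stage_transitions(config, calls, prom_mats, assign, promoters, outdir, report):
    c1, c2 = list(calls)
    thr = config.params["loss_threshold"]
    if thr is None:
        thr = patterns.default_loss_threshold(
            prom_mats[("H3K27me3", c1)], assign.members("bivalent")
        )
    trans = patterns.call_transitions(
        calls[c1], calls[c2],
        (prom_mats[("H3K27me3", c1)], prom_mats[("H3K27me3", c2)]),
        loss_threshold=thr,
        k4me1_matrices=(prom_mats[("H3K4me1", c1)], prom_mats[("H3K4me1", c2)]),
    )
    gene_map = promoters.set_index("cgi_id")["gene_id"]
    out = trans.copy()
    out.insert(0, "gene_id", gene_map.reindex(out.index))
    write_tsv(out.reset_index(), outdir / "transitions.tsv")
    report["stages"]["transitions"] = {
        "loss_threshold": float(thr),
        "n_k27_loss": int(trans["k27_loss"].sum()),
        "group_counts": trans["group"].value_counts().to_dict(),
        "n_transition": int(trans["transition"].sum()),
    }
    return trans


def _stage_contrast(config, trans, promoters, bundle, outdir, report):
    if bundle.de_table is None:
        report["stages"]["contrast"] = {"skipped": "no DE table supplied"}
        return
    gene_map = promoters.set_index("cgi_id")["gene_id"]
    contrast = patterns.group_expression_contrast(
        trans, gene_map, bundle.de_table,
        lfc_cut=config.params["lfc_cut"], p_cut=config.params["p_cut"],
    )
    with open(outdir / "group_contrast.json", "w") as fh:
        json.dump(contrast, fh, indent=2, sort_keys=True, default=str)
    report["stages"]["contrast"] = {
        "wilcoxon_p": contrast["wilcoxon_p"],
        "chi2_stat": contrast["chi2_stat"],
        "lower_median_group": contrast["lower_median_group"],
        "n_biloss": contrast["groups"]["biloss"]["n"],
        "n_bigain": contrast["groups"]["bigain"]["n"],
    }


def _stage_expression(bundle, outdir, report):
    if bundle.expression is None:
        report["stages"]["expression"] = {"skipped": "no expression matrix"}
        return None
    taus = expression.tau_table(bundle.expression)
    write_tsv(taus.reset_index().rename(columns={"index": "gene"}),
              outdir / "tau.tsv")
    spec_sets = expression.select_tissue_specific(bundle.expression)
    rows = [
        {"tissue": t, "gene": g} for t, genes in spec_sets.items()
        for g in sorted(genes)
    ]
    write_tsv(pd.DataFrame(rows, columns=["tissue", "gene"]),
              outdir / "tissue_specific.tsv")
    report["stages"]["expression"] = {
        "median_tau": float(taus.median()),
        "n_specific_per_tissue": {t: len(g) for t, g in spec_sets.items()},
    }
    return spec_sets


def _stage_regress(config, bundle, spec_sets, prom_mats, enh_signal,
                   promoters, outdir, report):
    if spec_sets is None or not enh_signal:
        report["stages"]["regress"] = {"skipped": "needs expression and enhancers"}
        return
    focal = config.params["focal_tissue"] or sorted(spec_sets)[0]
    gene_map = promoters.set_index("cgi_id")["gene_id"]
    c1, c2 = bundle.conditions
    prom_signal = {}
    for mark in PROMOTER_MARKS:
        for cond in (c1, c2):
            s = signal.summarize_region(prom_mats[(mark, cond)], "body")
            s.index = gene_map.reindex(s.index)
            prom_signal[(mark, cond)] = s
    design, scaling = association.build_design(
        focal, spec_sets, prom_signal, enh_signal, conditions=(c1, c2)
    )
    write_tsv(design.reset_index(), outdir / f"design_{focal}.tsv")
    fit = association.fit_logistic(design, scaling=scaling)
    write_tsv(fit.table.reset_index().rename(columns={"index": "predictor"}),
              outdir / f"logistic_{focal}.tsv")
    with open(outdir / f"logistic_{focal}.json", "w") as fh:
        json.dump(fit.to_dict(), fh, indent=2, sort_keys=True, default=str)
    report["stages"]["regress"] = {
        "focal_tissue": focal,
        "n": fit.n,
        "n_positive": int(design["outcome"].sum()),
        "converged": fit.converged,
        "odds_ratios": fit.table["odds_ratio"].round(4).to_dict(),
    }


def _truth_comparison(report: dict, outdir: Path) -> None:
    """Compare pipeline calls to the planted truth (simulate mode only)."""
    from sklearn.metrics import adjusted_rand_score

    truth = pd.read_csv(outdir / "simulated" / "truth_promoters.tsv", sep="\t")
    truth = truth.set_index("cgi_id")
    part = pd.read_csv(outdir / "partition_trivalent.tsv", sep="\t").set_index("cgi_id")
    ari = adjusted_rand_score(
        truth.loc[part.index, "class"], part["role"]
    )
    role_acc = float((truth.loc[part.index, "class"] == part["role"]).mean())
    pats = {}
    conds = list(report["stages"].get("patterns", {}))
    for cond, col in zip(conds, ("pattern_wt", "pattern_ko")):
        path = outdir / f"patterns_{cond}.tsv"
        if path.exists():
            called = pd.read_csv(path, sep="\t").set_index("cgi_id")
            pats[cond] = float(
                (called["pattern"] == truth.loc[called.index, col]).mean()
            )
    trans = pd.read_csv(outdir / "transitions.tsv", sep="\t").set_index("cgi_id")
    pr = {}
    for grp in ("biloss", "bigain"):
        called = set(trans.index[trans["group"] == grp])
        planted = set(truth.index[truth["transition"] == grp])
        tp = len(called & planted)
        pr[grp] = {
            "precision": tp / len(called) if called else float("nan"),
            "recall": tp / len(planted) if planted else float("nan"),
            "n_called": len(called), "n_planted": len(planted),
        }
    report["truth_comparison"] = {
        "partition_ari": float(ari),
        "partition_role_accuracy": role_acc,
        "pattern_accuracy": pats,
        "transition": pr,
    }
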