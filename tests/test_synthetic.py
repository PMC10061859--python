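"""Generator behaviour: determinism, geometry, planted signal and expression."""
import numpy as np
import pandas as pd
import pytest

import trivalent as tv
from trivalent.config import SyntheticConfig
from trivalent.errors import ConfigError, SizingError


def test_seed_determinism_byte_identical(tmp_path):
    """Same config + seed twice -> byte-identical BED/TSV/bedGraph outputs."""
    cfg = dict(n_promoters=30, n_chroms=1, chrom_length=450_000, seed=7,
               n_specific_per_tissue=2)
    for d in ("a", "b"):
        g = tv.make_genome(SyntheticConfig(**cfg))
        g.write(tmp_path / d)
        tv.simulate_track(g, "H3K4me1", "WT").to_bedgraph(tmp_path / d / "t.bedgraph")
    for name in ("cgis.bed", "tss.bed", "truth_promoters.tsv", "t.bedgraph"):
        assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()


def test_cgi_length_range_below_200_rejected():
    with pytest.raises(ConfigError, match="cgi_length_range"):
        SyntheticConfig(cgi_length_range=(150, 400))


def test_every_cgi_overlaps_its_tss_window(small_genome):
    """Brute-force geometric check on the emitted intervals."""
    p = small_genome.promoters
    assert len(p) == 60
    lengths = p["end"] - p["start"]
    assert ((lengths >= 200) & (lengths <= 5000)).all()
    # >= 1 bp overlap with [tss-1000, tss+1000)
    assert ((p["start"] < p["tss"] + 1000) & (p["end"] > p["tss"] - 1000)).all()
    # promoter windows (CGI + shores) must not collide
    for chrom, sub in p.groupby("chrom"):
        sub = sub.sort_values("start")
        assert (sub["start"].to_numpy()[1:] - 1000
                >= sub["end"].to_numpy()[:-1] + 1000).all()


def test_infeasible_packing_names_required_length():
    with pytest.raises(SizingError, match="at least"):
        tv.make_genome(SyntheticConfig(n_promoters=1000, n_chroms=1,
                                       chrom_length=500_000))


def test_truth_label_invariants(small_genome):
    p = small_genome.promoters
    assert set(p.loc[p["transition"] != "none", "class"]) == {"bivalent"}
    g = small_genome.genes
    spec = g[g["tissue_specific"]]
    assert (spec["target_tissue"] != "").all()
    assert spec["gene_id"].is_unique


class TestTracks:
    def test_noiseless_center_equals_amplitude(self, noiseless_genome):
        """Zero-noise limit: CGI-center coverage equals the configured body amp."""
        g = noiseless_genome
        track = tv.simulate_track(g, "H3K4me3", "WT")
        active = g.promoters[g.promoters["class"] == "active"].iloc[0]
        center = (active["start"] + active["end"]) // 2
        amp = g.config.shape_params["active"]["H3K4me3"][0]
        assert track.get(active["chrom"])[center] == pytest.approx(amp, abs=1e-6)

    def test_unknown_mark_is_configuration_error(self, small_genome):
        with pytest.raises(ConfigError):
            tv.simulate_track(small_genome, "H3K9me3", "WT")
        with pytest.raises(ConfigError):
            tv.simulate_track(small_genome, "H3K4me1", "nonesuch")

    def test_bivalent_ko_h3k27me3_drops_to_baseline(self):
        """Monte-Carlo: mean KO H3K27me3 over bivalent CGIs ~ baseline."""
        cfg = SyntheticConfig(
            n_promoters=500, n_chroms=1, chrom_length=2_000_000,
            class_proportions={"low": 0.0, "bivalent": 1.0, "active": 0.0},
            place_enhancers=False, seed=13,
        )
        g = tv.make_genome(cfg)
        track = tv.simulate_track(g, "H3K27me3", "KO")
        mat = tv.bin_signal(track, g.promoters)
        body = tv.summarize_region(mat, "body")
        se = body.std() / np.sqrt(len(body))
        assert body.mean() <= cfg.baseline + 3 * se

    def test_nb_noise_mean_matches_constant_amplitude(self):
        """Law of large numbers: empirical mean within 2% of the flat mean."""
        c = 4.0
        amps = {cls: {m: (c, c) for m in tv.MARKS} for cls in tv.CLASSES}
        cfg = SyntheticConfig(
            n_promoters=20, n_chroms=1, chrom_length=1_100_000,
            baseline=c, shape_params=amps, transition_shore=(c, c),
            place_enhancers=False, enhancer_amp_sd=0.0, seed=2,
            n_tissues=2, n_specific_per_tissue=2,
        )
        g = tv.make_genome(cfg)
        track = tv.simulate_track(g, "H3K4me3", "WT")
        arr = track.get("chr1")[:1_000_000]
        assert arr.mean() == pytest.approx(c, rel=0.02)

    def test_transition_shore_deltas_identify_biloss(self, noiseless_genome):
        """Noiseless: negative shore-H3K4me1 delta set == planted biloss set."""
        g = noiseless_genome
        mats = {
            c: tv.bin_signal(tv.simulate_track(g, "H3K4me1", c), g.promoters)
            for c in ("WT", "KO")
        }
        delta = tv.summarize_region(mats["KO"], "shores") - tv.summarize_region(
            mats["WT"], "shores"
        )
        negative = set(delta.index[delta < -1e-9])
        planted = set(g.promoters.loc[g.promoters["transition"] == "biloss", "cgi_id"])
        assert negative == planted


class TestExpression:
    def test_planted_specific_genes_rank_first(self, noiseless_genome):
        expr = tv.make_expression(noiseless_genome)
        truth = noiseless_genome.genes.set_index("gene_id")
        for gene, row in truth[truth["tissue_specific"]].iterrows():
            t = row["target_tissue"]
            assert expr.loc[gene].idxmax() == t
            assert (expr[t] >= expr.loc[gene, t]).sum() <= 5  # top-5 by construction

    def test_single_tissue_gene_has_tau_one(self, noiseless_genome):
        expr = tv.make_expression(noiseless_genome)
        gene = noiseless_genome.genes.query("tissue_specific").iloc[0]["gene_id"]
        vec = expr.loc[gene].copy()
        vec[vec < vec.max()] = 0.0
        assert tv.tau(vec.to_numpy()) == pytest.approx(1.0)

    def test_planted_downregulation_survives_de_filter(self):
        """Biloss genes given log2FC = -2, p = 1e-6 pass the 1.2 / 0.1 cut."""
        cfg = SyntheticConfig(
            n_promoters=60, n_chroms=1, chrom_length=900_000, seed=1,
            n_specific_per_tissue=3,
            de_effects={"biloss": (-2.0, 0.0), "bigain": (2.0, 0.0),
                        "none": (0.0, 0.0)},
        )
        g = tv.make_genome(cfg)
        de = tv.make_de_table(g)
        sets = tv.filter_de(de, lfc_cut=1.2, p_cut=0.1)
        biloss_genes = set(g.genes.loc[g.genes["transition"] == "biloss", "gene_id"])
        assert biloss_genes <= sets["down"]
        assert not (biloss_genes & sets["up"])

    def test_sizing_error_when_too_many_specific_genes(self):
        with pytest.raises(SizingError):
            tv.make_genome(
                SyntheticConfig(n_promoters=20, n_chroms=1, chrom_length=400_000,
                                n_tissues=6, n_specific_per_tissue=10)
            )

    def test_expression_deterministic_under_seed(self, small_config):
        g1 = tv.make_genome(small_config)
        g2 = tv.make_genome(small_config)
        pd.testing.assert_frame_equal(tv.make_expression(g1), tv.make_expression(g2))
        pd.testing.assert_frame_equal(tv.make_de_table(g1), tv.make_de_table(g2))
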