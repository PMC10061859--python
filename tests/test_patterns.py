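"""H3K4me1 pattern calls, transition calling and group expression contrasts."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

import trivalent as tv
from trivalent.errors import DegenerateDataError, SchemaError


@pytest.fixture(scope="module")
def k4_wt(noiseless_matrices):
    return noiseless_matrices[("H3K4me1", "WT")]


@pytest.fixture(scope="module")
def noiseless_calls(noiseless_matrices):
    return {c: tv.classify_pattern(noiseless_matrices[("H3K4me1", c)], seed=0)
            for c in ("WT", "KO")}


class TestClassifyPattern:
    def test_planted_classes_map_to_expected_patterns(self, noiseless_calls,
                                                      noiseless_genome):
        truth = noiseless_genome.promoters.set_index("cgi_id")
        calls = noiseless_calls["WT"]
        expected = {"active": "typical_bimodal", "bivalent": "untypical_unimodal",
                    "low": "flat"}
        for cls, pat in expected.items():
            ids = truth.index[truth["class"] == cls]
            assert (calls.loc[ids, "pattern"] == pat).all()

    def test_body_dominates_shore_in_mapping(self, k4_wt):
        """A body-high row is unimodal regardless of its shores."""
        calls = tv.classify_pattern(k4_wt, seed=0)
        high_body = calls[calls["body_level"] == "high"]
        assert (high_body["pattern"] == "untypical_unimodal").all()

    def test_scale_invariance(self, k4_wt):
        scaled = k4_wt.copy_with(k4_wt.values * 7.3)
        a = tv.classify_pattern(k4_wt, seed=0)
        b = tv.classify_pattern(scaled, seed=0)
        assert (a["pattern"] == b["pattern"]).all()

    def test_constant_matrix_is_degenerate(self):
        vals = pd.DataFrame(np.ones((10, 12)),
                            index=pd.Index([f"c{i}" for i in range(10)], name="cgi_id"))
        vals.columns = [f"b{i}" for i in range(12)]
        mat = tv.SignalMatrix(values=vals, n_flank=4, n_body=4, flank_bp=200,
                              body_bp=pd.Series(400, index=vals.index))
        with pytest.raises(DegenerateDataError):
            tv.classify_pattern(mat)

    def test_too_few_rows_rejected(self, k4_wt):
        small = k4_wt.copy_with(k4_wt.values.iloc[:3])
        with pytest.raises(SchemaError):
            tv.classify_pattern(small)


class TestCallTransitions:
    def test_identical_conditions_call_nothing(self, noiseless_calls,
                                               noiseless_matrices):
        k27 = noiseless_matrices[("H3K27me3", "WT")]
        out = tv.call_transitions(
            noiseless_calls["WT"], noiseless_calls["WT"], (k27, k27),
            loss_threshold=1.0,
        )
        assert (out["h3k27me3_delta"] == 0).all()
        assert (out["group"] == "none").all()
        assert not out["transition"].any()

    def test_planted_groups_recovered_noiselessly(self, noiseless_calls,
                                                  noiseless_matrices,
                                                  noiseless_genome):
        k27 = (noiseless_matrices[("H3K27me3", "WT")],
               noiseless_matrices[("H3K27me3", "KO")])
        out = tv.call_transitions(noiseless_calls["WT"], noiseless_calls["KO"],
                                  k27, loss_threshold=4.0)
        truth = noiseless_genome.promoters.set_index("cgi_id")["transition"]
        assert (out["group"] == truth.reindex(out.index)).all()
        planted = truth != "none"
        assert (out.loc[planted[planted].index, "transition"]).all()

    def test_group_counts_partition_the_universe(self, noiseless_calls,
                                                 noiseless_matrices):
        k27 = (noiseless_matrices[("H3K27me3", "WT")],
               noiseless_matrices[("H3K27me3", "KO")])
        out = tv.call_transitions(noiseless_calls["WT"], noiseless_calls["KO"],
                                  k27, loss_threshold=4.0)
        counts = out["group"].value_counts()
        assert counts.sum() == len(out)
        assert set(counts.index) <= {"biloss", "bigain", "none"}

    def test_zeroed_ko_h3k27me3_flags_all_bivalent_as_loss(
        self, noiseless_calls, noiseless_matrices, noiseless_genome
    ):
        """Complete H3K27me3 abolition: every bivalent promoter loses."""
        k27_wt = noiseless_matrices[("H3K27me3", "WT")]
        zeroed = k27_wt.copy_with(k27_wt.values * 0.0)
        thr = tv.default_loss_threshold(
            k27_wt,
            noiseless_genome.promoters.loc[
                noiseless_genome.promoters["class"] == "bivalent", "cgi_id"],
        )
        out = tv.call_transitions(noiseless_calls["WT"], noiseless_calls["KO"],
                                  (k27_wt, zeroed), loss_threshold=thr)
        biv = noiseless_genome.promoters.query("`class` == 'bivalent'")["cgi_id"]
        assert out.loc[biv, "k27_loss"].all()

    def test_mismatched_universes_rejected(self, noiseless_calls,
                                           noiseless_matrices):
        k27 = noiseless_matrices[("H3K27me3", "WT")]
        with pytest.raises(SchemaError):
            tv.call_transitions(noiseless_calls["WT"],
                                noiseless_calls["KO"].iloc[::-1], (k27, k27), 1.0)


def transitions_frame(groups):
    idx = pd.Index([f"c{i}" for i in range(len(groups))], name="cgi_id")
    return pd.DataFrame({"group": groups}, index=idx)


def de_frame(genes, lfc, p=1e-6):
    return pd.DataFrame({"gene": genes, "log2FoldChange": lfc,
                         "pvalue": np.full(len(genes), p)})


class TestGroupExpressionContrast:
    def test_identical_distributions_give_p_one(self):
        trans = transitions_frame(["biloss"] * 5 + ["bigain"] * 5)
        gene_map = pd.Series([f"g{i}" for i in range(10)], index=trans.index)
        de = de_frame([f"g{i}" for i in range(10)], [1.0] * 10)
        rep = tv.group_expression_contrast(trans, gene_map, de)
        assert rep["wilcoxon_p"] == pytest.approx(1.0)

    def test_planted_effect_detected_with_direction(self):
        rng = np.random.default_rng(21)
        n = 200
        trans = transitions_frame(["biloss"] * n + ["bigain"] * n)
        genes = [f"g{i}" for i in range(2 * n)]
        gene_map = pd.Series(genes, index=trans.index)
        lfc = np.concatenate([rng.normal(0.5, 0.3, n), rng.normal(2.0, 0.3, n)])
        rep = tv.group_expression_contrast(trans, gene_map, de_frame(genes, lfc))
        assert rep["groups"]["biloss"]["median_lfc"] < rep["groups"]["bigain"]["median_lfc"]
        assert rep["lower_median_group"] == "biloss"
        assert rep["wilcoxon_p"] < 1e-10

    def test_chi2_matches_closed_form(self):
        """Up/down x group table {biloss: 10/40, bigain: 40/10} -> chi2 = 36."""
        trans = transitions_frame(["biloss"] * 50 + ["bigain"] * 50)
        genes = [f"g{i}" for i in range(100)]
        gene_map = pd.Series(genes, index=trans.index)
        lfc = np.concatenate([
            np.full(10, 3.0), np.full(40, -3.0),   # biloss: 10 up, 40 down
            np.full(40, 3.0), np.full(10, -3.0),   # bigain: 40 up, 10 down
        ])
        rep = tv.group_expression_contrast(trans, gene_map, de_frame(genes, lfc),
                                           lfc_cut=2.0, p_cut=0.05)
        assert rep["chi2_stat"] == pytest.approx(36.0)
        # independent closed form: n(ad-bc)^2 / (row and column margins)
        a, b, c, d = 10, 40, 40, 10
        n = a + b + c + d
        expected = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        assert rep["chi2_stat"] == pytest.approx(expected)

    def test_small_group_yields_undefined_statistics(self, caplog):
        trans = transitions_frame(["biloss"] * 2 + ["bigain"] * 5)
        genes = [f"g{i}" for i in range(7)]
        gene_map = pd.Series(genes, index=trans.index)
        with caplog.at_level("WARNING"):
            rep = tv.group_expression_contrast(trans, gene_map,
                                               de_frame(genes, [1.0] * 7))
        assert np.isnan(rep["wilcoxon_p"])
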