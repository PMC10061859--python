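"""Binning exactness, winsorizing and region summaries."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import trivalent as tv
from trivalent.errors import DegenerateDataError, SchemaError
from conftest import brute_force_bin_means, step_track


def promoters_frame(rows):
    return pd.DataFrame(rows, columns=["cgi_id", "chrom", "start", "end"])


ONE_PROMOTER = promoters_frame([("c1", "chr1", 2_000, 2_700)])


class TestBinSignal:
    def test_constant_track_fills_every_cell(self):
        track = step_track(np.full(10_000, 3.5))
        mat = tv.bin_signal(track, ONE_PROMOTER)
        assert np.allclose(mat.values.to_numpy(), 3.5)

    def test_indicator_track_separates_body_and_shores(self):
        arr = np.zeros(10_000)
        arr[2_000:2_700] = 1.0
        mat = tv.bin_signal(step_track(arr), ONE_PROMOTER)
        assert np.allclose(mat.block("body").to_numpy(), 1.0)
        assert np.allclose(mat.block("left_shore").to_numpy(), 0.0)
        assert np.allclose(mat.block("right_shore").to_numpy(), 0.0)

    def test_matches_bp_resolution_oracle_on_random_step_track(self):
        rng = np.random.default_rng(0)
        arr = np.repeat(rng.integers(0, 30, 200).astype(float), 50)  # step track
        mat = tv.bin_signal(step_track(arr), ONE_PROMOTER, n_flank=20, n_body=20)
        oracle = brute_force_bin_means(arr, 2_000, 2_700, 1_000, 20, 20)
        assert np.abs(mat.values.to_numpy()[0] - oracle).max() < 1e-9

    def test_linearity_in_the_track(self):
        rng = np.random.default_rng(1)
        x = rng.random(10_000) * 5
        y = rng.random(10_000) * 2
        mx = tv.bin_signal(step_track(x), ONE_PROMOTER).values.to_numpy()
        my = tv.bin_signal(step_track(y), ONE_PROMOTER).values.to_numpy()
        mz = tv.bin_signal(step_track(2 * x + 3 * y), ONE_PROMOTER).values.to_numpy()
        assert np.allclose(mz, 2 * mx + 3 * my, atol=1e-9)

    def test_edge_truncation_zero_fills(self, caplog):
        proms = promoters_frame([("c1", "chr1", 100, 500)])  # left shore off-contig
        arr = np.ones(5_000)
        with caplog.at_level("WARNING"):
            mat = tv.bin_signal(step_track(arr), proms)
        # first 900 bp of the left shore are virtual zeros
        left = mat.block("left_shore").to_numpy()[0]
        assert left[0] == 0.0
        assert np.allclose(mat.block("body").to_numpy(), 1.0)
        assert "truncated" in caplog.text

    def test_missing_contig_gives_zero_row(self, caplog):
        proms = promoters_frame([("c1", "chrX", 2_000, 2_700)])
        with caplog.at_level("WARNING"):
            mat = tv.bin_signal(step_track(np.ones(10_000)), proms)
        assert np.allclose(mat.values.to_numpy(), 0.0)

    def test_negative_coverage_clamped(self):
        arr = np.full(10_000, -2.0)
        mat = tv.bin_signal(step_track(arr), ONE_PROMOTER)
        assert np.allclose(mat.values.to_numpy(), 0.0)


class TestWinsorize:
    def test_pct_100_is_identity(self):
        rng = np.random.default_rng(2)
        mat = tv.bin_signal(step_track(rng.random(10_000)), ONE_PROMOTER)
        out = tv.winsorize_scale(mat, 100)
        pd.testing.assert_frame_equal(out.values, mat.values)

    def test_values_above_percentile_clamped(self):
        vals = pd.DataFrame(
            np.arange(1.0, 101.0).reshape(5, 20),
            index=pd.Index([f"c{i}" for i in range(5)], name="cgi_id"),
        )
        vals.columns = [f"b{i}" for i in range(20)]
        mat = tv.SignalMatrix(values=vals, n_flank=5, n_body=10, flank_bp=250,
                              body_bp=pd.Series(500, index=vals.index))
        cap = np.percentile(np.arange(1.0, 101.0), 95)
        out = tv.winsorize_scale(mat, 95).values.to_numpy()
        assert out.max() == cap
        ref = np.minimum(np.sort(np.arange(1.0, 101.0)), cap)
        assert np.allclose(np.sort(out.ravel()), ref)

    def test_constant_matrix_unchanged(self):
        mat = tv.bin_signal(step_track(np.full(10_000, 2.0)), ONE_PROMOTER)
        assert np.allclose(tv.winsorize_scale(mat, 95).values.to_numpy(), 2.0)

    def test_non_finite_rejected(self):
        mat = tv.bin_signal(step_track(np.ones(10_000)), ONE_PROMOTER)
        mat.values.iloc[0, 0] = np.inf
        with pytest.raises(DegenerateDataError):
            tv.winsorize_scale(mat, 95)


class TestSummarizeRegion:
    def test_constant_matrix_every_region(self):
        mat = tv.bin_signal(step_track(np.full(10_000, 4.0)), ONE_PROMOTER)
        for region in ("left_shore", "body", "right_shore", "shores", "full"):
            assert tv.summarize_region(mat, region).iloc[0] == pytest.approx(4.0)

    def test_block_averages_and_weighted_full(self):
        arr = np.zeros(10_000)
        arr[2_000:2_700] = 2.0   # body 2, shores 0
        mat = tv.bin_signal(step_track(arr), ONE_PROMOTER)
        assert tv.summarize_region(mat, "body").iloc[0] == pytest.approx(2.0)
        assert tv.summarize_region(mat, "shores").iloc[0] == pytest.approx(0.0)
        expected_full = (700 * 2.0) / (700 + 2_000)
        assert tv.summarize_region(mat, "full").iloc[0] == pytest.approx(expected_full)

    def test_shores_is_mean_of_left_and_right(self):
        rng = np.random.default_rng(3)
        mat = tv.bin_signal(step_track(rng.random(10_000)), ONE_PROMOTER)
        left = tv.summarize_region(mat, "left_shore")
        right = tv.summarize_region(mat, "right_shore")
        expected = (left + right) / 2
        assert np.allclose(tv.summarize_region(mat, "shores"), expected)

    def test_full_equals_bp_resolution_mean(self):
        """Conservation: the weighted full summary is the padded-window mean."""
        rng = np.random.default_rng(4)
        arr = np.repeat(rng.integers(0, 10, 500).astype(float), 20)
        mat = tv.bin_signal(step_track(arr), ONE_PROMOTER)
        bp_mean = arr[1_000:3_700].mean()
        assert tv.summarize_region(mat, "full").iloc[0] == pytest.approx(bp_mean, abs=1e-9)

    def test_unknown_region_rejected(self):
        mat = tv.bin_signal(step_track(np.ones(10_000)), ONE_PROMOTER)
        with pytest.raises(KeyError):
            tv.summarize_region(mat, "promoter")


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.lists(st.floats(0, 100), min_size=40, max_size=40),
       st.integers(300, 2_000))
def test_binning_conserves_mass_property(levels, body_len):
    """Full summary equals the bp mean for arbitrary 100-bp step tracks."""
    arr = np.repeat(np.asarray(levels), 100)
    proms = promoters_frame([("c1", "chr1", 1_000, 1_000 + body_len)])
    mat = tv.bin_signal(step_track(arr), proms)
    window = arr[0: body_len + 2_000]
    assert tv.summarize_region(mat, "full").iloc[0] == pytest.approx(
        window.mean(), abs=1e-9
    )
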