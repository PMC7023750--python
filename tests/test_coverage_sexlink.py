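import numpy as np
import pandas as pd
import pytest

from wpal import coverage_sexlink as cs
from wpal import synthetic_data as sd


def _track(depth, chrom="c", start=0):
    return sd.DepthTrack(chrom=chrom, depth=np.asarray(depth), start=start)


class TestWindowMedian:
    def test_non_overlapping_default(self):
        df = cs.window_median_depth(_track([1, 2, 3, 4, 5, 6]), window=3)
        assert list(df["median_depth"]) == [2.0, 5.0]
        assert list(df["short"]) == [False, False]

    def test_lower_median_even_window(self):
        df = cs.window_median_depth(_track([1, 2, 3, 10]), window=4)
        assert df["median_depth"].iloc[0] == 2.0  # lower median, deterministic

    def test_short_last_window_flagged(self):
        df = cs.window_median_depth(_track([5] * 7), window=4)
        assert list(df["short"]) == [False, True]
        assert df["end"].iloc[-1] == 7

    def test_sliding(self):
        # sliding stops once a window reaches the end of the track
        df = cs.window_median_depth(_track([1, 2, 3, 4]), window=2, step=1)
        assert list(df["start"]) == [0, 1, 2]
        assert df["end"].iloc[-1] == 4

    def test_step_greater_than_window_rejected(self):
        with pytest.raises(ValueError):
            cs.window_median_depth(_track([1, 2, 3]), window=2, step=3)


class TestLog2Ratio:
    def test_scalar_and_array(self):
        assert cs.log2_depth_ratio(3, 1) == pytest.approx(1.0)
        out = cs.log2_depth_ratio([3, 1], [1, 3])
        assert out == pytest.approx([1.0, -1.0])

    def test_zero_depths_finite(self):
        assert np.isfinite(cs.log2_depth_ratio(0, 0))

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            cs.log2_depth_ratio(-1, 5)


def _marker_table():
    # 18 background intervals (balanced depths) + 2 female-specific ones
    rng = np.random.default_rng(0)
    n_bg = 18
    bg = pd.DataFrame(
        {
            "chrom": "c",
            "start": np.arange(n_bg) * 1000,
            "end": np.arange(n_bg) * 1000 + 100,
            "pooled_F": rng.poisson(200, n_bg),
            "pooled_M": rng.poisson(200, n_bg),
            "reseq_F": rng.poisson(40, n_bg),
            "reseq_M": rng.poisson(40, n_bg),
        }
    )
    fs = pd.DataFrame(
        {
            "chrom": "c",
            "start": [50_000, 60_000],
            "end": [50_100, 60_100],
            "pooled_F": [210, 190],
            "pooled_M": [0, 1],
            "reseq_F": [80, 75],
            "reseq_M": [0, 0],
        }
    )
    return pd.concat([bg, fs], ignore_index=True)


class TestTwoRuleClassifier:
    def test_calls_planted_markers(self):
        out = cs.call_female_specific_markers(_marker_table())
        assert out["is_female_specific"].sum() == 2
        assert set(out[out["is_female_specific"]]["start"]) == {50_000, 60_000}

    def test_rule2_required(self):
        df = _marker_table()
        df.loc[df["start"] == 50_000, "reseq_F"] = 10  # log2(11/1) ~ 3.46 < 5
        out = cs.call_female_specific_markers(df)
        assert not out[out["start"] == 50_000]["is_female_specific"].iloc[0]

    def test_fixed_l_override(self):
        out = cs.call_female_specific_markers(_marker_table(), fixed_l=-100.0)
        assert out["is_female_specific"].sum() == 0
        assert (out["L"] == -100.0).all()

    def test_l_divisor_literal_definition(self):
        df = _marker_table()
        out_n = cs.call_female_specific_markers(df, l_divisor="n_intervals")
        out_1 = cs.call_female_specific_markers(df, l_divisor="one")
        q = np.quantile(out_1["rule1_stat"], 0.05)
        assert out_1["L"].iloc[0] == pytest.approx(q)
        assert out_n["L"].iloc[0] == pytest.approx(q / len(df))

    def test_all_zero_depths_warns_no_calls(self):
        df = _marker_table()
        for c in ("pooled_F", "pooled_M", "reseq_F", "reseq_M"):
            df[c] = 0
        with pytest.warns(UserWarning):
            out = cs.call_female_specific_markers(df)
        assert out["is_female_specific"].sum() == 0

    def test_too_few_intervals_rejected(self):
        with pytest.raises(ValueError):
            cs.call_female_specific_markers(_marker_table().head(1))


def test_w_contig_rule_three_markers():
    markers = pd.DataFrame(
        {
            "contig": ["a"] * 3 + ["b"] * 2,
            "is_female_specific": [True, True, True, True, True],
        }
    )
    calls = {c.contig: c.call for c in cs.classify_w_contigs(markers)}
    assert calls == {"a": "W_candidate", "b": "not_W"}


def test_classify_zw_regions_merges_runs():
    df = pd.DataFrame(
        {
            "chrom": ["c"] * 4,
            "start": [0, 10, 20, 30],
            "end": [10, 20, 30, 40],
            "median_depth": [50.0, 2.0, 0.0, 45.0],
        }
    )
    out = cs.classify_zw_regions(df, max_male_depth=10)
    assert out.to_dict("records") == [
        {"chrom": "c", "start": 0, "end": 10, "label": "ZW_homologous"},
        {"chrom": "c", "start": 10, "end": 30, "label": "W_specific"},
        {"chrom": "c", "start": 30, "end": 40, "label": "ZW_homologous"},
    ]


class TestMarkerRecode:
    def test_recode_mother_carrier(self):
        out = cs.recode_hemizygous_markers("+/-", "-/-", [True, False, True])
        assert out == {"mother": "AB", "father": "BB", "offspring": ["AB", "BB", "AB"]}

    def test_recode_father_carrier(self):
        out = cs.recode_hemizygous_markers("-/-", "+/-", [False])
        assert out["mother"] == "BB" and out["father"] == "AB"

    def test_unsupported_pattern_rejected(self):
        with pytest.raises(ValueError):
            cs.recode_hemizygous_markers("+/-", "+/-", [True])


def test_recovery_on_simulated_truth(default_truth):
    rng = np.random.default_rng(42)
    gbs = sd.simulate_pooled_gbs(default_truth, rng=rng)
    called = cs.call_female_specific_markers(gbs)
    score = cs.score_marker_calls(called, default_truth.hemizygous_intervals)
    assert score["sensitivity"] >= 0.9
    assert score["fpr"] <= 0.01
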