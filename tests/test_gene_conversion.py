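import numpy as np
import pandas as pd
import pytest

from wpal import gene_conversion as gc
from wpal import synthetic_data as sd


def _sites(rows):
    cols = ["pos", "ref", "alt", "qual", "depth",
            "depth_A_ref", "depth_A_alt", "depth_B_ref", "depth_B_alt"]
    return pd.DataFrame(rows, columns=cols)


class TestFilter:
    def test_boundaries_inclusive(self):
        df = _sites(
            [
                (0, "A", "G", 20.0, 300, 10, 10, 10, 10),  # kept: qual==20, depth==300
                (1, "A", "G", 19.9, 100, 10, 10, 10, 10),  # removed: qual
                (2, "A", "G", 60.0, 301, 10, 10, 10, 10),  # removed: depth
            ]
        )
        out = gc.filter_variants(df)
        assert list(out["pos"]) == [0]

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        df = _sites(
            [
                (i, "A", "G", float(rng.uniform(0, 60)), int(rng.integers(1, 400)),
                 10, 10, 10, 10)
                for i in range(200)
            ]
        )
        once = gc.filter_variants(df)
        twice = gc.filter_variants(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_empty_ok(self):
        assert gc.filter_variants(_sites([])).empty


def test_drop_shadow_sites():
    df = _sites([(i, "A", "G", 60.0, 100, 10, 10, 10, 10) for i in range(10)])
    out = gc.drop_shadow_sites(df, [(3, 6)])
    assert list(out["pos"]) == [0, 1, 2, 6, 7, 8, 9]


class TestClassify:
    def test_constructed_examples(self):
        df = _sites(
            [
                # one arm of four carries alt in focal; sister fixed ref -> psv_focal
                (0, "A", "G", 60.0, 120, 45, 15, 60, 0),
                # sister-private PSV
                (1, "A", "G", 60.0, 120, 60, 0, 45, 15),
                # both species near-fixed, opposite alleles -> fixed difference
                (2, "A", "G", 60.0, 120, 58, 2, 1, 59),
                # PSV in both species -> shared variant
                (3, "A", "G", 60.0, 120, 45, 15, 44, 16),
                # intermediate but off-band (f = 0.60) -> other
                (4, "A", "G", 60.0, 120, 24, 36, 60, 0),
                # no sister coverage -> other
                (5, "A", "G", 60.0, 60, 45, 15, 0, 0),
            ]
        )
        out = gc.classify_sites(df, arm_copy_number=4, af_tol=0.05)
        assert list(out["classification"]) == [
            "psv_focal", "psv_sister", "fixed_difference", "shared_variant", "other", "other",
        ]

    def test_copy_number_validation(self):
        with pytest.raises(ValueError):
            gc.classify_sites(_sites([]), arm_copy_number=1)

    def test_agreement_with_simulated_truth(self, default_truth):
        rng = np.random.default_rng(11)
        pileup = sd.simulate_collapsed_pileup(default_truth, rng=rng)
        out = gc.classify_sites(gc.filter_variants(pileup))
        known = out[out["truth_class"] != "other"]
        agree = (known["classification"] == known["truth_class"]).mean()
        assert agree >= 0.95


def test_density_tracks_conserve_counts():
    rng = np.random.default_rng(1)
    df = _sites(
        [(int(p), "A", "G", 60.0, 120, 45, 15, 60, 0) for p in rng.integers(0, 5000, 300)]
    )
    out = gc.classify_sites(df)
    tracks = gc.density_tracks(out, reference_length=5000, window=100)
    assert len(tracks) == 50
    assert tracks["psv_focal"].sum() == (out["classification"] == "psv_focal").sum()
    assert tracks[["fixed", "psv_focal", "psv_sister", "shared", "other"]].to_numpy().sum() == len(df)


def test_relative_depth_units():
    out = gc.relative_depth(np.array([30.0, 60.0, 120.0]), genome_mean_depth=30.0)
    assert out == pytest.approx([2.0, 4.0, 8.0])
    with pytest.raises(ValueError):
        gc.relative_depth(np.array([1.0]), 0.0)


class TestDetectRegions:
    def _tracks(self, psv, fixed, depth=4.0, window=100):
        n = len(psv)
        return pd.DataFrame(
            {
                "window_start": np.arange(n) * window,
                "window_end": np.arange(1, n + 1) * window,
                "fixed": fixed,
                "psv_focal": psv,
                "psv_sister": np.zeros(n, dtype=int),
                "shared": np.zeros(n, dtype=int),
                "other": np.zeros(n, dtype=int),
                "depth_n": np.full(n, depth),
            }
        )

    def test_planted_run_detected(self):
        psv = [2] * 10 + [0] * 30 + [2] * 10
        fixed = [1] * 50
        out = gc.detect_converted_regions(self._tracks(psv, fixed))
        assert len(out) == 1
        assert (out["start"].iloc[0], out["end"].iloc[0]) == (1000, 4000)

    def test_depth_band_enforced(self):
        psv = [2] * 10 + [0] * 30 + [2] * 10
        fixed = [1] * 50
        out = gc.detect_converted_regions(self._tracks(psv, fixed, depth=2.0))
        assert out.empty

    def test_short_run_rejected(self):
        psv = [2] * 10 + [0] * 5 + [2] * 10
        fixed = [1] * 25
        assert gc.detect_converted_regions(self._tracks(psv, fixed)).empty

    def test_fixed_floor_required(self):
        psv = [2] * 10 + [0] * 30 + [2] * 10
        fixed = [0] * 50
        assert gc.detect_converted_regions(self._tracks(psv, fixed)).empty

    def test_relaxing_psv_threshold_is_monotone(self):
        rng = np.random.default_rng(3)
        psv = rng.integers(0, 3, 80)
        fixed = rng.integers(1, 4, 80)
        tracks = self._tracks(psv, fixed)
        covered_prev = set()
        for thr in (0.0, 1.0, 2.0):
            out = gc.detect_converted_regions(
                tracks, max_psv_per_100bp=thr, depth_band=None
            )
            covered = set()
            for r in out.itertuples():
                covered.update(range(r.start, r.end, 100))
            assert covered_prev <= covered
            covered_prev = covered


def test_reciprocal_overlap():
    assert gc.reciprocal_overlap((0, 100), (0, 100)) == 1.0
    assert gc.reciprocal_overlap((0, 100), (50, 150)) == 0.5
    assert gc.reciprocal_overlap((0, 100), (200, 300)) == 0.0
    assert gc.reciprocal_overlap((0, 1000), (0, 100)) == pytest.approx(0.1)
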