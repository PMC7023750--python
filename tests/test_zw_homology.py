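import itertools
import math

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

from wpal import synthetic_data as sd
from wpal import zw_homology as zw

# ---------------------------------------------------------------------------
# independent NG86 oracle (string-based, Biopython translation)

_BASES = "TCAG"


def _aa(codon):
    return str(Seq(codon).translate())  # '*' for stops


def oracle_sites(codon):
    """Synonymous sites of one codon; mutations to stops excluded."""
    total = 0.0
    for i in range(3):
        syn = non = 0
        for b in _BASES:
            if b == codon[i]:
                continue
            alt = codon[:i] + b + codon[i + 1 :]
            if _aa(alt) == "*":
                continue
            if _aa(alt) == _aa(codon):
                syn += 1
            else:
                non += 1
        if syn + non:
            total += syn / (syn + non)
    return total


def oracle_diffs(c1, c2):
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    results = []
    for order in itertools.permutations(diff):
        cur, sd_, nd_, blocked = c1, 0, 0, False
        for i in order:
            nxt = cur[:i] + c2[i] + cur[i + 1 :]
            if _aa(nxt) == "*":
                blocked = True
            if _aa(cur) == _aa(nxt) and _aa(cur) != "*" and _aa(nxt) != "*":
                sd_ += 1
            else:
                nd_ += 1
            cur = nxt
        results.append((blocked, sd_, nd_))
    usable = [r for r in results if not r[0]] or results
    return (
        sum(r[1] for r in usable) / len(usable),
        sum(r[2] for r in usable) / len(usable),
    )


def oracle_ds_dn(pairs):
    S = (sum(oracle_sites(a) for a, _ in pairs) + sum(oracle_sites(b) for _, b in pairs)) / 2
    N = 3 * len(pairs) - S
    sd_ = sum(oracle_diffs(a, b)[0] for a, b in pairs)
    nd_ = sum(oracle_diffs(a, b)[1] for a, b in pairs)
    ps, pn = sd_ / S, nd_ / N

    def jc(p):
        return None if p >= 0.75 else -0.75 * math.log(1 - 4 * p / 3)

    return jc(ps), jc(pn)


ALL_CODONS = [
    a + b + c
    for a in _BASES
    for b in _BASES
    for c in _BASES
    if _aa(a + b + c) != "*"
]


class TestNG86:
    def test_matches_oracle_on_random_pairs(self):
        rng = np.random.default_rng(0)
        for trial in range(20):
            pairs = [
                (ALL_CODONS[rng.integers(len(ALL_CODONS))], ALL_CODONS[rng.integers(len(ALL_CODONS))])
                for _ in range(30)
            ]
            res = zw.estimate_ds_dn(pairs)
            ods, odn = oracle_ds_dn(pairs)
            if ods is None:
                assert res.saturated_s
            else:
                assert res.ds == pytest.approx(ods, abs=1e-9)
            if odn is None:
                assert res.saturated_n
            else:
                assert res.dn == pytest.approx(odn, abs=1e-9)

    def test_identical_sequences_zero(self):
        pairs = [(c, c) for c in ALL_CODONS[:20]]
        res = zw.estimate_ds_dn(pairs)
        assert res.ds == 0.0 and res.dn == 0.0

    def test_known_single_codon_sites(self):
        # TTT (Phe): only position 3 changes can be synonymous (TTC), 1 of 3
        assert zw.estimate_ds_dn([("TTT", "TTT")] * 10).syn_sites == pytest.approx(10 / 3)

    def test_min_codons_enforced(self):
        with pytest.raises(ValueError):
            zw.estimate_ds_dn([("TTT", "TTT")] * 5)

    def test_recovers_planted_divergence(self):
        rng = np.random.default_rng(1)
        z = sd._random_cds(rng, 4000)
        w = sd._evolve_cds(z, rng, 0.05)
        res = zw.estimate_ds_dn(zw.codon_align(w, z))
        # synonymous sites evolve neutrally at the planted rate
        assert res.ds == pytest.approx(0.05, rel=0.25)


class TestCodonAlign:
    def test_simple_alignment(self):
        pairs = zw.codon_align("ATGGCTTTT" * 4, "ATGGCTTTT" * 4)
        assert len(pairs) == 12
        assert all(a == b for a, b in pairs)

    def test_trailing_stop_trimmed(self):
        cds = "ATGGCTTTT" * 4
        assert len(zw.codon_align(cds + "TAA", cds)) == 12

    def test_length_validation(self):
        with pytest.raises(ValueError, match="divisible by 3"):
            zw.codon_align("ATGGC", "ATGGCT")

    def test_internal_stop_rejected(self):
        with pytest.raises(ValueError, match="internal stop"):
            zw.codon_align("ATGTAAGCTGCTGCTGCT", "ATGGCTGCTGCTGCTGCT")


def _protein_sets(rng, n=6, length=150, divergence=0.02):
    a, b = {}, {}
    for i in range(n):
        z = sd._random_cds(rng, length)
        w = sd._evolve_cds(z, rng, divergence)
        a[f"a{i}"] = str(Seq(z).translate())
        b[f"b{i}"] = str(Seq(w).translate())
    return a, b


class TestSearchAndMBH:
    def test_mbh_symmetry(self):
        rng = np.random.default_rng(2)
        a, b = _protein_sets(rng)
        h_ab = zw.all_vs_all_protein_search(a, b)
        h_ba = zw.all_vs_all_protein_search(b, a)
        fwd = zw.mutual_best_hits(h_ab, h_ba)
        rev = zw.mutual_best_hits(h_ba, h_ab)
        assert {(r.a, r.b) for r in fwd.itertuples()} == {(r.b, r.a) for r in rev.itertuples()}
        assert len(fwd) == 6

    def test_identity_threshold_boundary(self):
        rng = np.random.default_rng(3)
        a, b = _protein_sets(rng, n=4, divergence=0.01)  # ~99% aa identity
        low_a, low_b = _protein_sets(rng, n=1, divergence=0.60)  # far below 90%
        a["a_low"], b["b_low"] = low_a["a0"], low_b["b0"]
        h_ab = zw.all_vs_all_protein_search(a, b)
        h_ba = zw.all_vs_all_protein_search(b, a)
        mbh = zw.mutual_best_hits(h_ab, h_ba, min_identity=90.0, min_coverage=0.7)
        assert "a_low" not in set(mbh["a"])
        assert len(mbh) == 4

    def test_invalid_residues_skipped_with_warning(self):
        rng = np.random.default_rng(4)
        a, b = _protein_sets(rng, n=2)
        a["bad"] = "MKLX*"
        with pytest.warns(UserWarning):
            zw.all_vs_all_protein_search(a, b)


class TestTandemArrays:
    def _positions(self, coords):
        return pd.DataFrame(
            [{"gene_id": g, "chrom": c, "start": s, "end": s + 1000} for g, c, s in coords]
        )

    def _hits(self, pairs):
        rows = []
        for q, s in pairs:
            rows.append({"query": q, "subject": s, "identity": 95.0, "coverage": 0.9,
                         "score": 500.0, "bitscore": 200.0, "evalue": 1e-50})
        return pd.DataFrame(rows)

    def test_single_linkage_chain(self):
        pos = self._positions([("g1", "c", 0), ("g2", "c", 300_000), ("g3", "c", 600_000)])
        hits = self._hits([("g1", "g2"), ("g2", "g3")])  # 600 kb ends linked via g2
        arrays = zw.tandem_arrays(hits, pos, {"g1": "M" * 100, "g2": "M" * 120, "g3": "M" * 110})
        assert arrays["array_id"].nunique() == 1
        assert arrays.loc[arrays["is_representative"], "gene_id"].tolist() == ["g2"]

    def test_window_and_evalue_limits(self):
        pos = self._positions([("g1", "c", 0), ("g2", "c", 600_000), ("g3", "d", 0)])
        hits = self._hits([("g1", "g2"), ("g1", "g3")])
        weak = self._hits([("g1", "g2")])
        weak["evalue"] = 1e-5
        arrays = zw.tandem_arrays(pd.concat([hits, weak]), pos, {g: "M" * 100 for g in ("g1", "g2", "g3")})
        # 600 kb apart and cross-chromosome links both rejected
        assert arrays["array_id"].nunique() == 3


class TestCategorize:
    def test_priority_partition(self):
        arrays = pd.DataFrame(
            [
                {"gene_id": "g_t1", "array_id": "array_0", "array_size": 2, "is_representative": True},
                {"gene_id": "g_t2", "array_id": "array_0", "array_size": 2, "is_representative": False},
                {"gene_id": "g_zw", "array_id": "array_1", "array_size": 2, "is_representative": True},
                {"gene_id": "g_x", "array_id": "array_1", "array_size": 2, "is_representative": False},
            ]
        )
        out_hits = pd.DataFrame(
            [{"query": "g_anc", "subject": "o1", "identity": 92.0, "coverage": 0.9,
              "score": 400.0, "bitscore": 150.0, "evalue": 1e-40}]
        )
        out_pos = pd.DataFrame([{"gene_id": "o1", "chrom": "outChr15", "start": 0, "end": 10}])
        cats = zw.categorize_genes(
            ["g_zw", "g_t1", "g_t2", "g_x", "g_auto", "g_anc", "g_nm", "g_none"],
            mbh_to_partner={"g_zw": "z1"},
            mbh_to_autosome={"g_auto": "a1", "g_zw": "a9"},
            tandem=arrays,
            outgroup_hits=out_hits,
            outgroup_positions=out_pos,
            any_best_hit={"g_nm": "z9", "g_zw": "z1"},
        )
        got = dict(zip(cats["gene_id"], cats["category"]))
        assert got == {
            "g_zw": "ZW_homolog",  # priority over tandem/autosome
            "g_t1": "tandem_duplicate",
            "g_t2": "tandem_duplicate",
            "g_x": "tandem_duplicate",
            "g_auto": "transposed_from_autosome",
            "g_anc": "ancestral",
            "g_nm": "non_mutual",
            "g_none": "no_hit",
        }
        assert len(cats) == 8  # a partition: each gene exactly once


class TestStrataScan:
    def test_two_strata_detected(self):
        rng = np.random.default_rng(5)
        trips = sd.simulate_strata_pairs(rng, strata=((0.02, 15), (0.10, 15)))
        rows = [
            {"a": "w", "b": "z", "ds": zw.estimate_ds_dn(zw.codon_align(w, z)).ds, "z_pos": p}
            for w, z, p in trips
        ]
        res = zw.strata_scan(pd.DataFrame(rows))
        assert res["n_segments"] == 2
        assert res["segments"][0]["mean_ds"] < res["segments"][1]["mean_ds"]

    def test_uniform_divergence_single_segment(self):
        rng = np.random.default_rng(6)
        trips = sd.simulate_strata_pairs(rng, strata=((0.04, 30),))
        rows = [
            {"a": "w", "b": "z", "ds": zw.estimate_ds_dn(zw.codon_align(w, z)).ds, "z_pos": p}
            for w, z, p in trips
        ]
        res = zw.strata_scan(pd.DataFrame(rows))
        assert res["n_segments"] == 1

    def test_windowed_summary(self):
        df = pd.DataFrame(
            {"a": list("abcd"), "b": list("wxyz"),
             "ds": [0.01, 0.03, 0.05, 0.07], "z_pos": [0, 50_000, 150_000, 199_000]}
        )
        res = zw.strata_scan(df, window=100_000)
        win = res["windowed"]
        assert list(win["n_pairs"]) == [2, 2]
        assert win["mean_ds"].iloc[0] == pytest.approx(0.02)
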