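import numpy as np
import pandas as pd
import pytest

from wpal import palindrome_detect as pdx
from wpal import synthetic_data as sd
from wpal._seq import random_dna, revcomp


def brute_force_inverted_seeds(sequence, k, step):
    """Independent O(n^2) oracle: every sampled k-mer vs every position."""
    found = set()
    n = len(sequence)
    for q in range(0, n - k + 1, step):
        kmer = sequence[q : q + k]
        if "N" in kmer:
            continue
        target = revcomp(kmer)
        t = sequence.find(target)
        while t != -1:
            if abs(q - t) >= k:  # non-overlapping footprints
                found.add((min(q, t), max(q, t)))
            t = sequence.find(target, t + 1)
    return found


def _planted_sequence(rng, arm=400, gap=120, flank=600):
    arm_seq = random_dna(rng, arm)
    return (
        random_dna(rng, flank)
        + arm_seq
        + random_dna(rng, gap)
        + revcomp(arm_seq)
        + random_dna(rng, flank)
    )


class TestSeeds:
    def test_seed_completeness_vs_brute_force(self):
        rng = np.random.default_rng(0)
        for trial in range(5):
            seq = _planted_sequence(rng)
            seeds = pdx.find_inverted_seeds(seq, k=40, step=7)
            got = {(min(s.plus, s.minus), max(s.plus, s.minus)) for s in seeds}
            assert got == brute_force_inverted_seeds(seq, k=40, step=7)

    def test_no_seeds_in_random_sequence(self):
        rng = np.random.default_rng(1)
        seq = random_dna(rng, 5000)
        assert pdx.find_inverted_seeds(seq, k=40, step=5) == []

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            pdx.find_inverted_seeds("ACGT" * 100, k=10, step=5)
        with pytest.raises(ValueError):
            pdx.find_inverted_seeds("ACGT" * 100, k=20, step=0)

    def test_n_kmers_skipped(self):
        rng = np.random.default_rng(2)
        seq = _planted_sequence(rng)
        seq = seq[:650] + "N" * 10 + seq[660:]
        # must not raise, and still find seeds away from the N block
        pdx.find_inverted_seeds(seq, k=40, step=7)


class TestExtension:
    def test_exact_palindrome_recovered_full_length(self):
        rng = np.random.default_rng(3)
        arm = random_dna(rng, 1500)
        seq = random_dna(rng, 800) + arm + random_dna(rng, 300) + revcomp(arm) + random_dna(rng, 800)
        seeds = pdx.find_inverted_seeds(seq, k=100, step=20)
        hits = pdx.extend_and_chain(seq, seeds, min_length=1000)
        assert len(hits) == 1
        h = hits[0]
        # exact extension may overrun by a few chance-complementary flank bases
        assert abs(h.plus[0] - 800) <= 8 and abs(h.plus[1] - 2300) <= 8
        assert abs(h.minus[0] - 2600) <= 8 and abs(h.minus[1] - 4100) <= 8
        assert h.percent_identity == 100.0

    def test_diverged_arms_verified_identity(self):
        rng = np.random.default_rng(4)
        arm = sd.random_dna_arr(rng, 2000)
        from wpal._seq import arr_to_seq, evolve_arr

        a = arr_to_seq(evolve_arr(arm, rng, 0.005))
        b = arr_to_seq(evolve_arr(arm, rng, 0.005))
        seq = random_dna(rng, 500) + a + random_dna(rng, 200) + revcomp(b) + random_dna(rng, 500)
        hits = pdx.extend_and_chain(seq, pdx.find_inverted_seeds(seq), min_length=1000)
        assert len(hits) == 1
        assert hits[0].percent_identity > 98.0
        assert hits[0].aligned_length >= 1900


def test_strand_involution():
    """Detection on the reverse complement yields mirrored coordinates."""
    rng = np.random.default_rng(5)
    seq = _planted_sequence(rng, arm=1200, gap=400, flank=1500)
    fwd = pdx.extend_and_chain(seq, pdx.find_inverted_seeds(seq), min_length=1000)
    rc = revcomp(seq)
    rev = pdx.extend_and_chain(rc, pdx.find_inverted_seeds(rc), min_length=1000)
    n = len(seq)

    def mirrored(h):
        # interval (s, e) on the forward strand maps to (n-e, n-s)
        return tuple(sorted([(n - h.plus[1], n - h.plus[0]), (n - h.minus[1], n - h.minus[0])]))

    assert {mirrored(h) for h in rev} == {tuple(sorted([h.plus, h.minus])) for h in fwd}


class TestAssembly:
    def test_planted_two_palindrome_block(self, default_truth):
        t = default_truth
        pals, _ = pdx.detect_palindromes(t.w_sequence)
        assert [p.name for p in pals] == ["W.P1", "W.P2"]
        p1, p2 = pals
        labels1 = [a[0] for a in p1.arms]
        assert labels1 == ["arm1", "arm2"]
        assert [a[0] for a in p2.arms] == ["arm3a", "arm3b", "arm4b", "arm4a"]
        truth_by_label = {a.label: (a.start, a.end) for a in t.palindrome_layout}
        for label, s, e, _ in p1.arms + p2.arms:
            ts, te = truth_by_label[label]
            assert abs(s - ts) <= 50 and abs(e - te) <= 50
        # P1 has a located spacer, P2's is unidentified (inner arms abut)
        assert p1.spacers[0][2] > p1.spacers[0][1]
        assert p2.spacers[0][2] <= p2.spacers[0][1]
        # pre-arm attached to P1, unambiguously
        assert p1.pre_arm is not None and not p1.ambiguous
        ts, te = t.pre_arm
        assert abs(p1.pre_arm[0] - ts) <= 50 and abs(p1.pre_arm[1] - te) <= 50

    def test_single_palindrome_labels(self):
        rng = np.random.default_rng(6)
        arm = random_dna(rng, 1500)
        seq = random_dna(rng, 700) + arm + random_dna(rng, 250) + revcomp(arm) + random_dna(rng, 700)
        pals, _ = pdx.detect_palindromes(seq)
        assert len(pals) == 1
        assert [a[0] for a in pals[0].arms] == ["arm1", "arm2"]


class TestReport:
    def test_size_arithmetic_on_planted(self, default_truth):
        pals, _ = pdx.detect_palindromes(default_truth.w_sequence)
        rep = pdx.palindrome_report(pals)
        located = rep.dropna(subset=["start"])
        assert (located["size"] == located["end"] - located["start"] + 1).all()

    def test_from_coordinates_round_trip(self):
        comps = [("arm1", 101, 200, "+"), ("Spacer1", 201, 220, "."), ("arm2", 221, 320, "-")]
        p = pdx.Palindrome.from_coordinates_1based("X", comps)
        rep = p.report()
        row = rep[rep["component"] == "arm1"].iloc[0]
        assert (row["start"], row["end"], row["size"]) == (101, 200, 100)


def test_divergence_profile_conserves_total_differences(default_truth):
    t = default_truth
    prof = pdx.arm_divergence_profile(
        t.arm_sequences["arm1"], t.arm_sequences["arm2"], window=100
    )
    assert int(np.sum(prof.differences)) == prof.total_differences
    # converted tract (template coords) should be a run of zero-difference windows
    s, e = t.conversion_tracts[0]
    tract = prof.differences[s // 100 : e // 100]
    assert tract.sum() == 0
    outside = np.concatenate([prof.differences[: s // 100], prof.differences[e // 100 :]])
    assert outside.sum() > 0
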