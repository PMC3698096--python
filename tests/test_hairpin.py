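"""Folding engine and stem-loop criteria tests.

The independent oracle enumerates every single-stem structure explicitly
(chains of nested pairs) and scores them with the public energy terms, so
it shares no code path with the interval dynamic program it checks.
"""

import dataclasses
import itertools

import numpy as np
import pytest

from mirmos.hairpin import (MAX_INTERIOR, MIN_HAIRPIN_LOOP, FoldResult,
                            HairpinCandidate, WindowRead, _STACKS,
                            check_criteria, duplex_cleanliness, extract_window,
                            fold_mfe, hairpin_penalty, locate_arms,
                            loop_energy, read_stack_consistency)
from mirmos.io_formats import AnnotationSet, GenomicInterval, revcomp
from mirmos.mapping import TagHit

PAIRABLE = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"),
            ("G", "T"), ("T", "G")}


def enumerate_single_stem_mfe(seq: str, max_interior: int = MAX_INTERIOR
                              ) -> float:
    """Exhaustive enumeration oracle: best energy over all single-stem
    structures (or 0.0 for the empty structure)."""
    n = len(seq)
    pairable = [(i, j) for i in range(n) for j in range(i + 4, n)
                if (seq[i], seq[j]) in PAIRABLE]
    best = [0.0]

    def rec(i: int, j: int, acc: float) -> None:
        closed = acc + hairpin_penalty(j - i - 1)
        if closed < best[0]:
            best[0] = closed
        for k in range(i + 1, min(i + 2 + max_interior, j - 4) + 1):
            a = k - i - 1
            for l in range(j - 1, max(k + 4, j - 1 - (max_interior - a)) - 1,
                           -1):
                if (seq[k], seq[l]) in PAIRABLE:
                    rec(k, l, acc + loop_energy(seq, i, j, k, l))

    for i, j in pairable:
        rec(i, j, 0.0)
    return best[0]


class TestFoldMfe:
    def test_clean_gc_stem_structure(self):
        fold = fold_mfe("GGGGGGGGGAAAACCCCCCCCC")
        assert fold.structure == "(((((((((....)))))))))"

    def test_gc_stem_energy_matches_hand_sum(self):
        # 8 GC/GC stacks plus the tetraloop initiation from the same tables
        expected = 8 * _STACKS["GC"]["GC"] + hairpin_penalty(4)
        fold = fold_mfe("GGGGGGGGGAAAACCCCCCCCC")
        assert fold.energy == pytest.approx(expected, abs=1e-9)
        assert fold.energy < -10.0

    def test_homopolymer_is_unfoldable(self):
        fold = fold_mfe("A" * 20)
        assert fold.structure == "." * 20
        assert fold.energy == 0.0

    def test_length_bounds_rejected(self):
        with pytest.raises(ValueError):
            fold_mfe("ACGT" * 4)            # 16 nt, below minimum
        with pytest.raises(ValueError):
            fold_mfe("ACGTACGTACGTACGTACGN")  # contains N

    def test_energy_never_positive_and_structure_valid(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            seq = "".join(rng.choice(list("ACGT"), size=60))
            fold = fold_mfe(seq)
            assert fold.energy <= 0.0
            assert len(fold.structure) == len(seq)
            table = fold.pair_table()
            for i, j in enumerate(table):
                if j >= 0:
                    assert (seq[min(i, j)], seq[max(i, j)]) in PAIRABLE

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(5)
        for _ in range(60):
            n = int(rng.integers(20, 31))
            seq = "".join(rng.choice(list("ACGT"), size=n))
            assert fold_mfe(seq).energy == pytest.approx(
                enumerate_single_stem_mfe(seq), abs=1e-9), seq

    def test_extra_stacked_gc_pair_never_raises_energy(self):
        rng = np.random.default_rng(23)
        for _ in range(10):
            seq = "".join(rng.choice(list("ACGT"), size=40))
            inner = fold_mfe(seq).energy
            outer = fold_mfe("G" + seq + "C").energy
            assert outer <= inner + 1e-9


class TestArms:
    @staticmethod
    def designed(arm: str):
        from mirmos.synthetic_data import _design_precursor
        rng = np.random.default_rng(3)
        return _design_precursor(rng, arm)

    @pytest.mark.parametrize("arm", ["5p", "3p"])
    def test_designed_duplex_star_matches_truth(self, arm):
        pre, mspan, sspan, mature, star = self.designed(arm)
        fold = fold_mfe(pre)
        located_arm, located_star = locate_arms(fold, mspan)
        assert located_arm == arm
        assert located_star == sspan
        assert pre[mspan[0]:mspan[1]] == mature
        assert pre[sspan[0]:sspan[1]] == star

    def test_mature_on_loop_has_no_arm(self):
        pre, mspan, _, _, _ = self.designed("5p")
        fold = fold_mfe(pre)
        loop = fold.loop_span
        mid_span = (loop[0] - 3, loop[1] + 3)
        arm, star = locate_arms(fold, mid_span)
        assert arm is None and star is None

    def test_unfolded_sequence_has_no_arm(self):
        fold = FoldResult("A" * 30, "." * 30, 0.0)
        assert locate_arms(fold, (2, 24)) == (None, None)


def _candidate(energy: float = -30.0, context: str = "intergenic"):
    pre, mspan, sspan, _, _ = TestArms.designed("5p")
    fold = fold_mfe(pre)
    fold = dataclasses.replace(fold, energy=energy)
    return HairpinCandidate(
        GenomicInterval("c1", 1000, 1000 + len(pre), "+"), pre, fold,
        mspan, "5p", sspan, context)


class TestCriteria:
    @staticmethod
    def stacked_reads(cand, n=50, modal=0.8, seed=0):
        rng = np.random.default_rng(seed)
        ms, me = cand.mature_span
        reads = []
        for _ in range(n):
            shift = 0 if rng.random() < modal else int(rng.choice([-1, 1]))
            reads.append(WindowRead(ms + shift, me + shift, 1))
        return reads

    def test_planted_candidate_passes_all(self):
        cand = _candidate()
        report = check_criteria(cand, self.stacked_reads(cand))
        assert (report.in_one_arm and report.duplex_clean and report.energy_ok
                and report.context_ok and report.read_stack_ok)
        assert report.passed

    def test_exonic_context_fails(self):
        cand = _candidate(context="exonic")
        report = check_criteria(cand, self.stacked_reads(cand))
        assert not report.context_ok and not report.passed

    @pytest.mark.parametrize("energy,ok", [(-19.9, False), (-20.0, False),
                                           (-20.1, True)])
    def test_energy_threshold_is_strict(self, energy, ok):
        cand = _candidate(energy=energy)
        report = check_criteria(cand, self.stacked_reads(cand))
        assert report.energy_ok is ok

    def test_passed_is_conjunction(self):
        cand = _candidate(energy=-19.9)
        report = check_criteria(cand, self.stacked_reads(cand))
        assert not report.passed


class TestReadStack:
    def test_isomir_stack_passes(self):
        cand = _candidate()
        ok, diag = read_stack_consistency(
            cand, TestCriteria.stacked_reads(cand, n=50, modal=0.8))
        assert ok
        assert diag["modal_fraction"] >= 0.7

    def test_uniform_scatter_fails(self):
        cand = _candidate()
        rng = np.random.default_rng(9)
        n = len(cand.window_seq)
        reads = [WindowRead(s, min(n, s + 22), 1)
                 for s in rng.integers(0, n - 22, size=50)]
        ok, diag = read_stack_consistency(cand, reads)
        assert not ok

    def test_minimum_support_boundary(self):
        cand = _candidate()
        reads = TestCriteria.stacked_reads(cand, n=3)
        ok, diag = read_stack_consistency(cand, reads)
        assert not ok and diag["total_reads"] == 3


class TestExtractWindow:
    GENOME = None

    @classmethod
    def genome(cls):
        if cls.GENOME is None:
            rng = np.random.default_rng(2)
            cls.GENOME = {"c1": "".join(rng.choice(list("ACGT"), size=2000))}
        return cls.GENOME

    def test_full_window_length(self):
        hit = TagHit("x" * 22, GenomicInterval("c1", 500, 522, "+"), 0)
        seq, iv, span = extract_window(hit, self.genome(), flank=100)
        assert len(seq) == 222 and span == (100, 122)
        assert (iv.start, iv.end) == (400, 622)

    def test_left_clip_at_contig_edge(self):
        hit = TagHit("x" * 22, GenomicInterval("c1", 10, 32, "+"), 0)
        seq, iv, span = extract_window(hit, self.genome(), flank=100)
        assert iv.start == 0 and span == (10, 32)

    def test_minus_strand_is_reverse_complement(self):
        g = self.genome()
        hit = TagHit("x" * 22, GenomicInterval("c1", 500, 522, "-"), 0)
        seq, iv, span = extract_window(hit, g, flank=100)
        assert seq == revcomp(g["c1"][400:622])
        assert span == (100, 122)

    def test_too_clipped_window_skipped(self):
        g = {"c1": "ACGTACGTACGTACGTACGTACGTAC"}  # 26 nt contig
        hit = TagHit("x" * 22, GenomicInterval("c1", 2, 24, "+"), 0)
        assert extract_window(hit, g, flank=100) is None


class TestDuplexCleanliness:
    def test_clean_designed_stem(self):
        pre, mspan, _, _, _ = TestArms.designed("5p")
        assert duplex_cleanliness(fold_mfe(pre), mspan)

    def test_large_loop_fails(self):
        # a hairpin whose mature side carries a 5-nt internal loop
        stem5 = "GCGCGCGC" + "AAAAA" + "GCGGCGGC"
        seq = stem5 + "AACAA" + revcomp("GCGCGCGC" + "GCGGCGGC")
        fold = fold_mfe(seq)
        assert not duplex_cleanliness(fold, (0, len(stem5)))
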