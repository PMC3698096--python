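"""Duplex scoring vs brute-force DP, Fisher/BH oracles, enrichment power."""

import functools
import math

import numpy as np
import pytest

from mirmos.io_formats import revcomp
from mirmos.targets import (GAP_EXTEND, GAP_OPEN, MATCH, MISMATCH, SEED_WEIGHT,
                            WOBBLE, go_enrichment, predict_targets,
                            score_duplex, targets_by_mirna)

WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
GU = {("G", "T"), ("T", "G")}


def oracle_best_local(mature: str, utr: str) -> float:
    """Independent recursive local-alignment oracle with affine gaps."""
    q = mature[::-1]
    L, n = len(q), len(utr)

    def sub(i, j):
        w = SEED_WEIGHT if 2 <= L - i <= 8 else 1.0
        key = (q[i], utr[j])
        base = MATCH if key in WC else (WOBBLE if key in GU else MISMATCH)
        return base * w

    @functools.lru_cache(maxsize=None)
    def state(i, j, s):
        # best score of an alignment ENDING at (i, j) in state s
        if i < 0 or j < 0:
            return -math.inf
        if s == "M":
            prev = max(0.0, state(i - 1, j - 1, "M"),
                       state(i - 1, j - 1, "X"), state(i - 1, j - 1, "Y"))
            return prev + sub(i, j)
        if s == "X":   # gap in the UTR
            return max(state(i - 1, j, "M") + GAP_OPEN,
                       state(i - 1, j, "X") + GAP_EXTEND)
        return max(state(i, j - 1, "M") + GAP_OPEN,
                   state(i, j - 1, "Y") + GAP_EXTEND)

    best = 0.0
    for i in range(L):
        for j in range(n):
            best = max(best, state(i, j, "M"))
    return best


class TestScoreDuplex:
    def test_perfect_22mer_scores_215(self):
        rng = np.random.default_rng(83)
        mature = "".join(rng.choice(list("ACGT"), size=22))
        utr = revcomp(mature)
        score, site = score_duplex(mature, utr)
        assert score == pytest.approx(215.0)
        assert site.utr_span == (0, 22)

    def test_perfect_seed_alone_scores_140(self):
        # only positions 2-8 can pair (A cannot pair A): 7 x 5 x 4 = 140
        mature = "A" + "GTGCCGA" + "A" * 14
        utr = "AAAAA" + revcomp("GTGCCGA") + "AAAAA"
        score, _ = score_duplex(mature, utr)
        assert score == pytest.approx(140.0)

    def test_matches_brute_force_dp(self):
        rng = np.random.default_rng(89)
        for _ in range(25):
            mature = "".join(rng.choice(list("ACGT"), size=22))
            n = int(rng.integers(25, 41))
            utr = "".join(rng.choice(list("ACGT"), size=n))
            if rng.random() < 0.4:   # embed a partial complement
                frag = revcomp(mature)[5:20]
                pos = int(rng.integers(0, n - len(frag)))
                utr = utr[:pos] + frag + utr[pos + len(frag):]
            got, _ = score_duplex(mature, utr)
            assert got == pytest.approx(oracle_best_local(mature, utr)), \
                (mature, utr)

    def test_shuffled_utr_rarely_reaches_cutoff(self):
        rng = np.random.default_rng(7)
        mature = "".join(rng.choice(list("ACGT"), size=22))
        utr = list(revcomp(mature) + "".join(rng.choice(list("ACGT"), 8)))
        below = 0
        for _ in range(200):
            rng.shuffle(utr)
            score, _ = score_duplex(mature, "".join(utr))
            below += score < 150.0
        assert below >= 0.95 * 200


class TestPredictTargets:
    def test_planted_perfect_site_found(self):
        rng = np.random.default_rng(97)
        mature = "".join(rng.choice(list("ACGT"), size=22))
        utr = ("".join(rng.choice(list("ACGT"), 40)) + revcomp(mature)
               + "".join(rng.choice(list("ACGT"), 40)))
        sites, _ = predict_targets({"m1": mature}, {"t1": utr})
        assert len(sites) == 1
        assert sites[0].score == pytest.approx(215.0)
        assert sites[0].utr_span == (40, 62)

    def test_no_site_above_cutoff_gives_empty(self):
        sites, _ = predict_targets({"m1": "A" * 22}, {"t1": "A" * 80})
        assert sites == []

    def test_two_disjoint_sites_both_reported(self):
        rng = np.random.default_rng(101)
        mature = "".join(rng.choice(list("ACGT"), size=22))
        spacer = "".join(rng.choice(list("ACGT"), 30))
        utr = revcomp(mature) + spacer + revcomp(mature)
        sites, _ = predict_targets({"m1": mature}, {"t1": utr})
        assert len(sites) == 2
        spans = sorted(s.utr_span for s in sites)
        assert spans[0][1] <= spans[1][0]

    def test_transcripts_without_utr_counted(self):
        sites, stats = predict_targets({"m1": "A" * 22},
                                       {"t1": "", "t2": "C" * 40})
        assert stats["transcripts_without_utr"] == 1


def hypergeom_tail(a, b, c, d) -> float:
    """P(X >= a) by direct enumeration of the hypergeometric pmf."""
    n_targets = a + b
    K = a + c             # term-positive transcripts
    N = a + b + c + d
    denom = math.comb(N, n_targets)
    return sum(math.comb(K, x) * math.comb(N - K, n_targets - x)
               for x in range(a, min(K, n_targets) + 1)) / denom


class TestGoEnrichment:
    def go_setting(self, a, b, c, d):
        targets = {f"t{i}" for i in range(a + b)}
        others = {f"o{i}" for i in range(c + d)}
        go_map = {f"t{i}": ["GO:X"] for i in range(a)}
        go_map.update({f"o{i}": ["GO:X"] for i in range(c)})
        return targets, go_map, targets | others

    def test_fisher_matches_hypergeometric_enumeration(self):
        for a, b, c, d in [(8, 2, 10, 80), (5, 15, 5, 25), (3, 0, 1, 9),
                           (10, 10, 15, 15), (3, 47, 2, 48)]:
            targets, go_map, background = self.go_setting(a, b, c, d)
            res = go_enrichment(targets, go_map, background, min_targets=3)
            assert len(res) == 1
            assert res[0].p_value == pytest.approx(
                hypergeom_tail(a, b, c, d), abs=1e-10)
            assert (res[0].a, res[0].b, res[0].c, res[0].d) == (a, b, c, d)

    def test_term_with_no_target_hits_not_tested(self):
        targets, go_map, background = self.go_setting(0, 10, 10, 80)
        assert go_enrichment(targets, go_map, background) == []

    def test_small_terms_skipped(self):
        targets, go_map, background = self.go_setting(2, 8, 10, 80)
        assert go_enrichment(targets, go_map, background, min_targets=3) == []

    def test_empty_target_set(self):
        assert go_enrichment(set(), {}, {"t1"}) == []

    def test_bh_qvalues_monotone_and_conservative(self):
        rng = np.random.default_rng(103)
        targets = {f"t{i}" for i in range(30)}
        others = {f"o{i}" for i in range(120)}
        go_map: dict[str, list[str]] = {}
        for term_i in range(12):
            term = f"GO:{term_i}"
            for t in rng.choice(sorted(targets), size=int(rng.integers(3, 12)),
                                replace=False):
                go_map.setdefault(t, []).append(term)
            for o in rng.choice(sorted(others), size=int(rng.integers(3, 40)),
                                replace=False):
                go_map.setdefault(o, []).append(term)
        res = go_enrichment(targets, go_map, targets | others, fdr=0.01)
        by_p = sorted(res, key=lambda r: r.p_value)
        qs = [r.fdr_q for r in by_p]
        assert qs == sorted(qs)
        for r in res:
            assert r.fdr_q >= r.p_value - 1e-12
        assert sum(r.significant for r in res) <= \
            sum(r.p_value < 0.01 for r in res)

    def test_planted_enrichment_detected(self):
        """80% of 40 targeted transcripts carry the term vs 10% background."""
        rng = np.random.default_rng(11)
        targets = {f"t{i}" for i in range(40)}
        others = {f"o{i}" for i in range(160)}
        go_map = {}
        for t in sorted(targets):
            if rng.random() < 0.8:
                go_map[t] = ["GO:SYN1"]
        for o in sorted(others):
            if rng.random() < 0.1:
                go_map[o] = ["GO:SYN1"]
        res = go_enrichment(targets, go_map, targets | others, fdr=0.01)
        syn = next(r for r in res if r.go_term == "GO:SYN1")
        assert syn.significant and syn.fdr_q < 0.01


class TestTargetsByMirna:
    def test_deduplication(self):
        from mirmos.targets import TargetSite
        sites = [TargetSite("m1", "t1", (0, 20), 160.0, ("", "", "")),
                 TargetSite("m1", "t1", (30, 50), 155.0, ("", "", "")),
                 TargetSite("m1", "t2", (0, 20), 151.0, ("", "", ""))]
        assert targets_by_mirna(sites) == {"m1": {"t1", "t2"}}
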