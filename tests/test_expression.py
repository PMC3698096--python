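"""Counting tolerance, expression gate, CPM identities, clustering."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import fcluster
from sklearn.metrics import adjusted_rand_score

from mirmos.expression import (ExpressionMatrix, cluster_profiles,
                               count_reads, filter_expressed, normalize_cpm,
                               stage_specificity)
from mirmos.hairpin import FoldResult, HairpinCandidate, MirnaGene
from mirmos.io_formats import GenomicInterval
from mirmos.mapping import TagHit
from mirmos.preprocess import SAMPLES, SmallRNATag
from mirmos.synthetic_data import TEMPLATES


def _gene(contig="c1", start=1000, strand="+", mature_len=22):
    pre = "A" * 200
    cand = HairpinCandidate(
        GenomicInterval(contig, start - 50, start + 150, strand), pre,
        FoldResult(pre, "." * 200, -30.0),
        (50, 50 + mature_len), "5p", (120, 142), "intergenic")
    return MirnaGene("g1", cand, "A" * mature_len, "C" * 22, True)


def _tag(seq_len, counts):
    return SmallRNATag("A" * seq_len, counts)


def _hit(tag_seq, contig, start, end, strand="+"):
    return TagHit(tag_seq, GenomicInterval(contig, start, end, strand), 0)


class TestCountReads:
    def setup_method(self):
        self.gene = _gene()           # mature at c1:[1000,1022) +
        self.mature = self.gene.mature_interval()
        assert (self.mature.start, self.mature.end) == (1000, 1022)

    def count(self, start, end, counts=(10, 0, 0, 0, 0, 0), length=22):
        tag = SmallRNATag("A" * length, counts)
        hits = {tag.sequence: [_hit(tag.sequence, "c1", start, end)]}
        m = count_reads([self.gene], hits, [tag])
        return int(m.raw.loc["g1|mature", "E"])

    def test_exact_span_counted(self):
        assert self.count(1000, 1022) == 10

    def test_isomir_within_tolerance_counted(self):
        # 5' shifted +1, 3' shifted -2
        assert self.count(1001, 1020, length=19) == 10

    def test_five_prime_beyond_tolerance_not_counted(self):
        assert self.count(1003, 1025) == 0

    def test_three_prime_beyond_tolerance_not_counted(self):
        assert self.count(1000, 1028, length=28) == 0

    def test_wrong_strand_not_counted(self):
        tag = SmallRNATag("A" * 22, (5, 0, 0, 0, 0, 0))
        hits = {tag.sequence: [_hit(tag.sequence, "c1", 1000, 1022, "-")]}
        m = count_reads([self.gene], hits, [tag])
        assert m.raw.to_numpy().sum() == 0


class TestExpressionGate:
    def matrix(self, mature_total, star_total):
        raw = pd.DataFrame(
            [[mature_total, 0, 0, 0, 0, 0], [star_total, 0, 0, 0, 0, 0]],
            index=["g1|mature", "g1|star"], columns=list(SAMPLES))
        return ExpressionMatrix(raw)

    def test_fourteen_reads_dropped(self):
        assert len(filter_expressed(self.matrix(14, 14)).raw) == 0

    def test_fifteen_mature_reads_keep_both_rows(self):
        kept = filter_expressed(self.matrix(15, 0))
        assert list(kept.raw.index) == ["g1|mature", "g1|star"]

    def test_star_only_expression_keeps_gene(self):
        kept = filter_expressed(self.matrix(0, 20))
        assert len(kept.raw) == 2


class TestCpm:
    def test_formula_arithmetic(self):
        raw = pd.DataFrame([[250] + [1] * 5, [9_999_750] + [1] * 5],
                           index=["a", "b"], columns=list(SAMPLES))
        m = normalize_cpm(ExpressionMatrix(raw))
        assert m.cpm.loc["a", "E"] == pytest.approx(25.0)

    def test_zero_raw_gives_zero_cpm(self):
        raw = pd.DataFrame([[0, 5, 5, 5, 5, 5], [10, 5, 5, 5, 5, 5]],
                           index=["a", "b"], columns=list(SAMPLES))
        m = normalize_cpm(ExpressionMatrix(raw))
        assert m.cpm.loc["a", "E"] == 0.0

    def test_columns_sum_to_one_million(self):
        rng = np.random.default_rng(61)
        raw = pd.DataFrame(rng.integers(1, 500, size=(30, 6)),
                           index=[f"r{i}" for i in range(30)],
                           columns=list(SAMPLES))
        m = normalize_cpm(ExpressionMatrix(raw))
        assert np.allclose(m.cpm.sum(axis=0), 1e6, atol=1e-6)

    def test_scale_invariance(self):
        rng = np.random.default_rng(67)
        raw = pd.DataFrame(rng.integers(1, 500, size=(10, 6)),
                           index=[f"r{i}" for i in range(10)],
                           columns=list(SAMPLES))
        a = normalize_cpm(ExpressionMatrix(raw)).cpm
        b = normalize_cpm(ExpressionMatrix(raw * 2)).cpm
        assert np.allclose(a, b)

    def test_zero_column_rejected(self):
        raw = pd.DataFrame([[1, 1, 1, 1, 1, 0]], index=["a"],
                           columns=list(SAMPLES))
        with pytest.raises(ValueError):
            normalize_cpm(ExpressionMatrix(raw))


def _cpm_matrix(rows: dict[str, list[float]]) -> ExpressionMatrix:
    raw = pd.DataFrame.from_dict(rows, orient="index", columns=list(SAMPLES))
    m = ExpressionMatrix(raw)
    m.cpm = raw.astype(float)
    return m


class TestClustering:
    def test_identical_profiles_merge_first(self):
        m = _cpm_matrix({
            "a": [100, 0, 0, 0, 0, 0], "b": [100, 0, 0, 0, 0, 0],
            "c": [0, 100, 0, 0, 0, 0], "d": [0, 0, 100, 0, 0, 0],
            "e": [0, 0, 0, 100, 0, 0],
        })
        asg = cluster_profiles(m, k=4)
        assert asg.clusters["a"] == asg.clusters["b"]
        assert asg.linkage_matrix[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_three_profile_average_linkage_oracle(self):
        """Hand-computed: (1,0,...) and (0,1,0...) vs (1,1,0...).

        With log2(x+1) transform off the correlation matrix is computable
        by hand: corr(a,b) = -0.2, corr(a,c) = corr(b,c) = 0.6325, so c
        merges with {a or b} before a merges b.
        """
        m = _cpm_matrix({"a": [1, 0, 0, 0, 0, 0], "b": [0, 1, 0, 0, 0, 0],
                         "c": [1, 1, 0, 0, 0, 0]})
        asg = cluster_profiles(m, k=2, log_transform=False)
        d_ab = 1 - np.corrcoef([1, 0, 0, 0, 0, 0], [0, 1, 0, 0, 0, 0])[0, 1]
        d_ac = 1 - np.corrcoef([1, 0, 0, 0, 0, 0], [1, 1, 0, 0, 0, 0])[0, 1]
        assert d_ac < d_ab
        # first merge joins c with one of a/b at distance d_ac
        assert asg.linkage_matrix[0, 2] == pytest.approx(d_ac)
        # cutting at k=2 leaves the other singleton on its own
        labels = [asg.clusters[r] for r in ("a", "b", "c")]
        assert len(set(labels)) == 2

    def test_permutation_invariance(self):
        rng = np.random.default_rng(71)
        rows = {f"r{i}": list(rng.integers(0, 200, size=6))
                for i in range(24)}
        m1 = _cpm_matrix(rows)
        order = list(rows)
        rng.shuffle(order)
        m2 = _cpm_matrix({k: rows[k] for k in order})
        a1 = cluster_profiles(m1, k=4).clusters
        a2 = cluster_profiles(m2, k=4).clusters
        names = list(rows)
        assert adjusted_rand_score([a1[n] for n in names],
                                   [a2[n] for n in names]) == 1.0

    def test_template_recovery(self):
        """Profiles drawn from the five stage templates are recovered."""
        rng = np.random.default_rng(73)
        rows, labels = {}, []
        for i in range(60):
            t = (i % 5) + 1
            base = np.array(TEMPLATES[t])
            noisy = base * np.exp(rng.normal(0, 0.2, size=6))
            rows[f"r{i}"] = list(1e4 * noisy / noisy.sum())
            labels.append(t)
        m = _cpm_matrix(rows)
        asg = cluster_profiles(m, k=5)
        found = [asg.clusters[f"r{i}"] for i in range(60)]
        assert adjusted_rand_score(labels, found) >= 0.9

    def test_too_few_rows_rejected(self):
        m = _cpm_matrix({"a": [1, 0, 0, 0, 0, 0]})
        with pytest.raises(ValueError):
            cluster_profiles(m, k=5)

    def test_zero_variance_row_handled(self):
        m = _cpm_matrix({"a": [5, 5, 5, 5, 5, 5], "b": [1, 0, 0, 0, 0, 0],
                         "c": [0, 1, 0, 0, 0, 0], "d": [0, 0, 1, 0, 0, 0],
                         "e": [0, 0, 0, 1, 0, 0]})
        asg = cluster_profiles(m, k=5, log_transform=False)
        assert set(asg.clusters) == set("abcde")


class TestStageSpecificity:
    def test_majority_sample_labelled(self):
        row = pd.Series([900, 25, 25, 25, 12.5, 12.5], index=list(SAMPLES))
        label, blood = stage_specificity(row)
        assert label == "embryo"

    def test_blood_up(self):
        row = pd.Series([0, 0, 0, 0, 100, 300], index=list(SAMPLES))
        _, blood = stage_specificity(row)
        assert blood == "up"

    def test_blood_down(self):
        row = pd.Series([0, 0, 0, 0, 300, 100], index=list(SAMPLES))
        _, blood = stage_specificity(row)
        assert blood == "down"

    def test_uniform_is_shared(self):
        row = pd.Series([10.0] * 6, index=list(SAMPLES))
        label, blood = stage_specificity(row)
        assert label == "shared" and blood == "none"

    def test_all_zero_is_none(self):
        row = pd.Series([0.0] * 6, index=list(SAMPLES))
        assert stage_specificity(row) == ("none", "none")

    def test_low_abundance_blood_change_ignored(self):
        row = pd.Series([100, 100, 100, 100, 2, 8], index=list(SAMPLES))
        _, blood = stage_specificity(row)
        assert blood == "none"
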