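"""Expression quantification and stage-profile clustering.

Reads are counted per mature/star arm with isomiR tolerance (5' end within
2 nt, 3' end within 5 nt of the annotated span), genes pass an
at-least-15-pooled-reads expression gate (on either arm), counts are
normalized to counts-per-million of each sample's total assigned counts,
and profiles are clustered hierarchically with average linkage on
1 - Pearson correlation of log2(CPM + 1).
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from . import config
from .preprocess import SAMPLES

log = logging.getLogger("mirmos.expression")


@dataclasses.dataclass
class ExpressionMatrix:
    """miRNA/miRNA* rows x six samples, raw counts and CPM."""

    raw: pd.DataFrame                  # integer counts
    cpm: pd.DataFrame | None = None

    @property
    def rows(self) -> list[str]:
        return list(self.raw.index)


def _ends(interval) -> tuple[int, int]:
    """(five_prime, three_prime) genomic coordinates of an interval."""
    if interval.strand == "+":
        return interval.start, interval.end
    return interval.end, interval.start


def count_reads(genes, hits_by_tag, tags,
                tol5: int = config.ISOMIR_5P_TOL,
                tol3: int = config.ISOMIR_3P_TOL) -> ExpressionMatrix:
    """Raw count matrix with mature and star counted as separate rows.

    A tag hit counts toward an arm when it is on the same strand and its
    5' end is within ``tol5`` nt and its 3' end within ``tol3`` nt of the
    annotated span.  A hit eligible for both arms is assigned to the one
    with the nearer 5' end.
    """
    spans = []   # (contig, strand, five, three, row_index)
    row_ids = []
    for g in genes:
        for arm_name, iv in (("mature", g.mature_interval()),
                             ("star", g.star_interval())):
            if iv is None:
                continue
            five, three = _ends(iv)
            spans.append((iv.contig_id, iv.strand, five, three,
                          len(row_ids)))
            row_ids.append(f"{g.gene_id}|{arm_name}")
    by_key: dict[tuple[str, str], list] = {}
    for contig, strand, five, three, ridx in spans:
        by_key.setdefault((contig, strand), []).append((five, three, ridx))

    counts = np.zeros((len(row_ids), len(SAMPLES)), dtype=int)
    tag_counts = {t.sequence: t.counts for t in tags}
    ambiguous = 0
    for tag_seq, hits in hits_by_tag.items():
        cvec = tag_counts.get(tag_seq)
        if cvec is None:
            continue
        for h in hits:
            iv = h.interval
            cand = by_key.get((iv.contig_id, iv.strand))
            if not cand:
                continue
            h5, h3 = _ends(iv)
            eligible = [(abs(h5 - five), ridx)
                        for five, three, ridx in cand
                        if abs(h5 - five) <= tol5 and abs(h3 - three) <= tol3]
            if not eligible:
                continue
            if len(eligible) > 1:
                ambiguous += 1
                eligible.sort()
            counts[eligible[0][1]] += np.asarray(cvec)
    if ambiguous:
        log.info("count_reads: %d hits eligible for both arms, assigned to "
                 "the nearer 5' end", ambiguous)
    raw = pd.DataFrame(counts, index=row_ids, columns=list(SAMPLES))
    return ExpressionMatrix(raw)


def filter_expressed(matrix: ExpressionMatrix,
                     min_reads: int = config.EXPR_MIN_READS
                     ) -> ExpressionMatrix:
    """Keep genes whose mature OR star has >= min_reads pooled raw reads.

    Both rows of a retained gene are kept.
    """
    totals = matrix.raw.sum(axis=1)
    gene_best: dict[str, int] = {}
    for row_id, total in totals.items():
        gene = row_id.rsplit("|", 1)[0]
        gene_best[gene] = max(gene_best.get(gene, 0), int(total))
    keep = [rid for rid in matrix.raw.index
            if gene_best[rid.rsplit("|", 1)[0]] >= min_reads]
    return ExpressionMatrix(matrix.raw.loc[keep].copy())


def normalize_cpm(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """CPM: count / sample total counted reads x 1e6, computed exactly."""
    colsums = matrix.raw.sum(axis=0)
    zero = [s for s in matrix.raw.columns if colsums[s] == 0]
    if zero:
        raise ValueError(f"zero column sum for samples: {zero}")
    matrix.cpm = matrix.raw / colsums * 1.0e6
    return matrix


@dataclasses.dataclass
class ClusterAssignment:
    clusters: dict[str, int]           # row id -> 1..k
    linkage_matrix: np.ndarray


def _correlation_distance(data: np.ndarray) -> np.ndarray:
    """1 - Pearson correlation between rows; rows with zero variance get
    distance 1 to every other row (correlation undefined)."""
    n = data.shape[0]
    sd = data.std(axis=1)
    dist = np.ones((n, n))
    np.fill_diagonal(dist, 0.0)
    ok = sd > 0
    if ok.sum() >= 2:
        sub = data[ok]
        corr = np.corrcoef(sub)
        idx = np.nonzero(ok)[0]
        dist[np.ix_(idx, idx)] = np.clip(1.0 - corr, 0.0, 2.0)
        np.fill_diagonal(dist, 0.0)
    if (~ok).any():
        log.info("cluster_profiles: %d zero-variance rows assigned "
                 "distance 1", int((~ok).sum()))
    return dist


def cluster_profiles(matrix: ExpressionMatrix,
                     k: int = config.K_CLUSTERS,
                     log_transform: bool = True) -> ClusterAssignment:
    """Average-linkage hierarchical clustering of stage profiles.

    Rows are log2(CPM+1)-transformed, compared by Pearson correlation
    distance, and the tree is cut into exactly k clusters.
    """
    if matrix.cpm is None:
        raise ValueError("normalize_cpm must run before clustering")
    if len(matrix.cpm) < k:
        raise ValueError(f"need at least k={k} rows to cut {k} clusters")
    data = matrix.cpm.to_numpy(dtype=float)
    if log_transform:
        data = np.log2(data + 1.0)
    dist = _correlation_distance(data)
    Z = linkage(squareform(dist, checks=False), method="average")
    labels = fcluster(Z, t=k, criterion="maxclust")
    return ClusterAssignment(dict(zip(matrix.cpm.index, map(int, labels))),
                             Z)


def stage_specificity(row_cpm: pd.Series,
                      fraction: float = config.SPECIFICITY_FRACTION,
                      blood_fold: float = config.BLOOD_FOLD,
                      blood_min_cpm: float = config.BLOOD_MIN_CPM,
                      ) -> tuple[str, str]:
    """(stage label, blood-meal flag) for one expression row.

    The stage label is the sample holding at least half the row's total
    CPM, "shared" otherwise, "none" for an all-zero row.  The blood flag
    compares blood-fed (B) and sugar-fed (F) females at a minimum
    abundance.
    """
    total = float(row_cpm.sum())
    if total == 0:
        return "none", "none"
    frac = row_cpm / total
    label = "shared"
    top = frac.idxmax()
    if frac[top] >= fraction:
        label = {"E": "embryo", "L": "larva", "P": "pupa", "M": "male",
                 "F": "female", "B": "blood_fed"}[top]
    b, f = float(row_cpm["B"]), float(row_cpm["F"])
    blood = "none"
    if b >= blood_fold * f and b >= blood_min_cpm:
        blood = "up"
    elif f >= blood_fold * b and f >= blood_min_cpm:
        blood = "down"
    return label, blood


def write_expression_tsv(matrix: ExpressionMatrix, path) -> None:
    df = matrix.raw.copy()
    if matrix.cpm is not None:
        for s in SAMPLES:
            df[f"cpm_{s}"] = matrix.cpm[s].round(3)
    df.index.name = "row_id"
    df.to_csv(path, sep="\t")


def write_clusters_tsv(matrix: ExpressionMatrix,
                       assignment: ClusterAssignment, path) -> None:
    rows = []
    for rid in matrix.cpm.index:
        label, blood = stage_specificity(matrix.cpm.loc[rid])
        rows.append({"row_id": rid, "cluster": assignment.clusters[rid],
                     "specificity": label, "blood_flag": blood})
    from .io_formats import write_tsv
    write_tsv(rows, path, ["row_id", "cluster", "specificity", "blood_flag"])
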