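"""Seed-weighted 3' UTR target prediction and GO term enrichment.

Target sites are scored by local alignment of the mature miRNA (antisense,
3'->5') against the UTR with miRanda-style constants: Watson-Crick pair +5,
G:U wobble +1, mismatch -3, gap open -9, gap extend -4, and a 4x weight on
miRNA positions 2-8 (the seed).  A perfect 22-nt complement scores 215;
sites at or above the cutoff (150) are emitted.  Per expression cluster,
target transcripts are tested for GO term over-representation with
one-sided Fisher's exact tests and Benjamini-Hochberg FDR control.
"""

from __future__ import annotations

import dataclasses
import logging

from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from . import config

log = logging.getLogger("mirmos.targets")

MATCH = 5.0
WOBBLE = 1.0
MISMATCH = -3.0
GAP_OPEN = -9.0
GAP_EXTEND = -4.0
SEED_WEIGHT = 4.0
SEED_RANGE = (2, 8)        # 1-based positions from the miRNA 5' end

_WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_GU = {("G", "T"), ("T", "G")}   # mature G : UTR U and mature U : UTR G

NEG_INF = float("-inf")


@dataclasses.dataclass(frozen=True)
class TargetSite:
    mirna_id: str
    transcript_id: str
    utr_span: tuple[int, int]      # half-open within the UTR
    score: float
    duplex: tuple[str, str, str]   # miRNA 3'->5', pairing line, UTR 5'->3'


def _pair_score(m_base: str, u_base: str, weight: float) -> float:
    key = (m_base, u_base)
    if key in _WC:
        return MATCH * weight
    if key in _GU:
        return WOBBLE * weight
    return MISMATCH * weight


def score_duplex(mature_seq: str, utr_window: str
                 ) -> tuple[float, TargetSite | None]:
    """Best local duplex between a mature miRNA and a UTR window.

    Affine-gap Smith-Waterman over the reversed mature (so the miRNA runs
    3'->5' against the UTR 5'->3'), with the per-position substitution
    score multiplied by 4 at miRNA positions 2-8.  Returns the maximum
    score and the corresponding site (None when nothing aligns).
    """
    q = mature_seq[::-1]            # q[i] is miRNA position len-i (1-based)
    L, n = len(q), len(utr_window)
    weights = [SEED_WEIGHT if SEED_RANGE[0] <= L - i <= SEED_RANGE[1]
               else 1.0 for i in range(L)]
    # M: q[i-1] aligned to u[j-1]; X: gap in UTR; Y: gap in miRNA
    M = [[0.0] * (n + 1) for _ in range(L + 1)]
    X = [[NEG_INF] * (n + 1) for _ in range(L + 1)]
    Y = [[NEG_INF] * (n + 1) for _ in range(L + 1)]
    best, best_cell = 0.0, None
    for i in range(1, L + 1):
        mi = q[i - 1]
        wi = weights[i - 1]
        Mi, Mi1 = M[i], M[i - 1]
        Xi, Xi1 = X[i], X[i - 1]
        Yi = Y[i]
        for j in range(1, n + 1):
            s = _pair_score(mi, utr_window[j - 1], wi)
            prev = max(Mi1[j - 1], Xi1[j - 1], Y[i - 1][j - 1], 0.0)
            m = prev + s
            Mi[j] = m if m > 0 else 0.0
            x = max(Mi1[j] + GAP_OPEN, Xi1[j] + GAP_EXTEND)
            Xi[j] = x
            y = max(Mi[j - 1] + GAP_OPEN, Yi[j - 1] + GAP_EXTEND)
            Yi[j] = y
            if Mi[j] > best:
                best, best_cell = Mi[j], (i, j)
    if best_cell is None:
        return 0.0, None
    # traceback through match cells only is enough to recover the span
    i, j = best_cell
    mline, pline, uline = [], [], []
    state = "M"
    while i > 0 and j > 0:
        if state == "M":
            if M[i][j] <= 0:
                break
            s = _pair_score(q[i - 1], utr_window[j - 1], weights[i - 1])
            mline.append(q[i - 1])
            uline.append(utr_window[j - 1])
            key = (q[i - 1], utr_window[j - 1])
            pline.append("|" if key in _WC else
                         (":" if key in _GU else " "))
            prev = M[i][j] - s
            i, j = i - 1, j - 1
            if abs(prev) < 1e-9:
                break
            if abs(X[i][j] - prev) < 1e-9:
                state = "X"
            elif abs(Y[i][j] - prev) < 1e-9:
                state = "Y"
        elif state == "X":
            mline.append(q[i - 1])
            uline.append("-")
            pline.append(" ")
            up = X[i][j]
            i -= 1
            state = "X" if abs(X[i][j] + GAP_EXTEND - up) < 1e-9 else "M"
        else:
            mline.append("-")
            uline.append(utr_window[j - 1])
            pline.append(" ")
            left = Y[i][j]
            j -= 1
            state = "Y" if abs(Y[i][j] + GAP_EXTEND - left) < 1e-9 else "M"
    span = (j, best_cell[1])
    site = TargetSite("query", ".", span, best,
                      ("".join(reversed(mline)), "".join(reversed(pline)),
                       "".join(reversed(uline))))
    return best, site


def predict_targets(mirna_seqs: dict[str, str], utrs: dict[str, str],
                    cutoff: float = config.TARGET_CUTOFF
                    ) -> tuple[list[TargetSite], dict]:
    """Non-overlapping target sites at or above the cutoff, per miRNA x UTR.

    The best site is found, masked, and the search repeated until the best
    remaining score drops below the cutoff.  Transcripts without a UTR
    sequence are skipped and counted.
    """
    sites: list[TargetSite] = []
    skipped = sum(1 for seq in utrs.values() if not seq)
    for mid, mseq in sorted(mirna_seqs.items()):
        for tid, utr in sorted(utrs.items()):
            if not utr or len(utr) < len(mseq):
                continue
            masked = utr
            for _ in range(20):    # safety bound on sites per UTR
                score, site = score_duplex(mseq, masked)
                if site is None or score < cutoff:
                    break
                s, e = site.utr_span
                sites.append(dataclasses.replace(
                    site, mirna_id=mid, transcript_id=tid))
                masked = masked[:s] + "N" * (e - s) + masked[e:]
    if skipped:
        log.info("predict_targets: %d transcripts lack an annotated 3' UTR",
                 skipped)
    return sites, {"transcripts_without_utr": skipped}


def targets_by_mirna(sites: list[TargetSite]) -> dict[str, set[str]]:
    """Deduplicated target transcript sets per miRNA."""
    out: dict[str, set[str]] = {}
    for s in sites:
        out.setdefault(s.mirna_id, set()).add(s.transcript_id)
    return out


@dataclasses.dataclass
class EnrichmentResult:
    go_term: str
    cluster: int
    a: int       # targets with the term
    b: int       # targets without
    c: int       # background non-targets with the term
    d: int       # background non-targets without
    p_value: float
    fdr_q: float
    significant: bool


def go_enrichment(target_tids: set[str], go_map: dict[str, list[str]],
                  background_tids: set[str],
                  fdr: float = config.GO_FDR,
                  min_targets: int = config.GO_MIN_TARGETS,
                  cluster: int = 0) -> list[EnrichmentResult]:
    """One-sided Fisher over-representation tests per GO term.

    The background is the set of transcripts with an annotated 3' UTR (the
    universe targets are drawn from); terms carried by fewer than
    ``min_targets`` target transcripts are not tested.  Benjamini-Hochberg
    adjustment runs across the tested terms; significant means q < fdr.
    """
    targets = target_tids & background_tids
    if not targets:
        return []
    others = background_tids - targets
    term_targets: dict[str, int] = {}
    term_background: dict[str, int] = {}
    for tid in background_tids:
        for term in go_map.get(tid, ()):
            term_background[term] = term_background.get(term, 0) + 1
            if tid in targets:
                term_targets[term] = term_targets.get(term, 0) + 1
    tested = sorted(t for t, a in term_targets.items() if a >= min_targets)
    if not tested:
        return []
    results = []
    pvals = []
    for term in tested:
        a = term_targets[term]
        b = len(targets) - a
        c = term_background[term] - a
        d = len(others) - c
        _, p = fisher_exact([[a, b], [c, d]], alternative="greater")
        pvals.append(p)
        results.append(EnrichmentResult(term, cluster, a, b, c, d, p, 1.0,
                                        False))
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    for r, q in zip(results, qvals):
        r.fdr_q = float(q)
        r.significant = q < fdr
    return sorted(results, key=lambda r: (r.p_value, r.go_term))


def enrichment_by_cluster(sites: list[TargetSite],
                          mirna_clusters: dict[str, int],
                          go_map: dict[str, list[str]],
                          background_tids: set[str],
                          fdr: float = config.GO_FDR
                          ) -> list[EnrichmentResult]:
    """Run the GO test separately for the targets of each expression cluster."""
    per_mirna = targets_by_mirna(sites)
    by_cluster: dict[int, set[str]] = {}
    for mid, tids in per_mirna.items():
        cl = mirna_clusters.get(mid)
        if cl is None:
            continue
        by_cluster.setdefault(cl, set()).update(tids)
    out: list[EnrichmentResult] = []
    for cl in sorted(by_cluster):
        out.extend(go_enrichment(by_cluster[cl], go_map, background_tids,
                                 fdr=fdr, cluster=cl))
    return out


def read_go_map(path) -> dict[str, list[str]]:
    go_map: dict[str, list[str]] = {}
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            tid, _, terms = line.rstrip("\n").partition("\t")
            go_map[tid] = [t for t in terms.split(";") if t]
    return go_map


def write_targets_tsv(sites: list[TargetSite], path) -> None:
    from .io_formats import write_tsv
    rows = [{"mirna": s.mirna_id, "transcript": s.transcript_id,
             "start": s.utr_span[0], "end": s.utr_span[1],
             "score": round(s.score, 1)} for s in sites]
    write_tsv(rows, path, ["mirna", "transcript", "start", "end", "score"])


def write_enrichment_tsv(results: list[EnrichmentResult], path) -> None:
    from .io_formats import write_tsv
    rows = [{"cluster": r.cluster, "go_term": r.go_term, "a": r.a, "b": r.b,
             "c": r.c, "d": r.d, "p_value": f"{r.p_value:.6g}",
             "fdr_q": f"{r.fdr_q:.6g}", "significant": r.significant}
            for r in results]
    write_tsv(rows, path, ["cluster", "go_term", "a", "b", "c", "d",
                           "p_value", "fdr_q", "significant"])
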