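"""Pre-miRNA hairpin discovery.

The core inference of the pipeline: windows of genomic context around mapped
small-RNA loci are folded with a built-in single-stem minimum-free-energy
folder, and each candidate is judged against the classic stem-loop criteria
(mature on one arm of a clean duplex, fold energy below -20 kcal/mol,
intergenic or intronic context) plus a read-stack consistency check that the
observed reads pile up the way Dicer products do.

The folder is a nearest-neighbour dynamic program restricted to single
hairpins (no multibranch loops): stacks, bulges and internal loops between
consecutive pairs of one helix, closed by a terminal hairpin loop.  That is
exactly the structure space a pre-miRNA is evaluated in, and the restriction
makes the model small enough to embed its parameter tables directly.
"""

from __future__ import annotations

import dataclasses
import functools
import logging
import math
from typing import Iterable, Sequence

import numba
import numpy as np

from . import config
from .io_formats import AnnotationSet, GenomicInterval, revcomp

log = logging.getLogger("mirmos.hairpin")

# --- energy model ------------------------------------------------------------
#
# Nearest-neighbour parameters in kcal/mol at 37 C, RNA alphabet with T
# standing in for U.  Pairs allowed: Watson-Crick plus G:U wobble.

_ENC = {"A": 0, "C": 1, "G": 2, "T": 3}
_BASES = "ACGT"

# pair codes: 4*i + j for the 6 allowed pairs
_ALLOWED = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"),
            ("G", "T"), ("T", "G")}
OK_PAIR = [False] * 16
for _a, _b in _ALLOWED:
    OK_PAIR[4 * _ENC[_a] + _ENC[_b]] = True

# stacking energies: row = outer pair 5'X...Y3', column = inner pair stacked
# on it.  Keys written in RNA convention (AU == A:T here).
_STACKS = {
    "AT": {"AT": -0.9, "CG": -2.2, "GC": -2.1, "GT": -0.6, "TA": -1.1, "TG": -1.4},
    "CG": {"AT": -2.1, "CG": -3.3, "GC": -2.4, "GT": -1.4, "TA": -2.1, "TG": -2.1},
    "GC": {"AT": -2.4, "CG": -3.4, "GC": -3.3, "GT": -1.5, "TA": -2.2, "TG": -2.5},
    "GT": {"AT": -1.3, "CG": -2.5, "GC": -2.1, "GT": -0.5, "TA": -1.4, "TG": 1.3},
    "TA": {"AT": -1.3, "CG": -2.4, "GC": -2.1, "GT": -1.0, "TA": -0.9, "TG": -1.3},
    "TG": {"AT": -1.0, "CG": -1.5, "GC": -1.4, "GT": 0.3, "TA": -0.6, "TG": -0.5},
}

# loop initiation penalties by size; larger loops extrapolated with the
# Jacobson-Stockmayer log term, 1.75 * RT * ln(n / n_ref), RT = 0.616.
_RT175 = 1.75 * 0.616
_HAIRPIN = {3: 5.4, 4: 5.6, 5: 5.7, 6: 5.4, 7: 6.0, 8: 5.5, 9: 6.4}
_BULGE = {1: 3.8, 2: 2.8, 3: 3.2, 4: 3.6, 5: 4.0, 6: 4.4}
_INTERNAL = {2: 1.5, 3: 1.6, 4: 1.7, 5: 2.0, 6: 2.1, 7: 2.3, 8: 2.5,
             9: 2.6, 10: 2.8}
_ASYM = 0.5          # per-nt internal-loop asymmetry penalty
_ASYM_CAP = 3.0
MAX_INTERIOR = 10    # max unpaired bases between consecutive helix pairs
MIN_HAIRPIN_LOOP = 3
MIN_FOLD_LEN = 20
MAX_FOLD_LEN = 400


def hairpin_penalty(size: int) -> float:
    if size in _HAIRPIN:
        return _HAIRPIN[size]
    return _HAIRPIN[9] + _RT175 * math.log(size / 9.0)


def bulge_penalty(size: int) -> float:
    if size in _BULGE:
        return _BULGE[size]
    return _BULGE[6] + _RT175 * math.log(size / 6.0)


def internal_penalty(size: int) -> float:
    if size in _INTERNAL:
        return _INTERNAL[size]
    return _INTERNAL[10] + _RT175 * math.log(size / 10.0)


def loop_energy(seq: str, i: int, j: int, k: int, l: int) -> float:
    """Energy of the loop between helix pairs (i,j) and the inner (k,l)."""
    a, b = k - i - 1, j - l - 1
    if a == 0 and b == 0:
        return _STACKS[seq[i] + seq[j]][seq[k] + seq[l]]
    if a == 0 or b == 0:
        return bulge_penalty(a + b)
    return internal_penalty(a + b) + min(_ASYM * abs(a - b), _ASYM_CAP)


# flat 16x16 stack table for the DP inner loop
_STACK16 = [math.inf] * 256
for _po in range(16):
    if OK_PAIR[_po]:
        _row = _STACKS[_BASES[_po // 4] + _BASES[_po % 4]]
        for _pi in range(16):
            if OK_PAIR[_pi]:
                _STACK16[_po * 16 + _pi] = _row[_BASES[_pi // 4] + _BASES[_pi % 4]]

_BULGE_PEN = [0.0] + [bulge_penalty(s) for s in range(1, MAX_INTERIOR + 1)]
_INTL_PEN = [0.0, 0.0] + [internal_penalty(s)
                          for s in range(2, 2 * MAX_INTERIOR + 1)]
_ASYM_PEN = [min(_ASYM * d, _ASYM_CAP) for d in range(MAX_INTERIOR + 1)]

_INF = math.inf


# --- fold result -------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class FoldResult:
    sequence: str
    structure: str
    energy: float

    def pair_table(self) -> list[int]:
        """partner index per position, -1 if unpaired."""
        table = [-1] * len(self.structure)
        stack: list[int] = []
        for i, c in enumerate(self.structure):
            if c == "(":
                stack.append(i)
            elif c == ")":
                j = stack.pop()
                table[i], table[j] = j, i
        return table

    @property
    def loop_span(self) -> tuple[int, int] | None:
        """Half-open span of the terminal hairpin loop, None if unfolded."""
        opens = [i for i, c in enumerate(self.structure) if c == "("]
        closes = [i for i, c in enumerate(self.structure) if c == ")"]
        if not opens:
            return None
        return opens[-1] + 1, closes[0]


_OK_PAIR_ARR = np.array(OK_PAIR, dtype=np.bool_)
_STACK16_ARR = np.array(_STACK16, dtype=np.float64)
_BULGE_ARR = np.array(_BULGE_PEN, dtype=np.float64)
_INTL_ARR = np.array(_INTL_PEN, dtype=np.float64)
_ASYM_ARR = np.array(_ASYM_PEN, dtype=np.float64)
_HAIRPIN_ARR = np.array([0.0] * MIN_HAIRPIN_LOOP
                        + [hairpin_penalty(s)
                           for s in range(MIN_HAIRPIN_LOOP, MAX_FOLD_LEN + 1)],
                        dtype=np.float64)


@numba.njit(cache=True)
def _fold_core(enc, n, max_interior, ok_pair, stack16, bulge_pen, intl_pen,
               asym_pen, hairpin_pen):      # pragma: no cover - jitted
    E = np.full(n * n, np.inf)
    back = np.full(n * n, -1, dtype=np.int64)
    gbest = 0.0
    groot = -1
    for d in range(MIN_HAIRPIN_LOOP + 1, n):
        for i in range(n - d):
            j = i + d
            pc_out = 4 * enc[i] + enc[j]
            if not ok_pair[pc_out]:
                continue
            best = hairpin_pen[d - 1]
            bk = -1
            kmax = min(i + 1 + max_interior, j - MIN_HAIRPIN_LOOP - 1)
            row = pc_out * 16
            for k in range(i + 1, kmax + 1):
                a = k - i - 1
                ck4 = 4 * enc[k]
                lmin = max(k + MIN_HAIRPIN_LOOP + 1,
                           j - 1 - (max_interior - a))
                for l in range(j - 1, lmin - 1, -1):
                    e_in = E[k * n + l]
                    if e_in == np.inf:
                        continue
                    b = j - 1 - l
                    if a == 0 and b == 0:
                        le = stack16[row + ck4 + enc[l]]
                    elif a == 0 or b == 0:
                        le = bulge_pen[a + b]
                    else:
                        le = intl_pen[a + b] + asym_pen[abs(a - b)]
                    t = e_in + le
                    if t < best:
                        best = t
                        bk = k * n + l
            idx = i * n + j
            E[idx] = best
            back[idx] = bk
            if best < gbest:
                gbest = best
                groot = idx
    return gbest, groot, back


@functools.lru_cache(maxsize=8192)
def fold_mfe(sequence: str, max_interior: int = MAX_INTERIOR) -> FoldResult:
    """Minimum-free-energy single-hairpin structure of *sequence*.

    Dynamic program over closing pairs: ``E(i,j)`` is the best energy of a
    single-stem structure closed by the pair (i, j); the global optimum also
    allows the empty structure at 0 kcal/mol, so the reported energy is
    never positive.  Results are memoized: folding is pure and the same
    windows recur across pipeline stages.
    """
    n = len(sequence)
    if not (MIN_FOLD_LEN <= n <= MAX_FOLD_LEN):
        raise ValueError(f"fold_mfe: length {n} outside "
                         f"[{MIN_FOLD_LEN}, {MAX_FOLD_LEN}]")
    if "N" in sequence:
        raise ValueError("fold_mfe: sequence contains N")
    enc = np.array([_ENC[c] for c in sequence], dtype=np.int64)
    gbest, groot, back = _fold_core(
        enc, n, max_interior, _OK_PAIR_ARR, _STACK16_ARR, _BULGE_ARR,
        _INTL_ARR, _ASYM_ARR, _HAIRPIN_ARR)
    structure = ["."] * n
    idx = int(groot)
    while idx >= 0:
        structure[idx // n] = "("
        structure[idx % n] = ")"
        idx = int(back[idx])
    return FoldResult(sequence, "".join(structure), round(float(gbest), 10))


# --- candidate types ---------------------------------------------------------

@dataclasses.dataclass
class HairpinCandidate:
    window_interval: GenomicInterval
    window_seq: str
    fold: FoldResult
    mature_span: tuple[int, int]        # window-local, half-open
    arm: str | None                     # "5p", "3p" or None
    star_span: tuple[int, int] | None
    context: str                        # intergenic / intronic / exonic


@dataclasses.dataclass
class CriteriaReport:
    in_one_arm: bool
    duplex_clean: bool
    energy_ok: bool
    context_ok: bool
    read_stack_ok: bool

    @property
    def passed(self) -> bool:
        return (self.in_one_arm and self.duplex_clean and self.energy_ok
                and self.context_ok and self.read_stack_ok)


@dataclasses.dataclass
class MirnaGene:
    gene_id: str
    precursor: HairpinCandidate
    mature_seq: str
    star_seq: str | None
    star_observed: bool
    lineage: str | None = None

    def _local_to_genomic(self, span: tuple[int, int]) -> GenomicInterval:
        w = self.precursor.window_interval
        s, e = span
        if w.strand == "+":
            return GenomicInterval(w.contig_id, w.start + s, w.start + e, "+")
        return GenomicInterval(w.contig_id, w.end - e, w.end - s, "-")

    def mature_interval(self) -> GenomicInterval:
        return self._local_to_genomic(self.precursor.mature_span)

    def star_interval(self) -> GenomicInterval | None:
        if self.precursor.star_span is None:
            return None
        return self._local_to_genomic(self.precursor.star_span)


# --- window extraction -------------------------------------------------------

def extract_window(hit, genome: dict[str, str], flank: int = config.FLANK):
    """Genomic window of ``flank`` nt on each side of a mapped tag locus.

    Returns ``(sequence, interval, mature_local_span)`` with the sequence
    oriented so the tag reads 5'->3' (minus-strand hits are
    reverse-complemented).  Returns None when clipping at a contig edge
    leaves too little context to judge a hairpin.
    """
    iv = hit.interval
    contig = genome[iv.contig_id]
    wstart = max(0, iv.start - flank)
    wend = min(len(contig), iv.end + flank)
    if wend - wstart < len(iv) + 20:
        log.info("extract_window: %s:%d-%d skipped, clipped window too short",
                 iv.contig_id, iv.start, iv.end)
        return None
    seq = contig[wstart:wend]
    if iv.strand == "+":
        span = (iv.start - wstart, iv.end - wstart)
    else:
        seq = revcomp(seq)
        span = (wend - iv.end, wend - iv.start)
    window = GenomicInterval(iv.contig_id, wstart, wend, iv.strand)
    return seq, window, span


# --- arm / star geometry -----------------------------------------------------

def _nearest_paired(table: list[int], pos: int, lo: int, hi: int,
                    step: int) -> int | None:
    p = pos
    while lo <= p < hi:
        if table[p] >= 0:
            return p
        p += step
    return None


def locate_arms(fold: FoldResult, mature_span: tuple[int, int]
                ) -> tuple[str | None, tuple[int, int] | None]:
    """Assign the mature span to a hairpin arm and predict the star span.

    The mature must lie entirely on one side of the terminal loop; the star
    is the duplex partner shifted to leave the canonical 2-nt 3' overhangs
    on both ends.  Returns (None, None) when the fold has no stem or the
    mature crosses the loop.
    """
    loop = fold.loop_span
    if loop is None:
        return None, None
    ms, me = mature_span
    loop_start, loop_end = loop
    if me <= loop_start:
        arm = "5p"
    elif ms >= loop_end:
        arm = "3p"
    else:
        return None, None

    table = fold.pair_table()
    n = len(table)
    # anchor on the pairing partners of the mature 5' end and of the base
    # two in from the mature 3' end (the 2-nt overhang rule)
    p5 = _nearest_paired(table, ms, ms, me, +1)
    p3 = _nearest_paired(table, me - 3, ms, me, -1)
    if p5 is None or p3 is None:
        return arm, None
    lo = table[p3] - (me - 3 - p3)
    hi = table[p5] + (p5 - ms) + 3
    star = (max(0, min(lo, hi - 1)), min(n, max(hi, lo + 1)))
    if star[1] - star[0] < 15 or _spans_overlap(star, mature_span):
        return arm, None
    return arm, star


def _spans_overlap(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


# --- criteria ----------------------------------------------------------------

def duplex_cleanliness(fold: FoldResult, mature_span: tuple[int, int],
                       max_unpaired: int = config.MAX_UNPAIRED_MATURE,
                       max_loop: int = config.MAX_DUPLEX_LOOP) -> bool:
    """No large internal loops or mismatches in the mature-star duplex.

    The mature's paired positions are split into helix runs wherever the
    bulge/internal loop to the next pair exceeds ``max_loop`` on either
    strand; everything outside the longest clean run (mismatches, large
    loops, breathing helix ends pairing off-duplex) counts as unpaired,
    and at most ``max_unpaired`` such bases are tolerated.
    """
    ms, me = mature_span
    table = fold.pair_table()
    paired = [i for i in range(ms, me) if table[i] >= 0]
    if not paired:
        return False
    runs: list[list[int]] = [[paired[0]]]
    for prev, cur in zip(paired, paired[1:]):
        gap_mature = cur - prev - 1
        gap_star = abs(table[prev] - table[cur]) - 1
        if gap_mature > max_loop or gap_star > max_loop:
            runs.append([])
        runs[-1].append(cur)
    longest = max(len(r) for r in runs)
    return (me - ms) - longest <= max_unpaired


@dataclasses.dataclass(frozen=True)
class WindowRead:
    """A tag occurrence inside a candidate window, window-local coordinates."""
    start: int
    end: int
    count: int


def read_stack_consistency(candidate: HairpinCandidate,
                           reads: Sequence[WindowRead],
                           min_reads: int = config.MIN_STACK_READS,
                           modal_fraction: float = config.MODAL_5P_FRACTION,
                           max_outside: float = config.MAX_OUTSIDE_FRACTION,
                           ) -> tuple[bool, dict]:
    """Do the mapped reads pile up like Dicer products?

    Requires enough total reads, a dominant (modal) 5' end among mature-arm
    reads, reads confined to the two arms, and -- when star reads exist --
    a star 5' end consistent with the predicted duplex (within 1 nt).
    """
    diag: dict = {"total_reads": 0, "modal_fraction": 0.0,
                  "outside_fraction": 0.0, "star_reads": 0}
    loop = candidate.fold.loop_span
    total = sum(r.count for r in reads)
    diag["total_reads"] = total
    if total < min_reads or loop is None:
        return False, diag

    ms, me = candidate.mature_span
    star = candidate.star_span
    arm_reads: dict[str, dict[int, int]] = {"mature": {}, "star": {}}
    outside = 0
    for r in reads:
        if _spans_overlap((r.start, r.end), (ms, me)) and \
                _overlap_len((r.start, r.end), (ms, me)) >= (r.end - r.start) // 2:
            arm_reads["mature"][r.start] = \
                arm_reads["mature"].get(r.start, 0) + r.count
        elif star is not None and _spans_overlap((r.start, r.end), star) and \
                _overlap_len((r.start, r.end), star) >= (r.end - r.start) // 2:
            arm_reads["star"][r.start] = \
                arm_reads["star"].get(r.start, 0) + r.count
        else:
            outside += r.count
    diag["outside_fraction"] = outside / total
    mature_total = sum(arm_reads["mature"].values())
    if mature_total == 0:
        return False, diag
    modal5, modal_count = max(arm_reads["mature"].items(),
                              key=lambda kv: (kv[1], -kv[0]))
    diag["modal_fraction"] = modal_count / mature_total
    star_total = sum(arm_reads["star"].values())
    diag["star_reads"] = star_total
    ok = (diag["modal_fraction"] >= modal_fraction
          and diag["outside_fraction"] <= max_outside)
    if ok and star_total > 0 and star is not None:
        smodal, _ = max(arm_reads["star"].items(),
                        key=lambda kv: (kv[1], -kv[0]))
        ok = abs(smodal - star[0]) <= 1
    return ok, diag


def _overlap_len(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def check_criteria(candidate: HairpinCandidate,
                   reads: Sequence[WindowRead],
                   energy_threshold: float = config.ENERGY_THRESHOLD,
                   ) -> CriteriaReport:
    """Apply the stem-loop criteria plus read-stack confirmation."""
    in_one_arm = candidate.arm is not None
    clean = in_one_arm and duplex_cleanliness(candidate.fold,
                                              candidate.mature_span)
    energy_ok = candidate.fold.energy < energy_threshold
    context_ok = candidate.context in ("intergenic", "intronic")
    stack_ok, _ = read_stack_consistency(candidate, reads)
    return CriteriaReport(in_one_arm, clean, energy_ok, context_ok, stack_ok)


# --- full discovery ----------------------------------------------------------

def _cluster_hits(weighted_hits):
    """Group (hit, pooled_count) by overlap on (contig, strand)."""
    keyed: dict[tuple[str, str], list] = {}
    for hit, cnt in weighted_hits:
        keyed.setdefault((hit.interval.contig_id, hit.interval.strand),
                         []).append((hit, cnt))
    clusters = []
    for _, items in sorted(keyed.items()):
        items.sort(key=lambda hc: (hc[0].interval.start, hc[0].interval.end))
        cur: list = []
        cur_end = -1
        for hit, cnt in items:
            if cur and hit.interval.start >= cur_end:
                clusters.append(cur)
                cur = []
                cur_end = -1
            cur.append((hit, cnt))
            cur_end = max(cur_end, hit.interval.end)
        if cur:
            clusters.append(cur)
    return clusters


def call_mirna_genes(tags, hits_by_tag, genome: dict[str, str],
                     annotation: AnnotationSet,
                     flank: int = config.FLANK,
                     min_seed_reads: int = config.MIN_SEED_READS,
                     energy_threshold: float = config.ENERGY_THRESHOLD,
                     star_tolerance: int = 2,
                     ):
    """Run discovery over all mapped tag loci.

    Candidate seeds are read clusters with at least ``min_seed_reads``
    pooled reads; each seeds a flanked window anchored on its most abundant
    tag (0-mismatch hits preferred).  Overlapping windows on the same strand
    are merged, keeping the lower-energy fold.  Returns the accepted genes
    and a per-candidate criteria table.
    """
    import bisect

    counts = {t.sequence: sum(t.counts) for t in tags}
    # all hits indexed by (contig, strand) for window read-stack collection
    all_hits: dict[tuple[str, str], list] = {}
    seed_hits = []
    for tag_seq, hits in hits_by_tag.items():
        pooled = counts.get(tag_seq, 0)
        for h in hits:
            all_hits.setdefault(
                (h.interval.contig_id, h.interval.strand), []).append(
                (h.interval.start, h.interval.end, pooled))
            if pooled >= min_seed_reads:
                seed_hits.append((h, pooled))
    for key in all_hits:
        all_hits[key].sort()
    starts_index = {key: [s for s, _, _ in lst]
                    for key, lst in all_hits.items()}

    # merge seed clusters whose flanked windows would overlap: isomiR
    # stacks and the mature/star stacks of one precursor seed one gene
    clusters = _cluster_hits(seed_hits)
    merged_clusters: list[list] = []
    prev_key = None
    prev_end = -1
    for cluster in clusters:
        iv0 = cluster[0][0].interval
        key = (iv0.contig_id, iv0.strand)
        start = min(h.interval.start for h, _ in cluster) - flank
        end = max(h.interval.end for h, _ in cluster) + flank
        if merged_clusters and key == prev_key and start < prev_end:
            merged_clusters[-1].extend(cluster)
            prev_end = max(prev_end, end)
        else:
            merged_clusters.append(list(cluster))
            prev_key, prev_end = key, end

    merged = []
    for cluster in merged_clusters:
        # anchor on the most abundant tag (the putative mature modal
        # isomiR), preferring perfect hits; the duplex partner's stack is
        # lighter and becomes the star
        rep, _ = max(cluster,
                     key=lambda hc: (hc[1], -hc[0].n_mismatch,
                                     -hc[0].interval.start))
        ext = extract_window(rep, genome, flank)
        if ext is None:
            continue
        wseq, wiv, mspan = ext
        if "N" in wseq:
            continue
        fold = fold_mfe(wseq)
        arm, star = locate_arms(fold, mspan)
        mid = (wiv.start + wiv.end) // 2
        cand = HairpinCandidate(wiv, wseq, fold, mspan, arm, star,
                                annotation.context_at(wiv.contig_id, mid))
        merged.append((cand, cluster))

    genes: list[MirnaGene] = []
    reports: list[dict] = []
    for idx, (cand, cluster) in enumerate(merged, 1):
        wiv = cand.window_interval
        key = (wiv.contig_id, wiv.strand)
        reads = []
        lst = all_hits.get(key, [])
        starts = starts_index.get(key, [])
        lo = bisect.bisect_left(starts, wiv.start - config.MAX_TAG_LEN)
        for s, e, cnt in lst[lo:bisect.bisect_right(starts, wiv.end)]:
            if e <= wiv.end and s >= wiv.start:
                if wiv.strand == "+":
                    reads.append(WindowRead(s - wiv.start, e - wiv.start,
                                            cnt))
                else:
                    reads.append(WindowRead(wiv.end - e, wiv.end - s, cnt))
        report = check_criteria(cand, reads, energy_threshold)
        row = {"candidate_id": f"cand_{idx}",
               "contig": wiv.contig_id, "start": wiv.start, "end": wiv.end,
               "strand": wiv.strand, "energy": cand.fold.energy,
               "context": cand.context, "arm": cand.arm,
               "in_one_arm": report.in_one_arm,
               "duplex_clean": report.duplex_clean,
               "energy_ok": report.energy_ok,
               "context_ok": report.context_ok,
               "read_stack_ok": report.read_stack_ok,
               "passed": report.passed}
        reports.append(row)
        if not report.passed:
            continue
        ms, me = cand.mature_span
        mature_seq = cand.window_seq[ms:me]
        star_seq = None
        star_observed = False
        if cand.star_span is not None:
            ss, se = cand.star_span
            star_seq = cand.window_seq[ss:se]
            star_observed = any(
                abs(r.start - ss) <= star_tolerance
                and abs(r.end - se) <= star_tolerance + 3
                for r in reads)
        gene_id = f"mir_{wiv.contig_id}_{wiv.start}_{wiv.strand}"
        genes.append(MirnaGene(gene_id, cand, mature_seq, star_seq,
                               star_observed))
    return genes, reports
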