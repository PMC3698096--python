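"""Homology search and lineage classification of discovered miRNA genes.

Two complementary searches: a permissive word-seeded catalog search against
known-miRNA sets (low-stringency, E-value <= 10, word size 7, followed by
an identity/length inspection), and a genome scan that locates near-exact
copies of the mature in other species' assemblies and scores them with a
hairpin-context bonus, homologue present when the best score reaches 35.
Presence across species is then folded into a lineage label (conserved
beyond mosquitoes, mosquito-, Culicinae-, Aedes- or species-specific), and
mature/star arm switches between species are flagged.
"""

from __future__ import annotations

import dataclasses
import logging
import math

from . import config
from .hairpin import duplex_cleanliness, fold_mfe, locate_arms
from .io_formats import revcomp
from .mapping import brute_force_map

log = logging.getLogger("mirmos.homology")

MOSQUITO_GENERA_SPECIES = ("Aae", "Cqu", "Aga")


@dataclasses.dataclass(frozen=True)
class HomologyHit:
    query_id: str
    subject_id: str
    species: str
    query_span: tuple[int, int]
    subject_span: tuple[int, int]
    identities: int
    mismatches: int
    score: float
    source: str                    # catalog_search | genome_scan
    evalue: float | None = None


@dataclasses.dataclass
class LineageLabel:
    label: str
    presence: dict[str, bool]


# --- catalog search ----------------------------------------------------------

def _ungapped_extend(q: str, s: str, qi: int, si: int, w: int
                     ) -> tuple[int, int, int, int]:
    """Extend a shared word in both directions, maximizing +1/-2 score.

    Returns (query_start, subject_start, length, identities) of the
    best-scoring extension containing the seed word.
    """
    # right extension from the end of the word
    best_r, score, r = 0, 0, 0
    while qi + w + best_r + r < len(q) and si + w + best_r + r < len(s):
        score += 1 if q[qi + w + best_r + r] == s[si + w + best_r + r] else -2
        r += 1
        if score > 0:
            best_r, score, r = best_r + r, 0, 0
        elif score < -4:
            break
    # left extension from the start of the word
    best_l, score, l = 0, 0, 0
    while qi - best_l - l - 1 >= 0 and si - best_l - l - 1 >= 0:
        score += 1 if q[qi - best_l - l - 1] == s[si - best_l - l - 1] else -2
        l += 1
        if score > 0:
            best_l, score, l = best_l + l, 0, 0
        elif score < -4:
            break
    qs, ss = qi - best_l, si - best_l
    length = w + best_l + best_r
    ident = sum(1 for k in range(length) if q[qs + k] == s[ss + k])
    return qs, ss, length, ident


def catalog_search(mature_seq: str, catalog, query_id: str = "query",
                   word_size: int = config.BLAST_WORD_SIZE,
                   max_evalue: float = config.BLAST_MAX_EVALUE,
                   ) -> list[HomologyHit]:
    """Word-seeded ungapped local search of a mature against a catalog.

    Catalog entries are (id, sequence) pairs or objects with ``entry_id``/
    ``mature_seq``/``species`` attributes.  Scoring is +1 match / -2
    mismatch; E = K*m*n*exp(-lambda*S) with fixed small-catalog constants.
    Hits with E <= max_evalue are returned sorted by score (best per
    subject).
    """
    if not catalog:
        raise ValueError("empty catalog")
    entries = []
    for e in catalog:
        if hasattr(e, "mature_seq"):
            entries.append((e.entry_id, e.mature_seq,
                            getattr(e, "species", ".")))
        else:
            sid, seq = e[0], e[1]
            entries.append((sid, seq, e[2] if len(e) > 2 else "."))
    cat_len = sum(len(seq) for _, seq, _ in entries)
    q = mature_seq
    words = {q[i:i + word_size]: i
             for i in range(len(q) - word_size + 1)}
    best_per_subject: dict[str, HomologyHit] = {}
    for sid, seq, sp in entries:
        for si in range(len(seq) - word_size + 1):
            qi = words.get(seq[si:si + word_size])
            if qi is None:
                continue
            qs, ss, length, ident = _ungapped_extend(q, seq, qi, si,
                                                     word_size)
            score = ident - 2 * (length - ident)
            evalue = (config.BLAST_K * len(q) * cat_len
                      * math.exp(-config.BLAST_LAMBDA * score))
            if evalue > max_evalue:
                continue
            hit = HomologyHit(query_id, sid, sp, (qs, qs + length),
                              (ss, ss + length), ident, length - ident,
                              float(score), "catalog_search", evalue)
            prev = best_per_subject.get(sid)
            if prev is None or hit.score > prev.score:
                best_per_subject[sid] = hit
    return sorted(best_per_subject.values(),
                  key=lambda h: (-h.score, h.subject_id))


def inspect_hit(hit: HomologyHit,
                min_identity: float = config.INSPECT_MIN_IDENTITY,
                min_length: int = config.INSPECT_MIN_LENGTH) -> bool:
    """Surrogate for manual inspection of permissive catalog hits."""
    length = hit.identities + hit.mismatches
    return (length >= min_length
            and hit.identities / length >= min_identity)


# --- genome scan -------------------------------------------------------------

def _hairpin_context_ok(genome: dict[str, str], hit) -> bool:
    """Does the flanked locus fold into a clean one-arm hairpin below the
    energy threshold?  (Structural part of the scan bonus.)"""
    iv = hit.interval
    contig = genome[iv.contig_id]
    ws = max(0, iv.start - config.FLANK)
    we = min(len(contig), iv.end + config.FLANK)
    if we - ws < len(iv) + 20:
        return False
    seq = contig[ws:we]
    if iv.strand == "+":
        span = (iv.start - ws, iv.end - ws)
    else:
        seq = revcomp(seq)
        span = (we - iv.end, we - iv.start)
    if "N" in seq:
        return False
    fold = fold_mfe(seq)
    arm, _ = locate_arms(fold, span)
    return (arm is not None
            and duplex_cleanliness(fold, span)
            and fold.energy < config.ENERGY_THRESHOLD)


def genome_scan(mature_seq: str, species_genome: dict[str, str],
                max_mismatch: int = 3, query_id: str = "query",
                species: str = ".",
                cutoff: float = config.MAPMI_CUTOFF,
                ) -> list[HomologyHit]:
    """Scan a species genome for copies of the mature, hairpin-scored.

    Every locus within ``max_mismatch`` (Hamming, both strands) is scored
    S = 2*(L - mm) - 4*mm + B with B = +5 when the flanked locus passes
    the hairpin structure checks and -20 otherwise.  A homologue is
    considered present when the best S reaches the cutoff (35).
    """
    L = len(mature_seq)
    hits = []
    for h in brute_force_map(mature_seq, species_genome,
                             max_mismatch=max_mismatch):
        bonus = (config.HAIRPIN_BONUS if _hairpin_context_ok(species_genome, h)
                 else config.NONHAIRPIN_PENALTY)
        score = 2.0 * (L - h.n_mismatch) - 4.0 * h.n_mismatch + bonus
        hits.append(HomologyHit(
            query_id, h.interval.contig_id, species,
            (0, L), (h.interval.start, h.interval.end),
            L - h.n_mismatch, h.n_mismatch, score, "genome_scan"))
    return sorted(hits, key=lambda h: (-h.score, h.subject_id,
                                       h.subject_span))


def homologue_present(hits: list[HomologyHit],
                      cutoff: float = config.MAPMI_CUTOFF) -> bool:
    return any(h.score >= cutoff for h in hits)


# --- lineage classification --------------------------------------------------

REQUIRED_SPECIES = ("Aal", "Aae", "Cqu", "Aga", "Dmel")
LINEAGE_LABELS = ("conserved_beyond_mosquitoes", "mosquito_specific",
                  "culicinae_specific", "aedes_specific", "species_specific")


def classify_lineage(presence: dict[str, bool]) -> LineageLabel:
    """Most specific lineage label consistent with a species-presence map.

    Presence in the Drosophila group wins; then all three mosquito genera;
    then Aedes+Culex only; then Aedes only; anything else (including
    phylogenetically inconsistent patterns such as Aedes+Anopheles alone)
    is species-specific.
    """
    missing = [sp for sp in REQUIRED_SPECIES if sp not in presence]
    if missing:
        raise ValueError(f"presence map missing species: {missing}")
    aedes = presence["Aal"] or presence["Aae"]
    if presence["Dmel"]:
        label = "conserved_beyond_mosquitoes"
    elif aedes and presence["Cqu"] and presence["Aga"]:
        label = "mosquito_specific"
    elif aedes and presence["Cqu"]:
        label = "culicinae_specific"
    elif presence["Aal"] and presence["Aae"] and not presence["Aga"]:
        label = "aedes_specific"
    else:
        if presence["Aga"]:
            log.warning("phylogenetically inconsistent presence pattern %s; "
                        "labelling species_specific", presence)
        label = "species_specific"
    return LineageLabel(label, dict(presence))


# --- arm switch --------------------------------------------------------------

def _best_identity(a: str, b: str) -> int:
    """Maximum number of matching positions over all ungapped offsets."""
    best = 0
    for off in range(-(len(a) - 1), len(b)):
        matches = 0
        for i in range(len(a)):
            j = i + off
            if 0 <= j < len(b) and a[i] == b[j]:
                matches += 1
        best = max(best, matches)
    return best


def detect_arm_switch(query_mature: str, query_star: str | None,
                      homolog_mature: str, homolog_star: str | None,
                      min_identity: int = 18) -> bool:
    """True when the query's mature matches the homologue's star arm and
    vice versa -- the miR-1174-style mature/star swap between species."""
    if query_star is None or homolog_star is None:
        return False
    return (_best_identity(query_mature, homolog_star) >= min_identity
            and _best_identity(query_star, homolog_mature) >= min_identity)


# --- per-gene annotation -----------------------------------------------------

def annotate_genes(genes, catalogs: dict[str, list],
                   mock_genomes: dict[str, dict[str, str]]) -> list[dict]:
    """Classify every discovered gene against all mock species.

    Presence per species comes from the genome scan (both the 1- and
    3-mismatch settings are run and reported); the catalog search supplies
    the best-hit annotation; lineage and arm-switch flags are derived.
    """
    rows = []
    for gene in genes:
        presence = {"Aal": True}
        row: dict = {"gene_id": gene.gene_id}
        best_entry = None
        for sp, genome in mock_genomes.items():
            scan3 = genome_scan(gene.mature_seq, genome, 3, gene.gene_id, sp)
            # the 1-mismatch setting is a subset of the 3-mismatch scan
            scan1 = [h for h in scan3 if h.mismatches <= 1]
            present = homologue_present(scan1) or homologue_present(scan3)
            presence[sp] = present
            row[f"score1_{sp}"] = scan1[0].score if scan1 else None
            row[f"score3_{sp}"] = scan3[0].score if scan3 else None
            row[f"present_{sp}"] = present
            if present and catalogs.get(sp):
                hits = [h for h in catalog_search(gene.mature_seq,
                                                  catalogs[sp],
                                                  gene.gene_id)
                        if inspect_hit(h)]
                if hits:
                    row[f"best_hit_{sp}"] = hits[0].subject_id
                    entry = next((e for e in catalogs[sp]
                                  if e.entry_id == hits[0].subject_id), None)
                    if best_entry is None and entry is not None:
                        best_entry = entry
        label = classify_lineage(presence)
        gene.lineage = label.label
        row["lineage"] = label.label
        row["arm_switch"] = False
        if best_entry is not None:
            row["arm_switch"] = detect_arm_switch(
                gene.mature_seq, gene.star_seq,
                best_entry.mature_seq, best_entry.star_seq)
        # an arm-switched homologue may not be the best mature-vs-mature
        # hit at all; check every catalog entry as a fallback
        if not row["arm_switch"] and gene.star_seq is not None:
            for sp, entries in catalogs.items():
                if row["arm_switch"]:
                    break
                for e in entries:
                    if detect_arm_switch(gene.mature_seq, gene.star_seq,
                                         e.mature_seq, e.star_seq):
                        row["arm_switch"] = True
                        row["arm_switch_subject"] = e.entry_id
                        break
        rows.append(row)
    return rows


def write_homology_tsv(rows: list[dict], path) -> None:
    from .io_formats import write_tsv
    if not rows:
        write_tsv([], path, ["gene_id", "lineage", "arm_switch"])
        return
    cols = ["gene_id", "lineage", "arm_switch"]
    extra = sorted({k for r in rows for k in r} - set(cols))
    write_tsv(rows, path, cols + extra)
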