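"""Tag-to-genome alignment keeping hits with at most one mismatch.

Seed-and-extend with a pigeonhole guarantee: each tag is split into two
halves; any locus within Hamming distance 1 matches at least one half
exactly, so exact hash lookups of both halves enumerate every candidate
locus.  Both strands are handled by also querying the reverse complement.
"""

from __future__ import annotations

import dataclasses
import logging
from collections import defaultdict

from . import config
from .io_formats import GenomeSequence, GenomicInterval, revcomp

log = logging.getLogger("mirmos.mapping")


@dataclasses.dataclass(frozen=True)
class TagHit:
    tag: str
    interval: GenomicInterval
    n_mismatch: int
    mismatch_position: int | None = None  # index within the tag, 5'->3'


class SeedIndex:
    """Hash of every k-mer position in the genome (plus strand only)."""

    def __init__(self, genome: list[GenomeSequence] | dict[str, str],
                 k: int = config.INDEX_K):
        if k > 12:
            raise ValueError(f"seed k={k} too large (max 12)")
        if k > config.MIN_TAG_LEN // 2:
            raise ValueError(
                f"seed k={k} breaks the pigeonhole guarantee for "
                f"{config.MIN_TAG_LEN}-nt tags")
        self.k = k
        if isinstance(genome, dict):
            genome = [GenomeSequence(c, s) for c, s in genome.items()]
        self.contigs: dict[str, str] = {g.contig_id: g.sequence
                                        for g in genome}
        self.positions: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for g in genome:
            seq = g.sequence
            for i in range(len(seq) - k + 1):
                kmer = seq[i:i + k]
                if "N" not in kmer:
                    self.positions[kmer].append((g.contig_id, i))


def _check_locus(tag: str, contig_seq: str, start: int) -> tuple[int, int] | None:
    """Hamming-compare tag to contig_seq[start:]; None if distance > 1."""
    end = start + len(tag)
    if start < 0 or end > len(contig_seq):
        return None
    mm, mm_pos = 0, None
    for i in range(len(tag)):
        if tag[i] != contig_seq[start + i]:
            mm += 1
            if mm > 1:
                return None
            mm_pos = i
    return mm, mm_pos


def map_tag(tag: str, index: SeedIndex) -> list[TagHit]:
    """All genomic loci (both strands) within Hamming distance 1 of the tag."""
    if "N" in tag:
        return []
    k = index.k
    hits: dict[tuple[str, int, str], TagHit] = {}
    for strand, query in (("+", tag), ("-", revcomp(tag))):
        n = len(query)
        # two pigeonhole seeds: prefix and suffix halves
        seeds = [(query[:k], 0), (query[n - k:], n - k)]
        seen_starts: set[tuple[str, int]] = set()
        for seed, offset in seeds:
            for contig_id, pos in index.positions.get(seed, ()):
                start = pos - offset
                if (contig_id, start) in seen_starts:
                    continue
                seen_starts.add((contig_id, start))
                res = _check_locus(query, index.contigs[contig_id], start)
                if res is None:
                    continue
                mm, mm_pos = res
                if strand == "-" and mm_pos is not None:
                    mm_pos = n - 1 - mm_pos  # report in tag coordinates
                hits[(contig_id, start, strand)] = TagHit(
                    tag, GenomicInterval(contig_id, start, start + n, strand),
                    mm, mm_pos)
    return sorted(hits.values(),
                  key=lambda h: (h.interval.contig_id, h.interval.start,
                                 h.interval.strand))


def map_all(tags, index: SeedIndex):
    """Map every tag; returns (hits_by_tag_sequence, unmapped_tag_list)."""
    hits_by_tag: dict[str, list[TagHit]] = {}
    unmapped = []
    multimapped = 0
    for tag in tags:
        seq = tag.sequence if hasattr(tag, "sequence") else tag
        hits = map_tag(seq, index)
        if hits:
            hits_by_tag[seq] = hits
            if len(hits) > 1:
                multimapped += 1
        else:
            unmapped.append(tag)
    log.info("map_all: %d mapped (%d multimapped), %d unmapped",
             len(hits_by_tag), multimapped, len(unmapped))
    return hits_by_tag, unmapped


def brute_force_map(tag: str, genome: dict[str, str],
                    max_mismatch: int = 1) -> list[TagHit]:
    """Exhaustive Hamming scan of every locus on both strands.

    Independent of the seed index; used as the testing oracle and for
    small ad-hoc scans.
    """
    import numpy as np

    hits = []
    n = len(tag)
    for strand, query in (("+", tag), ("-", revcomp(tag))):
        q = np.frombuffer(query.encode(), dtype=np.uint8)
        for contig_id, seq in genome.items():
            if len(seq) < n:
                continue
            arr = np.frombuffer(seq.encode(), dtype=np.uint8)
            windows = np.lib.stride_tricks.sliding_window_view(arr, n)
            mm = (windows != q).sum(axis=1)
            for start in np.nonzero(mm <= max_mismatch)[0]:
                start = int(start)
                diff = np.nonzero(windows[start] != q)[0]
                mm_pos = int(diff[0]) if diff.size else None
                if strand == "-" and mm_pos is not None:
                    mm_pos = n - 1 - mm_pos
                hits.append(TagHit(
                    tag, GenomicInterval(contig_id, start, start + n, strand),
                    int(mm[start]), mm_pos))
    return sorted(hits, key=lambda h: (h.interval.contig_id,
                                       h.interval.start, h.interval.strand))


def write_hits_tsv(hits_by_tag, path) -> None:
    from .io_formats import write_tsv
    rows = []
    for tag_seq, hits in sorted(hits_by_tag.items()):
        for h in hits:
            rows.append({"contig": h.interval.contig_id,
                         "start": h.interval.start, "end": h.interval.end,
                         "tag": tag_seq, "strand": h.interval.strand,
                         "mm": h.n_mismatch})
    write_tsv(rows, path, ["contig", "start", "end", "tag", "strand", "mm"])
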