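"""Raw reads -> clean, length-selected, contaminant-free collapsed tags.

Order of operations: 3' adapter trim, insert quality check, 18-30 nt length
selection, collapse to unique tags with per-sample counts, then structural
ncRNA/repeat contaminant removal.  Read counts are conserved at every step
and reported per drop reason.
"""

from __future__ import annotations

import dataclasses
import logging
from collections import Counter, defaultdict

import pandas as pd

from . import config
from .io_formats import AnnotationSet, STRUCTURAL_FEATURES, iter_fastq, revcomp

log = logging.getLogger("mirmos.preprocess")

SAMPLES = ("E", "L", "P", "M", "F", "B")


@dataclasses.dataclass
class SmallRNATag:
    """A collapsed unique read sequence with per-sample counts."""

    sequence: str
    counts: tuple[int, ...]          # keyed by SAMPLES order
    flags: frozenset = frozenset()   # e.g. {"exon"}, {"intron"}

    def __post_init__(self):
        if not (config.MIN_TAG_LEN <= len(self.sequence)
                <= config.MAX_TAG_LEN):
            raise ValueError(f"tag length {len(self.sequence)} out of range")
        if "N" in self.sequence:
            raise ValueError("tag contains N")
        if sum(self.counts) < 1:
            raise ValueError("tag with zero total count")


def trim_adapter(read_sequence: str, adapter3: str,
                 min_overlap: int = config.MIN_ADAPTER_OVERLAP,
                 max_mismatch: int = config.MAX_ADAPTER_MISMATCH,
                 ) -> str | None:
    """Locate the leftmost 3' adapter match and return the insert.

    A match is an overlap of at least ``min_overlap`` nt between a read
    suffix and the adapter prefix with at most ``max_mismatch`` mismatches;
    the leftmost match wins.  Returns None when no adapter is found or the
    insert is empty.
    """
    if len(adapter3) < min_overlap:
        raise ValueError(f"adapter shorter than {min_overlap} nt")
    rlen = len(read_sequence)
    last = rlen - min_overlap
    if last < 0:
        return None
    best = None
    a0, a1 = adapter3[0], adapter3[1]
    for p in range(0, last + 1):
        # prefilter: two leading mismatches already exceed the budget
        if (max_mismatch <= 1 and read_sequence[p] != a0
                and read_sequence[p + 1] != a1):
            continue
        ov = min(len(adapter3), rlen - p)
        mm = 0
        for i in range(ov):
            if read_sequence[p + i] != adapter3[i]:
                mm += 1
                if mm > max_mismatch:
                    break
        else:
            best = p
            break
    if best is None or best == 0:
        return None
    return read_sequence[:best]


def filter_length(sequences, min_len: int = config.MIN_TAG_LEN,
                  max_len: int = config.MAX_TAG_LEN):
    """Keep sequences with min_len <= length <= max_len; log drop counts."""
    kept, dropped = [], Counter()
    for seq in sequences:
        if len(seq) < min_len:
            dropped["short"] += 1
        elif len(seq) > max_len:
            dropped["long"] += 1
        else:
            kept.append(seq)
    if dropped:
        log.info("filter_length: dropped %s", dict(dropped))
    return kept, dict(dropped)


def collapse_tags(per_sample_sequences: dict[str, list[str]]
                  ) -> list[SmallRNATag]:
    """Collapse surviving reads into unique tags with a 6-vector of counts.

    Missing samples contribute a zero column; the sum of all counts equals
    the number of input reads.
    """
    counts: dict[str, list[int]] = defaultdict(lambda: [0] * len(SAMPLES))
    for s_idx, sample in enumerate(SAMPLES):
        for seq in per_sample_sequences.get(sample, ()):
            counts[seq][s_idx] += 1
    return [SmallRNATag(seq, tuple(c))
            for seq, c in sorted(counts.items())]


def filter_contaminants(tags: list[SmallRNATag], annotation: AnnotationSet,
                        genome: dict[str, str]
                        ) -> tuple[list[SmallRNATag], dict]:
    """Remove tags matching structural ncRNA/repeat features (either strand).

    Exon/intron matches are NOT removed; they are flagged so the hairpin
    stage can enforce genomic context, which keeps intronic miRNAs alive.
    """
    structural = annotation.feature_sequences(genome, STRUCTURAL_FEATURES)
    genic = {
        "exon": annotation.feature_sequences(genome, frozenset({"exon"})),
        "intron": annotation.feature_sequences(genome, frozenset({"intron"})),
    }
    sep = "#"
    struct_blob = sep.join(structural + [revcomp(s) for s in structural])
    genic_blobs = {cls: sep.join(seqs + [revcomp(s) for s in seqs])
                   for cls, seqs in genic.items()}

    kept, n_removed = [], 0
    for tag in tags:
        fwd = tag.sequence
        if struct_blob and fwd in struct_blob:
            n_removed += sum(tag.counts)
            continue
        flags = {cls for cls, blob in genic_blobs.items()
                 if blob and fwd in blob}
        kept.append(dataclasses.replace(tag, flags=frozenset(flags))
                    if flags else tag)
    log.info("filter_contaminants: removed %d reads as structural ncRNA/"
             "repeat", n_removed)
    return kept, {"contaminant_reads": n_removed}


def size_distribution(tags: list[SmallRNATag]) -> pd.DataFrame:
    """Per-sample read-fraction histogram over tag lengths 18-30."""
    import numpy as np

    lengths = range(config.MIN_TAG_LEN, config.MAX_TAG_LEN + 1)
    counts = np.zeros((len(lengths), len(SAMPLES)))
    for tag in tags:
        counts[len(tag.sequence) - config.MIN_TAG_LEN] += tag.counts
    table = pd.DataFrame(counts, index=list(lengths), columns=list(SAMPLES))
    totals = table.sum(axis=0)
    zero = [s for s in SAMPLES if totals[s] == 0]
    if zero:
        raise ValueError(f"samples with zero reads: {zero}")
    return table / totals


def preprocess_libraries(library_paths: dict[str, str], adapter: str,
                         annotation: AnnotationSet | None = None,
                         genome: dict[str, str] | None = None,
                         min_len: int = config.MIN_TAG_LEN,
                         max_len: int = config.MAX_TAG_LEN,
                         min_quality: int = config.MIN_BASE_QUALITY,
                         ) -> tuple[list[SmallRNATag], dict]:
    """Full preprocessing of six stage libraries into collapsed tags.

    Returns the tags (contaminant-filtered when annotation+genome are
    given) and a per-sample accounting dict in which input reads equal
    kept + dropped-by-reason.
    """
    per_sample: dict[str, list[str]] = {}
    stats: dict[str, dict] = {}
    qmin = chr(min_quality + 33)
    for sample, path in library_paths.items():
        dropped = Counter()
        kept: list[str] = []
        n_in = 0
        for _, seq, qual in iter_fastq(path):
            n_in += 1
            insert = trim_adapter(seq, adapter)
            if insert is None:
                dropped["no_adapter"] += 1
                continue
            if any(q < qmin for q in qual[:len(insert)]):
                dropped["low_quality"] += 1
                continue
            if "N" in insert:
                dropped["ambiguous"] += 1
                continue
            if len(insert) < min_len:
                dropped["short"] += 1
            elif len(insert) > max_len:
                dropped["long"] += 1
            else:
                kept.append(insert)
        per_sample[sample] = kept
        stats[sample] = {"input": n_in, "kept": len(kept), **dropped}
        assert n_in == len(kept) + sum(dropped.values())
    tags = collapse_tags(per_sample)
    if annotation is not None and genome is not None:
        tags, cont = filter_contaminants(tags, annotation, genome)
        stats["contaminants"] = cont
    return tags, stats


def write_tags_tsv(tags: list[SmallRNATag], path) -> None:
    from .io_formats import write_tsv
    rows = [{"sequence": t.sequence, "len": len(t.sequence),
             **{f"count_{s}": c for s, c in zip(SAMPLES, t.counts)},
             "flags": ",".join(sorted(t.flags)) or None}
            for t in tags]
    write_tsv(rows, path,
              ["sequence", "len"] + [f"count_{s}" for s in SAMPLES]
              + ["flags"])
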