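"""Readers and writers for every external format the pipeline touches.

Single home for coordinate conventions: internally everything is 0-based,
half-open, on the plus strand; GFF3 files are converted on the way in and
out.  All parsers reject malformed records rather than silently repairing
them, and every accepted record round-trips through its writer unchanged.
"""

from __future__ import annotations

import dataclasses
import gzip
import logging
from pathlib import Path
from typing import IO, Iterable, Iterator

from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator
from intervaltree import IntervalTree

log = logging.getLogger("mirmos.io")

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

RECOGNIZED_FEATURES = frozenset(
    {"exon", "intron", "gene", "three_prime_UTR",
     "rRNA", "tRNA", "snRNA", "snoRNA", "repeat"}
)
STRUCTURAL_FEATURES = frozenset({"rRNA", "tRNA", "snRNA", "snoRNA", "repeat"})


class ParseError(ValueError):
    """Malformed record in an input file."""


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


# --- domain types ------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class GenomeSequence:
    contig_id: str
    sequence: str

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"contig {self.contig_id}: empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclasses.dataclass(frozen=True)
class GenomicInterval:
    """0-based, half-open interval on a named contig."""

    contig_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"bad interval {self.contig_id}:{self.start}-{self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (self.contig_id == other.contig_id
                and self.start < other.end and other.start < self.end)


@dataclasses.dataclass(frozen=True)
class Feature:
    interval: GenomicInterval
    feature_class: str
    transcript_id: str


class AnnotationSet:
    """Genome annotation with fast per-contig overlap queries."""

    def __init__(self, features: Iterable[Feature] = ()):
        self.features: list[Feature] = list(features)
        self._trees: dict[str, IntervalTree] = {}
        for f in self.features:
            tree = self._trees.setdefault(f.interval.contig_id, IntervalTree())
            tree.addi(f.interval.start, f.interval.end, f)

    def __len__(self) -> int:
        return len(self.features)

    def overlapping(self, contig_id: str, start: int, end: int,
                    classes: frozenset | None = None) -> list[Feature]:
        tree = self._trees.get(contig_id)
        if tree is None:
            return []
        hits = [iv.data for iv in tree.overlap(start, end)]
        if classes is not None:
            hits = [f for f in hits if f.feature_class in classes]
        return sorted(hits, key=lambda f: (f.interval.start, f.interval.end,
                                           f.feature_class))

    def context_at(self, contig_id: str, pos: int) -> str:
        """Genomic context of a single point: exonic, intronic or intergenic.

        Exon overlap wins over intron; a point inside a gene body but in no
        exon counts as intronic.
        """
        classes = {f.feature_class
                   for f in self.overlapping(contig_id, pos, pos + 1)}
        if "exon" in classes or "three_prime_UTR" in classes:
            return "exonic"
        if "intron" in classes or "gene" in classes:
            return "intronic"
        return "intergenic"

    def feature_sequences(self, genome: dict[str, str],
                          classes: frozenset) -> list[str]:
        """Plus-strand sequences of all features of the given classes."""
        out = []
        for f in self.features:
            if f.feature_class in classes:
                iv = f.interval
                out.append(genome[iv.contig_id][iv.start:iv.end])
        return out


# --- low-level file handling -------------------------------------------------

def _open_text(path: str | Path) -> IO[str]:
    """Open a possibly gzip-compressed text file, detected by magic bytes."""
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path)


# --- FASTA / FASTQ -----------------------------------------------------------

def read_fasta(path: str | Path) -> list[GenomeSequence]:
    """Read FASTA records; sequences are upper-cased and U is converted to T."""
    records: list[GenomeSequence] = []
    seen: set[str] = set()
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if not rec.id:
                raise ParseError(f"{path}: record {len(records) + 1} has an "
                                 "empty header")
            if rec.id in seen:
                raise ParseError(f"{path}: duplicate record id {rec.id!r}")
            seq = str(rec.seq).upper().replace("U", "T")
            if not seq:
                raise ParseError(f"{path}: record {rec.id!r} is empty")
            seen.add(rec.id)
            records.append(GenomeSequence(rec.id, seq))
    return records


def write_fasta(records: Iterable[GenomeSequence | tuple[str, str]],
                path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            cid, seq = ((rec.contig_id, rec.sequence)
                        if isinstance(rec, GenomeSequence) else rec)
            fh.write(f">{cid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_fastq(path: str | Path) -> list[tuple[str, str, str]]:
    """Read 4-line FASTQ records as (read_id, sequence, quality) tuples."""
    out: list[tuple[str, str, str]] = []
    with _open_text(path) as fh:
        try:
            for title, seq, qual in FastqGeneralIterator(fh):
                if len(seq) != len(qual):
                    raise ParseError(
                        f"{path}: record {title.split()[0]!r} sequence/quality"
                        " length mismatch")
                out.append((title.split()[0], seq.upper(), qual))
        except ValueError as exc:  # malformed record from Biopython
            raise ParseError(f"{path}: {exc}") from exc
    return out


def iter_fastq(path: str | Path) -> Iterator[tuple[str, str, str]]:
    """Streaming variant of :func:`read_fastq` for large libraries."""
    with _open_text(path) as fh:
        try:
            for title, seq, qual in FastqGeneralIterator(fh):
                yield title.split()[0], seq.upper(), qual
        except ValueError as exc:
            raise ParseError(f"{path}: {exc}") from exc


# --- GFF3 --------------------------------------------------------------------

def read_gff3(path: str | Path) -> AnnotationSet:
    """Read GFF3 (1-based, inclusive) into internal 0-based half-open features.

    Feature types outside the recognized set are skipped and counted in a
    single log line.  Attribute `ID` or `Parent` supplies the transcript id.
    """
    features: list[Feature] = []
    skipped = 0
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 columns, "
                                 f"got {len(cols)}")
            contig, _, ftype, start_s, end_s, _, strand, _, attrs = cols
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError:
                raise ParseError(
                    f"{path}:{lineno}: non-numeric coordinates") from None
            if start1 > end1:
                raise ParseError(f"{path}:{lineno}: start {start1} > "
                                 f"end {end1}")
            if ftype not in RECOGNIZED_FEATURES:
                skipped += 1
                continue
            attr_map = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
            tid = attr_map.get("ID") or attr_map.get("Parent") or "."
            if strand not in ("+", "-"):
                strand = "+"
            features.append(Feature(
                GenomicInterval(contig, start1 - 1, end1, strand),
                ftype, tid))
    if skipped:
        log.info("read_gff3: skipped %d unrecognized feature lines", skipped)
    return AnnotationSet(features)


def write_gff3(features: Iterable[Feature], path: str | Path,
               source: str = "mirmos") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            iv = f.interval
            fh.write("\t".join([
                iv.contig_id, source, f.feature_class,
                str(iv.start + 1), str(iv.end), ".", iv.strand, ".",
                f"ID={f.transcript_id}",
            ]) + "\n")


def write_mirna_gff3(genes, path: str | Path) -> None:
    """Write discovered miRNA genes as pre_miRNA features with miRNA children.

    Coordinates are re-converted to GFF3's 1-based inclusive convention.
    Attributes carry the lineage label when one has been assigned.
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            pre = g.precursor.window_interval
            children = [("miRNA", g.mature_interval(), f"{g.gene_id}_mature")]
            if g.star_seq is not None:
                children.append(("miRNA", g.star_interval(),
                                 f"{g.gene_id}_star"))
            for _, iv, name in children:
                if not (pre.start <= iv.start and iv.end <= pre.end
                        and iv.contig_id == pre.contig_id):
                    raise ValueError(
                        f"{name}: child interval not contained in precursor")
            attrs = f"ID={g.gene_id}"
            if getattr(g, "lineage", None):
                attrs += f";lineage={g.lineage}"
            fh.write("\t".join([
                pre.contig_id, "mirmos", "pre_miRNA",
                str(pre.start + 1), str(pre.end), ".", pre.strand, ".",
                attrs]) + "\n")
            for ftype, iv, name in children:
                fh.write("\t".join([
                    iv.contig_id, "mirmos", ftype,
                    str(iv.start + 1), str(iv.end), ".", iv.strand, ".",
                    f"ID={name};Parent={g.gene_id}"]) + "\n")


# --- Vienna dot-bracket ------------------------------------------------------

def _check_balanced(structure: str) -> None:
    depth = 0
    for c in structure:
        if c == "(":
            depth += 1
        elif c == ")":
            depth -= 1
            if depth < 0:
                raise ValueError(f"unbalanced structure {structure!r}")
        elif c != ".":
            raise ValueError(f"bad structure character {c!r}")
    if depth != 0:
        raise ValueError(f"unbalanced structure {structure!r}")


def write_dotbracket(records: Iterable[tuple[str, str, str, float]],
                     path: str | Path) -> None:
    """Write Vienna-style records: ``>id``, sequence, ``structure (energy)``.

    Energy is printed to 0.1 kcal/mol as RNAfold does.
    """
    with open(path, "w") as fh:
        for rid, seq, struct, energy in records:
            if len(struct) != len(seq):
                raise ValueError(
                    f"{rid}: structure length {len(struct)} != sequence "
                    f"length {len(seq)}")
            _check_balanced(struct)
            fh.write(f">{rid}\n{seq}\n{struct} ({energy:.1f})\n")


def read_dotbracket(path: str | Path) -> list[tuple[str, str, str, float]]:
    out = []
    lines = [ln.rstrip("\n") for ln in _open_text(path)]
    for i in range(0, len(lines), 3):
        if not lines[i]:
            continue
        rid = lines[i][1:]
        seq = lines[i + 1]
        struct, _, energy = lines[i + 2].rpartition(" (")
        out.append((rid, seq, struct, float(energy.rstrip(")"))))
    return out


# --- TSV helpers -------------------------------------------------------------

def write_tsv(rows: list[dict], path: str | Path, columns: list[str]) -> None:
    """Write a header+rows TSV with '.' for missing values."""
    with open(path, "w") as fh:
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            fh.write("\t".join(
                "." if row.get(c) is None else str(row[c])
                for c in columns) + "\n")
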