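"""Synthetic study generator: a toy genome with planted miRNA genes and six
stage-specific small-RNA libraries.

Emulates the structure of a mosquito developmental small-RNA experiment:
six libraries (embryo, larva, pupa, male, sugar-fed female, blood-fed
female) dominated by ~22-nt miRNA reads, a ~28-nt piRNA-like band in the
embryo/larva/female libraries only, structural-ncRNA contaminants, 3'
adapters on every read, and isomiR end heterogeneity.  Planted pre-miRNA
hairpins are designed to satisfy the discovery criteria by construction;
a held-out set is planted inside exons as negative controls.  A ground
truth manifest is written alongside the data and is the only source of
truth for recovery tests.
"""

from __future__ import annotations

import dataclasses
import gzip
import logging
from pathlib import Path

import numpy as np

from . import config as cfg
from .config import stage_seed
from .hairpin import fold_mfe, locate_arms
from .io_formats import (AnnotationSet, Feature, GenomeSequence,
                         GenomicInterval, revcomp, write_fasta, write_tsv)
from .preprocess import SAMPLES

log = logging.getLogger("mirmos.synthetic")

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# stage-profile templates over (E, L, P, M, F, B); five biased clusters
TEMPLATES = {
    1: (0.75, 0.05, 0.05, 0.05, 0.05, 0.05),   # embryo-biased
    2: (0.05, 0.75, 0.05, 0.05, 0.05, 0.05),   # larva-biased
    3: (0.05, 0.05, 0.75, 0.05, 0.05, 0.05),   # pupa-biased
    4: (0.05, 0.05, 0.05, 0.75, 0.05, 0.05),   # male-biased
    5: (0.04, 0.04, 0.04, 0.04, 0.42, 0.42),   # female-biased
}
PIRNA_LIBRARIES = ("E", "L", "F", "B")

ISOMIR_5P = ((-1, 0, 1), (0.1, 0.8, 0.1))
ISOMIR_3P = ((-2, -1, 0, 1, 2), (0.05, 0.2, 0.5, 0.2, 0.05))
MATURE_LENGTHS = ((21, 22, 23), (0.15, 0.7, 0.15))

SPECIES = ("Aae", "Cqu", "Aga", "Dmel")
LINEAGE_PRESENCE = {
    "aedes": ("Aae",),
    "culicinae": ("Aae", "Cqu"),
    "mosquito": ("Aae", "Cqu", "Aga"),
    "conserved": ("Aae", "Cqu", "Aga", "Dmel"),
}


@dataclasses.dataclass
class SimulationConfig:
    seed: int = 42
    n_contigs: int = 2
    contig_length: int = 200_000
    gc: float = 0.5
    n_planted: int = 40
    n_exon_controls: int = 4
    reads_per_library: int = 100_000
    fraction_mirna_reads: float = 0.70
    fraction_pirna_like: float = 0.15
    fraction_contaminant: float = 0.08
    adapter_seq: str = "TGGAATTCTCGGGTGCCAAGG"
    star_read_fraction: float = 0.10
    mismatch_rate: float = 0.01   # per-read chance of one sequencing error

    def __post_init__(self):
        fracs = (self.fraction_mirna_reads, self.fraction_pirna_like,
                 self.fraction_contaminant)
        if any(not 0 <= f <= 1 for f in fracs) or sum(fracs) > 1:
            raise ValueError("read fractions must lie in [0,1] and sum <= 1")
        if self.reads_per_library <= 0:
            raise ValueError("reads_per_library must be positive")


@dataclasses.dataclass
class PlantedMirna:
    gene_id: str
    mature_seq: str
    star_seq: str
    precursor_interval: GenomicInterval
    arm_of_mature: str                     # 5p / 3p
    stage_profile: tuple[float, ...]       # over SAMPLES
    lineage_truth: str
    weight: float
    template: int
    blood_flag: str                        # none / up / down
    exon_control: bool
    arm_switched: bool
    oriented_precursor: str                # 5'->3' in transcript orientation
    mature_local: tuple[int, int]
    star_local: tuple[int, int]

    def mature_interval(self) -> GenomicInterval:
        p = self.precursor_interval
        s, e = self.mature_local
        if p.strand == "+":
            return GenomicInterval(p.contig_id, p.start + s, p.start + e, "+")
        return GenomicInterval(p.contig_id, p.end - e, p.end - s, "-")


# --- genome + annotation -----------------------------------------------------

def _random_dna(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(BASES, size=n, p=p).tobytes().decode()


_NC_CLASSES = (("rRNA", 1500, 2), ("tRNA", 80, 3), ("snRNA", 150, 2),
               ("snoRNA", 120, 2), ("repeat", 400, 4))


def generate_genome(config: SimulationConfig
                    ) -> tuple[list[GenomeSequence], AnnotationSet]:
    """Random background genome with genes, UTRs and contaminant ncRNA loci.

    Deterministic for a fixed seed.  Protein-coding genes carry three exons
    separated by introns, with the tail of the last exon annotated as the
    3' UTR; structural ncRNA and repeat loci sit in intergenic space.
    """
    rng = np.random.default_rng(stage_seed(config.seed, "genome"))
    min_len = 40_000
    if config.contig_length < min_len:
        raise ValueError(
            f"contig_length {config.contig_length} too short for the "
            f"requested features (need >= {min_len})")
    contigs: list[GenomeSequence] = []
    features: list[Feature] = []
    genes_per_contig = max(3, min(10, config.contig_length // 20_000))
    for c in range(config.n_contigs):
        cid = f"contig{c + 1}"
        seq = _random_dna(rng, config.contig_length, config.gc)
        contigs.append(GenomeSequence(cid, seq))
        # lay features down left to right with random intergenic gaps
        pos = int(rng.integers(1_000, 2_000))
        step = config.contig_length // (genes_per_contig + 2)
        for g in range(genes_per_contig):
            strand = "+" if rng.random() < 0.5 else "-"
            tid = f"{cid}_t{g + 1}"
            exon_lens = rng.integers(500, 1_000, size=3)
            intron_lens = rng.integers(800, 2_000, size=2)
            cursor = pos
            gene_start = cursor
            for i in range(3):
                features.append(Feature(
                    GenomicInterval(cid, cursor, cursor + int(exon_lens[i]),
                                    strand), "exon", tid))
                cursor += int(exon_lens[i])
                if i < 2:
                    features.append(Feature(
                        GenomicInterval(cid, cursor,
                                        cursor + int(intron_lens[i]), strand),
                        "intron", tid))
                    cursor += int(intron_lens[i])
            utr_len = int(rng.integers(250, 450))
            features.append(Feature(
                GenomicInterval(cid, cursor - utr_len, cursor, strand),
                "three_prime_UTR", tid))
            features.append(Feature(
                GenomicInterval(cid, gene_start, cursor, strand), "gene", tid))
            pos = gene_start + step
        # ncRNA/repeat loci in the remaining tail of the contig
        nc_pos = pos + 2_000
        for klass, length, count in _NC_CLASSES:
            for i in range(count):
                if nc_pos + length + 500 > config.contig_length:
                    raise ValueError("contig too short for ncRNA loci")
                features.append(Feature(
                    GenomicInterval(cid, nc_pos, nc_pos + length, "+"),
                    klass, f"{cid}_{klass}{i + 1}"))
                nc_pos += length + int(rng.integers(300, 800))
    return contigs, AnnotationSet(features)


# --- hairpin design ----------------------------------------------------------

def _design_precursor(rng: np.random.Generator, arm: str
                      ) -> tuple[str, tuple[int, int], tuple[int, int], str, str]:
    """One hairpin precursor with mature/star duplex and 2-nt 3' overhangs.

    Layout (5p mature): x(5) + mature(L) + loop(11, A/C only) + revcomp
    stem with at most one designed mismatch + y(5).  Returns the oriented
    precursor, the local mature and star spans, and the two sequences.
    """
    L = int(rng.choice(MATURE_LENGTHS[0], p=MATURE_LENGTHS[1]))
    a, g = 5, 11
    while True:
        mature = _random_dna(rng, L, 0.5)
        x = _random_dna(rng, a, 0.5)
        y = _random_dna(rng, 5, 0.5)
        loop = "".join(rng.choice(np.frombuffer(b"AC", dtype=np.uint8),
                                  size=g).tobytes().decode())
        # two designed mismatches in the partner arm, well inside the
        # duplex and apart from each other: keeps the stem clean by the
        # duplex criteria while making the two arms distinguishable from
        # each other's reverse complement (as in real miRNA duplexes)
        partner = list(revcomp(mature))
        p1 = int(rng.integers(4, L - 9))
        p2 = p1 + 4 + int(rng.integers(0, L - 9 - p1))
        for pos in (p1, p2):
            cur = partner[pos]
            partner[pos] = {"A": "G", "G": "A", "C": "T", "T": "C"}[cur]
        partner = "".join(partner)
        if arm == "5p":
            pre = x + mature + loop + partner + y
            mspan = (a, a + L)
            sspan = (a + L + g + 2, a + 2 * L + g + 2)
        else:
            pre = x + partner + loop + mature + y
            mspan = (a + L + g, a + 2 * L + g)
            sspan = (a + 2, a + L + 2)
        fold = fold_mfe(pre)
        located_arm, located_star = locate_arms(fold, mspan)
        if (fold.energy < cfg.ENERGY_THRESHOLD and located_arm == arm
                and located_star is not None):
            star = pre[sspan[0]:sspan[1]]
            return pre, mspan, sspan, mature, star


def _occupied_tree(annotation: AnnotationSet, contigs) -> dict[str, list]:
    occ: dict[str, list[tuple[int, int]]] = {g.contig_id: [] for g in contigs}
    for f in annotation.features:
        if f.feature_class != "gene":
            occ[f.interval.contig_id].append(
                (f.interval.start, f.interval.end))
    for c in occ:
        occ[c].sort()
    return occ


def _is_free(occ: list[tuple[int, int]], start: int, end: int,
             margin: int) -> bool:
    return all(end + margin <= s or e + margin <= start for s, e in occ)


def plant_hairpins(contigs: list[GenomeSequence], annotation: AnnotationSet,
                   config: SimulationConfig
                   ) -> tuple[list[GenomeSequence], list[PlantedMirna]]:
    """Plant designed pre-miRNA hairpins into the genome.

    Most genes go to intergenic space, a quarter inside introns, and
    ``n_exon_controls`` extra genes are deliberately planted inside exons
    as negative controls for the genomic-context criterion.  Returns the
    modified genome and the ground truth.
    """
    rng = np.random.default_rng(stage_seed(config.seed, "plant"))
    seqs = {g.contig_id: bytearray(g.sequence.encode()) for g in contigs}
    occ = _occupied_tree(annotation, contigs)
    planted_occ: dict[str, list[tuple[int, int]]] = {c: [] for c in seqs}
    introns = [f.interval for f in annotation.features
               if f.feature_class == "intron"]
    exons = [f.interval for f in annotation.features
             if f.feature_class == "exon"]
    lineages = list(LINEAGE_PRESENCE)
    planted: list[PlantedMirna] = []

    n_total = config.n_planted + config.n_exon_controls
    for i in range(n_total):
        exon_control = i >= config.n_planted
        arm = "5p" if rng.random() < 0.5 else "3p"
        pre, mspan, sspan, mature, star = _design_precursor(rng, arm)
        plen = len(pre)
        strand = "+" if rng.random() < 0.5 else "-"
        placed = None
        for _ in range(2_000):
            if exon_control:
                iv = exons[int(rng.integers(len(exons)))]
                if len(iv) < plen + 80:
                    continue
                start = int(rng.integers(iv.start + 30,
                                         iv.end - plen - 30))
                cid = iv.contig_id
            elif not exon_control and rng.random() < 0.25 and introns:
                iv = introns[int(rng.integers(len(introns)))]
                if len(iv) < plen + 120:
                    continue
                start = int(rng.integers(iv.start + 50,
                                         iv.end - plen - 50))
                cid = iv.contig_id
            else:
                cid = contigs[int(rng.integers(len(contigs)))].contig_id
                start = int(rng.integers(
                    500, len(seqs[cid]) - plen - 500))
                if not _is_free(occ[cid], start, start + plen, 60):
                    continue
            if _is_free(planted_occ[cid], start, start + plen, 300):
                placed = (cid, start)
                break
        if placed is None:
            raise ValueError("no free space left to plant hairpins")
        cid, start = placed
        insert = pre if strand == "+" else revcomp(pre)
        seqs[cid][start:start + plen] = insert.encode()
        planted_occ[cid].append((start, start + plen))

        template = (i % 5) + 1
        profile = np.array(TEMPLATES[template], dtype=float)
        blood_flag = "none"
        if template == 5:
            blood_flag = "up" if i % 2 else "down"
            if blood_flag == "up":
                profile[5] *= 3.0
            else:
                profile[4] *= 3.0
        profile = profile * np.exp(rng.normal(0.0, 0.2, size=6))
        profile = tuple(profile / profile.sum())
        planted.append(PlantedMirna(
            gene_id=f"planted_{i + 1:03d}",
            mature_seq=mature, star_seq=star,
            precursor_interval=GenomicInterval(cid, start, start + plen,
                                               strand),
            arm_of_mature=arm,
            stage_profile=profile,
            lineage_truth=lineages[i % len(lineages)],
            weight=float(np.exp(rng.normal(0.0, 0.8))),
            template=template, blood_flag=blood_flag,
            exon_control=exon_control,
            arm_switched=False,
            oriented_precursor=pre,
            mature_local=mspan, star_local=sspan))
    new_contigs = [GenomeSequence(g.contig_id,
                                  seqs[g.contig_id].decode())
                   for g in contigs]
    return new_contigs, planted


# --- libraries ---------------------------------------------------------------

def _mutate_one(rng: np.random.Generator, seq: str) -> str:
    pos = int(rng.integers(len(seq)))
    alt = "ACGT".replace(seq[pos], "")
    return seq[:pos] + alt[int(rng.integers(3))] + seq[pos + 1:]


def simulate_libraries(contigs: list[GenomeSequence],
                       annotation: AnnotationSet,
                       planted: list[PlantedMirna],
                       config: SimulationConfig,
                       ) -> dict[str, list[tuple[str, str, str]]]:
    """Six stage libraries as in-memory FASTQ records (id, seq, qual).

    Per library: miRNA reads drawn from planted genes in proportion to
    weight x stage profile, with isomiR end shifts, occasional sequencing
    errors and mature/star arm choice; a 26-30 nt piRNA-like band from
    repeat loci in E/L/F/B only; contaminant fragments of structural
    ncRNAs; random degradation fragments; every read carries the 3'
    adapter.  Deterministic per seed.
    """
    if not planted:
        raise ValueError("no planted genes to simulate from")
    rng = np.random.default_rng(stage_seed(config.seed, "libraries"))
    genome = {g.contig_id: g.sequence for g in contigs}
    repeats = [f.interval for f in annotation.features
               if f.feature_class == "repeat"]
    structural = [f.interval for f in annotation.features
                  if f.feature_class in ("rRNA", "tRNA", "snRNA", "snoRNA")]
    if config.fraction_mirna_reads == 0:
        log.warning("fraction_mirna_reads is 0: libraries are pure noise")

    weights = np.array([p.weight for p in planted])
    profiles = np.array([p.stage_profile for p in planted])
    libraries: dict[str, list[tuple[str, str, str]]] = {}
    adapter = config.adapter_seq
    for s_idx, sample in enumerate(SAMPLES):
        n = config.reads_per_library
        n_mir = int(round(n * config.fraction_mirna_reads))
        n_pi = (int(round(n * config.fraction_pirna_like))
                if sample in PIRNA_LIBRARIES else 0)
        n_cont = int(round(n * config.fraction_contaminant))
        n_deg = n - n_mir - n_pi - n_cont
        reads: list[str] = []

        p = weights * profiles[:, s_idx]
        if p.sum() == 0:      # no gene expressed at this stage
            n_deg += n_mir
            n_mir = 0
        else:
            p = p / p.sum()
        gene_idx = (rng.choice(len(planted), size=n_mir, p=p)
                    if n_mir else np.empty(0, dtype=int))
        use_star = rng.random(n_mir) < config.star_read_fraction
        s5 = rng.choice(ISOMIR_5P[0], size=n_mir, p=ISOMIR_5P[1])
        s3 = rng.choice(ISOMIR_3P[0], size=n_mir, p=ISOMIR_3P[1])
        erred = rng.random(n_mir) < config.mismatch_rate
        for gi, star_r, d5, d3, err in zip(gene_idx, use_star, s5, s3, erred):
            g = planted[gi]
            lo, hi = g.star_local if star_r else g.mature_local
            seq = g.oriented_precursor[lo + d5:hi + d3]
            if err:
                seq = _mutate_one(rng, seq)
            reads.append(seq)

        for _ in range(n_pi):
            iv = repeats[int(rng.integers(len(repeats)))]
            length = int(np.clip(round(rng.normal(28.0, 1.0)), 26, 30))
            start = int(rng.integers(iv.start, iv.end - length))
            frag = genome[iv.contig_id][start:start + length]
            reads.append(frag if rng.random() < 0.5 else revcomp(frag))

        for _ in range(n_cont):
            iv = structural[int(rng.integers(len(structural)))]
            length = int(rng.integers(18, 31))
            start = int(rng.integers(iv.start, iv.end - length))
            frag = genome[iv.contig_id][start:start + length]
            reads.append(frag if rng.random() < 0.5 else revcomp(frag))

        for _ in range(n_deg):
            cid = contigs[int(rng.integers(len(contigs)))].contig_id
            length = int(rng.integers(18, 31))
            start = int(rng.integers(0, len(genome[cid]) - length))
            frag = genome[cid][start:start + length]
            reads.append(frag if rng.random() < 0.5 else revcomp(frag))

        order = rng.permutation(len(reads))
        records = []
        for out_i, ri in enumerate(order):
            full = reads[ri] + adapter
            records.append((f"{sample}_{out_i + 1}", full, "I" * len(full)))
        libraries[sample] = records
    return libraries


def dinucleotide_shuffle(seq: str, seed: int) -> str:
    """Shuffle a sequence preserving its exact dinucleotide counts.

    Altschul-Erikson: treat bases as vertices and adjacent pairs as edges
    of a multigraph, fix a random spanning set of "last" edges oriented
    toward the terminal base so an Eulerian walk exists, shuffle the
    remaining edges, and read the walk off.  Used as the negative-control
    oracle: shuffling destroys planted hairpins but keeps local
    composition.
    """
    if len(seq) < 3:
        return seq
    rng = np.random.default_rng(seed)
    vertices = sorted(set(seq))
    edges: dict[str, list[str]] = {v: [] for v in vertices}
    for a, b in zip(seq, seq[1:]):
        edges[a].append(b)
    last = seq[-1]
    for _ in range(1_000):
        last_edge = {}
        for v in vertices:
            if v == last or not edges[v]:
                continue
            last_edge[v] = edges[v][int(rng.integers(len(edges[v])))]
        # connectivity: every vertex must reach `last` via last edges
        ok = True
        for v in last_edge:
            seen, cur = set(), v
            while cur != last and cur in last_edge and cur not in seen:
                seen.add(cur)
                cur = last_edge[cur]
            if cur != last:
                ok = False
                break
        if ok:
            break
    else:       # pragma: no cover - practically unreachable for DNA
        raise RuntimeError("dinucleotide shuffle failed to converge")
    shuffled_edges = {}
    for v in vertices:
        rest = list(edges[v])
        if v in last_edge:
            rest.remove(last_edge[v])
        rng.shuffle(rest)
        shuffled_edges[v] = rest + ([last_edge[v]] if v in last_edge else [])
    out = [seq[0]]
    cur = seq[0]
    nxt = {v: 0 for v in vertices}
    for _ in range(len(seq) - 1):
        i = nxt[cur]
        nxt[cur] += 1
        cur = shuffled_edges[cur][i]
        out.append(cur)
    return "".join(out)


# --- mock species catalogs ---------------------------------------------------

@dataclasses.dataclass
class CatalogEntry:
    entry_id: str
    species: str
    gene_id: str
    mature_seq: str        # the arm annotated as mature in this species
    star_seq: str
    precursor_seq: str
    arm: str               # arm carrying this species' mature


def _species_copy(rng: np.random.Generator, g: PlantedMirna, max_subs: int
                  ) -> tuple[str, str, str]:
    """Precursor copy with <=max_subs compensated substitutions in the
    mature, keeping the duplex intact."""
    pre = list(g.oriented_precursor)
    ms, me = g.mature_local
    ss, se = g.star_local
    n_subs = int(rng.integers(0, max_subs + 1))
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    positions = rng.choice(np.arange(ms + 3, me - 3), size=n_subs,
                           replace=False)
    for pos in positions:
        pos = int(pos)
        cur = pre[pos]
        new = "ACGT".replace(cur, "")[int(rng.integers(3))]
        pre[pos] = new
        # compensate the duplex partner inside the star span when it exists
        partner = ss + (me - 3 - pos) if pos <= me - 3 else -1
        if 0 <= partner < len(pre):
            pre[partner] = comp[new]
    pre = "".join(pre)
    return pre, pre[ms:me], pre[ss:se]


def make_known_catalogs(planted: list[PlantedMirna],
                        config: SimulationConfig,
                        ) -> tuple[dict[str, list[CatalogEntry]],
                                   dict[str, dict[str, str]]]:
    """Mock per-species miRNA catalogs and genomes implied by lineage truth.

    Each planted gene is present, with at most two substitutions, exactly
    in the species its lineage implies; conserved genes also appear in the
    Drosophila mock.  One culicinae gene is planted arm-switched in the
    Culex mock: its catalog mature is the other arm.
    """
    rng = np.random.default_rng(stage_seed(config.seed, "catalogs"))
    catalogs: dict[str, list[CatalogEntry]] = {sp: [] for sp in SPECIES}
    genomes: dict[str, dict[str, str]] = {sp: {} for sp in SPECIES}
    switch_gene = next(
        (g for g in planted
         if g.lineage_truth == "culicinae" and not g.exon_control), None)
    for g in planted:
        if g.exon_control:
            continue
        for sp in LINEAGE_PRESENCE[g.lineage_truth]:
            pre, mature, star = _species_copy(rng, g, max_subs=2)
            switched = (switch_gene is not None
                        and g.gene_id == switch_gene.gene_id
                        and sp == "Cqu")
            if switched:
                g.arm_switched = True
                mature, star = star, mature
                arm = "3p" if g.arm_of_mature == "5p" else "5p"
            else:
                arm = g.arm_of_mature
            entry = CatalogEntry(f"{sp.lower()}-{g.gene_id}", sp, g.gene_id,
                                 mature, star, pre, arm)
            catalogs[sp].append(entry)
            flank5 = _random_dna(rng, 120, 0.5)
            flank3 = _random_dna(rng, 120, 0.5)
            genomes[sp][f"{sp}_{g.gene_id}"] = flank5 + pre + flank3
    return catalogs, genomes


# --- GO map ------------------------------------------------------------------

GO_TERMS = tuple(f"GO:{7_000_000 + i}" for i in range(8))


def make_go_map(annotation: AnnotationSet, config: SimulationConfig
                ) -> dict[str, list[str]]:
    """Assign 1-4 random GO terms to every transcript with a 3' UTR."""
    rng = np.random.default_rng(stage_seed(config.seed, "go"))
    tids = sorted({f.transcript_id for f in annotation.features
                   if f.feature_class == "three_prime_UTR"})
    go_map = {}
    for tid in tids:
        k = int(rng.integers(1, 5))
        go_map[tid] = sorted(
            rng.choice(GO_TERMS, size=k, replace=False).tolist())
    return go_map


# --- output ------------------------------------------------------------------

def _write_fastq_gz(records, path: Path) -> None:
    # mtime=0 keeps gzip output byte-identical across runs
    with open(path, "wb") as raw:
        with gzip.GzipFile(filename="", mode="wb", fileobj=raw,
                           mtime=0) as fh:
            for rid, seq, qual in records:
                fh.write(f"@{rid}\n{seq}\n+\n{qual}\n".encode())


TRUTH_COLUMNS = [
    "gene_id", "contig", "precursor_start", "precursor_end", "strand",
    "mature_start", "mature_end", "mature_seq", "star_seq", "arm",
    "lineage", "template", "blood_flag", "exon_control", "arm_switched",
    "weight"] + [f"profile_{s}" for s in SAMPLES]


def write_truth(planted: list[PlantedMirna], path: Path) -> None:
    rows = []
    for g in planted:
        miv = g.mature_interval()
        row = {"gene_id": g.gene_id, "contig": g.precursor_interval.contig_id,
               "precursor_start": g.precursor_interval.start,
               "precursor_end": g.precursor_interval.end,
               "strand": g.precursor_interval.strand,
               "mature_start": miv.start, "mature_end": miv.end,
               "mature_seq": g.mature_seq, "star_seq": g.star_seq,
               "arm": g.arm_of_mature, "lineage": g.lineage_truth,
               "template": g.template, "blood_flag": g.blood_flag,
               "exon_control": int(g.exon_control),
               "arm_switched": int(g.arm_switched),
               "weight": f"{g.weight:.6f}"}
        row.update({f"profile_{s}": f"{p:.6f}"
                    for s, p in zip(SAMPLES, g.stage_profile)})
        rows.append(row)
    write_tsv(rows, path, TRUTH_COLUMNS)


def generate_all(config: SimulationConfig, out_dir: str | Path) -> dict:
    """Run the full generator and write every output file.

    Outputs: genome.fa, annotation.gff3, truth.tsv, go_map.tsv,
    known_<species>.fa and mock_genome_<species>.fa per species, and
    lib_<S>.fastq.gz per sample.  Byte-identical for a fixed seed.
    """
    from .io_formats import write_gff3

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    contigs, annotation = generate_genome(config)
    contigs, planted = plant_hairpins(contigs, annotation, config)
    libraries = simulate_libraries(contigs, annotation, planted, config)
    catalogs, mock_genomes = make_known_catalogs(planted, config)
    go_map = make_go_map(annotation, config)

    write_fasta(contigs, out / "genome.fa")
    write_gff3(annotation.features, out / "annotation.gff3")
    write_truth(planted, out / "truth.tsv")
    with open(out / "go_map.tsv", "w") as fh:
        fh.write("transcript_id\tgo_terms\n")
        for tid, terms in sorted(go_map.items()):
            fh.write(f"{tid}\t{';'.join(terms)}\n")
    for sp in SPECIES:
        write_fasta([(e.entry_id, e.mature_seq) for e in catalogs[sp]],
                    out / f"known_{sp}.fa")
        write_fasta(sorted(mock_genomes[sp].items()),
                    out / f"mock_genome_{sp}.fa")
    paths = {}
    for sample, records in libraries.items():
        p = out / f"lib_{sample}.fastq.gz"
        _write_fastq_gz(records, p)
        paths[sample] = str(p)
    return {"contigs": contigs, "annotation": annotation,
            "planted": planted, "libraries": paths,
            "catalogs": catalogs, "mock_genomes": mock_genomes,
            "go_map": go_map, "out_dir": str(out)}
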