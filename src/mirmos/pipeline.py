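"""Pipeline orchestration and the packaged novel-miRNA catalog.

``run_all`` executes the stages in order -- optional simulation,
preprocessing, mapping, hairpin discovery, homology, expression and
target/GO analysis -- writing every stage output plus a run manifest with
the seed, parameter hash and output checksums, so identical configs and
inputs give identical manifests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import importlib.resources
import json
import logging
import time
from pathlib import Path

from . import expression, homology, mapping, preprocess, targets
from .config import PipelineConfig
from .hairpin import call_mirna_genes
from .io_formats import (GenomicInterval, read_fasta, read_gff3,
                         write_dotbracket, write_mirna_gff3, write_tsv)

log = logging.getLogger("mirmos.pipeline")

CATALOG_RESOURCE = "novel_mirna_catalog.tsv"
CATALOG_SHA256 = ("66bacc66618b8e7f6a37ae43078e8f4e6d4c62c7d6576f6fe4"
                  "787a99e73c0fc8")


# --- packaged novel-miRNA catalog -------------------------------------------

@dataclasses.dataclass(frozen=True)
class NovelMirnaRecord:
    name: str
    sequence: str
    longest_extension: str | None
    contig: str
    printed_start: int
    printed_end: int
    strand: str
    section: str
    interval: GenomicInterval
    gene: str                 # base gene name, locus suffixes collapsed
    is_star: bool


def _base_gene(name: str) -> str:
    base = name.rstrip("*")
    head, _, tail = base.rpartition("-")
    if tail.isdigit() and head.endswith(("new1", "new2", "new3", "new4",
                                         "new5", "new6", "new7", "new8",
                                         "new9", "new10", "new11", "new12",
                                         "new13", "new14", "new15")):
        return head
    return base


def load_novel_mirna_catalog() -> list[NovelMirnaRecord]:
    """The packaged catalog of novel mosquito miRNAs.

    Minus-strand loci are printed with start > end (the printed order
    encodes transcript orientation); the loader sorts each pair into
    (min, max) and keeps the strand.  Star rows share their gene's locus;
    "-1"/"-2" suffixed loci produce the same mature and collapse to one
    gene name.  The file checksum is verified on load.
    """
    data = (importlib.resources.files("mirmos.data") / CATALOG_RESOURCE
            ).read_bytes()
    digest = hashlib.sha256(data).hexdigest()
    if digest != CATALOG_SHA256:
        raise ValueError(f"novel miRNA catalog checksum mismatch: {digest}")
    lines = data.decode().splitlines()
    header = lines[0].split("\t")
    records = []
    for line in lines[1:]:
        row = dict(zip(header, line.split("\t")))
        start_p, end_p = int(row["start"]), int(row["end"])
        lo, hi = min(start_p, end_p), max(start_p, end_p)
        interval = GenomicInterval(row["contig"], lo - 1, hi, row["strand"])
        ext = None if row["longest_extension"] == "." else \
            row["longest_extension"]
        records.append(NovelMirnaRecord(
            row["name"], row["sequence"], ext, row["contig"],
            start_p, end_p, row["strand"], row["section"], interval,
            _base_gene(row["name"]), row["name"].endswith("*")))
    return records


def catalog_gene_summary(records: list[NovelMirnaRecord]) -> dict:
    """Distinct gene count and per-section gene tallies of the catalog."""
    genes: dict[str, str] = {}
    for r in records:
        genes.setdefault(r.gene, r.section)
    per_section: dict[str, int] = {}
    for section in genes.values():
        per_section[section] = per_section.get(section, 0) + 1
    return {"n_genes": len(genes), "per_section": per_section,
            "n_records": len(records)}


# --- orchestration -----------------------------------------------------------

def _sha256_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(config: PipelineConfig, simulate=None) -> dict:
    """Execute every pipeline stage and write a run directory.

    When ``simulate`` (a SimulationConfig) is given, synthetic inputs are
    generated first and the config's input paths are pointed at them.
    Returns a results dict; raises with the failing stage's name on error.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    stage = "setup"
    t_stage = time.time()

    def _tick(done: str) -> None:
        nonlocal t_stage
        log.info("stage %-12s %6.1f s", done, time.time() - t_stage)
        t_stage = time.time()

    try:
        catalogs = {}
        mock_genomes = {}
        if simulate is not None:
            stage = "simulate"
            from .synthetic_data import generate_all
            sim = generate_all(simulate, out / "data")
            config.genome = str(out / "data" / "genome.fa")
            config.annotation = str(out / "data" / "annotation.gff3")
            config.go_map = str(out / "data" / "go_map.tsv")
            config.adapter = simulate.adapter_seq
            config.libraries = sim["libraries"]
            catalogs = sim["catalogs"]
            mock_genomes = sim["mock_genomes"]

        _tick(stage)
        stage = "load_inputs"
        for field in ("genome", "annotation"):
            if not Path(getattr(config, field)).exists():
                raise FileNotFoundError(
                    f"missing input for config field '{field}': "
                    f"{getattr(config, field)}")
        contigs = read_fasta(config.genome)
        genome = {c.contig_id: c.sequence for c in contigs}
        annotation = read_gff3(config.annotation)

        _tick(stage)
        stage = "preprocess"
        tags_raw, pp_stats = preprocess.preprocess_libraries(
            config.libraries, config.adapter,
            min_len=config.min_len, max_len=config.max_len)
        size_dist = preprocess.size_distribution(tags_raw)
        size_dist.to_csv(out / "size_distribution.tsv", sep="\t")
        tags, cont_stats = preprocess.filter_contaminants(
            tags_raw, annotation, genome)
        preprocess.write_tags_tsv(tags, out / "tags.tsv")
        results["preprocess_stats"] = pp_stats
        results["size_distribution"] = size_dist
        results["tags"] = tags

        _tick(stage)
        stage = "map"
        index = mapping.SeedIndex(contigs)
        hits_by_tag, unmapped = mapping.map_all(tags, index)
        mapping.write_hits_tsv(hits_by_tag, out / "hits.tsv")
        results["n_mapped_tags"] = len(hits_by_tag)
        results["n_unmapped_tags"] = len(unmapped)

        _tick(stage)
        stage = "discover"
        genes, reports = call_mirna_genes(
            tags, hits_by_tag, genome, annotation,
            flank=config.flank, energy_threshold=config.energy_threshold)
        write_tsv(reports, out / "candidates.tsv",
                  list(reports[0].keys()) if reports else ["candidate_id"])
        write_mirna_gff3(genes, out / "genes.gff3")
        write_dotbracket(
            [(g.gene_id, g.precursor.window_seq, g.precursor.fold.structure,
              g.precursor.fold.energy) for g in genes],
            out / "precursors.dotbracket")
        results["genes"] = genes
        results["n_candidates"] = len(reports)

        _tick(stage)
        stage = "homology"
        if mock_genomes:
            hom_rows = homology.annotate_genes(genes, catalogs, mock_genomes)
            homology.write_homology_tsv(hom_rows, out / "homology.tsv")
            results["homology"] = hom_rows

        _tick(stage)
        stage = "quantify"
        matrix = expression.count_reads(genes, hits_by_tag, tags)
        results["pre_gate_matrix"] = expression.ExpressionMatrix(
            matrix.raw.copy())
        matrix = expression.filter_expressed(matrix, config.expr_min_reads)
        if len(matrix.raw) > 0:
            matrix = expression.normalize_cpm(matrix)
            expression.write_expression_tsv(matrix, out / "expression.tsv")
        clusters = {}
        if len(matrix.raw) >= config.k_clusters:
            assignment = expression.cluster_profiles(matrix,
                                                     k=config.k_clusters)
            expression.write_clusters_tsv(matrix, assignment,
                                          out / "clusters.tsv")
            clusters = assignment.clusters
        results["expression"] = matrix
        results["clusters"] = clusters

        _tick(stage)
        stage = "targets"
        utr_feats = [f for f in annotation.features
                     if f.feature_class == "three_prime_UTR"]
        utrs = {}
        for f in utr_feats:
            iv = f.interval
            seq = genome[iv.contig_id][iv.start:iv.end]
            from .io_formats import revcomp
            utrs[f.transcript_id] = seq if iv.strand == "+" else revcomp(seq)
        mirna_seqs = {f"{g.gene_id}|mature": g.mature_seq for g in genes}
        mirna_seqs.update({f"{g.gene_id}|star": g.star_seq for g in genes
                           if g.star_seq is not None and g.star_observed})
        sites, t_stats = targets.predict_targets(mirna_seqs, utrs,
                                                 config.target_cutoff)
        targets.write_targets_tsv(sites, out / "targets.tsv")
        go_map = targets.read_go_map(config.go_map) \
            if Path(config.go_map).exists() else {}
        background = set(utrs)
        enrich = targets.enrichment_by_cluster(
            sites, clusters, go_map, background, fdr=config.fdr)
        targets.write_enrichment_tsv(enrich, out / "enrichment.tsv")
        results["target_sites"] = sites
        results["enrichment"] = enrich

        _tick(stage)
        stage = "manifest"
        outputs = sorted(p for p in out.rglob("*") if p.is_file())
        manifest = {
            "seed": config.seed,
            "param_hash": config.param_hash(),
            "config": config.to_dict(),
            "outputs": {str(p.relative_to(out)): _sha256_file(p)
                        for p in outputs},
        }
        manifest["manifest_hash"] = hashlib.sha256(
            json.dumps(manifest, sort_keys=True).encode()).hexdigest()
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        results["manifest"] = manifest
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
    return results
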