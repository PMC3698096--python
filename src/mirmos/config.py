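"""Pipeline configuration.

Every tunable threshold of the pipeline lives here, once.  Stage modules
import these defaults rather than re-declaring them, so a configured
:class:`PipelineConfig` is the single source of truth for a run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Any

import yaml

log = logging.getLogger("mirmos")

# --- preprocessing -----------------------------------------------------------
MIN_TAG_LEN = 18          # nt, smallest tag kept after trimming
MAX_TAG_LEN = 30          # nt, largest tag kept
MIN_ADAPTER_OVERLAP = 6   # nt of 3' adapter prefix required for a trim
MAX_ADAPTER_MISMATCH = 1  # mismatches tolerated in the adapter overlap
MIN_BASE_QUALITY = 10     # reads with any insert base below this are dropped

# --- mapping -----------------------------------------------------------------
MAX_MAP_MISMATCH = 1      # genome hits kept at Hamming distance <= 1
INDEX_K = 9               # seed k-mer size for the hash index

# --- hairpin discovery -------------------------------------------------------
FLANK = 100               # nt of genomic context on each side of a tag locus
ENERGY_THRESHOLD = -20.0  # kcal/mol; hairpins must fold strictly below this
MIN_SEED_READS = 5        # pooled reads required to seed a candidate locus
MAX_UNPAIRED_MATURE = 4   # duplex cleanliness: unpaired mature bases allowed
MAX_DUPLEX_LOOP = 3       # duplex cleanliness: largest bulge/internal loop
MODAL_5P_FRACTION = 0.70  # read-stack: fraction sharing the modal 5' end
MAX_OUTSIDE_FRACTION = 0.10  # read-stack: reads off the two arms
MIN_STACK_READS = 5       # read-stack: minimum reads on the precursor

# --- homology ----------------------------------------------------------------
BLAST_WORD_SIZE = 7       # seed word for the catalog search
BLAST_MAX_EVALUE = 10.0   # permissive catalog-search cutoff
BLAST_LAMBDA = 1.33       # ungapped Karlin-Altschul lambda
BLAST_K = 0.621           # ungapped Karlin-Altschul K
INSPECT_MIN_IDENTITY = 0.60   # post-search inspection: identity over the hit
INSPECT_MIN_LENGTH = 16       # post-search inspection: aligned length
MAPMI_CUTOFF = 35.0       # genome-scan score above which a homologue counts
HAIRPIN_BONUS = 5.0       # genome-scan bonus for a hairpin-forming locus
NONHAIRPIN_PENALTY = -20.0

# --- expression --------------------------------------------------------------
EXPR_MIN_READS = 15       # pooled raw reads for a gene to count as expressed
ISOMIR_5P_TOL = 2         # counting tolerance at the 5' end, nt
ISOMIR_3P_TOL = 5         # counting tolerance at the 3' end, nt
K_CLUSTERS = 5            # expression-profile clusters
SPECIFICITY_FRACTION = 0.5   # stage specificity: share of total CPM required
BLOOD_FOLD = 2.0          # blood-meal response fold-change
BLOOD_MIN_CPM = 10.0      # blood-meal response minimum CPM

# --- targets & GO ------------------------------------------------------------
TARGET_CUTOFF = 150.0     # duplex score below which a site is discarded
GO_FDR = 0.01             # Benjamini-Hochberg q-value threshold
GO_MIN_TARGETS = 3        # GO terms tested only with this many target hits


@dataclasses.dataclass
class PipelineConfig:
    """All stage parameters plus input/output paths for one run."""

    # paths
    genome: str = "genome.fa"
    annotation: str = "annotation.gff3"
    go_map: str = "go_map.tsv"
    libraries: dict[str, str] = dataclasses.field(default_factory=dict)
    catalogs: dict[str, str] = dataclasses.field(default_factory=dict)
    out_dir: str = "run"
    # parameters
    adapter: str = "TGGAATTCTCGGGTGCCAAGG"
    min_len: int = MIN_TAG_LEN
    max_len: int = MAX_TAG_LEN
    max_mm_map: int = MAX_MAP_MISMATCH
    flank: int = FLANK
    energy_threshold: float = ENERGY_THRESHOLD
    expr_min_reads: int = EXPR_MIN_READS
    mapmi_cutoff: float = MAPMI_CUTOFF
    target_cutoff: float = TARGET_CUTOFF
    fdr: float = GO_FDR
    k_clusters: int = K_CLUSTERS
    seed: int = 42

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def param_hash(self) -> str:
        """Stable hash of the full parameter set, for the run manifest."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def stage_seed(seed: int, stage: str) -> int:
    """Derive a per-stage substream seed from the run seed.

    Salting with the stage name lets a stage be re-run reproducibly without
    replaying its predecessors' random draws.
    """
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(levelname)s\t%(name)s\t%(message)s",
    )
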