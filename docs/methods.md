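# Methods

This note documents the models and procedures implemented in `mirmos`, the
choices made where the design was genuinely open, and what the synthetic
study does and does not establish about real data.

## Single-stem MFE folding

Pre-miRNA evaluation needs only hairpin geometry, so the folding engine is
a nearest-neighbour minimum-free-energy dynamic program restricted to
single-stem structures: one helix whose consecutive pairs may be separated
by bulges and internal loops (at most 10 unpaired bases between
consecutive pairs, on both strands combined), closed by a terminal hairpin
loop of at least 3 nt.  Multibranch loops and pseudoknots are outside the
model.  `E(i,j)` is the best energy of a structure closed by pair `(i,j)`;
the empty structure scores 0, so reported energies are never positive.

Parameters are embedded Turner-style tables in kcal/mol at 37 °C:
stacking energies for all combinations of the six allowed pairs
(Watson-Crick plus G:U), hairpin/bulge/internal-loop initiation penalties
by size with a Jacobson-Stockmayer `1.75·RT·ln(n/n_ref)` extrapolation
(RT = 0.616), and an internal-loop asymmetry penalty of 0.5 kcal/mol per
nt capped at 3.  Terminal-AU and loop-sequence bonuses are deliberately
omitted: the pipeline's decisions depend on an energy threshold of
-20 kcal/mol against stems 20+ bp deep, where these ~0.5 kcal/mol terms
are immaterial.  The DP is verified against exhaustive enumeration of
every single-stem structure on random sequences up to 30 nt, and an
optional external folding backend can be compared manually; all shipped
analyses use the built-in engine.

The interior-size cap (10 nt) bounds the DP at `O(n²·c²)` and is also a
model statement: a "hairpin" interrupted by a >10-nt interior loop is not
a pre-miRNA-like stem, and candidates containing any loop above 3 nt in
the duplex are rejected later anyway.

## Discovery criteria

Candidates are seeded at the loci of mapped tags carrying at least 5
pooled reads; windows of 100 nt genomic context on each side are folded,
and windows overlapping on the same strand are merged.  The merged
candidate is anchored on its most abundant tag (ties prefer perfect
hits): read abundance, not fold energy, decides which arm is the mature,
because in every deep-sequenced miRNA locus the mature strand is the
abundant one.  Criteria:

- **one arm** — the mature lies entirely 5' or 3' of the terminal loop;
- **clean duplex** — the mature's paired bases are split into helix runs
  wherever a bulge/internal loop exceeds 3 nt on either strand; all bases
  outside the longest run (mismatches, large loops, breathing helix ends)
  count as unpaired, and at most 4 are tolerated;
- **energy** — window fold strictly below -20.0 kcal/mol (boundary
  tested: -19.9 fails, -20.1 passes);
- **context** — the window midpoint falls in intergenic or intronic
  space.  Structural-ncRNA/repeat tags are removed during cleaning, but
  exon/intron-matching tags are only flagged and carried forward, so
  intronic miRNAs survive while the genic-context rule is enforced here,
  at the hairpin, where it is decidable;
- **read stack** — ≥5 reads on the precursor, ≥70 % of mature-arm reads
  share the modal 5' end, ≤10 % of reads fall outside the two arms, and
  any star reads must start within 1 nt of the predicted star.

The star span is the duplex partner of the mature shifted to leave 2-nt
3' overhangs on both ends (anchored on the partners of the mature 5' end
and of the base two in from its 3' end); a star is marked *observed* when
a tag maps within 2 nt of that span.  Discovery pools all six samples, so
a gene expressed in a single stage is still found.

## Homology, lineage, arm switches

The catalog search is a 7-mer-seeded ungapped local alignment (+1/-2)
with Karlin-Altschul E-values (λ = 1.33, K = 0.621, m·n = query ×
catalog length) at the permissive cutoff E ≤ 10; a surviving hit must
then pass an inspection rule of ≥60 % identity over ≥16 nt.  The genome
scan finds every locus within 1 or 3 mismatches (the 1-mismatch setting
is by construction a subset of the 3-mismatch scan and both are
reported) and scores it `S = 2·(L-mm) - 4·mm + B`, where B is +5 when the
flanked locus folds into a clean one-arm hairpin below -20 kcal/mol and
-20 otherwise; a homologue counts as present at S ≥ 35.  The constants
are calibrated so that an exact 22-mer at a hairpin locus scores 49,
three mismatches at a hairpin locus score 31, and an exact match without
a hairpin scores 24 — only near-exact, structure-supported copies clear
the cutoff.

Presence across the mock species resolves to the most specific label:
Drosophila-group presence → conserved beyond mosquitoes; all three
mosquito genera → mosquito-specific; Aedes + Culex → Culicinae-specific;
both Aedes species only → Aedes-specific; anything else (including
phylogenetically inconsistent patterns such as Aedes + Anopheles alone)
→ species-specific with a warning.  An arm switch is called when the
query's mature matches the homologue's star arm with ≥18 nt identity and
vice versa.

## Expression

Counting tolerates isomiR heterogeneity: a hit is assigned to an arm when
its 5' end is within 2 nt and its 3' end within 5 nt of the annotated
span on the same strand; a hit eligible for both arms goes to the nearer
5' end.  The expression gate keeps a gene when mature or star reaches 15
pooled raw reads (raw, before normalization); both rows of a kept gene
are retained.  CPM divides by the per-sample total of all counted rows
(mature + star).  Clustering: log2(CPM+1), distance 1 - Pearson
correlation (zero-variance rows get distance 1 to everything), average
linkage, tree cut at exactly k = 5.  Stage specificity labels a row by
the sample holding ≥50 % of its CPM; blood response is a 2-fold
comparison of blood-fed vs sugar-fed females with a 10-CPM floor.  These
thresholds are declared defaults, configurable.

## Targets and GO

Target scoring is a seed-weighted affine-gap local alignment of the
mature (antisense, 3'→5') against the UTR: Watson-Crick +5, G:U wobble
+1, mismatch -3, gap open -9, gap extend -4, with the substitution score
at miRNA positions 2-8 multiplied by 4.  A perfect 22-mer scores 215 and
a perfect seed alone 140, so the site cutoff of 150 demands seed pairing
plus 3'-supplementary support.  Sites are emitted greedily
best-first with masking, so reported sites never overlap.  No separate
thermodynamic filter is applied; the score is the criterion.

GO enrichment runs per expression cluster: one-sided Fisher's exact test
per term carried by ≥3 target transcripts, against the background of all
transcripts with an annotated 3' UTR, Benjamini-Hochberg across the
tested terms, significant at q < 0.01.  GO terms are treated as flat
labels; DAG ancestor propagation is out of scope.

## Synthetic study

The generator emulates the study design, not sequencing physics.  Default
scale: 2 contigs × 200 kb of i.i.d. background at GC 0.5 with
three-exon genes, 3' UTRs and structural-ncRNA/repeat loci; 40 planted
genes (plus 4 exon-planted negative controls) built as
5-nt flank + mature arm + 11-nt A/C loop + complementary arm + 5-nt
flank, with exactly two designed duplex mismatches placed well inside the
stem — as in real miRNA duplexes — which also keeps each arm
distinguishable from the other's reverse complement at one mapping
mismatch.  Mature lengths are 21-23 nt peaked at 22.  Stage profiles come
from five biased templates (embryo, larva, pupa, male, female) with a
×3 blood up/down modifier on female-biased genes and lognormal jitter;
per-gene abundance is lognormal.  Six libraries of 100,000 reads mix
70 % miRNA-derived reads (isomiR shifts: 5' ∈ {-1,0,+1} with P(0)=0.8,
3' ∈ {-2..+2} peaked at 0; 10 % of reads from the star arm; 1 % of reads
carry one sequencing error), a 26-30 nt repeat-derived band (15 %) in the
embryo/larva/female libraries only, structural-ncRNA fragments (8 %), and
random degradation fragments; every read carries the 3' adapter.  Mock
genomes/catalogs for *Ae. aegypti*, *Cu. quinquefasciatus*, *An. gambiae*
and a *Drosophila* group contain each gene exactly where its planted
lineage implies, with ≤2 duplex-compensated substitutions, and one
Culicinae gene is planted arm-switched in the Culex mock.  A truth
manifest (TSV) accompanies every run and is the sole source of truth for
recovery tests.  Outputs are byte-identical for a fixed seed (gzip
written with zero mtime).

What passing does **not** show about real data: no ligation or PCR bias,
no realistic quality model, no paralogous gene families or repeat-derived
multimapping ambiguity, no genuine piRNA biology (the 26-30 nt band is a
size-distribution stand-in), and planted hairpins are cleaner than many
genuine precursors.  The oracle tests (exhaustive folding enumeration,
exhaustive Hamming mapping, hypergeometric enumeration, brute-force
alignment DP) are scale-independent and carry the correctness burden for
the primitives; the synthetic study establishes that the assembled
pipeline recovers a known answer under its stated conditions.

The negative control shuffles the genome preserving exact dinucleotide
counts (Altschul-Erikson) — local composition survives, hairpins do not —
and the pipeline must call zero genes on it.

## Numerical and degenerate-input choices

- Coordinates are 0-based half-open on the plus strand everywhere
  internally; GFF3 converts at the boundary, and printed minus-strand
  catalog loci (start > end, orientation encoded in the order) are sorted
  to (min, max) with strand kept on load.
- Sequences containing N are excluded from folding and mapping (undefined
  pairing energy); genomes may contain N.
- Windows clipped at contig edges to under tag length + 20 nt are skipped
  with a log entry.
- The "~22 nt" and "~28 nt" read classes are operationalized as the
  closed bins [21, 23] and [26, 30]; the piRNA-band restriction is tested
  as a ≥1.5-fold excess over the pupa and male libraries.
- "Adequately expressed" in recovery tests means an expected pooled
  read count of at least the 15-read expression gate, computed from the
  truth manifest.
- One run seed drives every stage through name-salted substreams
  (SHA-256 of `"seed:stage"`, reduced below 2³¹), so a stage can be
  re-run reproducibly without replaying its predecessors.
- Clustering ties are resolved by SciPy's deterministic average-linkage
  ordering; partitions are invariant to row order (tested via adjusted
  Rand index = 1).
- Problem sizes in the shipped tests — 200-sequence folding oracle at
  ≤30 nt, 1,000-tag mapping oracle on 50 kb, the 100k-read default study
  — were chosen as the smallest scales at which every recovery statistic
  is stable across seeds.

## Known limitations

- The folder's energy tables are a compact Turner-style subset; absolute
  energies differ from full-featured folders by a few kcal/mol on long
  flanked windows, which is why the threshold criterion, not the absolute
  value, is the contract.
- Homology E-values use fixed ungapped Karlin-Altschul constants, adequate
  for the permissive E ≤ 10 pre-filter role only.
- Star-arm annotation for genes whose star is unobserved is geometric
  prediction, not evidence.
- Multimapped tags count fully at every locus; no fractional assignment.
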