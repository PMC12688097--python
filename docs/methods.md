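# Methods

This note documents the models and procedures implemented in `ohnomir`,
the parameters that matter, the synthetic study conditions, and the
numerical choices made where the design was genuinely open. It states no
empirical result that the test suite or the analysis drivers do not
themselves compute.

## Seed-weighted global alignment

Mature miRNAs (19–25 nt) recognize targets mainly through their seed
region, canonically nucleotides 2–8 from the 5′ end. The alignment is a
standard global dynamic program over column scores:

- substitution column: ±`in_seed_weight` (default 5) if the consumed
  nucleotide of **either** sequence lies in its own seed window, else
  ±`out_seed_weight` (default 1);
- gap column: `gap_penalty` (default −2), end gaps included.

A 22-nt self-alignment therefore scores 7·5 + 15·1 = 50 under defaults.
Gene-pair similarity is the maximum over the Cartesian product of the two
genes' matures, with ties broken by mature id for determinism.

Open choices and how they were fixed:

- **Gap penalty.** The weighting scheme specifies only match/mismatch
  magnitudes; matures are near-equal length, so gaps are rare. We use a
  uniform, configurable −2 per gap column, identical in and out of seed,
  and penalize end gaps (true global alignment) because end-trimming
  would inflate similarity for short RNAs.
- **Seed classification of a substitution column.** "Either sequence's
  seed window" is the symmetric, conservative reading; windows are
  1-based, 6mer = 2–7, 7mer = 2–8, 8mer = 2–9.
- **Co-optimal tracebacks** prefer diagonal > up > left; the score is
  unaffected.
- DNA input is normalized T→U on ingest.

Correctness is checked against an independent exhaustive oracle that
enumerates all monotone position matchings (equivalent to enumerating all
global alignments, because gap ordering never changes the score) for all
pairs up to length 8.

## Duplicate catalog

- WGD and SSD pair lists may overlap; the catalog keeps one copy labeled
  WGD (and per-miRNA labels for single-miRNA analyses use the same WGD
  priority), so the two sets are disjoint.
- **Intragenic containment** uses the host's gene-body interval (not
  transcript structure): a miRNA is intragenic iff its full interval lies
  within the host interval. Strand conservation means
  relative_strand(miRNA₁, host₁) = relative_strand(miRNA₂, host₂); both
  sense-sense and antisense-antisense configurations qualify.
- **RBH** is computed within each host-gene pair (not globally): a
  candidate survives iff each member is the other's best-scoring partner
  among that host pair's candidates. Tied best hits are discarded rather
  than broken arbitrarily — a conservative, high-confidence choice. The
  output is a partial matching per host pair.
- **Duplication timing**: a pair is pre-2R iff its last-common-ancestor
  clade is strictly older than Vertebrata in a configurable ordered
  lineage (an NCBI-style order ships as the default). Curated exceptions
  (e.g. known misannotations) enter through the manual-override mechanism
  rather than transcript-level logic.

## Network curation

- Evidence filters: tissue-category whitelist, direct-evidence and
  high-throughput flags, and a top-score-quantile cut computed over the
  full input table. Rows tied with the quantile threshold are **kept**,
  making the cut independent of row order.
- Mature→gene collapse expands a mature produced by k loci into k
  gene-level edges and merges duplicates; 5p/3p edges of one gene are
  unioned (the network is unweighted — edge multiplicities from multiple
  evidence rows are not used). Unmapped matures are dropped with a
  warning, since real exports always contain orphans.
- Duplicate pairs whose two gene-level nodes have the exact same target
  set are excluded from enrichment/similarity (they are database-level
  indistinguishable); pairs with a member absent from the network are
  likewise dropped and counted.
- PPI tables are thresholded strictly (confidence > 960 by default),
  deduplicated as unordered pairs, self-loops removed.

## Motif enrichment

Subjects are duplicate pairs (V, bifan, PPI-bifan) or single miRNAs with
WGD-priority labels (PPI-delta). Counts:

- V: |targets(a) ∩ targets(b)|;
- bifan: distinct duplicate target pairs (deduplicated as unordered
  pairs) fully co-targeted by both miRNAs; by default the target pair's
  origin must equal the miRNA pair's (configurable off for plain bifans,
  mandatory for PPI-bifans);
- PPI-bifan: bifans whose target pair carries a PPI edge;
- PPI-delta: PPI-coupled duplicate target pairs both targeted by one
  miRNA.

The **null ensemble** applies bipartite double-edge swaps (default 10
proposals per edge; proposals creating existing edges or no-ops are
skipped), preserving every outdegree and indegree exactly — a hard,
per-replicate assertion in the tests. Replicates are seeded from spawns
of a single seed and streamed; full null networks are never stored.

The **pairwise Z-score** holds the subject's node identities fixed and
recomputes its count on every replicate; Z = (n − mean)/sd with the
population (ddof = 0) standard deviation, since the ensemble is the whole
population of interest (configurable). Degenerate cases follow the
stated rules — sd = 0 with mean ≠ 0: the subject is discarded and
reported; sd = 0 with mean = 0: Z = 0. Note that the Z = 0 rule applies
regardless of the real count n, so a pair observed with n > 0 whose null
counts are all zero is scored 0, not +∞; this is a deliberate,
documented convention (its verbal gloss in the source literature is
internally inconsistent; we implement the symbolic rule). A run-level
check warns when discarded subjects exceed 1% of the evaluable set.
Summaries bin V counts as {0, 1–50, >50} and other motifs as {0, ≥1}.

## Synthetic study conditions

The generator emulates the five input classes with planted, recoverable
structure. Defaults (the study conditions used by the analysis drivers
and the acceptance checks):

| parameter | default | rationale |
|---|---|---|
| n_wgd_pairs / n_ssd_pairs | 100 / 100 | two same-sized contrast groups |
| dice_wgd / dice_ssd | 0.30 / 0.05 | strong vs weak planted target overlap |
| bifan_plant_rate | 0.5 (WGD only) | half of WGD pairs co-target a duplicate target pair |
| ppi_couple_prob | 0.8 | planted target pairs usually PPI-coupled |
| seed conservation WGD/SSD | 0.95 / 0.50 | near-identical vs divergent seeds |
| non-seed conservation WGD/SSD | 0.75 / 0.35 | lower than seed, same ordering |
| expr_shift_wgd | +1.0 (log scale) | WGD miRNAs more expressed |
| outdegree law | k^−2.2 on [10, 300] | heavy tail at realistic density (below) |
| frac_intragenic | 0.15 | minority of pairs hosted intragenic |
| n_tissues | 10 | one sample per tissue |

**Density.** The outdegree exponent 2.2 reproduces a long-tailed degree
distribution; the lower bound 10 sets the mean outdegree to ≈29 targets,
matching the edge density of a realistic curated miRNA–target network
(~1.4% of the target space per miRNA) at the desk scale of 2,000 target
genes. At densities an order of magnitude lower the degree-preserving
null ensemble is degenerate — nearly every subject's null counts are all
zero and the double-zero rule forces Z = 0 across the board — so no
enrichment contrast can exist for *any* method; matching realistic
density is a property of the study design, not a tuning of any outcome.

**Planting.** Shared targets are allocated first (s ≈ dice·(k_a+k_b)/2,
clamped to the smaller degree when a draw makes the exact value
infeasible), then each member fills its remaining degree with private
targets drawn jointly without replacement, so planted pairs are never
accidentally indistinguishable; dice = 1 deliberately produces the
identical-set (indistinguishable) case. Bifan-planted WGD pairs co-target
a dedicated duplicate target pair, which receives a high-confidence PPI
edge with probability `ppi_couple_prob`; background PPI edges avoid
planted pairs so the zero-coupling case is exact. Raw interaction rows
carry evidence attributes; decoy rows (20% of the table) fail every
criterion, so evidence filtering recovers the planted network. Matures
whose derived sequence is byte-identical to the template share one mature
id across both loci, emulating the database redundancy that motivates
gene-level collapse. Expression is log-normal (log-mean 4.0, log-sd 1.0)
with the WGD shift applied per WGD-priority gene label.

All stages draw from independent substreams of one seed; identical
config + seed gives byte-identical output files. A truth manifest
(planted intragenic pairs, bifan plantings, PPI couplings, realized dice)
accompanies every bundle.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: no phylogenetic sequence evolution (pair
similarity is i.i.d. per-position conservation), no subgenome synteny
(α/β and 1R/2R labels are random annotations, not simulated history), no
correlated evidence noise or study-attention bias in the interaction
tables, no transcript-level annotation structure, and uniform tissue
effects in expression. Recovery results demonstrate the correctness of
the pipeline's inference under the planted model, not the biological
claims themselves.

## Problem sizes

The default study uses 450 miRNA genes (100+100 pairs plus singletons and
decoys), 2,000 target genes (~11,600 gene-level edges), 10 tissues, and
100 null replicates in the drivers and recovery checks; the null-model
invariant checks use a ~1,000-edge network with 100 replicates, and the
alignment oracle sweep covers ~10⁴ pairs up to length 8. These sizes keep
every driver and the full test suite in the minutes range on one CPU
while leaving all planted contrasts statistically unambiguous; replicate
counts and sizes are configurable upward (the enrichment default in the
CLI is 1,000 replicates).

## Known limitations

- The rewiring chain's mixing is assessed only by an edge-Jaccard
  randomization check, not by formal mixing diagnostics; 10 swaps per
  edge is a standard but heuristic choice.
- Dice planting controls the expectation, not the variance, of pair
  overlap; degree draws at the clamp boundary bias realized dice slightly
  toward the feasible range (realized values are recorded in the truth
  manifest).
- The expression model attributes shared (ambiguous) matures to no
  precursor and excludes them, as a mature-level atlas cannot attribute
  them either.
- `compare_sources` contrasts independent synthetic realizations; it
  emulates the *procedure* of swapping interaction databases, not the
  correlated error structure of real alternative databases.
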