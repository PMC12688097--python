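# ohnomir

Analysis toolkit for **ohnolog miRNA pairs** — miRNA duplicates retained
from the two rounds of whole-genome duplication (WGD, "1R/2R") at the base
of the vertebrate lineage — and their role in the post-transcriptional
regulatory network, contrasted with small-scale-duplication (SSD) pairs.

It is written for computational/systems biologists who want to reproduce or
extend this kind of duplicate-miRNA network analysis: every step is a
tested library function, exercisable end-to-end on synthetic data with
planted, recoverable structure (no database downloads required).

## What it computes

**Seed-weighted sequence similarity.** Mature miRNAs are aligned with a
global (Needleman–Wunsch) alignment whose substitution weight depends on
the seed region (positions 2–8 from the 5′ end, 7mer convention): in-seed
match/mismatch scores ±5, out-of-seed ±1, gaps −2 (configurable; 6mer/8mer
windows and weights ±3…±6 are supported for sensitivity checks). A gene
pair's similarity is the maximum over all mature×mature alignments.

**Intragenic duplicate detection.** Given duplicate host-gene pairs,
candidate miRNA pairs are miRNAs fully contained in both hosts
(*bona fide* only) that conserve strand orientation relative to their
hosts; multi-miRNA hosts are resolved by a reciprocal-best-alignment-hit
(RBH) filter, with tied best hits discarded.

**Network curation.** Mature-level miRNA→target exports are evidence
filtered (tissue category, direct evidence, high-throughput method, top
score quantile), collapsed to miRNA-gene level (a mature produced by two
loci expands to both), and duplicate pairs with identical target sets —
indistinguishable in the databases — are excluded. PPI tables are
thresholded (confidence > 960) into an undirected network.

**Motif enrichment.** For each duplicate pair (subject), four motifs are
counted: V (common target), bifan (both miRNAs target both members of a
duplicate target pair of the same origin), PPI-bifan (the target pair also
interacts at the protein level), and PPI-delta (one miRNA targets both
members of a PPI-coupled duplicate pair). Each subject's count *n* is
compared against 1,000 (configurable) degree-preserving rewirings of the
bipartite network via the pairwise Z-score

```
Z = (n − n̄_null) / σ_null
```

with the degenerate-ensemble rules: σ_null = 0 and n̄_null ≠ 0 → the
subject is discarded; σ_null = 0 and n̄_null = 0 → Z = 0.

**Similarity & expression.** Target overlap is the Sørensen–Dice
coefficient S(A,B) = 2|A∩B|/(|A|+|B|); expression matrices are isoform
summed and per-sample normalized, with pair distances 1 − cosine
similarity and per-tissue WGD vs SSD median comparisons.

## Worked example

The numbered drivers under `analysis/` run the whole study on synthetic
data with planted structure (100 WGD pairs with target-overlap 0.3, 50%
given a planted bifan, PPI coupling 0.8; 100 SSD pairs with overlap 0.05
and nothing planted; +1 log-scale WGD expression shift):

```bash
cd analysis
python 01_simulate.py && python 03_catalog.py && python 05_enrichment.py
```

prints (seed 1):

```
Retained 30 intragenic pairs; exactly the planted set
V          median Z  WGD=13.68 SSD=2.30  bins WGD={'0': 0, '1-50': 100, '>50': 0} ...
BIFAN      median Z  WGD=0.00 SSD=0.00  bins WGD={'0': 50, '>=1': 50} SSD={'0': 100, '>=1': 0}
PPI_BIFAN  median Z  WGD=0.00 SSD=0.00  bins WGD={'0': 56, '>=1': 44} SSD={'0': 100, '>=1': 0}
V-motif median Z: WGD 13.7 vs SSD 2.3; pairs with >=1 PPI-bifan: WGD 44% vs SSD 0%
```

i.e. the planted asymmetries are recovered: the WGD group shows strong
V-motif enrichment against the degree-preserving null, half of WGD pairs
sit in at least one bifan (none of the SSD pairs do), and the catalog
stage returns exactly the planted intragenic pairs. `06_similarity_expression.py`
adds `Mean Sørensen-Dice: WGD=0.294, SSD=0.060` and
`WGD median expression exceeds SSD in 10/10 tissues`.

The same steps are available as a CLI (`ohnomir simulate|align|catalog|
network|enrich|similarity|expression|run-all|compare`); `ohnomir run-all
--seed 1 --out out/` writes every artifact plus a `report.json` whose
bytes are reproducible given the seed.

## Layout

- `src/ohnomir/` — the library: `synthetic`, `alignment`, `catalog`,
  `network`, `motifs`, `similarity`, `pipeline`, `cli`, `io`, `model`.
- `analysis/` — numbered narrative drivers writing tables to `results/`.
- `docs/methods.md` — models, parameters, numerical choices, limitations.
- `tests/` — unit, property (hypothesis) and acceptance suites.
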