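# Methods

## Overview

`srlens` quantifies where and why short-read (SR) metagenome assemblies fail
relative to long-read (LR) reference contigs. The unit of analysis is the
**window**: a fixed-width slice of an LR contig (default 1 kb, sliding by
500 bp). Because every window has the same length, per-window metrics —
percent recovery, depth, SNP load, graph structure — are directly comparable
across the whole assembly. The pipeline runs seven stages: windowing,
coverage filtering, alignment recovery, cross-assembler consistency, de
Bruijn graph metrics, gene-category enrichment, and bin-level aggregation.
A community simulator with planted coverage and strain-diversity structure
closes the loop so the whole pipeline runs with no external data or tools.

## Windowing

Windows of width `W` are emitted every `step` bases; a trailing residue
shorter than `W` is discarded so that all windows stay length-comparable
(`n = floor((L − W)/step) + 1` for a contig of length `L ≥ W`). Contigs
shorter than `W` yield no windows and are counted in the log. N bases are
allowed in windows and behave as mismatches during alignment. Window ids are
human-readable 1-based inclusive regions (`contig:start-end`); all internal
coordinates are 0-based half-open.

## Coverage filter

Per-base SR depth (3-column depth table, window- or contig-addressed) is
projected onto windows. A window enters the **reference set** iff at least a
fraction `min_breadth` (default 0.8) of its positions have depth ≥
`min_depth` (default 1): windows below that never had enough read
information to assemble, so scoring them would conflate "hard to assemble"
with "not sequenced". The boundary is inclusive (breadth exactly 0.8 is
retained). Windows are also classed low/high coverage at `cov_threshold`
(default 10x, mean depth ≥ threshold is high); the flag covers other
conventions.

SNPs are counted per window from a VCF (single-base REF, ≥ 1 single-base
ALT; optional quality cutoff, default none). A SNP in the 500 bp overlap
zone increments both windows — each window is scored independently. SNP
loads of window classes are compared with a two-sided Mann–Whitney U test
(exact null below 20 per group, normal approximation with tie correction
otherwise); the test is deliberately nonparametric because window SNP counts
are zero-inflated and overdispersed.

## Alignment and percent recovery

SR-assembled contigs are aligned to each window by seed-and-extend: exact
15-mer seeds on both strands, clustered by diagonal, each cluster resolved
by a full affine-gap Smith–Waterman over the spanned subject slice
(numba-compiled). Scoring is match +1, mismatch −2, gap open −5 for the
first gapped base and −2 for each additional base (the convention of the
SSW family of aligners; the test suite checks equivalence against
Biopython's independent dynamic-programming implementation). Only hits with
percent identity **strictly** above `min_identity` (default 99%) are kept;
the best hit per window and assembly is the longest one, ties broken by
identity then subject id so reruns are bit-identical.

**Percent recovery** = 100 × best-hit alignment columns / window length,
capped at 100. Alignment columns count matches + mismatches + gaps, so full
recovery requires a (near-)full-length single local alignment — chaining
across contigs is intentionally not performed. A window is *fully
assembled* at 100% recovery, *assembled at all* at ≥ 100 bp
(`any_assembled_min`). Best-hit lengths also define three recovery groups:
not recovered (0–499 bp), partially recovered (500–999 bp), fully recovered
(≥ 1 kb).

## Consistency (CA/NCA)

For one designated pair of assemblies, equal nonzero best-hit lengths make a
window **consistently assembled (CA)**; unequal lengths **NCA**. Windows
with no hit in either assembly are a third class, `unassembled`, rather
than CA — degenerate equality of zeros should not inflate agreement (a
strict-equality mode restores the two-class behavior). The difference in
percent recovery between the pair is histogrammed in half-open bins with a
dedicated closed [99, 100] bin that captures windows found by only one
assembler.

## De Bruijn graph metrics

For each retained window, the reads whose source interval overlaps the
window by ≥ 1 bp are collected and a compacted canonical de Bruijn graph is
built (default k = 31, no abundance filter). K-mers are counted in
canonical form (lexicographic min of k-mer and reverse complement; k odd
avoids self-complementary k-mers); maximal non-branching paths of the
bidirected graph are compacted into unitig nodes, the display unit of
assembly-graph viewers. Nodes sharing ≥ 1 canonical k-mer with the window
are flagged as **reference nodes** — an exact, deterministic criterion (a
shared 31-mer implies ≥ 96.8% local identity over its span) replacing
alignment-based flagging. Two metrics summarize local diversity:

- **graph size** — total node count; grows with the number of distinct
  sequence variants among the reads;
- **surrounding nodes** — non-reference nodes within ≤ `max_dist` (default
  3) edges of any reference node, by multi-source BFS on the undirected
  node graph; a proxy for how entangled the reference path is with variant
  paths, which is what actually derails an assembler.

Graphs can be exported/re-imported as GFA 1.0 (mean k-mer count and
reference flag as tags, (k−1)M overlaps).

## Gene enrichment

Each gene maps to the window containing its midpoint (earlier window on
ties) — windows overlap by 500 bp and midpoint assignment counts every gene
exactly once. The gene inherits the window's label: *fully* under the
chosen mode ("merged": 100% recovery in both designated assemblies; or a
single assembly label), *not fully* otherwise; genes on windows outside the
reference set are excluded. One two-sided Fisher's exact test per observed
COG category (genes with several letters count once per letter, standard
COG practice), Benjamini–Hochberg FDR across categories, direction from the
odds ratio relative to 1. Fractions of fully assembled genes are also
reported per gene type (CDS/tRNA/rRNA).

## Bin report

Windows with mean depth ≥ `min_cov` (default 1x) are cross-classified per
genome bin into {not/partially/fully recovered} × {low, high coverage}
cells; the six fractions sum to 1 per bin. Bins rank by fraction fully
recovered, descending, ties by bin id. A bin is "mostly fully recovered"
("mostly not recovered") if the respective fraction is at least 0.5 —
boundaries inclusive. The default low/high coverage boundary is 10x with a
flag, since both 10x and 20x conventions appear in practice. Bin summaries
are per assembly label (`bin_label`); the analysis uses the stronger
(bubble-popping) assembler so that bin ranking reflects island burden
rather than fragmentation noise at isolated variants.

## The community simulator

The simulator plants the two causal factors under study — coverage and
strain diversity — with known ground truth:

- **Genomes**: i.i.d. uniform DNA, default 3 × 50 kb (tests and analyses
  state their sizes per study); lognormal abundances (default σ = 1;
  studies isolating one factor set σ = 0 for equal abundances).
- **Haplotypes**: each genome has a major haplotype (emitted as the
  reference contig, standing in for an LR-assembled contig) and one minor
  haplotype at frequency f (default 0.3) carrying substitutions at
  `island_snp_density` (default 0.01/bp) inside a few non-overlapping
  **diversity islands** (default 2 × 5 kb) and `background_snp_density`
  (default 5e-4/bp) elsewhere — emulating strain-variable regions such as
  integrated viruses and defense islands over a quieter core.
- **Reads**: single-end 150 bp (pairing adds nothing to any implemented
  statistic), positions and strands uniform, i.i.d. substitution errors
  (default 1e-3), constant quality strings. Each genome extends a hidden
  flank of 2 × read length beyond both ends of the emitted reference
  contig and reads are drawn over the flanked genome, so reference windows
  see edge-free uniform coverage — as contigs embedded in larger replicons
  would. Depth tables and VCFs are emitted from read provenance, which
  preserves the exact file formats while avoiding an external mapper; no
  mapping noise is simulated.
- **Genes** tile each reference contig (default 300 bp, alternating
  strand; ~4% tRNA, ~2% rRNA). Island genes carry the mobilome category X
  with probability `mobile_cog_fraction_in_islands` (default 0.8);
  all other genes draw uniformly from the non-X COG alphabet.
- **Bins**: ground truth is the genome of origin.
- **Determinism**: a single integer seed fixes every output byte-for-byte.

### Toy assemblers

`toy_assemble` emits every maximal non-branching path of the canonical
k-mer graph (length ≥ k) after dropping k-mers below `min_count`, in
deterministic lexicographic order. Two personalities stand in for the two
real SR assemblers:

1. k = 21, no variant handling — fragments at every bubble;
2. k = 31 with **simple-bubble popping** — the minor branch of an isolated
   SNP bubble (branch length ≤ 2k + 2, flanks ≥ 150 bp) is removed when its
   mean k-mer count is ≤ 0.5 of the major branch's, then the graph is
   recompacted.

Real assembler pairs differ most in exactly this treatment of low-frequency
variants; without it, two unitig assemblies at different k have identical
best-hit lengths (unitig boundaries in sequence space sit exactly at the
variant positions, independent of k) and the NCA class would be empty.
With it, the pair agrees on clean sequence and disagrees where population
variation sits, which also reproduces the elevated SNP load of NCA windows.

The abundance cutoff `min_count` defaults to 2 but must scale with depth:
in deep libraries, recurrent errors (two reads substituting the same base
at the same position) exceed any fixed cutoff and shatter unitigs.
`suggested_min_count(depth) = max(2, depth/25)` keeps error k-mers out
while staying far below real haplotype k-mer coverage (e.g. 8 at 200x,
where the minor haplotype still has ~48x k-mer depth).

## Problem sizes

The packaged studies are sized to run on a single CPU in minutes while
keeping every statistical comparison properly powered: the depth gradient
uses 2 × 20 kb genomes at 1–30x; the diversity study 3 × 30 kb genomes with
2 × 6 kb islands at 200x (≥ 50 windows in each comparison group, ≥ 300
genes for enrichment); the bin study 10 × 15 kb genomes at 50x. All
qualitative conclusions — recovery rising with depth, island windows
recovering worse with larger and more connected graphs, the planted mobile
category enriched among poorly assembled genes, island-carrying bins
ranking last — are scale-free properties of the mechanism, not of these
sizes.

## Numerical and design notes

- The identity threshold is strict (> 99.0), so a 1000-column alignment
  with 10 mismatches (99.0%) is excluded.
- Best-hit ties and all output orders are resolved deterministically;
  two runs with the same seed and inputs are byte-identical.
- Fisher tests use scipy's exact implementation (validated against exact
  Fraction-arithmetic enumeration to 1e-9 in the tests); FDR is
  Benjamini–Hochberg via statsmodels.
- Windows shorter than k, empty read sets, empty graphs, bins with zero
  qualifying windows, and degenerate enrichment labelings (no gene in one
  group) all degrade gracefully and are logged.
- Mean depth uses all positions of a window; breadth uses the
  ≥ `min_depth` indicator, so the two can disagree on ragged coverage.

## Limitations

- The simulator has no indel errors, no quality-dependent error profile,
  no chimeric contigs, and no inter-genome homology; repeats — a major
  real-world assembly obstacle — are absent, so the pipeline's behavior on
  repeat-induced failure is untested here.
- The toy assemblers are unitig assemblers without scaffolding or multi-k
  merging; absolute recovery values are not comparable to real assemblers,
  only the contrasts between planted conditions are meaningful.
- Depth and variants come from read provenance, not mapping, so mapping
  bias and variant-calling noise are out of scope.
- Graph metrics at high depth include error-derived nodes (no abundance
  filter by default, matching the raw-read graphs the metrics emulate);
  contrasts between window groups remain valid because the error load is
  coverage-matched across groups.
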