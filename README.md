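# srlens

**Window-level evaluation of short-read metagenome assemblies against
long-read reference contigs.**

Short-read (SR) metagenome assemblies of complex communities — soil above
all — miss parts of most genomes, and the missing parts are not random.
`srlens` quantifies *where* an SR assembly fails relative to long-read (LR)
reference contigs and *why*: too little coverage, or too much
within-population sequence diversity. It is aimed at researchers who have
(or simulate) paired LR/SR data and want per-region, per-gene and per-bin
accounting of SR assembly blind spots.

## The method

LR contigs are split into 1 kb windows sliding by 500 bp. Windows with at
least 1x SR depth over ≥ 80% of their length form the reference set. For
each window *w* and SR assembly, contigs are aligned locally (seeds +
affine-gap Smith–Waterman; only hits with identity > 99% kept) and

```
percent recovery(w) = 100 · |best local alignment| / |w|
```

Two assemblies are compared per window: equal nonzero best-hit lengths →
consistently assembled (**CA**), unequal → **NCA**, neither assembled →
unassembled. For each window, the compacted de Bruijn graph of its
underlying reads is built (canonical k-mers, k = 31); nodes sharing a
k-mer with the window are the reference path, and two statistics measure
local population diversity: **graph size** (total nodes) and **surrounding
nodes** (non-reference nodes within ≤ 3 edges of the reference path).
Genes inherit their window's fully/not-fully assembled label via midpoint
assignment; per-COG-category 2×2 tables are tested with Fisher's exact
test and Benjamini–Hochberg FDR. Finally windows aggregate per genome bin
into {not/partially/fully recovered} × {low/high coverage} fractions.

A built-in simulator generates communities with lognormal abundances,
planted "diversity islands" (a 30% minor haplotype at 0.01 SNPs/bp),
island-concentrated mobilome genes, and known bins — plus two toy unitig
assemblers (one fragments at variants, one pops isolated bubbles) — so the
entire pipeline runs end-to-end with no external data or tools. See
`docs/methods.md` for the full model.

## Worked example

Simulate a deep strain-diverse community and contrast windows inside
diversity islands with clean windows at identical 200x coverage:

```bash
python analysis/02_diversity_islands.py
```

prints (abridged):

```
             metric  island_mean  clean_mean  mannwhitney_p  n_island  n_clean
recovery_toyasm_k21        28.47       89.31       3.75e-26        60       93
recovery_toyasm_k31        35.66       95.81       1.22e-27        60       93
         graph_size       554.02      525.59       1.56e-07        60       93
  surrounding_nodes       241.25      214.76       4.58e-15        60       93

consistency classes: {'CA': 127, 'NCA': 50}
planted mobile-element category X: q = 6.00e-20 (enriched_in_not_fully)
```

Island windows recover a third as much sequence as clean windows despite
identical depth, their read graphs are bigger and more entangled around the
reference path, and the gene category planted inside islands is strongly
enriched among not-fully-assembled genes — diversity, not data, is the
limiting factor there. `analysis/01_depth_gradient.py` shows the
complementary coverage effect (fraction of fully recovered windows rises
0.00 → 0.00 → 0.78 → 0.87 across 1/3/10/30x), and
`analysis/03_bin_report.py` shows every island-carrying genome's bin
ranking below every island-free bin. Tables land in `results/`.

The same stages run on real inputs (FASTA assemblies, samtools-depth
tables, VCFs, blast outfmt-6 hit tables, annotation and bin TSVs) through
the CLI:

```bash
srlens all --reference lr.fasta --assembly megahit mh.fasta \
  --assembly metaspades ms.fasta --depth-tsv depth.tsv --vcf snps.vcf \
  --annotations-tsv genes.tsv --bins-tsv bins.tsv --outdir out/
```

(subcommands `simulate`, `windows`, `filter`, `recover`, `graph`,
`enrich`, `bins` run individual stages; `recover --hits-tsv LABEL FILE`
consumes precomputed alignment tables instead of the internal aligner).

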